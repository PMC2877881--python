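"""Empirical response-function estimation and variance partitioning.

If evoked skin-conductance responses really are scaled copies of one
template, the first principal component of the epoch matrix should be that
template, and its explained-variance fraction quantifies how far the
time-invariance assumption holds. The PCA here deliberately decomposes the
uncentred second-moment matrix of the (row-mean-centred) epochs: removing
the cross-epoch column mean would fold the common response shape itself into
the mean and leave PC1 describing deviations from it, which is not the
quantity of interest.

Variance is partitioned into a component common to all subjects (pooled
PC1), a between-subjects shape component (how much better each subject's own
PC1 does than the pooled one), and a residual that one response function per
subject cannot explain. The three fractions decompose the pooled variance
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_signal import EpochMatrix, EventSeries, SignalRecord
from .preprocess import FilterSpec, preprocess_chain

__all__ = [
    "PCAResult",
    "VariancePartition",
    "LagCorrelation",
    "epoch_pca",
    "variance_partition",
    "baseline_ratio",
    "filter_sweep",
    "lagged_correlation",
]


@dataclass
class PCAResult:
    """Eigen-decomposition of the epochs' uncentred second-moment matrix."""

    components: np.ndarray        # k x n_samples, orthonormal rows
    eigenvalues: np.ndarray       # descending, eigenvalues of X^T X
    explained_fraction: np.ndarray
    n_epochs: int


@dataclass
class VariancePartition:
    """Decomposition of pooled epoch variance into three exact fractions."""

    common: float
    between_subjects: float
    residual: float
    per_subject: list[float]

    def as_dict(self) -> dict[str, float | list[float]]:
        return {
            "common": self.common,
            "between_subjects": self.between_subjects,
            "residual": self.residual,
            "per_subject": list(self.per_subject),
        }


@dataclass
class LagCorrelation:
    """Shared variance (Pearson r^2) between two channels over a lag grid."""

    lags: np.ndarray
    r2: np.ndarray
    best_lag: float
    best_r2: float


def epoch_pca(epochs: EpochMatrix, k: int | None = None) -> PCAResult:
    """PCA of the included epochs without column-centring.

    Equivalent to the dense eigen-decomposition of M = X^T X, computed via
    the SVD of X for numerical robustness. Component 1 is oriented so its
    largest-magnitude sample is positive (SCRs deflect upward).
    """
    X = epochs.included_data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-excluded epochs")
    total = float(np.sum(X**2))
    if total == 0.0:
        raise ValueError("all-zero epoch matrix")
    kmax = min(X.shape)
    k = kmax if k is None else k
    if k > kmax:
        raise ValueError(f"k={k} exceeds min(n_epochs, n_samples)={kmax}")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s[:k] ** 2
    components = vt[:k].copy()
    for i in range(components.shape[0]):
        extreme = components[i, np.argmax(np.abs(components[i]))]
        if extreme < 0:
            components[i] = -components[i]
    return PCAResult(
        components=components,
        eigenvalues=eigenvalues,
        explained_fraction=eigenvalues / total,
        n_epochs=X.shape[0],
    )


def variance_partition(per_subject_epochs: Sequence[EpochMatrix]) -> VariancePartition:
    """Partition pooled epoch variance into common / between-subjects / residual.

    ``common`` is the fraction explained by the pooled PC1 over all subjects'
    epochs concatenated. Each subject's own PC1 fraction is combined across
    subjects weighted by that subject's total epoch variance, so the three
    components sum to 1 exactly. Because each subject's own PC1 is optimal
    for that subject, the weighted within-subject fraction can never fall
    below the pooled fraction, hence ``between_subjects`` >= 0 up to
    round-off.
    """
    if len(per_subject_epochs) < 2:
        raise ValueError("need at least 2 subjects")
    lam1 = []
    totals = []
    per_subject = []
    blocks = []
    for ep in per_subject_epochs:
        res = epoch_pca(ep, k=1)
        X = ep.included_data
        blocks.append(X)
        totals.append(float(np.sum(X**2)))
        lam1.append(float(res.eigenvalues[0]))
        per_subject.append(float(res.explained_fraction[0]))
    pooled = np.vstack(blocks)
    s1 = np.linalg.svd(pooled, compute_uv=False)[0]
    grand_total = float(np.sum(totals))
    common = s1**2 / grand_total
    within = float(np.sum(lam1)) / grand_total
    return VariancePartition(
        common=common,
        between_subjects=within - common,
        residual=1.0 - within,
        per_subject=per_subject,
    )


def baseline_ratio(evoked: EpochMatrix, baseline: EpochMatrix) -> float:
    """Baseline variance as a fraction of evoked-epoch variance.

    Both epoch sets must come through a shared z-transform (one
    standardisation of the whole continuous series) or the ratio is
    meaningless. Rows are mean-centred and variance pooled over epochs and
    samples; unequal epoch counts are handled by using mean squares.
    """
    ev = evoked.included_data
    bl = baseline.included_data
    ev = ev - ev.mean(axis=1, keepdims=True)
    bl = bl - bl.mean(axis=1, keepdims=True)
    denom = float(np.mean(ev**2))
    if denom == 0.0:
        raise ValueError("evoked epochs have zero variance")
    return float(np.mean(bl**2)) / denom


def filter_sweep(
    raw: SignalRecord,
    events: EventSeries,
    cutoffs: Sequence[float] = (0.0, 0.005, 0.01, 0.015, 0.02, 0.025),
    lp_cutoff: float = 5.0,
    target_fs: float = 10.0,
    epoch_len: float = 30.0,
) -> list[tuple[float, float]]:
    """Explained PC1 fraction as a function of the high-pass cut-off.

    Reruns the full preprocessing chain for each cut-off (0 = no high-pass)
    and reports the first-component explained-variance fraction, probing how
    strongly the necessary high-pass filtering shapes the apparent response.
    """
    for c in cutoffs:
        if c >= lp_cutoff:
            raise ValueError(f"cutoff {c} not below lp_cutoff {lp_cutoff}")
    out = []
    for c in cutoffs:
        spec = FilterSpec(hp_cutoff=c, lp_cutoff=lp_cutoff)
        _, epochs = preprocess_chain(raw, events, spec=spec,
                                     target_fs=target_fs, epoch_len=epoch_len)
        res = epoch_pca(epochs, k=1)
        out.append((float(c), float(res.explained_fraction[0])))
    return out


def lagged_correlation(a: SignalRecord, b: SignalRecord,
                       max_lag: float) -> LagCorrelation:
    """Pearson r^2 between a(t) and b(t + lag) over a symmetric lag grid.

    Lags run over every sample step in [-max_lag, max_lag]. ``best_lag`` is
    the argmax of r^2 with ties broken toward the smaller absolute lag; a
    negative best lag means b leads a.
    """
    if abs(a.fs - b.fs) > 1e-9:
        raise ValueError("signals must share a sampling rate")
    fs = a.fs
    m = min(a.n_samples, b.n_samples)
    L = int(round(max_lag * fs))
    if L < 1:
        raise ValueError("max_lag must cover at least one sample")
    if (m - L) / fs < 10.0 * max_lag:
        raise ValueError("overlapping support must be >= 10 x max_lag")
    xa = a.values[:m]
    xb = b.values[:m]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("constant input")
    ks = np.arange(-L, L + 1)
    r2 = np.empty(ks.size)
    for idx, k in enumerate(ks):
        if k >= 0:
            x, y = xa[: m - k], xb[k:m]
        else:
            x, y = xa[-k:m], xb[: m + k]
        r = np.corrcoef(x, y)[0, 1]
        r2[idx] = r * r
    best_idx = 0
    best = -1.0
    for idx in np.argsort(np.abs(ks), kind="stable"):
        if r2[idx] > best:
            best = r2[idx]
            best_idx = idx
    return LagCorrelation(
        lags=ks / fs,
        r2=r2,
        best_lag=float(ks[best_idx] / fs),
        best_r2=float(r2[best_idx]),
    )
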