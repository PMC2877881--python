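"""Convolution GLM: stick-function designs, amplitude estimation, linearity test.

Under the LTI model the measured signal is the convolution of sudomotor
input — idealised as unit impulses ("stick functions") at the event onsets —
with a response template, so each regressor is a shifted copy of a basis
function and the fitted coefficient is the response amplitude for that
event. A constant column absorbs the trial's baseline level.

The linearity analysis follows the paired-stimulus logic: estimate each
subject's response template from single-stimulus trials (PC1), fit every
double-stimulus trial with two shifted copies of that template plus a
constant, and ask whether the amplitude of the second response depends on
the inter-stimulus interval. Under superposition plus a purely neural
repetition effect, the second/first amplitude ratio is flat across ISIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .empirical_rf import epoch_pca
from .io_signal import EpochMatrix, EventSeries
from .response_model import BasisSet

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "LinearityReport",
    "build_design",
    "fit",
    "linearity_analysis",
    "paired_epochs",
]


@dataclass
class DesignMatrix:
    X: np.ndarray                      # n_samples x n_regressors
    names: list[str]
    fs: float
    event_map: list[dict] = field(default_factory=list)

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


@dataclass
class GLMFit:
    beta: np.ndarray
    se: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    residual_var: float                # fraction of total sum of squares
    names: list[str]

    @property
    def explained_var(self) -> float:
        return 1.0 - self.residual_var


def _shifted(row: np.ndarray, shift: int, n: int) -> np.ndarray:
    """Basis row convolved with a unit impulse at ``shift``, truncated at n."""
    col = np.zeros(n)
    avail = min(row.size, n - shift)
    if avail > 0:
        col[shift:shift + avail] = row[:avail]
    return col


def build_design(
    events: EventSeries,
    basis: BasisSet,
    n_samples: int,
    fs: float,
    per_event: bool = True,
) -> DesignMatrix:
    """Convolve each stick function with each basis row; append a constant.

    With ``per_event`` every event gets its own regressor set (per-trial
    amplitudes); otherwise events sharing a label share regressors, their
    shifted copies summing by superposition.
    """
    if abs(basis.fs - fs) > 1e-9:
        raise ValueError("basis sampling rate must match design rate")
    cols: list[np.ndarray] = []
    names: list[str] = []
    event_map: list[dict] = []
    labels = events.labels if events.labels is not None else [""] * len(events)

    def onset_sample(onset: float) -> int:
        s = int(round(onset * fs))
        if not (0 <= s < n_samples):
            raise ValueError(f"onset {onset} s outside [0, {n_samples / fs}) s")
        return s

    if per_event:
        for i, onset in enumerate(events.onsets):
            s = onset_sample(onset)
            for bi in range(basis.n_basis):
                cols.append(_shifted(basis.matrix[bi], s, n_samples))
                names.append(f"ev{i}_{basis.names[bi]}")
                event_map.append({"events": [i], "basis": basis.names[bi]})
    else:
        seen: dict[str, int] = {}
        order: list[str] = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(order)
                order.append(lab)
        for lab in order:
            idx = [i for i, l in enumerate(labels) if l == lab]
            for bi in range(basis.n_basis):
                col = np.zeros(n_samples)
                for i in idx:
                    col += _shifted(basis.matrix[bi], onset_sample(events.onsets[i]),
                                    n_samples)
                cols.append(col)
                tag = lab if lab else "all"
                names.append(f"{tag}_{basis.names[bi]}")
                event_map.append({"events": idx, "basis": basis.names[bi]})
    for j, col in enumerate(cols):
        if not np.any(col):
            raise ValueError(f"regressor {names[j]} is all zero")
    cols.append(np.ones(n_samples))
    names.append("constant")
    event_map.append({"events": [], "basis": "constant"})
    return DesignMatrix(X=np.column_stack(cols), names=names, fs=fs,
                        event_map=event_map)


def fit(y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares via a rank-revealing solve.

    Raises on rank deficiency (e.g. two events at the same onset make their
    regressors collinear). Standard errors assume i.i.d. residuals.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = design.X
    if y.size != X.shape[0]:
        raise ValueError(f"y has {y.size} samples, design has {X.shape[0]}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            "check for collinear regressors"
        )
    fitted = X @ beta
    residual = y - fitted
    total = float(np.sum(y**2))
    rss = float(np.sum(residual**2))
    dof = max(y.size - X.shape[1], 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return GLMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        fitted=fitted,
        residual=residual,
        residual_var=rss / total if total > 0 else 0.0,
        names=list(design.names),
    )


@dataclass
class LinearityReport:
    """Repetition x ISI amplitude table and within-subject slopes.

    ``trials`` holds one row per double trial with the fitted first and
    second amplitudes. ``amplitudes`` is the subject x ISI x repetition mean
    table. ``slopes`` holds the within-subject OLS slope of the second on the
    first amplitude, per ISI and pooled; ``slope_t``/``slope_p`` are the
    one-sample t-test of the pooled slopes against zero across subjects.
    """

    trials: pd.DataFrame
    amplitudes: pd.DataFrame
    slopes: pd.DataFrame
    slope_t: float
    slope_p: float
    per_isi_t: dict[float, tuple[float, float]]

    def mean_ratio(self, isi: float) -> float:
        """Group-level second/first amplitude ratio (ratio of mean betas)."""
        sub = self.trials[self.trials["isi"] == isi]
        return float(sub["beta2"].mean() / sub["beta1"].mean())

    def ratio_trend_slope(self) -> float:
        """OLS slope of the per-ISI mean ratio against ISI, per second."""
        isis = sorted(self.trials["isi"].unique())
        ratios = [self.mean_ratio(i) for i in isis]
        return float(np.polyfit(isis, ratios, 1)[0])


def paired_epochs(
    processed,
    events: EventSeries,
    subject: str = "",
    single_len: float = 30.0,
    pre_onset: float = 10.0,
):
    """Split a paired-stimulus session into single and double-trial epochs.

    Expects event labels of the form ``"single"``, ``"first_isi<d>"`` and
    ``"second_isi<d>"`` (as emitted by the paired simulation scenario).

    Epochs start ``pre_onset`` seconds *before* the (first) onset: zero-phase
    band-pass filtering makes the effective response acausal — every filtered
    response carries a slow dip that precedes its onset — so a purely causal
    template would leave the pre-onset portion of the second response
    unmodelled and bias its amplitude upward, the more so the longer the ISI.
    With the template estimated over [-pre_onset, single_len) from single
    trials and double-trial windows of [-pre_onset, single_len + max ISI),
    both regressors cover their response's full filtered extent and the
    amplitude ratio is recovered without ISI-dependent bias. Epochs whose
    pre-window starts before the recording are flagged excluded.

    Returns ``(singles, doubles)`` with ``doubles`` keyed by ISI in seconds;
    the within-epoch shift between the two regressors remains exactly the
    ISI, so downstream fitting needs no knowledge of ``pre_onset``.
    """
    from .preprocess import extract_epochs  # deferred: preprocess imports io only

    if events.labels is None:
        raise ValueError("paired analysis needs labelled events")
    labels = events.labels
    single_onsets = [o for o, l in zip(events.onsets, labels) if l == "single"]
    isis = sorted(
        {float(l.split("first_isi")[1]) for l in labels if l.startswith("first_isi")}
    )
    if not isis:
        raise ValueError("no double trials found in event labels")
    fs = processed.fs
    # keep epoch_len * fs integral for any analysis rate
    s_len = np.ceil((single_len + pre_onset) * fs) / fs
    d_len = np.ceil((single_len + max(isis) + pre_onset) * fs) / fs
    singles = extract_epochs(
        processed, EventSeries(np.asarray(single_onsets) - pre_onset),
        epoch_len=s_len, subject=subject,
    )
    doubles = {}
    for isi in isis:
        firsts = [o for o, l in zip(events.onsets, labels)
                  if l == f"first_isi{isi:g}"]
        doubles[isi] = extract_epochs(
            processed, EventSeries(np.asarray(firsts) - pre_onset),
            epoch_len=d_len, subject=subject,
        )
    return singles, doubles


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    vx = np.var(x)
    if vx == 0:
        return float("nan")
    return float(np.cov(x, y, ddof=0)[0, 1] / vx)


def linearity_analysis(
    singles: EpochMatrix,
    doubles: Mapping[float, EpochMatrix],
    fs: float | None = None,
) -> LinearityReport:
    """Per-subject template estimation and double-trial amplitude fits.

    For every subject (identified by ``meta.subject``): PC1 of that
    subject's single-stimulus epochs is the response template; each double
    trial of ISI ``d`` is fitted with [template@0, template@d, constant].
    Flat or non-responsive trials are kept — dropping them would bias the
    residual-variance picture.
    """
    fs = fs if fs is not None else singles.fs
    subjects = sorted(set(singles.meta["subject"]))
    rows = []
    for subj in subjects:
        s_mask = (singles.meta["subject"] == subj).to_numpy()
        s_sub = singles.subset(s_mask)
        if s_sub.included.sum() < 2:
            raise ValueError(f"subject {subj!r}: need >= 2 single trials")
        rf = epoch_pca(s_sub, k=1).components[0]
        if not np.any(rf):
            raise ValueError(f"subject {subj!r}: degenerate response template")
        for isi, dep in doubles.items():
            shift = int(round(isi * fs))
            d_mask = (dep.meta["subject"] == subj).to_numpy() & dep.included
            data = dep.data[d_mask]
            n = data.shape[1]
            X = np.column_stack(
                [_shifted(rf, 0, n), _shifted(rf, shift, n), np.ones(n)]
            )
            design = DesignMatrix(X=X, names=["first", "second", "constant"],
                                  fs=fs)
            for trial_i, y in enumerate(data):
                f = fit(y, design)
                rows.append(
                    {"subject": subj, "isi": float(isi), "trial": trial_i,
                     "beta1": f.beta[0], "beta2": f.beta[1]}
                )
    trials = pd.DataFrame(rows)
    amp = (
        trials.melt(id_vars=["subject", "isi"], value_vars=["beta1", "beta2"],
                    var_name="repetition", value_name="beta")
        .replace({"repetition": {"beta1": "first", "beta2": "second"}})
        .groupby(["subject", "isi", "repetition"], as_index=False)["beta"]
        .mean()
    )
    slope_rows = []
    pooled_slopes = []
    for subj in subjects:
        sub = trials[trials["subject"] == subj]
        for isi in sorted(sub["isi"].unique()):
            g = sub[sub["isi"] == isi]
            if len(g) < 2:
                raise ValueError(
                    f"subject {subj!r}, ISI {isi}: need >= 2 trials for a slope"
                )
            slope_rows.append(
                {"subject": subj, "isi": isi,
                 "slope": _ols_slope(g["beta1"].to_numpy(), g["beta2"].to_numpy())}
            )
        pooled = _ols_slope(sub["beta1"].to_numpy(), sub["beta2"].to_numpy())
        slope_rows.append({"subject": subj, "isi": "pooled", "slope": pooled})
        pooled_slopes.append(pooled)
    slopes = pd.DataFrame(slope_rows)

    def one_sample_t(vals) -> tuple[float, float]:
        # undefined with a single subject: report NaN rather than warn
        if len(vals) < 2:
            return float("nan"), float("nan")
        r = stats.ttest_1samp(vals, 0.0)
        return float(r.statistic), float(r.pvalue)

    t_stat, p_val = one_sample_t(pooled_slopes)
    per_isi_t = {}
    for isi in sorted(trials["isi"].unique()):
        vals = slopes[(slopes["isi"] == isi)]["slope"].to_numpy(dtype=float)
        per_isi_t[float(isi)] = one_sample_t(vals)
    return LinearityReport(
        trials=trials,
        amplitudes=amp,
        slopes=slopes,
        slope_t=t_stat,
        slope_p=p_val,
        per_isi_t=per_isi_t,
    )
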