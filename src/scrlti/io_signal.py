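"""Containers and plain-text I/O for skin-conductance time series, events and epochs.

All files are UTF-8 delimited text. ``#``-prefixed header lines carry metadata
as ``key=value`` pairs, so every fixture stays human-readable. Times are in
seconds throughout; conductance is in the units of the source recording
(microsiemens for raw data, dimensionless after z-scoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "EventSeries",
    "EpochMatrix",
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
    "read_epochs",
    "write_epochs",
]

#: metadata columns every EpochMatrix carries, one row per epoch
META_COLUMNS = ("subject", "condition", "onset", "excluded")


@dataclass
class SignalRecord:
    """A uniformly sampled conductance time series.

    Parameters
    ----------
    values : ndarray
        Conductance samples. Must be finite; gaps are an error at load time,
        never silently interpolated away.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    label : str
        Channel name, e.g. ``"palm"``, ``"finger"``, ``"foot"``.
    resampled : bool
        True when the loader interpolated non-uniform timestamps onto a
        uniform grid.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "scr"
    resampled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.size < 2:
            raise ValueError("a signal needs at least 2 samples")
        bad = ~np.isfinite(self.values)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} non-finite sample(s) at indices "
                f"{np.flatnonzero(bad)[:5].tolist()}... — gaps must be handled "
                "explicitly, not loaded"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds (n / fs)."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def copy_with(self, **kwargs) -> "SignalRecord":
        return replace(self, **kwargs)


@dataclass
class EventSeries:
    """Ordered event onsets in seconds, with optional condition labels."""

    onsets: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing (duplicates rejected)")
        if self.labels is not None and len(self.labels) != self.onsets.size:
            raise ValueError("labels length must match onsets")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class EpochMatrix:
    """n_epochs x n_samples matrix of post-onset segments plus provenance.

    ``meta`` has one row per epoch with columns ``subject``, ``condition``,
    ``onset`` (seconds, absolute signal time) and ``excluded`` (bool). Rows
    flagged excluded are dropped from every downstream statistic but kept in
    the container so exclusions stay auditable.
    """

    data: np.ndarray
    fs: float
    epoch_len: float
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            self.data = self.data.reshape(0, int(round(self.epoch_len * self.fs)))
        n_expected = int(round(self.epoch_len * self.fs))
        if self.data.shape[1] != n_expected:
            raise ValueError(
                f"n_samples {self.data.shape[1]} != round(epoch_len*fs) = {n_expected}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "subject": [""] * self.n_epochs,
                    "condition": [""] * self.n_epochs,
                    "onset": np.zeros(self.n_epochs),
                    "excluded": np.zeros(self.n_epochs, dtype=bool),
                }
            )
        if len(self.meta) != self.n_epochs:
            raise ValueError("meta must have one row per epoch")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ValueError(f"meta missing columns: {sorted(missing)}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of epochs that enter statistics."""
        return ~self.meta["excluded"].to_numpy(dtype=bool)

    @property
    def included_data(self) -> np.ndarray:
        return self.data[self.included]

    @staticmethod
    def concat(parts: Sequence["EpochMatrix"]) -> "EpochMatrix":
        """Stack epoch matrices that share fs and epoch_len."""
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if abs(p.fs - first.fs) > 1e-9 or abs(p.epoch_len - first.epoch_len) > 1e-9:
                raise ValueError("epoch matrices differ in fs or epoch_len")
        return EpochMatrix(
            data=np.vstack([p.data for p in parts]),
            fs=first.fs,
            epoch_len=first.epoch_len,
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
        )

    def subset(self, mask) -> "EpochMatrix":
        mask = np.asarray(mask)
        return EpochMatrix(
            data=self.data[mask],
            fs=self.fs,
            epoch_len=self.epoch_len,
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_headers(lines: Sequence[str]) -> dict[str, str]:
    headers: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body and not body.startswith("epoch\t"):
            key, _, value = body.partition("=")
            headers[key.strip()] = value.strip()
    return headers


def _load_table(path) -> tuple[np.ndarray, dict[str, str], list[str]]:
    raw_lines = Path(path).read_text(encoding="utf-8").splitlines()
    comment_lines = [ln for ln in raw_lines if ln.startswith("#")]
    data_lines = [ln for ln in raw_lines if ln.strip() and not ln.startswith("#")]
    headers = _parse_headers(comment_lines)
    rows = []
    for i, ln in enumerate(data_lines):
        parts = ln.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}: unparsable line {i + 1}: {ln!r}") from exc
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: inconsistent column counts")
    return np.asarray(rows, dtype=float), headers, comment_lines


# ---------------------------------------------------------------------------
# signals


def read_signal(path, fs_override: float | None = None) -> SignalRecord:
    """Read a signal file: (time, value) columns, or one value column + rate.

    The sampling rate comes from ``fs_override``, then a ``# fs=`` header,
    then (two-column files only) the timestamps themselves. Non-uniform
    timestamps are linearly interpolated onto a uniform grid at the stated
    rate and the result is marked ``resampled``; the lowest observed input
    rate triggers a warning when it falls below 10 Hz, where aliasing from
    a variable-rate source becomes a concern.
    """
    arr, headers, _ = _load_table(path)
    if arr.size == 0:
        raise ValueError(f"{path}: no data")
    t0 = float(headers.get("t0", 0.0))
    label = headers.get("label", "scr")
    header_fs = float(headers["fs"]) if "fs" in headers else None
    stated_fs = fs_override if fs_override is not None else header_fs

    if arr.shape[1] == 1:
        if stated_fs is None:
            raise ValueError(f"{path}: single-column file needs fs (header or override)")
        return SignalRecord(arr[:, 0], fs=stated_fs, t0=t0, label=label)

    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected 1 or 2 columns, got {arr.shape[1]}")
    t, v = arr[:, 0], arr[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    dt0 = float(np.median(dt))
    uniform = np.allclose(dt, dt0, rtol=1e-6, atol=1e-9 * max(dt0, 1.0))
    if uniform:
        return SignalRecord(v, fs=1.0 / dt0, t0=float(t[0]), label=label)
    # non-uniform: reconstruct a waveform on a uniform grid
    fs = stated_fs if stated_fs is not None else 1.0 / dt0
    lowest_rate = 1.0 / float(dt.max())
    if lowest_rate < 10.0:
        warnings.warn(
            f"{path}: lowest input rate {lowest_rate:.2f} Hz < 10 Hz; "
            "interpolated values may alias",
            stacklevel=2,
        )
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    values = np.interp(grid, t, v)
    return SignalRecord(values, fs=fs, t0=float(t[0]), label=label, resampled=True)


def write_signal(signal: SignalRecord, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={float(signal.fs)!r}\n# t0={float(signal.t0)!r}\n"
                 f"# label={signal.label}\n")
        for v in signal.values:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# events


def read_events(path) -> EventSeries:
    """Read an event file: one onset per line, optional second token = label."""
    raw_lines = Path(path).read_text(encoding="utf-8").splitlines()
    onsets: list[float] = []
    labels: list[str] = []
    any_label = False
    for i, ln in enumerate(raw_lines):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.replace(",", " ").split()
        try:
            onsets.append(float(parts[0]))
        except ValueError as exc:
            raise ValueError(f"{path}: unparsable line {i + 1}: {ln!r}") from exc
        if len(parts) > 1:
            any_label = True
            labels.append(" ".join(parts[1:]))
        else:
            labels.append("")
    order = np.argsort(onsets, kind="stable")
    sorted_onsets = np.asarray(onsets, dtype=float)[order]
    if np.any(np.diff(sorted_onsets) == 0):
        dup = sorted_onsets[np.flatnonzero(np.diff(sorted_onsets) == 0)[0]]
        raise ValueError(f"{path}: duplicate onset {dup}")
    sorted_labels = [labels[j] for j in order] if any_label else None
    return EventSeries(sorted_onsets, sorted_labels)


def write_events(events: EventSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, onset in enumerate(events.onsets):
            if events.labels is not None and events.labels[i]:
                fh.write(f"{float(onset)!r}\t{events.labels[i]}\n")
            else:
                fh.write(f"{float(onset)!r}\n")


# ---------------------------------------------------------------------------
# epochs


def write_epochs(epochs: EpochMatrix, path) -> None:
    """Write an EpochMatrix; round-trips losslessly (repr floats, tab meta)."""
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("refusing to write non-finite epoch data")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={float(epochs.fs)!r}\n")
        fh.write(f"# epoch_len={float(epochs.epoch_len)!r}\n")
        fh.write(f"# n_samples={epochs.n_samples}\n")
        for _, row in epochs.meta.iterrows():
            fh.write(
                "# epoch\t{}\t{}\t{}\t{}\n".format(
                    row["subject"], row["condition"], repr(float(row["onset"])),
                    int(bool(row["excluded"])),
                )
            )
        for row in epochs.data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_epochs(path) -> EpochMatrix:
    arr, headers, comment_lines = _load_table(path)
    for key in ("fs", "epoch_len"):
        if key not in headers:
            raise ValueError(f"{path}: missing '# {key}=' header")
    fs = float(headers["fs"])
    epoch_len = float(headers["epoch_len"])
    subjects, conditions, onsets, excluded = [], [], [], []
    for ln in comment_lines:
        body = ln.lstrip("#").strip("\n")
        body = body[1:] if body.startswith(" ") else body
        if body.startswith("epoch\t"):
            parts = body.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: malformed epoch meta line: {ln!r}")
            subjects.append(parts[1])
            conditions.append(parts[2])
            onsets.append(float(parts[3]))
            excluded.append(bool(int(parts[4])))
    n_samples = int(headers.get("n_samples", round(epoch_len * fs)))
    if arr.size == 0:
        arr = np.empty((0, n_samples))
    if arr.shape[0] != len(subjects):
        raise ValueError(
            f"{path}: {arr.shape[0]} data rows but {len(subjects)} meta lines"
        )
    meta = pd.DataFrame(
        {"subject": subjects, "condition": conditions, "onset": onsets,
         "excluded": excluded}
    )
    return EpochMatrix(arr, fs=fs, epoch_len=epoch_len, meta=meta)
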