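"""Preprocessing chain for skin-conductance recordings.

The standard pipeline mirrors common practice for event-related
electrodermal analysis: a zero-phase (bidirectional) first-order Butterworth
band-pass, decimation to a modest analysis rate, whole-series z-scoring to
absorb between-subject amplitude differences of peripheral origin, and
extraction of fixed-length post-onset epochs that are mean-centred per trial
because skin conductance level drifts between trials even after filtering.

Default cut-offs are 0.0159 Hz (first-order time constant 1/(2*pi*f) = 10 s)
and 5 Hz, with a 10 Hz analysis rate and 30 s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_signal import EpochMatrix, EventSeries, SignalRecord

__all__ = [
    "FilterSpec",
    "time_constant",
    "bandpass",
    "downsample",
    "ztransform",
    "extract_epochs",
    "preprocess_chain",
]

DEFAULT_HP = 0.0159
DEFAULT_LP = 5.0
DEFAULT_TARGET_FS = 10.0
DEFAULT_EPOCH_LEN = 30.0


def time_constant(cutoff_hz: float) -> float:
    """First-order filter time constant tau = 1/(2*pi*f) in seconds."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return 1.0 / (2.0 * np.pi * cutoff_hz)


@dataclass
class FilterSpec:
    """Band-pass configuration.

    ``hp_cutoff`` = 0 disables the high-pass (low-pass only). ``bidirectional``
    applies each filter forward and backward (zero phase); the effective
    magnitude response is then the squared single-pass magnitude.
    """

    hp_cutoff: float = DEFAULT_HP
    lp_cutoff: float = DEFAULT_LP
    order: int = 1
    bidirectional: bool = True

    def validate(self, fs: float) -> None:
        if self.hp_cutoff < 0:
            raise ValueError("hp_cutoff must be >= 0")
        if self.lp_cutoff <= self.hp_cutoff:
            raise ValueError("hp_cutoff must be below lp_cutoff")
        if self.lp_cutoff >= fs / 2:
            raise ValueError(
                f"lp_cutoff {self.lp_cutoff} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _filtfilt_one(x: np.ndarray, fs: float, cutoff: float, btype: str,
                  order: int, bidirectional: bool) -> np.ndarray:
    b, a = sps.butter(order, cutoff, btype=btype, fs=fs)
    if not bidirectional:
        zi = sps.lfilter_zi(b, a) * x[0]
        y, _ = sps.lfilter(b, a, x, zi=zi)
        return y
    # odd-symmetric extension of ~3/cutoff seconds, clipped to the signal
    padlen = min(int(round(3.0 * fs / cutoff)), x.size - 2)
    return sps.filtfilt(b, a, x, padtype="odd", padlen=max(padlen, 0))


def bandpass(record: SignalRecord, spec: FilterSpec | None = None) -> SignalRecord:
    """Zero-phase Butterworth band-pass; same length and rate as the input.

    High-pass and low-pass sections are first-order (by default) and applied
    as a cascade, each forward-backward. Signals shorter than three times the
    longest filter time constant are rejected: the transient would dominate.
    """
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    longest_tc = time_constant(spec.hp_cutoff if spec.hp_cutoff > 0 else spec.lp_cutoff)
    if record.duration < 3.0 * longest_tc:
        raise ValueError(
            f"signal of {record.duration:.1f} s shorter than filter warm-up "
            f"{3.0 * longest_tc:.1f} s"
        )
    y = _filtfilt_one(record.values, record.fs, spec.lp_cutoff, "lowpass",
                      spec.order, spec.bidirectional)
    if spec.hp_cutoff > 0:
        y = _filtfilt_one(y, record.fs, spec.hp_cutoff, "highpass",
                          spec.order, spec.bidirectional)
    return record.copy_with(values=y)


def downsample(record: SignalRecord, target_fs: float) -> SignalRecord:
    """Decimate by an integer factor, keeping every (fs/target_fs)-th sample.

    The signal must already be low-pass filtered below ``target_fs/2``; this
    function does not filter.
    """
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs {record.fs} Hz is not an integer multiple of target {target_fs} Hz"
        )
    step = int(round(ratio))
    if step == 1:
        return record.copy_with()
    return record.copy_with(values=record.values[::step].copy(), fs=target_fs)


def ztransform(record: SignalRecord) -> SignalRecord:
    """Standardise to mean 0, population SD 1 over the whole series.

    Applied once per subject and channel across the entire continuous
    recording, so evoked and baseline segments share one standardisation.
    """
    sd = float(np.std(record.values))
    if sd == 0.0:
        raise ValueError("cannot z-transform a constant signal")
    return record.copy_with(values=(record.values - np.mean(record.values)) / sd)


def extract_epochs(
    record: SignalRecord,
    events: EventSeries,
    epoch_len: float = DEFAULT_EPOCH_LEN,
    mean_centre: bool = True,
    subject: str = "",
) -> EpochMatrix:
    """Extract the ``epoch_len`` seconds following each event onset.

    Epoch sample 0 is the first sample at or after the onset (half-open
    window). Epochs that run past the end of the recording are zero-padded
    and flagged excluded rather than silently dropped. When ``mean_centre``
    is set, each row has its own mean removed, because tonic level can still
    differ between trials after filtering.
    """
    n_samp = epoch_len * record.fs
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError("epoch_len * fs must be integral")
    n_samp = int(round(n_samp))
    rows = np.zeros((len(events), n_samp))
    excluded = np.zeros(len(events), dtype=bool)
    for i, onset in enumerate(events.onsets):
        start = int(np.ceil((onset - record.t0) * record.fs - 1e-9))
        if start < 0:
            excluded[i] = True
            continue
        stop = start + n_samp
        if stop > record.n_samples:
            avail = max(record.n_samples - start, 0)
            rows[i, :avail] = record.values[start:start + avail]
            excluded[i] = True
            continue
        rows[i] = record.values[start:stop]
    if mean_centre:
        keep = ~excluded
        rows[keep] -= rows[keep].mean(axis=1, keepdims=True)
    labels = events.labels if events.labels is not None else [""] * len(events)
    meta = pd.DataFrame(
        {
            "subject": [subject] * len(events),
            "condition": list(labels),
            "onset": events.onsets,
            "excluded": excluded,
        }
    )
    return EpochMatrix(rows, fs=record.fs, epoch_len=epoch_len, meta=meta)


def preprocess_chain(
    raw: SignalRecord,
    events: EventSeries,
    spec: FilterSpec | None = None,
    target_fs: float = DEFAULT_TARGET_FS,
    epoch_len: float = DEFAULT_EPOCH_LEN,
    mean_centre: bool = True,
    subject: str = "",
) -> tuple[SignalRecord, EpochMatrix]:
    """Run band-pass -> downsample -> z-transform -> epoch + mean-centre.

    Returns both the processed continuous signal and the epoch matrix. The
    order matters and is fixed: z-scoring uses the statistics of the full
    decimated series, before any epoching.
    """
    filtered = bandpass(raw, spec)
    decimated = downsample(filtered, target_fs)
    standardised = ztransform(decimated)
    epochs = extract_epochs(standardised, events, epoch_len=epoch_len,
                            mean_centre=mean_centre, subject=subject)
    return standardised, epochs
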