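"""Synthetic electrodermal recordings with known ground truth.

The generator composes a recording as the sum of four components, each
returned separately so every analysis stage can be validated against what
actually went in:

* evoked SCRs — designed events convolved with a peak-normalised
  exponentially modified Gaussian kernel, amplitudes drawn from a normal
  truncated at zero (negative SCR amplitudes are non-physiological);
* spontaneous fluctuations — a homogeneous Poisson process of SCRs sharing
  the evoked kernel shape, since baseline fluctuations are the same class of
  phasic event;
* tonic drift — a random walk plus a few slow sinusoids below 0.01 Hz, i.e.
  below the default high-pass cut-off, emulating slow skin-conductance-level
  changes that can dwarf the responses themselves;
* white measurement noise.

Departures from the LTI ideal are injectable: per-event jitter of the kernel
parameters (violating time-invariance) and repetition suppression, which
scales the generating amplitude of repeated events within a trial — a neural
adaptation, so each emitted waveform stays a scaled template and the output
remains event-wise LTI.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .io_signal import EventSeries, SignalRecord
from .response_model import CRFParams, crf, default_params, exgauss_mode, exgauss_pdf

__all__ = ["SimConfig", "GroundTruth", "simulate", "scenario",
           "simulate_multisite", "rank1_epochs_with_noise_fraction",
           "SCENARIOS"]

#: seconds of kernel support kept after each onset (the tail is ~0 beyond this)
_KERNEL_WINDOW = 60.0

#: multisite defaults: conduction lag (s) and amplitude gain per site
MULTISITE_LAG = {"palm": 0.0, "finger": 0.4, "foot": 1.3}
MULTISITE_GAIN = {"palm": 1.0, "finger": 0.60, "foot": 0.33}

SCENARIOS = ("time_invariant", "shape_jittered", "nonlinear_suppression",
             "paired_isi", "multisite")


@dataclass
class SimConfig:
    """Full description of one synthetic recording.

    Amplitude units are microsiemens-like arbitrary units with a mean evoked
    amplitude of 1. Defaults represent a quiet laboratory recording: a
    spontaneous-fluctuation rate of ~2 per minute, spontaneous amplitudes a
    third of evoked ones, slow tonic drift of the same order as the
    responses, and small wide-band sensor noise.
    """

    fs: float = 100.0
    duration: float = 600.0
    event_onsets: Sequence[float] = ()
    event_labels: Sequence[str] | None = None
    event_trials: Sequence[int] | None = None        # trial id per event
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.4
    amplitude_trial_corr: float = 0.5    # within-trial correlation of amplitudes
    crf_params: CRFParams = field(default_factory=default_params)
    shape_jitter: tuple[float, float] = (0.0, 0.0)   # (sd_mu, sd_sigma), s
    spont_rate: float = 0.03                         # Poisson events / s
    spont_amp: tuple[float, float] = (0.3, 0.15)     # (mean, sd)
    tonic_step_sd: float = 1e-3                      # random-walk step sd / sample
    tonic_n_sines: int = 2
    tonic_sine_max_amp: float = 0.5                  # sine freqs < 0.01 Hz
    noise_sd: float = 0.02
    suppression_factor: float = 1.0                  # in (0, 1]
    suppression_isi_dependent: bool = False
    suppression_isi_scale: float = 5.0               # s
    site_lag: float = 0.0                            # s, shifts all onsets
    site_gain: float = 1.0                           # scales evoked + spontaneous
    label: str = "palm"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.suppression_factor <= 1.0):
            raise ValueError("suppression_factor must be in (0, 1]")
        for name in ("amplitude_sd", "spont_rate", "tonic_step_sd",
                     "noise_sd", "tonic_sine_max_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.amplitude_trial_corr <= 1.0):
            raise ValueError("amplitude_trial_corr must be in [0, 1]")
        if any(s < 0 for s in self.shape_jitter):
            raise ValueError("shape_jitter sds must be >= 0")
        onsets = np.asarray(self.event_onsets, dtype=float)
        if onsets.size and onsets.max() >= self.duration:
            raise ValueError("event onsets must lie within the duration")


@dataclass
class GroundTruth:
    """Everything the generator realised, component by component."""

    designed_onsets: np.ndarray
    designed_amplitudes: np.ndarray
    designed_params: list[CRFParams]
    designed_labels: list[str]
    spont_onsets: np.ndarray
    spont_amplitudes: np.ndarray
    evoked: np.ndarray
    spontaneous: np.ndarray
    tonic: np.ndarray
    noise: np.ndarray

    @property
    def all_onsets(self) -> np.ndarray:
        return np.sort(np.concatenate([self.designed_onsets, self.spont_onsets]))

    def total(self) -> np.ndarray:
        return self.evoked + self.spontaneous + self.tonic + self.noise


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _trial_correlated_amplitudes(rng: np.random.Generator, config: SimConfig,
                                 trials: np.ndarray) -> np.ndarray:
    """Evoked amplitudes with a shared per-trial arousal factor.

    Each trial draws a latent state z_t and each event an innovation e_i;
    the amplitude is mean + sd * (sqrt(rho) z_t + sqrt(1-rho) e_i), so events
    within one trial correlate with coefficient rho while the marginal stays
    N(mean, sd^2). Arousal fluctuates slowly, and empirically a large first
    response predicts a large second one, so rho > 0 is the realistic
    default. Negative draws are rejected event-wise (amplitudes are
    non-negative physiologically), keeping the trial factor intact.
    """
    n = trials.size
    if n == 0:
        return np.empty(0)
    mean, sd, rho = config.amplitude_mean, config.amplitude_sd, config.amplitude_trial_corr
    if sd == 0:
        return np.full(n, mean)
    z = {t: rng.standard_normal() for t in np.unique(trials)}
    amps = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            e = rng.standard_normal()
            a = mean + sd * (np.sqrt(rho) * z[trials[i]]
                             + np.sqrt(1.0 - rho) * e)
            if a >= 0:
                amps[i] = a
                break
        else:  # pragma: no cover - needs mean << 0
            amps[i] = 0.0
    return amps


def _add_kernel(out: np.ndarray, fs: float, onset: float, amplitude: float,
                params: CRFParams) -> None:
    """Add amplitude * peak-normalised kernel at ``onset`` into ``out``."""
    n = out.size
    start = int(np.ceil(onset * fs - 1e-9))
    if start >= n:
        return
    stop = min(n, start + int(round(_KERNEL_WINDOW * fs)))
    t = np.arange(start, stop) / fs - onset
    peak = exgauss_pdf(np.array([exgauss_mode(params)]), params)[0]
    out[start:stop] += amplitude * exgauss_pdf(t, params) / peak


def simulate(config: SimConfig) -> tuple[SignalRecord, GroundTruth]:
    """Generate one recording; bit-reproducible for a given seed.

    The innovation stream (amplitudes, jitters, spontaneous process, tonic
    drift) is driven by ``seed`` alone, while measurement noise is seeded
    from (seed, channel label): channels generated from the same seed share
    their physiological innovations but have independent sensor noise, which
    is what multi-site recordings of one sudomotor input look like.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)

    onsets = np.asarray(config.event_onsets, dtype=float)
    labels = (list(config.event_labels) if config.event_labels is not None
              else [""] * onsets.size)
    trials = (np.asarray(config.event_trials, dtype=int)
              if config.event_trials is not None
              else np.arange(onsets.size))

    amps = _trial_correlated_amplitudes(rng, config, trials)
    # repetition suppression: acts on the generating amplitude within a trial
    for trial_id in np.unique(trials):
        idx = np.flatnonzero(trials == trial_id)
        idx = idx[np.argsort(onsets[idx])]
        for k, i in enumerate(idx):
            if k == 0:
                continue
            amps[i] *= config.suppression_factor
            if config.suppression_isi_dependent:
                isi = onsets[i] - onsets[idx[k - 1]]
                amps[i] *= np.exp(-isi / config.suppression_isi_scale)

    sd_mu, sd_sigma = config.shape_jitter
    params_list = []
    for _ in range(onsets.size):
        if sd_mu == 0 and sd_sigma == 0:
            params_list.append(config.crf_params)
        else:
            p = config.crf_params
            new_sigma = max(p.sigma + sd_sigma * rng.standard_normal(), 0.05)
            params_list.append(replace(p, mu=p.mu + sd_mu * rng.standard_normal(),
                                       sigma=new_sigma))

    n_spont = rng.poisson(config.spont_rate * config.duration)
    spont_onsets = np.sort(rng.uniform(0.0, config.duration, n_spont))
    spont_amps = _truncated_normal(rng, config.spont_amp[0], config.spont_amp[1],
                                   n_spont)

    evoked = np.zeros(n)
    for onset, amp, p in zip(onsets, amps, params_list):
        _add_kernel(evoked, fs, onset + config.site_lag,
                    config.site_gain * amp, p)
    spontaneous = np.zeros(n)
    for onset, amp in zip(spont_onsets, spont_amps):
        _add_kernel(spontaneous, fs, onset + config.site_lag,
                    config.site_gain * amp, config.crf_params)

    tonic = np.zeros(n)
    if config.tonic_step_sd > 0:
        tonic += np.cumsum(config.tonic_step_sd * rng.standard_normal(n))
    if config.tonic_n_sines > 0 and config.tonic_sine_max_amp > 0:
        t = np.arange(n) / fs
        for _ in range(config.tonic_n_sines):
            f = rng.uniform(0.001, 0.01)
            a = rng.uniform(0.0, config.tonic_sine_max_amp)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            tonic += a * np.sin(2.0 * np.pi * f * t + phi)

    noise_rng = np.random.default_rng(
        [config.seed, zlib.crc32(config.label.encode()) & 0x7FFFFFFF]
    )
    noise = (config.noise_sd * noise_rng.standard_normal(n)
             if config.noise_sd > 0 else np.zeros(n))

    truth = GroundTruth(
        designed_onsets=onsets + config.site_lag,
        designed_amplitudes=config.site_gain * amps,
        designed_params=params_list,
        designed_labels=labels,
        spont_onsets=spont_onsets + config.site_lag,
        spont_amplitudes=config.site_gain * spont_amps,
        evoked=evoked,
        spontaneous=spontaneous,
        tonic=tonic,
        noise=noise,
    )
    record = SignalRecord(truth.total(), fs=fs, t0=0.0, label=config.label)
    return record, truth


def _grid(x: float) -> float:
    """Snap an onset to the 0.1 s (10 Hz analysis) grid."""
    return round(x * 10.0) / 10.0


def _single_event_design(rng: np.random.Generator, n_events: int,
                         lead_in: float = 10.0) -> tuple[list[float], float]:
    onsets = []
    t = lead_in
    for _ in range(n_events):
        onsets.append(_grid(t))
        t += float(rng.choice([30.0, 35.0, 40.0]))
    return onsets, onsets[-1] + 45.0


def _paired_design(rng: np.random.Generator, trials_per_condition: int = 10,
                   isis: tuple[float, ...] = (2.0, 5.5, 9.0)):
    """Randomised sequence of single and double trials, gaps of 30/35/40 s."""
    conditions = (["single"] * trials_per_condition
                  + [f"double_{isi}" for isi in isis
                     for _ in range(trials_per_condition)])
    order = rng.permutation(len(conditions))
    onsets: list[float] = []
    labels: list[str] = []
    trial_ids: list[int] = []
    t = 2.0  # short lead-in before the first trial
    for trial_no, ci in enumerate(order):
        cond = conditions[ci]
        if cond == "single":
            onsets.append(_grid(t))
            labels.append("single")
            trial_ids.append(trial_no)
            last = t
        else:
            isi = float(cond.split("_")[1])
            onsets.append(_grid(t))
            labels.append(f"first_isi{isi:g}")
            trial_ids.append(trial_no)
            onsets.append(_grid(t + isi))
            labels.append(f"second_isi{isi:g}")
            trial_ids.append(trial_no)
            last = t + isi
        t = last + float(rng.choice([30.0, 35.0, 40.0]))
    duration = _grid(t) + 45.0
    return onsets, labels, trial_ids, duration


def scenario(name: str, seed: int = 0, **overrides):
    """Build the SimConfig(s) for a named study design.

    ``time_invariant`` / ``shape_jittered``: ~16 single events separated by
    30-40 s of silence, with the kernel fixed or jittered per event.
    ``paired_isi``: 10 single and 10 double trials per ISI in {2, 5.5, 9} s,
    randomised order, 30/35/40 s gaps. ``nonlinear_suppression``: the paired
    design with the second event's generating amplitude scaled by 0.7,
    independent of ISI. ``multisite``: 20 single events observed at palm,
    finger and foot with site lags 0/0.4/1.3 s and gains 1/0.60/0.33, sharing
    one innovation stream (returns a list of three configs).
    """
    rng = np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])
    if name in ("time_invariant", "shape_jittered"):
        onsets, duration = _single_event_design(rng, n_events=16)
        cfg = SimConfig(
            event_onsets=onsets,
            event_labels=["single"] * len(onsets),
            duration=duration,
            shape_jitter=(0.3, 0.1) if name == "shape_jittered" else (0.0, 0.0),
            seed=seed,
        )
    elif name in ("paired_isi", "nonlinear_suppression"):
        onsets, labels, trial_ids, duration = _paired_design(rng)
        cfg = SimConfig(
            event_onsets=onsets,
            event_labels=labels,
            event_trials=trial_ids,
            duration=duration,
            suppression_factor=0.7 if name == "nonlinear_suppression" else 1.0,
            seed=seed,
        )
    elif name == "multisite":
        onsets, duration = _single_event_design(rng, n_events=20)
        configs = []
        for site in ("palm", "finger", "foot"):
            configs.append(
                replace(
                    SimConfig(
                        event_onsets=onsets,
                        event_labels=["single"] * len(onsets),
                        duration=duration + MULTISITE_LAG["foot"],
                        site_lag=MULTISITE_LAG[site],
                        site_gain=MULTISITE_GAIN[site],
                        label=site,
                        seed=seed,
                    ),
                    **overrides,
                )
            )
        return configs
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return replace(cfg, **overrides)


def simulate_multisite(configs: Sequence[SimConfig]):
    """Run :func:`simulate` for each site config of a multisite scenario."""
    return [simulate(c) for c in configs]


def rank1_epochs_with_noise_fraction(
    q: float,
    n_epochs: int = 100,
    n_samples: int = 300,
    fs: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Epoch matrix = amplitudes x one template + white noise of exact share q.

    The template is the mean-centred sampled CRF; rows are mean-centred, and
    the noise block is rescaled so that the realised noise sum of squares is
    exactly the fraction ``q`` of the total. Ideal input for checking that
    the PC1 explained fraction estimates 1 - q.
    """
    if not (0.0 <= q < 1.0):
        raise ValueError("q must be in [0, 1)")
    rng = np.random.default_rng(seed)
    v = crf(fs, default_params(duration=n_samples / fs))
    v = v - v.mean()
    v = v / np.linalg.norm(v)
    amps = _truncated_normal(rng, 1.0, 0.4, n_epochs)
    signal = np.outer(amps, v)
    noise = rng.standard_normal((n_epochs, n_samples))
    noise -= noise.mean(axis=1, keepdims=True)
    # orthogonalise against the signal so sums of squares add exactly
    noise -= np.sum(noise * signal) / np.sum(signal**2) * signal
    if q > 0:
        ss_sig = np.sum(signal**2)
        target = q / (1.0 - q) * ss_sig
        noise *= np.sqrt(target / np.sum(noise**2))
    else:
        noise[:] = 0.0
    return signal + noise
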