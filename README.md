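# scrlti

Linear time-invariant (LTI) convolution modelling of event-related skin
conductance responses (SCRs).

## The problem

Psychophysiologists infer sympathetic arousal from the amplitude of
event-related SCRs in the electrodermal (EDA) signal. That inference is only
well-founded if two implicit assumptions hold: **time-invariance** — within a
person, every evoked response is a scaled copy of one template — and
**linearity** — overlapping responses simply sum. Under these assumptions the
skin conductance signal is the output of an LTI system,

```
y(t) = Σ_i a_i · h(t − t_i) + ε(t),
```

where `h` is the response function, `t_i` the event onsets, `a_i` the
per-event amplitudes, and `ε` collects spontaneous fluctuations, tonic drift
and noise. `scrlti` implements the full analysis stack for testing and
exploiting this model, together with a ground-truth EDA simulator so every
stage can be validated quantitatively:

- **io_signal** — plain-text readers/writers and containers for signals,
  event lists and epoch matrices.
- **preprocess** — zero-phase first-order Butterworth band-pass
  (0.0159–5 Hz defaults; the high-pass corresponds to a 10 s time
  constant), decimation to 10 Hz, whole-series z-scoring, 30 s epoch
  extraction with per-trial mean-centring.
- **response_model** — the canonical response function (CRF) as an
  exponentially modified Gaussian `N(μ, σ²) * Exp(τ)`, calibrated so the
  peak lands at 3.9 s (palmar; presets 4.3 s finger, 5.0 s foot), plus
  analytic time and dispersion derivatives forming an informed basis set.
- **glm** — stick-function convolution designs, per-trial ordinary
  least-squares amplitude estimation, and the repetition × ISI linearity
  analysis for paired stimuli.
- **empirical_rf** — PCA estimation of response functions from epochs
  (uncentred, so PC1 *is* the template), exact variance partitioning into
  common / between-subjects / residual shares, baseline-variance ratios,
  high-pass cut-off sweeps, and time-lagged cross-site correlation.
- **simulate** — synthetic recordings with known evoked amplitudes,
  Poisson-timed spontaneous SCRs, tonic drift, sensor noise, and switchable
  violations of the model (shape jitter, repetition suppression).
- **cli** — `scrlti` command with one subcommand per stage.

## Worked example

```python
import numpy as np

from scrlti import EventSeries, FilterSpec, preprocess_chain
from scrlti.empirical_rf import epoch_pca, variance_partition
from scrlti.simulate import scenario, simulate
from scrlti.workflows import linearity_study, multisite_lag_study

# 1. simulate three subjects' event-related sessions and preprocess them
per_subject = []
for i in range(3):
    cfg = scenario("time_invariant", seed=i)
    record, truth = simulate(cfg)
    _, epochs = preprocess_chain(record, EventSeries(truth.designed_onsets),
                                 spec=FilterSpec(), subject=f"s{i}")
    per_subject.append(epochs)

# 2. how much variance does one response function explain per subject?
for ep in per_subject:
    res = epoch_pca(ep, k=1)
    subj = ep.meta['subject'][0]
    print(f"subject {subj}: PC1 explains {100 * res.explained_fraction[0]:.1f}% "
          f"of epoch variance (n={res.n_epochs})")

# 3. split pooled variance into common / between-subjects / residual
part = variance_partition(per_subject)
print(f"pooled: common {100 * part.common:.1f}%, "
      f"between-subjects {100 * part.between_subjects:.1f}%, "
      f"residual {100 * part.residual:.1f}%")

# 4. paired-stimulus linearity analysis with 30% repetition suppression
report = linearity_study(n_subjects=20, base_seed=0, suppression_factor=0.7)
for isi in (2.0, 5.5, 9.0):
    print(f"ISI {isi:>3} s: second/first amplitude ratio "
          f"{report.mean_ratio(isi):.3f}")
print(f"ISI trend {report.ratio_trend_slope():+.4f}/s, "
      f"within-subject slope t = {report.slope_t:.1f}")

# 5. cross-site lag recovery
lags = multisite_lag_study(seed=0)
for pair, lag in lags.items():
    print(f"{pair}: best lag {lag.best_lag:.1f} s "
          f"({100 * lag.best_r2:.1f}% shared variance)")
```

Output:

```
subject s0: PC1 explains 93.3% of epoch variance (n=16)
subject s1: PC1 explains 88.9% of epoch variance (n=16)
subject s2: PC1 explains 90.3% of epoch variance (n=16)
pooled: common 90.3%, between-subjects 0.6%, residual 9.1%
ISI 2.0 s: second/first amplitude ratio 0.681
ISI 5.5 s: second/first amplitude ratio 0.744
ISI 9.0 s: second/first amplitude ratio 0.710
ISI trend +0.0042/s, within-subject slope t = 8.7
palm_finger: best lag 0.4 s (97.0% shared variance)
palm_foot: best lag 1.3 s (82.0% shared variance)
```

Reading the numbers: one response function per simulated subject explains
~90% of epoch variance (the remainder is spontaneous activity, drift and
noise, as designed); the pooled decomposition attributes almost nothing to
between-subject shape differences because all subjects share a kernel. The
paired-stimulus analysis recovers the generating suppression factor 0.7 at
every ISI with a negligible ISI trend — the signature of linearity plus
purely neural repetition suppression — and the positive within-subject slope
reflects the generator's shared per-trial arousal factor. The cross-site
analysis recovers the constructed conduction lags exactly on the 10 Hz grid.

The same pipeline is available from the shell:

```sh
scrlti simulate --scenario paired_isi --seed 7 -o run
scrlti preprocess run.signal.txt run.events.txt -o prep
scrlti estimate-rf prep.epochs.txt -o rf.txt
scrlti basis --fs 10 -o basis.txt
scrlti glm prep.epochs.txt --basis basis.txt
```

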