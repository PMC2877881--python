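# Methods

## Model

The package treats the skin conductance signal as the output of a linear
time-invariant (LTI) system driven by impulsive sudomotor input. Each event
at onset `t_i` contributes `a_i · h(t − t_i)`: a scaled, shifted copy of one
response function `h`. Time-invariance means `h` is fixed within a person
and condition; linearity means overlapping responses add. Everything else in
the recording — spontaneous SCRs not locked to events, slow tonic drift of
the conductance level, sensor noise — is nuisance structure the analysis
must tolerate.

## Preprocessing

The chain is: band-pass filter → decimate → z-score → epoch → per-trial
mean-centre, in that order (z-scoring uses the statistics of the full
decimated series, not of individual epochs).

- **Band-pass.** First-order Butterworth sections, 0.0159 Hz high-pass and
  5 Hz low-pass by default, each applied forward and backward (zero phase).
  The high-pass cut-off corresponds to a first-order time constant of
  `1/(2π·0.0159) ≈ 10 s`; it removes tonic level, which decays far more
  slowly than any evoked response and can exceed it in amplitude. Because
  each section runs twice, the effective magnitude response is the squared
  single-pass magnitude — the analytic oracle used in the tests. Edge
  handling uses odd-symmetric extension of about `3/cutoff` seconds
  (clipped to the signal length), and signals shorter than three time
  constants are rejected rather than filtered badly.
- **Decimation** keeps every k-th sample (10 Hz default). The low-pass at
  5 Hz is exactly the anti-alias filter this requires.
- **z-scoring** (population SD) absorbs between-subject amplitude scale of
  peripheral origin (skin properties, electrode contact). It is applied
  once per subject and channel over the whole series so that evoked and
  baseline segments remain comparable.
- **Epochs** are the 30 s following each onset (sample 0 = first sample at
  or after the onset). Epochs running past the end of the recording are
  zero-padded and flagged excluded — never silently dropped — and excluded
  rows are skipped by all statistics. Per-trial mean-centring removes the
  residual between-trial level differences that survive filtering.

## Canonical response function

`h` is parameterised as the density of `N(μ, σ²) + Exp(τ)` — an
exponentially modified Gaussian, whose fast rise and slow exponential
recovery match the asymmetric SCR shape. The sampled CRF is peak-normalised
(max = 1) so that GLM amplitudes are in units of the modelled signal.

Defaults: σ = 0.7 s, τ = 1.6 s, and μ solved (1-D root of the mode
condition, which reduces to a shift: the mode offset from μ depends only on
σ and τ) so the peak lands at 3.9 s — the mean palmar peak latency. Site
presets move the peak to 4.3 s (finger) and 5.0 s (foot); conduction
distance delays the response but barely changes its shape. All three
parameters are user-settable and the calibration routine ships in the
package, so the defaults are reproducible rather than magic numbers.

Numerics: the density is evaluated in two algebraically identical branches
(scaled complementary error function `erfcx` on one side of the peak, the
factored exponential tail on the other) and is finite out to at least
`|t − μ|/σ = 40`. The mode is found by Brent root-finding on the stationary
condition; uniqueness follows from the monotonicity of `erfcx`.

The **time derivative** (∂/∂μ) and **dispersion derivative** (∂/∂σ) of the
peak-normalised CRF extend it into an informed basis set spanning small
latency and width deviations. They are analytic: the peak height does not
depend on μ, while its σ-dependence enters through the envelope theorem
(the derivative of the maximum is the partial at the mode). An optional
Gram–Schmidt step orthogonalises the derivative rows; this changes the
individual regressors but not the spanned space, so fitted values are
identical either way (test-pinned). Note the sampled CRF is normalised by
its grid maximum while the derivatives use the analytic mode value; at the
default parameters the mode lies on the 10 Hz grid and the two coincide.

## GLM

Designs convolve a unit impulse ("stick") at each onset with each basis row,
truncated to the analysis window, plus one constant column. Estimation is
ordinary least squares through a rank-revealing solve; coincident events are
reported as rank deficiency instead of returning arbitrary coefficients.
Amplitude means the coefficient of the canonical (first) basis function;
derivative coefficients are reported but not folded into a combined
amplitude.

## Linearity analysis

For each subject the response template is PC1 of the single-stimulus
epochs. Every double-stimulus trial is then fitted on its own window with
`[template@first, template@second, constant]`, giving per-trial amplitudes
(β₁, β₂). Reported are the repetition × ISI amplitude table, the pooled
ratio of mean second to mean first amplitude per ISI, the within-subject
regression slope of β₂ on β₁ (per ISI and pooled), and a one-sample t of
the pooled slopes across subjects. In place of a repeated-measures ANOVA,
the amplitude table carries the repetition and ISI effects and the slope
t-test carries the amplitude-coupling question; both are standard
off-the-shelf statistics, while the bespoke content is the estimation
pipeline that produces the amplitudes.

One design choice matters here. Zero-phase filtering is acausal: the
filtered response includes a slow dip that *precedes* the onset. A design
whose second regressor starts at the second onset leaves that response's
pre-onset portion unmodelled, which inflates β₂ — and the unmodelled span
grows with the ISI, manufacturing a spurious ISI trend (~+0.17 on the ratio
at ISI 9 s in noiseless simulation). `paired_epochs` therefore opens every
analysis window 10 s before the (first) onset and estimates the template
over [−10, 30) s, so both regressors cover the full filtered extent of
their response; double windows additionally extend to 30 s + max ISI after
the first onset so the second response is fully contained. With this
geometry the estimator is unbiased: noiseless fixed-amplitude simulations
recover the suppression factor to < 0.005 at every ISI. Trials whose
pre-window precedes the recording start are flagged excluded. Non-responses
(flat trials) are kept; dropping them would bias the residual picture.

## Empirical response functions and variance partitioning

Epoch PCA decomposes the *uncentred* second-moment matrix of the
row-mean-centred epochs (computed via SVD; the dense eigen-decomposition is
the test oracle). Removing the cross-epoch column mean first would fold a
common response shape into the mean and make PC1 a deviation score — the
wrong object when PC1 is meant to *be* the template. PC1 is oriented so its
extreme sample is positive (SCRs deflect upward).

The variance partition is exact by construction: `common` is the pooled-PC1
explained fraction over all subjects' epochs; within-subject fractions are
combined weighted by each subject's total epoch sum of squares, so
`common + between_subjects + residual = 1` identically, and
`between_subjects ≥ 0` because each subject's own PC1 is optimal for that
subject (the first eigenvalue of a sum of PSD matrices never exceeds the
sum of the first eigenvalues). Equal-weighting of subjects would break the
exact decomposition; variance-weighting was chosen for that reason.

`baseline_ratio` compares total variance of baseline epochs to evoked
epochs (mean squares, so epoch counts may differ). Both sets must share one
z-transform or the ratio is meaningless. The high-pass **filter sweep**
reruns the whole chain per cut-off (0 = low-pass only) and reports the PC1
fraction, probing how much the necessary filtering shapes the apparent
response.

**Lagged correlation** computes Pearson r² between two equal-rate channels
at every sample lag in ±max_lag, ties broken toward the smaller absolute
lag; a negative best lag means the second channel leads.

## Simulator

A recording is the exact sum of four components (the generator returns them
separately, and the reconstruction identity is test-pinned):

| component | default | rationale |
| --- | --- | --- |
| evoked SCRs | amplitudes ~ N(1, 0.4²) truncated at 0, a.u. | negative SCR amplitudes are non-physiological |
| within-trial amplitude correlation | ρ = 0.5 | responsiveness fluctuates slowly; a large first response predicts a large second one, so paired events share a per-trial arousal factor (marginal distribution unchanged) |
| spontaneous SCRs | Poisson, 0.03 events/s, amp ~ N(0.3, 0.15²) | ~2 non-specific fluctuations per minute with amplitudes well below evoked responses, typical of an awake resting recording; they share the evoked kernel shape, being the same class of event |
| tonic drift | random walk (step SD 10⁻³/sample at 100 Hz) + 2 sinusoids < 0.01 Hz, amp ≤ 0.5 | slow level changes larger than individual responses, deliberately placed below the high-pass cut-off so default preprocessing removes most of them |
| sensor noise | white, SD 0.02 | small wide-band measurement noise |

Model violations are explicit and controllable: per-event jitter of (μ, σ)
breaks time-invariance; repetition suppression multiplies the *generating*
amplitude of repeated events within a trial by a factor in (0, 1]
(optionally decaying with ISI) — a neural adaptation, so each emitted
waveform remains a scaled template and the output stays event-wise LTI.

Scenario presets encode the study designs: `time_invariant` /
`shape_jittered` (~16 single events, 30–40 s silences), `paired_isi` /
`nonlinear_suppression` (10 single and 10 double trials per ISI ∈ {2, 5.5,
9} s in randomised order, 2 s lead-in, 30/35/40 s silences after the last
stimulus of each trial), and `multisite` (palm/finger/foot sharing one
innovation stream with conduction lags 0/0.4/1.3 s and gains 1/0.60/0.33;
sensor noise is per-site). Onsets are snapped to the 0.1 s analysis grid.
Given a seed, output is bit-reproducible.

What the simulator does **not** emulate: biophysical sweat-duct dynamics,
amplitude-dependent shape changes, non-stationary spontaneous rates
(a config hook exists but defaults off), recording gaps, movement
artefacts, or electrode drift nonlinearities. Passing tests therefore show
that the estimators recover the truth *under the stated generative model*,
not that real recordings satisfy that model.

## Problem sizes and numerical choices

Validation runs use 20 simulated subjects × 40 trials for the linearity
study, 16–20 events per subject elsewhere, 100 × 300 epoch matrices for the
explained-variance calibration, and 50 random data sets for the partition
identities — sizes at which every check completes in seconds while the
stochastic assertions have comfortable margins. Root-finding tolerances are
1e-13 (mode solve); orthogonality and round-trip assertions use 1e-10 to
1e-12; the density-vs-convolution oracle uses a 1 ms midpoint-rule grid
(O(dt²), so the 1e-6 comparison is quadrature-dominated, not
implementation-dominated).

## Known limitations

- The CRF shape parameters (σ, τ) are calibrated to peak latency and
  qualitative rise/recovery asymmetry, not fitted to empirical SCR data;
  only the peak latencies are anchored to reported site means.
- The per-trial constant absorbs level but not within-trial linear drift;
  strong un-removed drift inflates amplitude noise.
- The lag grid is the sample grid; sub-sample lags are not interpolated.
- `fit` assumes i.i.d. residuals for its standard errors; EDA residuals are
  autocorrelated, so use the SEs comparatively, not inferentially.
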