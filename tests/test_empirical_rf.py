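import numpy as np
import pytest

from scrlti.empirical_rf import (
    baseline_ratio,
    epoch_pca,
    filter_sweep,
    lagged_correlation,
    variance_partition,
)
from scrlti.io_signal import EpochMatrix, EventSeries, SignalRecord
from scrlti.preprocess import FilterSpec, bandpass, downsample, extract_epochs, ztransform
from scrlti.simulate import SimConfig, rank1_epochs_with_noise_fraction, simulate

from conftest import make_epochs


def centred_shape(n=50):
    v = np.sin(np.linspace(0, np.pi, n)) ** 2
    v -= v.mean()
    return v / np.linalg.norm(v)


class TestEpochPCA:
    def test_rank_one_data_fully_explained(self):
        v = centred_shape()
        ep = make_epochs(np.outer([1.0, -2.0, 0.5], v))
        res = epoch_pca(ep, k=2)
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(res.components[0] @ v) == pytest.approx(1.0, abs=1e-10)

    def test_pc1_recovers_template_under_noise(self, rng):
        # SNR 10, 100 epochs: cosine similarity of PC1 with truth > 0.99
        v = centred_shape()
        amps = rng.normal(1.0, 0.3, 100)
        noise_var = np.mean(amps**2) / v.size / 10.0
        X = np.outer(amps, v) + rng.normal(0, np.sqrt(noise_var), (100, v.size))
        res = epoch_pca(make_epochs(X), k=1)
        assert abs(res.components[0] @ v) > 0.99

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 50))
        X -= X.mean(axis=1, keepdims=True)
        res = epoch_pca(make_epochs(X), k=5)
        # oracle: explicit second-moment matrix, dense symmetric eigensolver
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.max(np.abs(res.eigenvalues - evals[:5])) < 1e-8 * evals[0]
        for i in range(5):
            assert abs(abs(res.components[i] @ evecs[:, i]) - 1.0) < 1e-8

    def test_invariant_to_reordering_and_scaling(self, rng):
        X = rng.standard_normal((10, 30))
        a = epoch_pca(make_epochs(X)).explained_fraction
        b = epoch_pca(make_epochs(X[::-1])).explained_fraction
        c = epoch_pca(make_epochs(7.5 * X)).explained_fraction
        assert np.allclose(a, b, atol=1e-12)
        assert np.allclose(a, c, atol=1e-12)

    def test_pc1_oriented_positive(self, rng):
        v = -centred_shape()  # downward template
        ep = make_epochs(np.outer([1.0, 2.0], v))
        res = epoch_pca(ep, k=1)
        assert res.components[0][np.argmax(np.abs(res.components[0]))] > 0

    def test_excluded_epochs_ignored(self, rng):
        v = centred_shape()
        X = np.vstack([v, 2 * v, rng.standard_normal(50)])
        res = epoch_pca(make_epochs(X, excluded=[False, False, True]), k=1)
        assert res.n_epochs == 2
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            epoch_pca(make_epochs(np.ones((1, 10))))
        with pytest.raises(ValueError, match="all-zero"):
            epoch_pca(make_epochs(np.zeros((3, 10))))
        with pytest.raises(ValueError, match="exceeds"):
            epoch_pca(make_epochs(rng.standard_normal((3, 10))), k=5)

    @pytest.mark.parametrize("q", [0.2, 0.4])
    def test_explained_fraction_estimates_one_minus_noise_share(self, q):
        X = rank1_epochs_with_noise_fraction(q, n_epochs=100, n_samples=300, seed=7)
        res = epoch_pca(make_epochs(X), k=1)
        assert abs(res.explained_fraction[0] - (1.0 - q)) < 0.03


class TestVariancePartition:
    def test_shared_shape_noiseless(self):
        v = centred_shape()
        subj = [make_epochs(np.outer([1.0, 0.5], v)),
                make_epochs(np.outer([2.0, 1.5], v))]
        p = variance_partition(subj)
        assert p.common == pytest.approx(1.0, abs=1e-9)
        assert p.between_subjects == pytest.approx(0.0, abs=1e-9)
        assert p.residual == pytest.approx(0.0, abs=1e-9)

    def test_two_orthogonal_shapes_split_evenly(self):
        v1 = centred_shape()
        v2 = np.roll(v1, 25)
        v2 -= v2.mean()
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        scal = np.array([1.0, 1.5, 0.7])
        p = variance_partition(
            [make_epochs(np.outer(scal, v1)), make_epochs(np.outer(scal, v2))]
        )
        # each subject rank-1, shapes orthogonal with equal pooled weight
        assert p.per_subject == pytest.approx([1.0, 1.0], abs=1e-9)
        assert p.common == pytest.approx(0.5, abs=1e-9)
        assert p.between_subjects == pytest.approx(0.5, abs=1e-9)
        assert p.residual == pytest.approx(0.0, abs=1e-9)

    def test_components_always_sum_to_one(self, rng):
        subj = [make_epochs(rng.standard_normal((5, 40))) for _ in range(4)]
        p = variance_partition(subj)
        assert p.common + p.between_subjects + p.residual == pytest.approx(1.0, abs=1e-9)
        assert p.between_subjects >= -1e-9

    def test_needs_two_subjects(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            variance_partition([make_epochs(rng.standard_normal((3, 10)))])


class TestBaselineRatio:
    def test_identical_sets_give_one(self, rng):
        X = rng.standard_normal((4, 30))
        assert baseline_ratio(make_epochs(X), make_epochs(X.copy())) == pytest.approx(1.0)

    def test_variance_scales_quadratically(self, rng):
        X = rng.standard_normal((4, 30))
        X -= X.mean(axis=1, keepdims=True)
        r = baseline_ratio(make_epochs(X), make_epochs(0.5 * X))
        assert r == pytest.approx(0.25, abs=1e-12)

    def test_simulated_baseline_below_evoked_but_above_residual(self):
        # evoked epochs contain responses + spontaneous activity; baseline
        # epochs only the spontaneous background, so the ratio sits between
        # the residual fraction and one
        onsets = [round(10 + 35 * i, 1) for i in range(8)]
        cfg = SimConfig(duration=620.0, event_onsets=onsets, spont_rate=0.05,
                        noise_sd=0.01, seed=11)
        record, _ = simulate(cfg)
        processed = ztransform(downsample(bandpass(record, FilterSpec()), 10.0))
        evoked = extract_epochs(processed, EventSeries(np.asarray(onsets)))
        baseline = extract_epochs(processed, EventSeries(np.arange(320.0, 580.0, 30.0)))
        ratio = baseline_ratio(evoked, baseline)
        residual = 1.0 - epoch_pca(evoked, k=1).explained_fraction[0]
        assert residual < ratio < 1.0


@pytest.fixture(scope="module")
def drifting_recording():
    cfg = SimConfig(duration=400.0,
                    event_onsets=[round(10 + 35 * i, 1) for i in range(10)],
                    seed=3)
    record, _ = simulate(cfg)
    return record, EventSeries(np.asarray(cfg.event_onsets))


class TestFilterSweep:
    def test_default_grid_produces_six_pairs(self, drifting_recording):
        record, events = drifting_recording
        pairs = filter_sweep(record, events)
        assert [c for c, _ in pairs] == [0.0, 0.005, 0.01, 0.015, 0.02, 0.025]

    def test_noiseless_constant_shape_fully_explained_everywhere(self):
        cfg = SimConfig(duration=400.0,
                        event_onsets=[round(10 + 35 * i, 1) for i in range(10)],
                        amplitude_sd=0.3, spont_rate=0.0, noise_sd=0.0,
                        tonic_step_sd=0.0, tonic_n_sines=0, seed=3)
        record, _ = simulate(cfg)
        pairs = filter_sweep(record, EventSeries(np.asarray(cfg.event_onsets)))
        assert min(f for _, f in pairs) > 0.99

    def test_explained_fraction_varies_smoothly_with_cutoff(self, drifting_recording):
        record, events = drifting_recording
        fracs = [f for _, f in filter_sweep(record, events)]
        assert np.max(np.abs(np.diff(fracs))) < 0.05

    def test_cutoff_at_or_above_lowpass_rejected(self, drifting_recording):
        record, events = drifting_recording
        with pytest.raises(ValueError, match="below lp_cutoff"):
            filter_sweep(record, events, cutoffs=[0.0, 5.0])


class TestLaggedCorrelation:
    def test_identical_signals_zero_lag_unit_r2(self, rng):
        a = SignalRecord(rng.standard_normal(2000), fs=10.0)
        res = lagged_correlation(a, a, max_lag=5.0)
        assert res.best_lag == 0.0
        assert res.best_r2 == pytest.approx(1.0)

    def test_constructed_shift_recovered_exactly(self, rng):
        values = np.convolve(rng.standard_normal(2100), np.ones(8) / 8, "same")
        a = SignalRecord(values[:2000], fs=10.0)
        b = SignalRecord(np.concatenate([np.zeros(13), values[:1987]]), fs=10.0)
        res = lagged_correlation(a, b, max_lag=5.0)
        assert res.best_lag == pytest.approx(1.3)

    def test_affine_image_perfectly_shared(self, rng):
        values = rng.standard_normal(2000)
        a = SignalRecord(values, fs=10.0)
        b = SignalRecord(-2.0 * values + 5.0, fs=10.0)
        res = lagged_correlation(a, b, max_lag=5.0)
        assert res.best_lag == 0.0
        assert res.best_r2 == pytest.approx(1.0)

    def test_r2_bounded_and_lags_on_grid(self, rng):
        a = SignalRecord(rng.standard_normal(2000), fs=10.0)
        b = SignalRecord(rng.standard_normal(2000), fs=10.0)
        res = lagged_correlation(a, b, max_lag=2.0)
        assert np.all((res.r2 >= 0) & (res.r2 <= 1))
        assert res.best_lag in res.lags

    def test_errors(self, rng):
        a = SignalRecord(rng.standard_normal(2000), fs=10.0)
        const = SignalRecord(np.ones(2000), fs=10.0)
        with pytest.raises(ValueError, match="constant"):
            lagged_correlation(a, const, max_lag=2.0)
        short = SignalRecord(rng.standard_normal(30), fs=10.0)
        with pytest.raises(ValueError, match="overlap"):
            lagged_correlation(short, short, max_lag=2.0)
        b = SignalRecord(rng.standard_normal(2000), fs=20.0)
        with pytest.raises(ValueError, match="sampling rate"):
            lagged_correlation(a, b, max_lag=2.0)
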