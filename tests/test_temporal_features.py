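import numpy as np
import pytest
from hmmlearn.hmm import GaussianHMM
from hypothesis import given
from hypothesis import strategies as st

from convoscreen.temporal_features import (
    FeatureTimeSeries,
    GroupHmm,
    aggregate_stats,
    estimate_bpm_series,
    fit_group_hmm,
    hmm_state_summary,
    hrv_quantile_features,
    uniform_resample,
)


def _series(values, rate=1.0):
    return FeatureTimeSeries(values=np.asarray(values, dtype=float), rate=rate)


def _manual_hmm(means, transition, sd=0.1, startprob=None):
    """A GroupHmm with parameters set directly (no fitting)."""
    means = np.asarray(means, dtype=float)
    n, d = means.shape
    m = GaussianHMM(n_components=n, covariance_type="diag")
    m.startprob_ = np.asarray(startprob if startprob is not None
                              else np.full(n, 1 / n))
    transition = np.asarray(transition, dtype=float)
    m.transmat_ = transition / transition.sum(axis=1, keepdims=True)
    m.means_ = means
    m.covars_ = np.full((n, d), sd**2)
    return GroupHmm(model=m, t_max=100, n_states=n)


class TestAggregateStats:
    def test_mean_and_population_std(self):
        # values 1,2,3 in each of two dims: mean 2, population std sqrt(2/3)
        v = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        out = aggregate_stats(_series(v))
        assert np.allclose(out[:2], 2.0)
        assert np.allclose(out[2:], np.sqrt(2.0 / 3.0))

    def test_constant_series_and_single_frame(self):
        assert np.allclose(aggregate_stats(_series(np.full((50, 3), 7.0)))[3:], 0.0)
        single = aggregate_stats(_series([[4.0, -1.0]]))
        assert np.allclose(single, [4.0, -1.0, 0.0, 0.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            _series(np.empty((0, 3)))


class TestGroupHmmFit:
    @pytest.fixture(scope="class")
    def training_streams(self):
        rng = np.random.default_rng(3)
        means = np.array([[-3.0, 0.0], [0.0, 3.0], [3.0, 0.0], [0.0, -3.0]])
        T = np.full((4, 4), 0.05)
        np.fill_diagonal(T, 0.85)
        out = []
        for i in range(6):
            path = [0]
            for _ in range(199):
                path.append(rng.choice(4, p=T[path[-1]]))
            vals = means[path] + rng.normal(0, 0.3, size=(200, 2))
            out.append(_series(vals))
        return out

    def test_em_loglik_nondecreasing_over_20_iterations(self, training_streams):
        hmm = fit_group_hmm(training_streams, seed=0)
        hist = np.asarray(hmm.model.monitor_.history)
        assert len(hist) == 20
        assert np.all(np.diff(hist) >= -1e-6)

    def test_same_seed_identical_parameters(self, training_streams):
        a = fit_group_hmm(training_streams, seed=5)
        b = fit_group_hmm(training_streams, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.transition, b.transition)

    def test_tmax_and_validation_errors(self, training_streams):
        hmm = fit_group_hmm(training_streams, seed=0)
        assert hmm.t_max == 200
        with pytest.raises(ValueError):
            fit_group_hmm(training_streams[:1], seed=0)
        bad = training_streams[:2] + [_series(np.zeros((10, 3)))]
        with pytest.raises(ValueError):
            fit_group_hmm(bad, seed=0)


class TestStateSummary:
    def test_single_state_path_is_one_hot(self):
        hmm = _manual_hmm(
            means=[[0.0], [5.0], [10.0], [15.0]],
            transition=np.eye(4) * 0.97 + 0.01,
        )
        series = _series(np.full((40, 1), 10.0))
        s = hmm_state_summary(hmm, series)
        assert np.allclose(s.duration, [0, 0, 1, 0])
        assert s.frequency[2] == pytest.approx(100.0 / 40)
        assert s.duration.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(s.as_vector()) == 8

    def test_state_permutation_permutes_blocks(self):
        means = np.array([[0.0], [4.0], [8.0], [12.0]])
        T = 0.7 * np.eye(4) + 0.1
        hmm = _manual_hmm(means, T)
        perm = [2, 0, 3, 1]
        hmm_p = _manual_hmm(means[perm], T[np.ix_(perm, perm)],
                            startprob=np.full(4, 0.25)[perm])
        rng = np.random.default_rng(1)
        series = _series(means[rng.integers(0, 4, 60)] + rng.normal(0, 0.1, (60, 1)))
        a = hmm_state_summary(hmm, series)
        b = hmm_state_summary(hmm_p, series)
        inv = np.argsort(perm)
        assert np.allclose(a.duration, b.duration[inv])
        assert np.allclose(a.frequency, b.frequency[inv])

    def test_duration_matches_known_occupancy_when_noise_free(self):
        hmm = _manual_hmm([[0.0], [10.0], [20.0], [30.0]],
                          0.7 * np.eye(4) + 0.1, sd=0.5)
        path = np.array([0] * 70 + [1] * 30)
        series = _series(np.array([[0.0]] * 70 + [[10.0]] * 30))
        s = hmm_state_summary(hmm, series)
        assert np.allclose(s.duration, [0.7, 0.3, 0, 0])
        assert s.frequency[0] == pytest.approx(1.0)  # one run per 100 frames

    def test_dim_mismatch_rejected(self):
        hmm = _manual_hmm([[0.0], [1.0], [2.0], [3.0]], np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            hmm_state_summary(hmm, _series(np.zeros((5, 2))))


class TestBpmEstimation:
    def test_pure_tones(self):
        t = np.arange(0, 30, 1 / 30.0)
        for freq, bpm in [(1.2, 72.0), (1.0, 60.0)]:
            est = estimate_bpm_series(np.sin(2 * np.pi * freq * t), fs=30.0)
            assert np.all(np.abs(est - bpm) < 60.0 / 6.0)  # spectral resolution
            assert np.abs(est - bpm).max() < 1.0  # zero-padded peak grid

    def test_dominant_peak_wins_in_two_tone_signal(self):
        t = np.arange(0, 30, 1 / 30.0)
        wave = np.sin(2 * np.pi * 1.0 * t) + 0.1 * np.sin(2 * np.pi * 1.5 * t)
        est = estimate_bpm_series(wave, fs=30.0)
        assert np.abs(est - 60.0).max() < 1.0

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            estimate_bpm_series(np.zeros(100), fs=30.0)


class TestHrvQuantiles:
    def test_constant_and_linear_series(self):
        assert np.allclose(hrv_quantile_features(np.full(20, 70.0)), 70.0)
        q = hrv_quantile_features(np.arange(1.0, 101.0))
        assert np.allclose(q, [5.95, 25.75, 50.5, 75.25, 95.05])

    @given(st.lists(st.floats(40, 200), min_size=1, max_size=50))
    def test_output_nondecreasing(self, series):
        q = hrv_quantile_features(np.array(series))
        assert np.all(np.diff(q) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hrv_quantile_features(np.array([]))


class TestUniformResample:
    def test_identity_and_index_rule(self):
        s = _series(np.arange(9.0)[:, None])
        assert np.array_equal(uniform_resample(s, 9).values, s.values)
        out = uniform_resample(s, 5)
        assert np.array_equal(out.values[:, 0], [0, 2, 4, 6, 8])

    @given(st.integers(2, 60), st.integers(2, 60))
    def test_endpoints_always_retained(self, frames, target):
        if target > frames:
            frames, target = target, frames
        s = _series(np.arange(float(frames))[:, None])
        out = uniform_resample(s, target)
        assert out.values[0, 0] == 0
        assert out.values[-1, 0] == frames - 1
        assert out.n_frames == target

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            uniform_resample(_series(np.zeros((4, 1))), 5)
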