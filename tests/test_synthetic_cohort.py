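import numpy as np
import pytest

from convoscreen.synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    generate_markov_stream,
    generate_pulse_waveform,
    load_cohort,
    save_cohort,
)
from convoscreen.temporal_features import estimate_bpm_series

LIGHT_DIMS = {"emotion_aus": 4, "bpm": 1, "text_embedding": 16}


def _light_cfg(**kw):
    base = dict(n_participants=8, seed=7, length_range_min=(3.0, 5.0),
                modality_dims=dict(LIGHT_DIMS))
    base.update(kw)
    return CohortConfig(**base)


class TestCohortGeneration:
    def test_same_seed_gives_identical_cohorts(self):
        a = generate_cohort(_light_cfg())
        b = generate_cohort(_light_cfg())
        for ra, rb in zip(a, b):
            assert ra.participant_id == rb.participant_id
            assert ra.scores == rb.scores
            assert ra.attrs == rb.attrs
            for k in ra.streams:
                assert np.array_equal(ra.streams[k].values, rb.streams[k].values)
            for k in ra.static_vectors:
                assert np.array_equal(ra.static_vectors[k], rb.static_vectors[k])

    def test_default_config_cohort_size(self):
        records = generate_cohort(CohortConfig(seed=1))
        assert len(records) == 39
        assert len({r.participant_id for r in records}) == 39
        sample = records[0]
        assert sample.static_vectors["text_embedding"].shape == (8192,)
        assert sample.streams["facial_embedding"].dim == 1024
        del records

    def test_stream_durations_agree_with_interview_length(self):
        for r in generate_cohort(_light_cfg()):
            for name, s in r.streams.items():
                if name == "bpm":
                    continue  # derived stream: one estimate per hop, 5 s shorter
                expected = r.interview_len_s * s.rate
                assert abs(s.n_frames - expected) <= 1.0

    def test_scores_within_instrument_ranges(self):
        for r in generate_cohort(_light_cfg(n_participants=30, seed=2)):
            assert 0 <= r.scores.moca <= 30
            assert r.scores.cdr in (0.0, 0.5)
            assert 0 <= r.scores.lsns6 <= 30
            assert 0 <= r.scores.neuroticism <= 48
            assert r.attrs.diagnosis in ("NC", "MCI")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=3).validate()
        with pytest.raises(ValueError):
            CohortConfig(modality_dims={"x": 0}).validate()
        with pytest.raises(ValueError):
            CohortConfig(sampling_rates={"emotion_aus": -1}).validate()

    def test_group_bias_shifts_flagged_group_severity(self):
        cfg = _light_cfg(n_participants=150, seed=9, bias_attribute="sex",
                         bias_strength=1.5)
        recs = generate_cohort(cfg)
        f = [r.latent["cognition"] for r in recs if r.attrs.sex == "F"]
        m = [r.latent["cognition"] for r in recs if r.attrs.sex == "M"]
        assert np.mean(f) > np.mean(m) + 0.1

    def test_effect_size_zero_decouples_streams_from_latents(self):
        cfg = _light_cfg(n_participants=100, seed=4, effect_size=0.0)
        recs = generate_cohort(cfg)
        sev = np.array([r.latent["cognition"] for r in recs])
        feat = np.array([r.streams["emotion_aus"].values.mean() for r in recs])
        r = np.corrcoef(sev, feat)[0, 1]
        assert abs(r) < 0.25  # ~2.5 sigma at n=100


class TestMarkovStream:
    def test_absorbing_chain_stays_in_start_state(self):
        series, path = generate_markov_stream(
            n_states=3, transition=np.eye(3),
            emission_means=np.array([[0.0], [5.0], [9.0]]),
            emission_sd=0.0, length=50, seed=0,
            start_probs=np.array([1.0, 0.0, 0.0]),
        )
        assert np.all(path == 0)
        assert np.all(series.values == 0.0)

    def test_symmetric_two_state_occupancy_near_half(self):
        T = np.full((2, 2), 0.5)
        _, path = generate_markov_stream(
            2, T, np.zeros((2, 1)), 1.0, length=100_000, seed=1
        )
        occ = np.bincount(path, minlength=2) / len(path)
        assert np.allclose(occ, 0.5, atol=0.01)

    def test_zero_noise_emissions_equal_state_means(self):
        means = np.array([[1.0, -1.0], [3.0, 2.0]])
        series, path = generate_markov_stream(
            2, np.full((2, 2), 0.5), means, 0.0, length=200, seed=2
        )
        assert np.array_equal(series.values, means[path])

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            generate_markov_stream(2, np.array([[0.9, 0.2], [0.5, 0.5]]),
                                   np.zeros((2, 1)), 1.0, 10, 0)


class TestPulseWaveform:
    def test_zero_jitter_gives_pure_oscillation(self):
        pw = generate_pulse_waveform(72.0, 0.0, 30.0, 30.0, seed=0)
        est = estimate_bpm_series(pw.samples, pw.fs)
        assert np.abs(est - 72.0).max() < 1.0

    def test_ground_truth_bpm_constant_without_jitter(self):
        pw = generate_pulse_waveform(60.0, 0.0, 30.0, 30.0, seed=0)
        assert np.all(pw.true_bpm == 60.0)

    def test_jittered_estimates_track_ground_truth(self):
        pw = generate_pulse_waveform(72.0, 3.0, 120.0, 30.0, seed=3)
        est = estimate_bpm_series(pw.samples, pw.fs)
        # window i spans seconds [i, i+6): compare to windowed truth mean
        truth = np.array([pw.true_bpm[i : i + 6].mean() for i in range(len(est))])
        assert np.corrcoef(est, truth)[0, 1] > 0.8

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_pulse_waveform(20.0, 0.0, 10.0, 30.0, 0)
        with pytest.raises(ValueError):
            generate_pulse_waveform(120.0, 0.0, 10.0, 5.0, 0)  # undersampled


class TestSerialization:
    def test_roundtrip_preserves_scores_and_streams(self, tmp_path):
        cfg = _light_cfg(n_participants=5)
        records = generate_cohort(cfg)
        save_cohort(records, tmp_path / "cohort", config=cfg)
        loaded = load_cohort(tmp_path / "cohort")
        assert [r.participant_id for r in loaded] == [r.participant_id for r in records]
        for a, b in zip(records, loaded):
            assert a.scores.moca == b.scores.moca
            assert a.attrs.sex == b.attrs.sex
            np.testing.assert_allclose(
                a.streams["emotion_aus"].values,
                b.streams["emotion_aus"].values, rtol=1e-6,
            )
            np.testing.assert_allclose(
                a.static_vectors["text_embedding"],
                b.static_vectors["text_embedding"], rtol=1e-6,
            )
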