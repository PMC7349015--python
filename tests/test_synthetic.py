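"""Generator contracts: determinism, ground-truth consistency, and the
statistical structure each stream is supposed to carry."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import cogstates as cs
from cogstates.synthetic import SyntheticConfig, effective_amplitudes


def _amp_config(**overrides):
    base = {k: dict(v) for k, v in
            SyntheticConfig().band_amplitudes.items()}
    return SyntheticConfig(band_amplitudes=base, **overrides)


class TestEEGGeneration:
    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SyntheticConfig(seed=9)
        a, _ = cs.generate_eeg_session(cfg, "engaged", duration=5.0)
        b, _ = cs.generate_eeg_session(cfg, "engaged", duration=5.0)
        assert np.array_equal(a.data, b.data)

    def test_zero_amplitudes_and_noise_give_silence(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        cfg.band_amplitudes["engaged"] = {b: 0.0 for b in
                                          cfg.band_amplitudes["engaged"]}
        rec, _ = cs.generate_eeg_session(cfg, "engaged", duration=2.0)
        assert np.all(rec.data == 0.0)

    def test_single_band_has_unit_ground_truth_fraction(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        cfg.band_amplitudes["engaged"] = {
            "delta": 0.0, "theta": 0.0, "alpha": 10.0, "beta": 0.0, "gamma": 0.0}
        _, truth = cs.generate_eeg_session(cfg, "engaged", duration=5.0)
        np.testing.assert_allclose(truth["alpha"], 1.0)

    def test_realized_fractions_match_configured_within_one_percent(self):
        cfg = SyntheticConfig(noise_sd=0.0, seed=3)
        amps = cfg.band_amplitudes["non_engaged"]
        total = sum(a ** 2 for a in amps.values())
        _, truth = cs.generate_eeg_session(cfg, "non_engaged", duration=30.0)
        for band, a in amps.items():
            np.testing.assert_allclose(truth[band], a ** 2 / total, atol=0.01)

    def test_unknown_class_raises(self):
        with pytest.raises(KeyError):
            cs.generate_eeg_session(SyntheticConfig(), "bored")

    def test_strength_zero_collapses_class_amplitudes(self):
        cfg = SyntheticConfig(engagement_signal_strength=0.0)
        a = effective_amplitudes(cfg, "engaged")
        b = effective_amplitudes(cfg, "non_engaged")
        assert a == pytest.approx(b)


class TestBaseline:
    def test_segment_durations_total_36_seconds(self):
        base = cs.generate_baseline(SyntheticConfig(seed=2))
        assert base.duration == pytest.approx(36.0)
        assert base.open_eyes.n_samples == 1920  # 15 s at 128 Hz
        assert base.ready.n_samples == 6 * 128

    def test_closed_eyes_alpha_is_elevated(self):
        base = cs.generate_baseline(SyntheticConfig(seed=2, noise_sd=0.5))
        def alpha_rel(rec):
            rels = [cs.band_energies(cs.dwt_decompose(x, rec.fs)).rel["alpha"]
                    for x in rec.data]
            return np.mean(rels)
        assert alpha_rel(base.closed_eyes) > alpha_rel(base.open_eyes)

    def test_reproducible(self):
        cfg = SyntheticConfig(seed=5)
        a = cs.generate_baseline(cfg)
        b = cs.generate_baseline(cfg)
        assert np.array_equal(a.closed_eyes.data, b.closed_eyes.data)


class TestLandmarks:
    def test_frame_count_follows_fps_and_duration(self):
        seq, _ = cs.generate_landmark_sequence(
            SyntheticConfig(seed=1), "engaged", duration=10.0)
        assert seq.n_frames == 300

    def test_zero_blink_rate_keeps_ear_nearly_constant(self):
        cfg = SyntheticConfig(seed=1, landmark_jitter=0.0,
                              blink_rate={"engaged": 0.0, "non_engaged": 0.0})
        seq, events = cs.generate_landmark_sequence(cfg, "engaged",
                                                    duration=30.0)
        assert events == []
        ears = cs.frame_feature_series(seq)["ear"]
        assert ears.std() < 0.02

    def test_blink_dips_match_ground_truth_events(self):
        cfg = SyntheticConfig(seed=8, landmark_jitter=0.0,
                              blink_rate={"engaged": 12.0})
        seq, events = cs.generate_landmark_sequence(cfg, "engaged",
                                                    duration=60.0)
        detected = cs.count_blinks(cs.frame_feature_series(seq)["ear"].to_numpy())
        assert detected == len(events)
        # rate sanity: Poisson(12) over one minute
        assert 3 <= len(events) <= 24


class TestTrialLog:
    def test_zero_rate_class_makes_no_mistakes(self):
        cfg = SyntheticConfig(seed=4, mistake_rate={"high": 0.0, "low": 6.0})
        log = cs.generate_trial_log(cfg, ["high"] * 30)
        assert all(ok for _, ok in log.trials)

    def test_mean_mistakes_match_truncated_poisson_oracle(self):
        # oracle: E[min(Poisson(6), trials_per_window)] computed by direct
        # summation of the Poisson pmf
        lam, trials_per_window = 6.0, 10
        k = np.arange(0, 200)
        pmf = stats.poisson.pmf(k, lam)
        expected = float(np.sum(np.minimum(k, trials_per_window) * pmf))
        var = float(np.sum((np.minimum(k, trials_per_window) - expected) ** 2 * pmf))
        n_windows = 1000
        cfg = SyntheticConfig(seed=4, mistake_rate={"high": 0.0, "low": lam})
        log = cs.generate_trial_log(cfg, ["low"] * n_windows)
        mistakes = [log.mistakes_in(10.0 * i, 10.0 * (i + 1))
                    for i in range(n_windows)]
        tol = 3.0 * np.sqrt(var / n_windows)
        assert np.mean(mistakes) == pytest.approx(expected, abs=tol)

    def test_fixed_seed_identical(self):
        cfg = SyntheticConfig(seed=12)
        a = cs.generate_trial_log(cfg, ["low", "high"] * 5)
        b = cs.generate_trial_log(cfg, ["low", "high"] * 5)
        assert a.trials == b.trials


class TestEngagementScores:
    def test_strength_one_separates_classes_at_half(self):
        cfg = SyntheticConfig(seed=6, engagement_signal_strength=1.0)
        series = cs.generate_engagement_scores(cfg, [1, 0] * 100)
        v = series.values
        assert v[::2].min() >= 0.5 and v[1::2].max() <= 0.5

    def test_strength_zero_removes_class_dependence(self):
        cfg = SyntheticConfig(seed=6, engagement_signal_strength=0.0)
        engaged = cs.generate_engagement_scores(cfg, [1] * 50, seed=99)
        non = cs.generate_engagement_scores(cfg, [0] * 50, seed=99)
        np.testing.assert_array_equal(engaged.values, non.values)

    def test_fourteen_minute_session_yields_84_scores(self):
        cfg = SyntheticConfig(seed=6)
        series = cs.generate_engagement_scores(cfg, [1] * 84)
        assert len(series.scores) == 84
        assert series.scores[-1][0] == pytest.approx(830.0)


class TestCohort:
    def test_same_config_twice_is_identical(self, small_config):
        a, truth_a = cs.generate_cohort(small_config)
        b, truth_b = cs.generate_cohort(small_config)
        assert truth_a.equals(truth_b)
        for ba, bb in zip(a, b):
            assert np.array_equal(ba.eeg.data, bb.eeg.data)
            assert ba.trial_log.trials == bb.trial_log.trials

    def test_empty_cohort_is_valid(self):
        bundles, truth = cs.generate_cohort(SyntheticConfig(n_subjects=0))
        assert bundles == [] and truth.empty

    def test_bundles_are_internally_consistent(self, small_config):
        bundle, truth = next(cs.iter_cohort(small_config))
        n_int = len(truth)
        assert bundle.eeg.duration == pytest.approx(10.0 * n_int)
        assert len(bundle.engagement.scores) == n_int
        assert cs.validate_session(bundle) == []
        # engagement scores agree with the latent state at strength 1
        for (_, s), e in zip(bundle.engagement.scores,
                             truth["engagement_state"]):
            assert (s > 0.5) == bool(e)

    def test_modalities_subset_is_respected(self):
        cfg = SyntheticConfig(n_subjects=1, session_duration=30.0,
                              modalities=("eeg", "scores"))
        bundle, _ = next(cs.iter_cohort(cfg))
        assert bundle.landmarks is None and bundle.trial_log is None
        assert bundle.engagement is not None

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            cfg = _amp_config()
            cfg.band_amplitudes["engaged"]["alpha"] = -1.0
            SyntheticConfig(band_amplitudes=cfg.band_amplitudes)
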