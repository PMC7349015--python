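"""Time-domain statistics, Hjorth parameters, wavelet band powers and
decibel normalization, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram

import cogstates as cs
from cogstates.eeg_features import (
    CANONICAL_BANDS,
    decomposition_level,
    frequency_features,
)
from cogstates.errors import BaselineError, FormatError
from cogstates.io_sessions import EMOTIV_14, EEGRecording
from cogstates.synthetic import SyntheticConfig


def brute_force_mobility(x):
    """Literal evaluation: sqrt(var(forward diff)/var(x)), population var."""
    x = np.asarray(x, dtype=float)
    return np.sqrt(np.var(np.diff(x)) / np.var(x))


def brute_force_complexity(x):
    dx = np.diff(np.asarray(x, dtype=float))
    return brute_force_mobility(dx) / brute_force_mobility(x)


class TestHjorth:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 500)
        assert cs.hjorth_mobility(x) == pytest.approx(2.0, abs=1e-5)
        assert cs.hjorth_complexity(x) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("freq", [2.0, 5.0, 20.0])
    def test_sinusoid_matches_brute_force_and_closed_form(self, freq):
        fs, secs = 128.0, 10
        x = np.sin(2 * np.pi * freq * np.arange(int(fs * secs)) / fs)
        assert cs.hjorth_mobility(x) == pytest.approx(
            brute_force_mobility(x), abs=1e-9)
        assert cs.hjorth_complexity(x) == pytest.approx(
            brute_force_complexity(x), abs=1e-9)
        # per-sample closed form for a long pure tone
        assert cs.hjorth_mobility(x) == pytest.approx(
            2 * np.sin(np.pi * freq / fs), rel=2e-3)
        assert cs.hjorth_complexity(x) == pytest.approx(1.0, rel=5e-3)

    def test_constant_series_is_undefined(self):
        assert np.isnan(cs.hjorth_mobility(np.ones(100)))
        assert np.isnan(cs.hjorth_complexity(np.ones(100)))

    def test_linear_ramp_complexity_is_undefined(self):
        ramp = np.linspace(0.0, 1.0, 100)
        assert np.isfinite(cs.hjorth_mobility(ramp))
        assert np.isnan(cs.hjorth_complexity(ramp))

    def test_too_short_series_raises(self):
        with pytest.raises(FormatError):
            cs.hjorth_mobility([1.0, 2.0])


class TestTimeDomain:
    def test_fourteen_channels_yield_210_features(self, rng):
        rec = EEGRecording(rng.normal(size=(14, 1280)), 128.0, EMOTIV_14)
        feats = cs.time_domain_features(rec)
        assert len(feats) == 210
        assert feats.index[0] == "AF3_min"
        assert feats.index[-1] == "AF4_hjorth_complexity"

    def test_quartiles_are_ordered_between_extremes(self, rng):
        for _ in range(20):
            x = rng.normal(scale=rng.uniform(0.1, 10), size=200)
            rec = EEGRecording(x[None, :], 128.0, ("AF3",))
            f = cs.time_domain_features(rec)
            assert (f["AF3_min"] <= f["AF3_q1"] <= f["AF3_q2"]
                    <= f["AF3_q3"] <= f["AF3_max"])

    def test_shapiro_on_gaussian_draws_rarely_rejects(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(200):
            rec = EEGRecording(rng.normal(size=(1, 1280)), 128.0, ("AF3",))
            p = cs.time_domain_features(rec)["AF3_sw_p"]
            rejections += p <= 0.01
        assert rejections <= 10  # >= 95% of seeds retain normality

    def test_constant_channel_gets_nan_sentinels_not_zeros(self):
        rec = EEGRecording(np.full((1, 128), 3.0), 128.0, ("AF3",))
        f = cs.time_domain_features(rec)
        assert f["AF3_mean"] == 3.0 and f["AF3_max"] == 3.0
        for stat in ("kurtosis", "skewness", "sw_W", "sw_p",
                     "hjorth_mobility", "cv"):
            assert np.isnan(f[f"AF3_{stat}"])


def _periodogram_band_powers(x, fs):
    """Independent band-power oracle via the periodogram."""
    f, pxx = periodogram(x, fs)
    out = {}
    for band, (lo, hi) in CANONICAL_BANDS.items():
        out[band] = pxx[(f > lo) & (f <= hi)].sum()
    total = pxx.sum()
    return {k: v / total for k, v in out.items()}


class TestWavelet:
    def test_band_map_at_headset_rate(self):
        dec = cs.dwt_decompose(np.random.default_rng(0).normal(size=1280), 128.0)
        assert dec.level == 4
        mapping = {b.name: (b.f_lo, b.f_hi, b.label) for b in dec.bands}
        assert mapping["A4"] == (0.0, 4.0, "delta")
        assert mapping["D4"] == (4.0, 8.0, "theta")
        assert mapping["D3"] == (8.0, 16.0, "alpha")
        assert mapping["D2"] == (16.0, 32.0, "beta")
        assert mapping["D1"] == (32.0, 64.0, "gamma")

    def test_band_map_at_high_rate_matches_dyadic_table(self):
        assert decomposition_level(1000.0) == 7
        dec = cs.dwt_decompose(np.random.default_rng(0).normal(size=8000), 1000.0)
        mapping = {b.name: b.label for b in dec.bands}
        assert mapping["D4"] == "gamma"      # ~31-63 Hz
        assert mapping["D3"] == "noise"      # 63-125 Hz, out of interest range
        assert mapping["D1"] == "noise"

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=1280)
        dec = cs.dwt_decompose(x, 128.0)
        np.testing.assert_allclose(dec.reconstruct(), x, atol=1e-8)

    def test_too_short_signal_raises(self):
        with pytest.raises(FormatError):
            cs.dwt_decompose(np.ones(1), 128.0)

    @pytest.mark.parametrize("freq,band", [
        (2.0, "delta"), (6.0, "theta"), (10.0, "alpha"),
        (24.0, "beta"), (40.0, "gamma"),
    ])
    def test_band_power_agrees_with_periodogram_oracle(self, freq, band):
        fs = 128.0
        x = np.sin(2 * np.pi * freq * np.arange(1280) / fs)
        rel = cs.band_energies(cs.dwt_decompose(x, fs)).rel
        oracle = _periodogram_band_powers(x, fs)
        assert max(rel, key=rel.get) == max(oracle, key=oracle.get) == band
        assert rel[band] == pytest.approx(oracle[band], rel=0.15)

    def test_alpha_sinusoid_dominates_alpha_band(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(1280) / 128.0)
        bp = cs.band_energies(cs.dwt_decompose(x, 128.0))
        assert bp.rel["alpha"] >= 0.85
        assert all(bp.rel.get(b, 0.0) <= 0.1
                   for b in ("delta", "theta", "beta", "gamma"))

    def test_zero_signal_gives_undefined_relative_powers(self):
        bp = cs.band_energies(cs.dwt_decompose(np.zeros(256), 128.0))
        assert bp.e_total == 0.0
        assert all(np.isnan(v) for v in bp.rel.values())

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_relative_powers_sum_to_one(self, seed):
        x = np.random.default_rng(seed).normal(size=640)
        rel = cs.band_energies(cs.dwt_decompose(x, 128.0)).rel
        assert sum(rel.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in rel.values())


class TestBaselineNormalization:
    @pytest.mark.parametrize("activity,baseline,expected", [
        (10.0, 10.0, 0.0), (100.0, 10.0, 10.0), (1.0, 10.0, -10.0),
    ])
    def test_decibel_conversion(self, activity, baseline, expected):
        assert cs.baseline_normalize(activity, baseline).value == pytest.approx(
            expected)

    def test_zero_activity_clamps_at_floor(self):
        assert cs.baseline_normalize(0.0, 10.0).value == -120.0

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(BaselineError):
            cs.baseline_normalize(1.0, 0.0)


@pytest.fixture(scope="module")
def window():
    cfg = SyntheticConfig(seed=17)
    rec, _ = cs.generate_eeg_session(cfg, "engaged", duration=10.0)
    return rec


class TestWindowFeatures:
    def test_mode_cardinalities(self, window):
        assert len(cs.extract_window_features(window, mode="frequency")) == 70
        assert len(cs.extract_window_features(window, mode="time")) == 210
        assert len(cs.extract_window_features(window, mode="combined")) == 280

    def test_activity_equal_to_baseline_gives_zero_db(self, rng):
        data = rng.normal(size=(2, 36 * 128))
        rec = EEGRecording(data, 128.0, ("AF3", "F7"))
        base = cs.BaselineRecording(
            open_eyes=rec.slice_seconds(0, 15),
            closed_eyes=rec.slice_seconds(15, 30),
            ready=rec.slice_seconds(30, 36))
        feats = frequency_features(rec, base)
        for ch in ("AF3", "F7"):
            assert feats[f"{ch}_db_avg"] == pytest.approx(0.0, abs=1e-9)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.normal(size=(3, 640))
        a = cs.extract_window_features(
            EEGRecording(data, 128.0, ("A", "B", "C")), mode="frequency")
        b = cs.extract_window_features(
            EEGRecording(data[::-1], 128.0, ("C", "B", "A")), mode="frequency")
        for name, value in a.items():
            assert b[name] == value
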