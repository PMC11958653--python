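import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cogload import eda, features as ft
from cogload import preprocess as pp
from cogload import synthetic as syn


def rr_series(values_ms, start=0.0):
    peaks = start + np.concatenate([[0.0], np.cumsum(values_ms) / 1000.0])
    return pp.RRSeries(rr=np.asarray(values_ms, float), peak_times=peaks)


def modulated_rr(freq_hz, amp_ms=50.0, mean_ms=800.0, duration_s=120.0):
    times, t = [], 0.0
    rr = []
    while t < duration_s:
        v = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
        rr.append(v)
        t += v / 1000.0
        times.append(t)
    return pp.RRSeries(rr=np.array(rr), peak_times=np.concatenate([[0.0], times]))


class TestHrvTime:
    def test_constant_series(self):
        out = ft.hrv_time_features(rr_series([800, 800, 800, 800]))
        assert out["RMSSD"] == 0
        assert out["SDRR"] == 0
        assert out["HR"] == 75.0
        assert out["PNN50"] == 0

    def test_rmssd_matches_hand_summation(self):
        # diffs 50, -60, 30 -> sum of squares 7000 over 3 differences
        out = ft.hrv_time_features(rr_series([800, 850, 790, 820]))
        assert np.isclose(out["RMSSD"], np.sqrt(7000.0 / 3.0))

    def test_printed_rmssd_variant(self):
        out = ft.hrv_time_features(rr_series([800, 850, 790, 820]), printed_rmssd=True)
        assert np.isclose(out["RMSSD"], np.sqrt(7000.0) / 3.0)

    def test_pnn50_by_direct_count(self):
        # diffs 60, -40: one of two exceeds 50 ms
        out = ft.hrv_time_features(rr_series([800, 860, 820]))
        assert out["PNN50"] == 50.0
        assert out["PNN25"] == 100.0

    def test_hr_identity(self, rng):
        vals = rng.uniform(700, 900, 30)
        out = ft.hrv_time_features(rr_series(vals))
        assert np.isclose(out["HR"], 60000.0 / out["MEAN"])


class TestPoincare:
    def test_constant_degenerate(self):
        assert ft.hrv_poincare(rr_series([800] * 5)) == (0.0, 0.0)

    def test_sd1_identity_with_rotated_coordinates(self, rng):
        vals = rng.uniform(700, 900, 40)
        sd1, sd2 = ft.hrv_poincare(rr_series(vals))
        # independent oracle: project consecutive pairs on the rotated axes
        x, y = vals[:-1], vals[1:]
        perp = (y - x) / np.sqrt(2)
        along = (x + y) / np.sqrt(2)
        assert np.isclose(sd1**2, np.var(perp, ddof=1))
        assert sd1 >= 0 and sd2 >= 0

    def test_alternating_series_short_term_dominates(self):
        sd1, sd2 = ft.hrv_poincare(rr_series([790, 810] * 10))
        assert sd1 > sd2


class TestSpectral:
    def test_hf_modulation_lands_in_hf_band(self):
        out = ft.hrv_spectral(modulated_rr(0.25))
        assert out["HF"] / (out["HF"] + out["LF"]) >= 0.9

    def test_lf_modulation_lands_in_lf_band(self):
        out = ft.hrv_spectral(modulated_rr(0.10))
        assert out["LF"] > out["HF"]

    def test_ratio_reciprocity(self):
        out = ft.hrv_spectral(modulated_rr(0.25))
        assert np.isclose(out["LF_HF"] * out["HF_LF"], 1.0)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(pp.InsufficientBeatsError):
            ft.hrv_spectral(rr_series([800] * 5))


class TestGsrFeatures:
    def _decomp(self, phasic, tonic_level=2.0, fs=50.0):
        phasic = np.asarray(phasic, float)
        tonic = np.full(phasic.size, tonic_level)
        return eda.SCDecomposition(
            sc=tonic + phasic, sc_tonic=tonic, sc_phasic=phasic,
            driver=np.zeros(phasic.size), fs=fs, tau=eda.DEFAULT_TAU,
            residual_rms=0.0,
        )

    def test_null_phasic(self):
        out = ft.gsr_features(self._decomp(np.zeros(3000)), events=[])
        assert out["AreaSCR"] == 0
        assert out["No_Peakes"] == 0
        assert out["STDSCRdata"] == 0
        assert out["AvgRiseTime"] == 0 and out["AvgDecayTime"] == 0

    def test_triangular_bump_area_matches_trapezoid_rule(self):
        fs = 50.0
        n = int(60 * fs)
        t = np.arange(n) / fs
        phasic = np.clip(1.0 - np.abs(t - 10.0), 0.0, None)  # base 2 s, height 1
        out = ft.gsr_features(self._decomp(phasic), events=[])
        assert abs(out["AreaSCR"] - 1.0) <= 2.0 / fs

    def test_nine_fields_exactly(self):
        out = ft.gsr_features(self._decomp(np.zeros(100)), events=[])
        assert list(out) == ft.GSR_FEATURE_NAMES
        assert len(out) == 9


class TestAccelFeatures:
    def test_static_posture(self):
        sig = pp.TriaxialSignal(np.ones(100), np.zeros(100), np.zeros(100), fs=50)
        out = ft.accel_features(sig)
        assert out["meanR"] == 1.0
        assert out["stdX"] == 0.0
        assert out["rangeY"] == 0.0

    def test_hand_statistics(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sig = pp.TriaxialSignal(x, np.zeros(5), np.zeros(5), fs=5)
        out = ft.accel_features(sig)
        assert out["meanX"] == 3.0
        assert out["medianX"] == 3.0
        assert np.isclose(out["stdX"], np.sqrt(2.5))
        assert out["minX"] == 1.0 and out["maxX"] == 5.0 and out["rangeX"] == 4.0

    def test_twenty_four_values(self):
        sig = pp.TriaxialSignal(np.ones(10), np.ones(10), np.ones(10), fs=10)
        assert len(ft.accel_features(sig)) == 24


class TestFeatureVectorProperties:
    def test_cardinalities(self, rng):
        vals = rng.uniform(700, 900, 80)
        hrv = ft.hrv_features(rr_series(vals))
        assert list(hrv) == ft.HRV_FEATURE_NAMES and len(hrv) == 19
        assert len(ft.ACCEL_FEATURE_NAMES) == 24

    def test_pnn_ordering_and_hr_identity(self, rng):
        for _ in range(20):
            vals = rng.uniform(600, 1000, 30)
            out = ft.hrv_time_features(rr_series(vals))
            assert out["PNN50"] <= out["PNN25"]
            assert np.isclose(out["HR"], 60000.0 / out["MEAN"])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        c=hst.floats(min_value=0.5, max_value=2.0),
        seed=hst.integers(min_value=0, max_value=1000),
    )
    def test_scale_equivariance(self, c, seed):
        vals = np.random.default_rng(seed).uniform(700, 900, 20)
        base = ft.hrv_time_features(rr_series(vals))
        sd1, sd2 = ft.hrv_poincare(rr_series(vals))
        scaled = ft.hrv_time_features(rr_series(vals * c))
        ssd1, ssd2 = ft.hrv_poincare(rr_series(vals * c))
        for key in ("RMSSD", "MEAN", "MEDIAN", "SDRR", "SDSD"):
            assert np.isclose(scaled[key], c * base[key])
        assert np.isclose(scaled["HR"], base["HR"] / c)
        assert np.isclose(ssd1, c * sd1) and np.isclose(ssd2, c * sd2)


class TestBuildFeatureTable:
    def test_physio_table_width_and_labels(self, small_study):
        table = ft.build_feature_table(small_study, cda_fs_work=10)
        meta = {"participant_id", "label", "window_index"}
        assert set(table.columns) - meta == set(
            ft.HRV_FEATURE_NAMES + ft.GSR_FEATURE_NAMES
        )
        assert len(table.columns) == 28 + 3
        assert set(table["label"]) <= {"baseline", "visual", "code"}
        assert not table[ft.HRV_FEATURE_NAMES + ft.GSR_FEATURE_NAMES].isna().any().any()

    def test_accel_table_width(self, small_study):
        table = ft.build_feature_table(small_study, include_accel=True, cda_fs_work=10)
        assert len(table.columns) == 52 + 3

    def test_three_minute_baseline_gives_three_windows(self):
        config = syn.StudyConfig(
            n_participants=2, fs=50.0, session_length_s=60.0,
            baseline_length_s=180.0, seed=3,
            effects=syn.ConditionEffects(
                rep_duration_mean_s={"visual": 10.0, "code": 16.0}
            ),
        )
        study = syn.generate_study(config)
        table = ft.build_feature_table(study, cda_fs_work=10)
        baseline_rows = table[table["label"] == "baseline"]
        assert (baseline_rows.groupby("participant_id").size() == 3).all()
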