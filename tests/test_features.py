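"""Frame-level feature extraction: hand oracles, scaling laws, assembly counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristppg import assemble_feature_row, build_dataset, frame_features
from wristppg.errors import DegenerateFrameError, WristPPGError
from wristppg.features import (
    FEATURE_NAMES,
    ar_coefficient,
    canonical_combo,
    feature_columns,
    kaiser_teager_energy,
    kte_features,
    lag1_autocorrelation,
    mean_wavelet_coefficient,
    psd_features,
    spectral_shape_features,
    sum_absolute_differences,
    temporal_features,
    zero_crossing_rate,
)

from .conftest import tone


class TestTemporal:
    def test_alternating_sequence_hand_values(self):
        frame = np.array([1.0, -1.0, 1.0, -1.0])
        feats = temporal_features(frame)
        assert feats["zcr"] == pytest.approx(1.0)
        assert feats["sad"] == pytest.approx(6.0)
        assert feats["acr"] == pytest.approx(-1.0)

    def test_constant_frame_degenerate_but_zcr_sad_defined(self):
        const = np.full(10, 3.0)
        assert sum_absolute_differences(const) == 0.0
        assert zero_crossing_rate(const) == 0.0
        with pytest.raises(DegenerateFrameError):
            temporal_features(const)

    def test_symmetric_frame_has_zero_skew(self):
        assert temporal_features(np.array([-1.0, 0.0, 1.0]))["skew"] == pytest.approx(0.0)


class TestPSD:
    def test_tone_psd_spikier_than_noise(self, rng):
        n = 72
        tone_frame = tone(1.2, duration=3.0)
        noise_frame = rng.normal(size=n)
        assert (
            psd_features(tone_frame, 24.0)["psd_kurt"]
            > psd_features(noise_frame, 24.0)["psd_kurt"]
        )

    def test_scaling_laws(self, rng):
        x = rng.normal(size=72)
        k = 3.0
        a, b = psd_features(x, 24.0), psd_features(k * x, 24.0)
        assert b["psd_mean"] == pytest.approx(k**2 * a["psd_mean"], rel=1e-9)
        assert b["psd_var"] == pytest.approx(k**4 * a["psd_var"], rel=1e-9)
        assert b["psd_kurt"] == pytest.approx(a["psd_kurt"], rel=1e-9)

    def test_periodogram_peak_at_tone_bin(self):
        from scipy.signal import periodogram

        x = tone(1.2, duration=3.0)
        f, pxx = periodogram(x - x.mean(), fs=24.0)
        assert abs(f[np.argmax(pxx)] - 1.2) <= 24.0 / 72 / 2 + 1e-9


class TestKTE:
    def test_hand_sequence(self):
        np.testing.assert_allclose(kaiser_teager_energy(np.array([1.0, 2.0, 3.0])), [1.0])
        feats = kte_features(np.array([1.0, 2.0, 3.0]))
        assert feats["kte_mean"] == pytest.approx(1.0)
        assert feats["kte_var"] == pytest.approx(0.0)

    def test_sinusoid_energy_nearly_constant(self):
        x = 2.0 * tone(1.2, duration=3.0)
        feats = kte_features(x)
        assert feats["kte_var"] < 1e-6 * max(feats["kte_mean"] ** 2, 1e-30)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_laws(self, k):
        rng = np.random.default_rng(99)
        x = rng.normal(size=72)
        a, b = kte_features(x), kte_features(k * x)
        assert b["kte_mean"] == pytest.approx(k**2 * a["kte_mean"], rel=1e-9)
        assert b["kte_kurt"] == pytest.approx(a["kte_kurt"], rel=1e-9)
        assert b["kte_skew"] == pytest.approx(a["kte_skew"], rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateFrameError):
            kaiser_teager_energy(np.array([1.0, 2.0]))


class TestSpectralShape:
    def test_symmetric_two_tone_has_zero_skew(self):
        # bin-aligned tones at 3 and 7 Hz (72 samples at 24 Hz -> 1/3 Hz bins)
        t = np.arange(72) / 24.0
        x = np.cos(2 * np.pi * 3.0 * t) + np.cos(2 * np.pi * 7.0 * t)
        assert spectral_shape_features(x, 24.0)["spec_skew"] == pytest.approx(0.0, abs=1e-6)

    def test_weak_high_tone_skews_positive(self):
        t = np.arange(72) / 24.0
        x = np.cos(2 * np.pi * 2.0 * t) + 0.2 * np.cos(2 * np.pi * 10.0 * t)
        assert spectral_shape_features(x, 24.0)["spec_skew"] > 0

    def test_amplitude_invariance(self, rng):
        x = rng.normal(size=72)
        a = spectral_shape_features(x, 24.0)
        b = spectral_shape_features(5.5 * x, 24.0)
        assert b["spec_skew"] == pytest.approx(a["spec_skew"], rel=1e-9)
        assert b["spec_kurt"] == pytest.approx(a["spec_kurt"], rel=1e-9)


class TestWaveletAR:
    def test_zero_frame_wavelet_mean_is_zero(self):
        assert mean_wavelet_coefficient(np.zeros(72)) == 0.0

    def test_ar1_process_recovery(self):
        rng = np.random.default_rng(7)
        n = 3000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        assert ar_coefficient(x) == pytest.approx(0.8, abs=0.1)

    def test_scaling_laws(self, rng):
        x = rng.normal(size=72)
        assert mean_wavelet_coefficient(4.0 * x) == pytest.approx(
            4.0 * mean_wavelet_coefficient(x), rel=1e-9
        )
        assert ar_coefficient(4.0 * x) == pytest.approx(ar_coefficient(x), rel=1e-9)

    def test_constant_frame_flagged(self):
        with pytest.raises(DegenerateFrameError):
            ar_coefficient(np.ones(72))


class TestAssembly:
    def test_eq_column_counts(self):
        assert len(feature_columns("rgb", False, True)) == 47
        assert len(feature_columns("rgb", True, True)) == 50
        assert len(feature_columns("g", False, False)) == 15
        assert len(feature_columns("rg", True, False)) == 32

    def test_every_symbol_maps_to_one_column(self):
        cols = feature_columns("rgb", True, True)
        assert len(cols) == len(set(cols))
        for w in ("red", "green", "blue"):
            for name in FEATURE_NAMES:
                assert f"{w}_{name}" in cols
            assert f"acdc_{w}" in cols
        assert "bmi" in cols and "spo2" in cols

    def test_assemble_row_matches_column_contract(self, rng):
        frames = {w: tone(1.2, duration=3.0) + 0.05 * rng.normal(size=72)
                  for w in ("red", "green", "blue")}
        acdc = {"red": 0.03, "green": 0.05, "blue": 0.04}
        row = assemble_feature_row(frames, acdc, 25.0, 98.0, "rgb", True, True)
        assert list(row) == feature_columns("rgb", True, True)
        assert all(np.isfinite(v) for v in row.values())

    def test_missing_channel_rejected(self):
        with pytest.raises(WristPPGError):
            assemble_feature_row({"red": tone(1.2, duration=3.0)}, {}, 25.0, 98.0, "rg")

    def test_combo_normalisation(self):
        assert canonical_combo("GB") == ("green", "blue")
        assert canonical_combo(["blue", "red"]) == ("red", "blue")
        assert canonical_combo("green") == ("green",)
        with pytest.raises(WristPPGError):
            canonical_combo("xyz")


class TestBuildDataset:
    def test_row_count_and_grouping(self, small_cohort, small_dataset):
        records, _ = small_cohort
        tab = small_dataset.table
        # 30 s at 24 Hz -> 10 frames per subject, 10 subjects
        assert len(tab) == 100
        assert tab.groupby("subject_id").size().eq(10).all()
        assert tab.columns[0] == "subject_id"
        assert "hba1c" in tab.columns

    def test_labels_constant_within_subject(self, small_dataset):
        assert small_dataset.table.groupby("subject_id")["hba1c"].nunique().eq(1).all()

    def test_features_finite_at_default_noise(self, small_dataset):
        X, _, _ = small_dataset.matrix("rgb", True, True)
        assert np.isfinite(X.to_numpy()).all()

    def test_determinism(self, small_config):
        from wristppg import generate_cohort

        r1, _ = generate_cohort(small_config)
        r2, _ = generate_cohort(small_config)
        d1 = build_dataset(r1).table
        d2 = build_dataset(r2).table
        assert d1.equals(d2)

    def test_matrix_subsetting(self, small_dataset):
        X, groups, y = small_dataset.matrix("g", include_acdc=True, include_external=False)
        assert X.shape[1] == 16
        assert groups.size == y.size == X.shape[0]
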