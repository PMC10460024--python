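"""Peak/valley detection and AC/DC ratio extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristppg import (
    CohortConfig,
    clean_config,
    compute_ac_dc,
    detect_peaks_valleys,
    generate_subject,
    subject_acdc,
    true_acdc,
)
from wristppg.acdc import channel_frame_results, frame_acdc
from wristppg.cohort import WAVELENGTHS, subject_seed
from wristppg.errors import (
    InvalidBaselineError,
    NoPulsationError,
    UnreliableSubjectError,
)

from .conftest import tone


class TestDetection:
    def test_sinusoid_extrema_found_at_analytic_positions(self):
        """sin(2*pi*1.2 t) over 3 s at 24 Hz peaks at samples 5,25,45,65."""
        frame = tone(1.2, duration=3.0)
        peaks, valleys = detect_peaks_valleys(frame, 24.0)
        assert 3 <= peaks.size <= 4 and 3 <= valleys.size <= 4
        for p in peaks:
            assert min(abs(p - e) for e in (5, 25, 45, 65)) <= 1
        for v in valleys:
            assert min(abs(v - e) for e in (15, 35, 55)) <= 1

    def test_constant_frame_raises_no_pulsation(self):
        with pytest.raises(NoPulsationError):
            detect_peaks_valleys(np.full(72, 3.0), 24.0)

    def test_two_beat_pulse_train(self):
        """Clean generated two-beat segment: exactly 2 peaks with a valley between."""
        cfg = clean_config(CohortConfig(seed=8, baseline_spread=1.0))
        rec = generate_subject(cfg, 6.0, 123)
        x = rec.signals["green"]
        fs = cfg.sampling_rate
        # the generator's heart rate is recoverable from the spectrum
        from scipy.signal import periodogram

        f, pxx = periodogram(x - x.mean(), fs=fs)
        hr_hz = f[np.argmax(pxx)]
        two_beats = x[: int(round(2 * fs / hr_hz)) + 1]
        peaks, valleys = detect_peaks_valleys(two_beats - two_beats.mean(), fs)
        assert peaks.size == 2
        assert any(peaks[0] < v < peaks[1] for v in valleys)

    def test_alternation_after_reconciliation(self):
        frame = tone(1.4, duration=3.0) + 0.05 * np.sin(
            2 * np.pi * 7.0 * np.arange(72) / 24.0
        )
        peaks, valleys = detect_peaks_valleys(frame, 24.0)
        merged = sorted([(p, "p") for p in peaks] + [(v, "v") for v in valleys])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_short_frame_rejected(self):
        with pytest.raises(NoPulsationError):
            detect_peaks_valleys(np.sin(np.arange(8)), 24.0, min_beat_interval=0.33)


class TestComputeAcDc:
    def test_sinusoid_identity(self):
        """B + A sin with B=100, A=2: AC = 4, DC2 = 100, AC/DC = 0.04."""
        frame = 100.0 + 2.0 * tone(1.2, duration=3.0)
        peaks, valleys = detect_peaks_valleys(frame - frame.mean(), 24.0)
        res = compute_ac_dc(frame, peaks, valleys, dc_mode="dc2")
        assert res.ac == pytest.approx(4.0, rel=0.01)
        assert res.dc2 == pytest.approx(100.0, rel=0.01)
        assert res.acdc == pytest.approx(0.04, rel=0.01)

    def test_hand_arithmetic_on_listed_extrema(self):
        """Peaks {102,104}, valleys {98,96}: AC=6, DC1=97, DC2=100."""
        values = np.array([100.0, 102.0, 100.0, 98.0, 100.0, 104.0, 100.0, 96.0])
        peaks = np.array([1, 5])
        valleys = np.array([3, 7])
        res = compute_ac_dc(values, peaks, valleys, dc_mode="dc2")
        assert res.ac == pytest.approx(6.0)
        assert res.dc1 == pytest.approx(97.0)
        assert res.dc2 == pytest.approx(100.0)
        res1 = compute_ac_dc(values, peaks, valleys, dc_mode="dc1")
        assert res1.acdc == pytest.approx(6.0 / 97.0)

    def test_dc_mean_mode_averages_both_definitions(self):
        values = np.array([100.0, 102.0, 100.0, 98.0, 100.0, 104.0, 100.0, 96.0])
        res = compute_ac_dc(values, [1, 5], [3, 7], dc_mode="dc_mean")
        assert res.acdc == pytest.approx(6.0 / ((97.0 + 100.0) / 2.0))

    def test_nonpositive_baseline_rejected(self):
        frame = 2.0 * tone(1.2, duration=3.0) - 50.0
        peaks, valleys = detect_peaks_valleys(frame, 24.0)
        with pytest.raises(InvalidBaselineError):
            compute_ac_dc(frame, peaks, valleys, dc_mode="dc2")

    def test_empty_extrema_rejected(self):
        with pytest.raises(NoPulsationError):
            compute_ac_dc(np.ones(10), np.array([]), np.array([2]))

    @settings(max_examples=25, deadline=None)
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_of_ratio(self, k):
        """Multiplying the record by k > 0 leaves AC/DC unchanged."""
        frame = 100.0 + 2.0 * tone(1.2, duration=3.0)
        peaks, valleys = detect_peaks_valleys(frame - frame.mean(), 24.0)
        base = compute_ac_dc(frame, peaks, valleys)
        scaled = compute_ac_dc(k * frame, peaks, valleys)
        assert scaled.acdc == pytest.approx(base.acdc, rel=1e-12)
        assert scaled.ac == pytest.approx(k * base.ac, rel=1e-12)

    def test_offset_shifts_dc_not_ac(self):
        frame = 100.0 + 2.0 * tone(1.2, duration=3.0)
        peaks, valleys = detect_peaks_valleys(frame - frame.mean(), 24.0)
        base = compute_ac_dc(frame, peaks, valleys)
        shifted = compute_ac_dc(frame + 7.0, peaks, valleys)
        assert shifted.ac == pytest.approx(base.ac, abs=1e-12)
        assert shifted.dc2 == pytest.approx(base.dc2 + 7.0, abs=1e-9)


class TestSubjectAcdc:
    def test_clean_record_recovers_programmed_ratio(self):
        cfg = clean_config(CohortConfig(seed=4))
        rec = generate_subject(cfg, 6.5, subject_seed(cfg, 1))
        for w in WAVELENGTHS:
            measured = subject_acdc(rec, w)
            assert measured == pytest.approx(true_acdc(cfg, 6.5, w), rel=0.02)

    def test_monotone_in_hba1c_on_clean_cohort(self):
        cfg = clean_config(CohortConfig(seed=6))
        values = []
        for i, h in enumerate(np.linspace(5.2, 7.7, 6)):
            rec = generate_subject(cfg, float(h), subject_seed(cfg, i))
            values.append(subject_acdc(rec, "red"))
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_green_exceeds_red_and_blue_per_subject(self):
        cfg = CohortConfig(seed=7)
        for i, h in enumerate((5.5, 6.5, 7.5)):
            rec = generate_subject(cfg, h, subject_seed(cfg, i))
            g = subject_acdc(rec, "green")
            assert g > subject_acdc(rec, "red")
            assert g > subject_acdc(rec, "blue")

    def test_all_frames_identical_signal_gives_frame_value(self):
        cfg = clean_config(CohortConfig(seed=1, baseline_spread=1.0))
        rec = generate_subject(cfg, 6.0, subject_seed(cfg, 0))
        results = channel_frame_results(rec.signals["green"], cfg.sampling_rate)
        per_frame = [r.acdc for r in results if r is not None]
        assert subject_acdc(rec, "green") == pytest.approx(np.mean(per_frame))
        # constant heart rate: every interior frame carries the same ratio
        assert np.std(per_frame[1:-1]) < 0.03 * np.mean(per_frame)

    def test_flat_record_is_unreliable(self):
        cfg = CohortConfig()
        rec = generate_subject(clean_config(cfg), 6.0, 1)
        flat = dataclasses.replace(
            rec, signals={w: np.full_like(rec.signals[w], 100.0) for w in WAVELENGTHS}
        )
        with pytest.raises(UnreliableSubjectError):
            subject_acdc(flat, "green")

    def test_frame_acdc_reads_values_on_baseline_trace(self):
        fs = 24.0
        conditioned = 2.0 * tone(1.2, duration=3.0)
        baseline_trace = 100.0 + conditioned
        res = frame_acdc(conditioned, baseline_trace, fs)
        assert res.dc2 == pytest.approx(100.0, rel=0.01)
        assert res.acdc == pytest.approx(0.04, rel=0.01)
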