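"""Peak/valley detection and AC/DC perfusion-ratio extraction.

For each 3 s frame the detector locates cardiac peaks and valleys on the
conditioned (band-passed, drift-removed) trace, then reads their values
from the low-pass trace so the baseline is intact.  The AC component is
the distance between the mean peak level and the mean valley level; the
DC component is either the average of valley values (``dc1``), the average
of adjacent peak/valley midpoints (``dc2``, the default), or the average
of the two (``dc_mean``).  The dimensionless AC/DC ratio is the quantity
linked to HbA1c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import WAVELENGTHS, CohortRecord
from .errors import (
    InvalidBaselineError,
    NoPulsationError,
    UnreliableSubjectError,
    WristPPGError,
)
from . import preprocess

#: default minimum beat spacing (s); 0.33 s caps detection at 180 bpm
MIN_BEAT_INTERVAL_S = 0.33
#: default prominence floor as a fraction of the frame interquartile range
MIN_PROMINENCE = 0.25

DC_MODES = ("dc1", "dc2", "dc_mean")


@dataclass(frozen=True)
class PeakValleyResult:
    peak_indices: np.ndarray
    valley_indices: np.ndarray
    peak_mean: float
    valley_mean: float
    ac: float
    dc1: float
    dc2: float
    acdc: float


def detect_peaks_valleys(
    frame: np.ndarray,
    sampling_rate: float,
    min_beat_interval: float = MIN_BEAT_INTERVAL_S,
    min_prominence: float = MIN_PROMINENCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate alternating cardiac peaks and valleys in one frame.

    Local maxima/minima are found with a minimum spacing of
    ``min_beat_interval`` and a prominence floor of ``min_prominence`` times
    the frame's interquartile range; consecutive extrema of the same kind
    are then reconciled by keeping the most extreme one, so the returned
    sequences strictly alternate in time.
    """
    frame = np.asarray(frame, dtype=float)
    distance = max(int(round(min_beat_interval * sampling_rate)), 1)
    if frame.size < 2 * distance:
        raise NoPulsationError(
            f"frame of {frame.size} samples too short for beat interval "
            f"{min_beat_interval} s"
        )
    q1, q3 = np.percentile(frame, [25, 75])
    prominence = min_prominence * (q3 - q1)
    if not np.isfinite(prominence) or np.ptp(frame) <= 0 or prominence <= 0:
        raise NoPulsationError("no pulsation: frame is flat or below prominence floor")
    peaks, _ = signal.find_peaks(frame, distance=distance, prominence=prominence)
    valleys, _ = signal.find_peaks(-frame, distance=distance, prominence=prominence)
    if peaks.size == 0 or valleys.size == 0:
        raise NoPulsationError("no pulsation: found no prominent peak/valley pair")
    return _enforce_alternation(frame, peaks, valleys)


def _enforce_alternation(
    frame: np.ndarray, peaks: np.ndarray, valleys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge detections in time order; of each same-kind run keep the extremum."""
    idx = np.concatenate([peaks, valleys])
    kind = np.concatenate([np.ones(peaks.size, int), np.zeros(valleys.size, int)])
    order = np.argsort(idx, kind="stable")
    idx, kind = idx[order], kind[order]

    kept_idx: list[int] = []
    kept_kind: list[int] = []
    for i, k in zip(idx, kind):
        if kept_kind and kept_kind[-1] == k:
            prev = kept_idx[-1]
            better = (frame[i] > frame[prev]) if k == 1 else (frame[i] < frame[prev])
            if better:
                kept_idx[-1] = i
        else:
            kept_idx.append(i)
            kept_kind.append(k)
    kept_idx_arr = np.asarray(kept_idx)
    kept_kind_arr = np.asarray(kept_kind)
    return kept_idx_arr[kept_kind_arr == 1], kept_idx_arr[kept_kind_arr == 0]


def compute_ac_dc(
    raw_frame: np.ndarray,
    peaks: np.ndarray,
    valleys: np.ndarray,
    dc_mode: str = "dc2",
    dc_reference: float = 0.0,
) -> PeakValleyResult:
    """AC, DC and AC/DC from detected extrema of a baseline-bearing frame.

    ``raw_frame`` must carry its physical baseline (raw or low-pass trace);
    ``dc_reference`` is added back when the caller supplies a zero-mean
    trace plus a separately tracked DC level.
    """
    if dc_mode not in DC_MODES:
        raise WristPPGError(f"unknown dc_mode {dc_mode!r}; choose from {DC_MODES}")
    peaks = np.asarray(peaks, dtype=int)
    valleys = np.asarray(valleys, dtype=int)
    if peaks.size == 0 or valleys.size == 0:
        raise NoPulsationError("need at least one peak and one valley")
    values = np.asarray(raw_frame, dtype=float) + dc_reference

    peak_mean = float(values[peaks].mean())
    valley_mean = float(values[valleys].mean())
    ac = peak_mean - valley_mean
    dc1 = valley_mean
    dc2 = _midpoint_mean(values, peaks, valleys)
    dc = {"dc1": dc1, "dc2": dc2, "dc_mean": 0.5 * (dc1 + dc2)}[dc_mode]
    if dc <= 0:
        raise InvalidBaselineError(f"selected DC ({dc_mode}) is non-positive: {dc:.4g}")
    return PeakValleyResult(
        peak_indices=peaks,
        valley_indices=valleys,
        peak_mean=peak_mean,
        valley_mean=valley_mean,
        ac=ac,
        dc1=dc1,
        dc2=dc2,
        acdc=ac / dc,
    )


def _midpoint_mean(values: np.ndarray, peaks: np.ndarray, valleys: np.ndarray) -> float:
    """Mean of (peak+valley)/2 over paired adjacent extrema.

    The i-th peak is paired with the i-th valley (both sequences are in
    time order and alternate after reconciliation, so pairs are adjacent
    beats); an unmatched trailing extremum is ignored.
    """
    n = min(peaks.size, valleys.size)
    mids = 0.5 * (values[peaks[:n]] + values[valleys[:n]])
    return float(np.mean(mids))


def frame_acdc(
    conditioned_frame: np.ndarray,
    baseline_frame: np.ndarray,
    sampling_rate: float,
    dc_mode: str = "dc2",
    min_beat_interval: float = MIN_BEAT_INTERVAL_S,
    min_prominence: float = MIN_PROMINENCE,
) -> PeakValleyResult:
    """Detect on the conditioned trace, measure on the baseline-bearing one."""
    conditioned_frame = np.asarray(conditioned_frame, dtype=float)
    baseline_frame = np.asarray(baseline_frame, dtype=float)
    # excursions below ~1e-9 of the baseline are filter round-off, not pulse
    scale = max(float(np.mean(np.abs(baseline_frame))), 1.0)
    if np.ptp(conditioned_frame) <= 1e-9 * scale:
        raise NoPulsationError("no pulsation: excursion negligible vs baseline")
    peaks, valleys = detect_peaks_valleys(
        conditioned_frame, sampling_rate, min_beat_interval, min_prominence
    )
    return compute_ac_dc(baseline_frame, peaks, valleys, dc_mode=dc_mode)


def channel_frame_results(
    raw_samples: np.ndarray,
    sampling_rate: float,
    dc_mode: str = "dc2",
    window_s: float = preprocess.WINDOW_S,
    min_beat_interval: float = MIN_BEAT_INTERVAL_S,
    min_prominence: float = MIN_PROMINENCE,
) -> list[PeakValleyResult | None]:
    """Per-frame AC/DC results for one raw channel (None where detection fails)."""
    chan = preprocess.preprocess_channel(raw_samples, sampling_rate)
    cond_frames = preprocess.segment(chan.samples, sampling_rate, window_s)
    lpf_frames = preprocess.segment(chan.lpf_samples, sampling_rate, window_s)
    out: list[PeakValleyResult | None] = []
    for cf, lf in zip(cond_frames, lpf_frames):
        try:
            out.append(
                frame_acdc(
                    cf.samples, lf.samples, sampling_rate,
                    dc_mode, min_beat_interval, min_prominence,
                )
            )
        except WristPPGError:
            out.append(None)
    return out


def subject_acdc(
    record: CohortRecord,
    wavelength: str,
    dc_mode: str = "dc2",
    window_s: float = preprocess.WINDOW_S,
) -> float:
    """Subject-level AC/DC: mean of per-frame ratios over successful frames.

    Raises :class:`UnreliableSubjectError` when fewer than half of the
    frames yield a detection.
    """
    if wavelength not in WAVELENGTHS:
        raise WristPPGError(f"unknown wavelength {wavelength!r}")
    results = channel_frame_results(
        record.signals[wavelength], record.sampling_rate, dc_mode, window_s
    )
    ok = [r.acdc for r in results if r is not None]
    if len(ok) < max(1, len(results) / 2):
        raise UnreliableSubjectError(
            f"subject {record.subject_id}/{wavelength}: detection succeeded on "
            f"{len(ok)}/{len(results)} frames"
        )
    return float(np.mean(ok))
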