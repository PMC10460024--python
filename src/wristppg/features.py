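"""Frame-level feature extraction for multi-wavelength PPG.

Fifteen features per wavelength per 3 s frame, in a fixed canonical order:

temporal        zcr, acr (lag-1 autocorrelation), skew, sad
PSD moments     psd_kurt, psd_var, psd_mean (periodogram values)
KTE moments     kte_kurt, kte_var, kte_mean, kte_skew
                (Kaiser-Teager energy psi[n] = x[n]^2 - x[n-1]*x[n+1])
spectral shape  spec_kurt, spec_skew (moments of frequency under the
                normalised magnitude spectrum)
wavelet         wavelet_mean (mean |CWT| coefficient, Mexican-hat, scales 1-9)
autoregressive  ar (lag-1 coefficient of an order-4 Yule-Walker fit)

The optional AC/DC block appends one perfusion-ratio column per wavelength
and the external block appends BMI and SpO2, giving the documented column
counts 15 per wavelength, 47 for RGB with externals, and 50 with AC/DC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats
from statsmodels.regression.linear_model import yule_walker

from . import acdc as acdc_mod
from . import preprocess
from .cohort import WAVELENGTHS, CohortRecord
from .errors import DegenerateFrameError, UnreliableSubjectError, WristPPGError

logger = logging.getLogger(__name__)

#: canonical per-wavelength feature order
FEATURE_NAMES = (
    "zcr", "acr",
    "psd_kurt", "psd_var", "psd_mean",
    "kte_kurt", "kte_var", "kte_mean", "kte_skew",
    "spec_kurt", "spec_skew",
    "wavelet_mean", "ar",
    "skew", "sad",
)
EXTERNAL_NAMES = ("bmi", "spo2")
WAVELET_SCALES = np.arange(1, 10)
AR_ORDER = 4


def zero_crossing_rate(frame: np.ndarray) -> float:
    """Sign changes of the mean-removed frame per sample step (zeros skipped)."""
    x = np.asarray(frame, dtype=float)
    centred = x - x.mean()
    signs = np.sign(centred)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(signs)) / (x.size - 1))


def sum_absolute_differences(frame: np.ndarray) -> float:
    return float(np.abs(np.diff(np.asarray(frame, dtype=float))).sum())


def lag1_autocorrelation(frame: np.ndarray) -> float:
    """Lag-1 autocorrelation: mean lagged product over population variance."""
    x = np.asarray(frame, dtype=float)
    centred = x - x.mean()
    var = float(np.mean(centred**2))
    if var == 0:
        raise DegenerateFrameError("constant frame: autocorrelation undefined")
    return float(np.mean(centred[:-1] * centred[1:]) / var)


def temporal_features(frame: np.ndarray) -> dict[str, float]:
    x = np.asarray(frame, dtype=float)
    if x.size < 3:
        raise DegenerateFrameError("frame shorter than 3 samples")
    if np.ptp(x) == 0:
        raise DegenerateFrameError("constant frame: skew and acr undefined")
    return {
        "zcr": zero_crossing_rate(x),
        "acr": lag1_autocorrelation(x),
        "skew": float(stats.skew(x)),
        "sad": sum_absolute_differences(x),
    }


def psd_features(frame: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """Mean, variance and kurtosis of the periodogram values.

    A single 72-sample frame is too short for multi-segment Welch averaging,
    so the plain periodogram of the mean-removed frame is used.
    """
    x = np.asarray(frame, dtype=float)
    if x.size < 8:
        raise DegenerateFrameError("frame too short for a PSD estimate")
    if np.ptp(x) == 0:
        raise DegenerateFrameError("constant frame: PSD moments undefined")
    _, pxx = signal.periodogram(x - x.mean(), fs=sampling_rate)
    return {
        "psd_kurt": float(stats.kurtosis(pxx)),
        "psd_var": float(np.var(pxx)),
        "psd_mean": float(np.mean(pxx)),
    }


def kaiser_teager_energy(frame: np.ndarray) -> np.ndarray:
    x = np.asarray(frame, dtype=float)
    if x.size < 3:
        raise DegenerateFrameError("KTE needs at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def kte_features(frame: np.ndarray) -> dict[str, float]:
    psi = kaiser_teager_energy(frame)
    return {
        "kte_kurt": float(stats.kurtosis(psi)),
        "kte_var": float(np.var(psi)),
        "kte_mean": float(np.mean(psi)),
        "kte_skew": float(stats.skew(psi)),
    }


def spectral_shape_features(frame: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """Skewness and kurtosis of frequency under the normalised magnitude spectrum.

    The DC bin is excluded; the remaining magnitudes are treated as a
    probability mass over frequency, and the third/fourth standardised
    moments about the spectral centroid are returned.  Both are invariant
    under amplitude scaling of the frame.
    """
    x = np.asarray(frame, dtype=float)
    if x.size < 8:
        raise DegenerateFrameError("frame too short for spectral-shape moments")
    mag = np.abs(np.fft.rfft(x - x.mean()))[1:]
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sampling_rate)[1:]
    total = mag.sum()
    if total == 0:
        raise DegenerateFrameError("all-zero spectrum")
    p = mag / total
    centroid = float(np.sum(p * freqs))
    sd = float(np.sqrt(np.sum(p * (freqs - centroid) ** 2)))
    if sd == 0:
        raise DegenerateFrameError("single-line spectrum: shape moments undefined")
    z = (freqs - centroid) / sd
    return {
        "spec_kurt": float(np.sum(p * z**4)),
        "spec_skew": float(np.sum(p * z**3)),
    }


def mean_wavelet_coefficient(frame: np.ndarray) -> float:
    """Mean absolute Mexican-hat CWT coefficient over scales 1-9."""
    x = np.asarray(frame, dtype=float)
    if x.size < 16:
        raise DegenerateFrameError("frame too short for a CWT")
    coeffs, _ = pywt.cwt(x, WAVELET_SCALES, "mexh")
    return float(np.mean(np.abs(coeffs)))


def ar_coefficient(frame: np.ndarray, order: int = AR_ORDER) -> float:
    """Lag-1 coefficient of an order-`order` Yule-Walker (MLE) AR fit."""
    x = np.asarray(frame, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFrameError("constant frame: AR fit degenerate")
    rho, _ = yule_walker(x - x.mean(), order=order, method="mle")
    return float(rho[0])


def wavelet_ar_features(frame: np.ndarray) -> dict[str, float]:
    return {
        "wavelet_mean": mean_wavelet_coefficient(frame),
        "ar": ar_coefficient(frame),
    }


def frame_features(frame: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """All 15 per-wavelength features of one conditioned frame, in canonical order."""
    vals: dict[str, float] = {}
    vals.update(temporal_features(frame))
    vals.update(psd_features(frame, sampling_rate))
    vals.update(kte_features(frame))
    vals.update(spectral_shape_features(frame, sampling_rate))
    vals.update(wavelet_ar_features(frame))
    ordered = {name: vals[name] for name in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in ordered.values()):
        raise DegenerateFrameError("non-finite feature value")
    return ordered


def canonical_combo(combo) -> tuple[str, ...]:
    """Normalise a wavelength combination ('RGB', ['green'], ...) to canonical order."""
    short = {"r": "red", "g": "green", "b": "blue"}
    if isinstance(combo, str):
        if combo.lower() in WAVELENGTHS:
            names = [combo.lower()]
        else:
            names = [short.get(c, c) for c in combo.lower()]
    else:
        names = [short.get(str(c).lower(), str(c).lower()) for c in combo]
    names_set = set(names)
    if not names_set or not names_set.issubset(WAVELENGTHS):
        raise WristPPGError(f"invalid wavelength combination {combo!r}")
    return tuple(w for w in WAVELENGTHS if w in names_set)


def feature_columns(
    combo, include_acdc: bool = False, include_external: bool = True
) -> list[str]:
    """Deterministic column list (wavelength-major, canonical feature order)."""
    waves = canonical_combo(combo)
    cols = [f"{w}_{name}" for w in waves for name in FEATURE_NAMES]
    if include_acdc:
        cols += [f"acdc_{w}" for w in waves]
    if include_external:
        cols += list(EXTERNAL_NAMES)
    return cols


def assemble_feature_row(
    frames_by_wavelength: dict[str, np.ndarray],
    acdc_by_wavelength: dict[str, float],
    bmi: float,
    spo2: float,
    combo,
    include_acdc: bool = False,
    include_external: bool = True,
    sampling_rate: float = 24.0,
) -> dict[str, float]:
    """One frame's feature vector for a wavelength combination."""
    waves = canonical_combo(combo)
    missing = [w for w in waves if w not in frames_by_wavelength]
    if missing:
        raise WristPPGError(f"missing channel(s) {missing} for combination {waves}")
    row: dict[str, float] = {}
    for w in waves:
        feats = frame_features(frames_by_wavelength[w], sampling_rate)
        row.update({f"{w}_{name}": v for name, v in feats.items()})
    if include_acdc:
        for w in waves:
            row[f"acdc_{w}"] = float(acdc_by_wavelength[w])
    if include_external:
        row["bmi"] = float(bmi)
        row["spo2"] = float(spo2)
    return row


@dataclass(frozen=True)
class Dataset:
    """Frame-level design matrix with subject grouping and labels."""

    table: pd.DataFrame  # subject_id, frame_index, features..., hba1c

    def matrix(self, combo="rgb", include_acdc: bool = True,
               include_external: bool = True):
        """Return (X, groups, y) restricted to a combination and feature flags."""
        cols = feature_columns(combo, include_acdc, include_external)
        X = self.table[cols].copy()
        return X, self.table["subject_id"].to_numpy(), self.table["hba1c"].to_numpy()


def build_dataset(
    records: list[CohortRecord],
    dc_mode: str = "dc2",
    window_s: float = preprocess.WINDOW_S,
    acdc_level: str = "subject",
) -> Dataset:
    """Full-cohort frame-level feature table (all three wavelengths).

    One row per (subject, frame) where every channel yielded a detection and
    finite features; dropped frames are counted in the log.  ``acdc_level``
    selects whether the AC/DC columns carry the subject-level mean ratio
    (one value per subject per wavelength, the default) or each frame's own
    ratio.
    """
    if acdc_level not in ("subject", "frame"):
        raise WristPPGError(f"acdc_level must be 'subject' or 'frame', got {acdc_level!r}")
    rows = []
    for rec in records:
        fs = rec.sampling_rate
        per_wave_results = {}
        per_wave_frames = {}
        for w in WAVELENGTHS:
            chan = preprocess.preprocess_channel(rec.signals[w], fs)
            per_wave_frames[w] = preprocess.segment(chan.samples, fs, window_s)
            per_wave_results[w] = acdc_mod.channel_frame_results(
                rec.signals[w], fs, dc_mode, window_s
            )
        n_frames = len(per_wave_frames[WAVELENGTHS[0]])
        subject_means = {}
        for w in WAVELENGTHS:
            ok = [r.acdc for r in per_wave_results[w] if r is not None]
            if len(ok) < max(1, n_frames / 2):
                raise UnreliableSubjectError(
                    f"subject {rec.subject_id}/{w}: {len(ok)}/{n_frames} frames usable"
                )
            subject_means[w] = float(np.mean(ok))
        dropped = 0
        for i in range(n_frames):
            if any(per_wave_results[w][i] is None for w in WAVELENGTHS):
                dropped += 1
                continue
            if acdc_level == "subject":
                acdc_vals = subject_means
            else:
                acdc_vals = {w: per_wave_results[w][i].acdc for w in WAVELENGTHS}
            try:
                row = assemble_feature_row(
                    {w: per_wave_frames[w][i].samples for w in WAVELENGTHS},
                    acdc_vals,
                    rec.bmi,
                    rec.spo2,
                    combo="rgb",
                    include_acdc=True,
                    include_external=True,
                    sampling_rate=fs,
                )
            except DegenerateFrameError:
                dropped += 1
                continue
            rows.append(
                {"subject_id": rec.subject_id, "frame_index": i, **row, "hba1c": rec.hba1c}
            )
        if dropped:
            logger.info("subject %s: dropped %d/%d frames", rec.subject_id, dropped, n_frames)
        if not any(r["subject_id"] == rec.subject_id for r in rows):
            raise UnreliableSubjectError(
                f"subject {rec.subject_id}: no valid frames after feature extraction"
            )
    return Dataset(table=pd.DataFrame(rows))
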