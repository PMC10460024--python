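"""Synthetic multi-wavelength PPG cohort generator.

Emulates a wrist reflectance-PPG study cohort: for each subject, three
channels (red 615 nm, green 525 nm, blue 465 nm) sampled at 24 Hz for
2 min, together with BMI, SpO2 and a reference HbA1c label.  Each channel
is a static baseline modulated by

* a pulsatile cardiac component whose peak-to-trough amplitude relative to
  the baseline (the AC/DC perfusion ratio) increases linearly with the
  subject's HbA1c,
* a respiratory oscillation below 0.33 Hz,
* a slow baseline drift, and
* white Gaussian noise.

The programmed AC/DC-versus-HbA1c line is exposed through
:func:`true_acdc`, which gives every downstream stage a recoverable ground
truth.  The green channel's ratio is largest by default, matching the
qualitative ordering reported for wrist measurements.

Per-subject, per-channel baseline levels vary (log-uniformly) to emulate
sensor-coupling and skin-tone differences between subjects; raw amplitude
features are therefore confounded across subjects while the dimensionless
AC/DC ratio is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

WAVELENGTHS = ("red", "green", "blue")


def _raised_cosine_sq(phase: np.ndarray) -> np.ndarray:
    """Squared raised-cosine beat template on [0, 1): min 0, max 1.

    Harmonic content stops at twice the beat frequency, so an 8 Hz low-pass
    leaves the peak-to-trough excursion essentially untouched for heart
    rates up to 100 bpm.
    """
    return ((1.0 - np.cos(2.0 * np.pi * phase)) / 2.0) ** 2


def _cosine(phase: np.ndarray) -> np.ndarray:
    """Pure sinusoidal beat template (min 0, max 1)."""
    return (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0


BEAT_TEMPLATES = {
    "raised_cosine_sq": _raised_cosine_sq,
    "cosine": _cosine,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Amplitude-like fields (`respiratory_amplitude`, `drift_amplitude`,
    `noise_sd`) are fractions of the channel baseline.  `acdc_base` is the
    per-wavelength AC/DC ratio at the bottom of the HbA1c range and
    `acdc_slope` its increase per HbA1c percentage point.
    """

    n_subjects: int = 22
    sampling_rate: float = 24.0          # Hz
    duration: float = 120.0              # s
    heart_rate_range: tuple[float, float] = (60.0, 100.0)   # bpm
    hba1c_range: tuple[float, float] = (5.2, 7.7)           # %
    acdc_base: dict[str, float] = field(
        default_factory=lambda: {"red": 0.020, "green": 0.030, "blue": 0.024}
    )
    acdc_slope: dict[str, float] = field(
        default_factory=lambda: {"red": 0.024, "green": 0.024, "blue": 0.024}
    )
    respiratory_rate: float = 0.25       # Hz, must stay below 0.33
    respiratory_amplitude: float = 0.010
    drift_amplitude: float = 0.010
    noise_sd: float = 0.003
    bmi_mean_sd: tuple[float, float] = (25.53, 2.77)
    bmi_range: tuple[float, float] = (19.50, 30.52)
    spo2_mean_sd: tuple[float, float] = (97.75, 0.79)
    spo2_range: tuple[float, float] = (96.0, 99.0)
    baseline_level: float = 1000.0       # arbitrary ADC counts
    baseline_spread: float = 2.0         # per-subject log-uniform factor
    beat_template: str = "raised_cosine_sq"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.respiratory_rate >= 0.33:
            raise ConfigurationError(
                "respiratory_rate must stay below 0.33 Hz "
                f"(got {self.respiratory_rate})"
            )
        if self.beat_template not in BEAT_TEMPLATES:
            raise ConfigurationError(
                f"unknown beat template {self.beat_template!r}; "
                f"choose from {sorted(BEAT_TEMPLATES)}"
            )
        lo, hi = self.hba1c_range
        if not lo < hi:
            raise ConfigurationError("hba1c_range must be increasing")
        for w in WAVELENGTHS:
            for h in (lo, hi):
                r = self.acdc_base[w] + self.acdc_slope[w] * (h - lo)
                if not 0.0 < r < 1.0:
                    raise ConfigurationError(
                        f"target AC/DC ratio {r:.3f} for {w} at HbA1c {h} "
                        "is outside (0, 1)"
                    )


@dataclass(frozen=True)
class CohortRecord:
    """One subject: three raw PPG channels plus covariates and label."""

    subject_id: str
    signals: dict[str, np.ndarray]       # wavelength -> samples
    sampling_rate: float
    bmi: float
    spo2: float
    hba1c: float

    @property
    def n_samples(self) -> int:
        return len(self.signals[WAVELENGTHS[0]])


def true_acdc(config: CohortConfig, hba1c: float, wavelength: str) -> float:
    """Programmed AC/DC ratio for a wavelength at a given HbA1c (%).

    Linear in HbA1c, anchored at the bottom of the configured range.
    """
    if wavelength not in WAVELENGTHS:
        raise ConfigurationError(f"unknown wavelength {wavelength!r}")
    lo = config.hba1c_range[0]
    return config.acdc_base[wavelength] + config.acdc_slope[wavelength] * (hba1c - lo)


def subject_seed(config: CohortConfig, subject_index: int) -> int:
    """Deterministic per-subject sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(config.seed), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_subject(
    config: CohortConfig,
    hba1c: float,
    seed: int,
    *,
    subject_id: str = "S00",
    bmi: float | None = None,
    spo2: float | None = None,
) -> CohortRecord:
    """Generate one subject's three-channel raw recording.

    Each channel is ``B_w * (1 + pulsatile + respiratory + drift + noise)``
    where the pulsatile term is a midpoint-centred beat template scaled so
    its peak-to-trough excursion over the baseline equals
    ``true_acdc(config, hba1c, w)``.  Identical ``(config, hba1c, seed)``
    yields a bit-identical record.
    """
    lo, hi = config.hba1c_range
    if not lo <= hba1c <= hi:
        raise ConfigurationError(
            f"hba1c {hba1c} outside configured range {config.hba1c_range}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(config.sampling_rate * config.duration))
    t = np.arange(n) / config.sampling_rate

    heart_rate = rng.uniform(*config.heart_rate_range)      # bpm
    beat_phase0 = rng.uniform(0.0, 1.0)
    resp_phase0 = rng.uniform(0.0, 2.0 * np.pi)
    drift_freq = rng.uniform(0.01, 0.05)                    # Hz
    drift_phase0 = rng.uniform(0.0, 2.0 * np.pi)
    template = BEAT_TEMPLATES[config.beat_template]

    phase = beat_phase0 + (heart_rate / 60.0) * t
    # centre the unit template so (max+min)/2 = 0, i.e. DC2 == baseline
    pulse_shape = template(phase % 1.0) - 0.5
    respiratory = config.respiratory_amplitude * np.sin(
        2.0 * np.pi * config.respiratory_rate * t + resp_phase0
    )
    drift = config.drift_amplitude * np.sin(
        2.0 * np.pi * drift_freq * t + drift_phase0
    )

    signals: dict[str, np.ndarray] = {}
    for w in WAVELENGTHS:
        ratio = true_acdc(config, hba1c, w)
        log_spread = math.log(config.baseline_spread)
        baseline = config.baseline_level * math.exp(
            rng.uniform(-log_spread, log_spread)
        )
        noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        signals[w] = baseline * (1.0 + ratio * pulse_shape + respiratory + drift + noise)

    if bmi is None:
        bmi = _truncated_normal(rng, config.bmi_mean_sd, config.bmi_range)
    if spo2 is None:
        spo2 = _truncated_normal(rng, config.spo2_mean_sd, config.spo2_range)
    return CohortRecord(
        subject_id=subject_id,
        signals=signals,
        sampling_rate=config.sampling_rate,
        bmi=float(bmi),
        spo2=float(spo2),
        hba1c=float(hba1c),
    )


def _truncated_normal(
    rng: np.random.Generator, mean_sd: tuple[float, float], bounds: tuple[float, float]
) -> float:
    mean, sd = mean_sd
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _hba1c_values(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Evenly spaced labels over the range plus small jitter.

    Guarantees label spread at small n while keeping draws stochastic;
    jitter SD is a sixth of the grid spacing, clipped back into range.
    """
    lo, hi = config.hba1c_range
    grid = np.linspace(lo, hi, config.n_subjects)
    spacing = (hi - lo) / max(config.n_subjects - 1, 1)
    jitter = rng.normal(0.0, spacing / 6.0, config.n_subjects)
    return np.clip(grid + jitter, lo, hi)


def generate_cohort(config: CohortConfig) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Generate the full cohort and its metadata table (one row per subject)."""
    if config.n_subjects < 2:
        raise ConfigurationError(
            "need at least 2 subjects for leave-one-subject-out evaluation"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 991]))
    hba1c = _hba1c_values(config, rng)
    records = []
    for i in range(config.n_subjects):
        records.append(
            generate_subject(
                config,
                float(hba1c[i]),
                subject_seed(config, i),
                subject_id=f"S{i:02d}",
            )
        )
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "bmi": [r.bmi for r in records],
            "spo2": [r.spo2 for r in records],
            "hba1c": [r.hba1c for r in records],
        }
    )
    return records, meta


def clean_config(config: CohortConfig) -> CohortConfig:
    """Copy of `config` with noise, respiration and drift switched off.

    Used for oracle-recovery checks where the measured AC/DC of a generated
    record must reproduce :func:`true_acdc`.
    """
    return replace(
        config, noise_sd=0.0, respiratory_amplitude=0.0, drift_amplitude=0.0
    )


# ---------------------------------------------------------------------------
# CSV round-trip (long-format signals + per-subject metadata)

def write_cohort(records: list[CohortRecord], meta: pd.DataFrame, outdir) -> None:
    """Write signals.csv (subject_id, sample_index, red, green, blue) and metadata.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chunks = []
    for r in records:
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": r.subject_id,
                    "sample_index": np.arange(r.n_samples),
                    **{w: r.signals[w] for w in WAVELENGTHS},
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(outdir / "signals.csv", index=False)
    meta.to_csv(outdir / "metadata.csv", index=False)


def read_cohort(indir, sampling_rate: float = 24.0) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Read a cohort previously written by :func:`write_cohort`."""
    from pathlib import Path

    indir = Path(indir)
    sig = pd.read_csv(indir / "signals.csv")
    meta = pd.read_csv(indir / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        sub = sig[sig["subject_id"] == row["subject_id"]].sort_values("sample_index")
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                signals={w: sub[w].to_numpy(float) for w in WAVELENGTHS},
                sampling_rate=sampling_rate,
                bmi=float(row["bmi"]),
                spo2=float(row["spo2"]),
                hba1c=float(row["hba1c"]),
            )
        )
    return records, meta
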