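"""Shared fixtures: small synthetic cohorts reused across test modules.

Session scope keeps the expensive feature builds to one per run.
"""

import dataclasses

import numpy as np
import pytest

from wristppg import CohortConfig, build_dataset, clean_config, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Ten subjects, 30 s recordings — enough frames for CV exercises."""
    return dataclasses.replace(CohortConfig(), n_subjects=10, duration=30.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    records, _ = small_cohort
    return build_dataset(records)


@pytest.fixture(scope="session")
def clean_small_config(small_config) -> CohortConfig:
    return clean_config(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230817)


def tone(freq: float, sampling_rate: float = 24.0, duration: float = 30.0,
         amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(sampling_rate * duration))) / sampling_rate
    return amplitude * np.sin(2.0 * np.pi * freq * t + phase)


def tone_amplitude(x: np.ndarray, freq: float, sampling_rate: float = 24.0) -> float:
    """Amplitude of the component at `freq`, interior samples only."""
    n = x.size
    lo, hi = n // 4, 3 * n // 4
    seg = x[lo:hi]
    t = np.arange(lo, hi) / sampling_rate
    z = np.exp(-2j * np.pi * freq * t)
    return float(2.0 * np.abs(np.mean(seg * z)))
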