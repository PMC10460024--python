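"""End-to-end experiment orchestration: simulate -> condition -> AC/DC ->
features -> model sweep -> evaluation report.

A single :class:`RunConfig` reaches every stage parameter and round-trips
through YAML.  The global seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence`` so each stage is independently reproducible.
Every intermediate table is persisted as CSV, and every number in the final
report is recomputable from those intermediates alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acdc as acdc_mod
from . import modeling, preprocess
from .cohort import WAVELENGTHS, CohortConfig, generate_cohort, write_cohort
from .errors import ConfigurationError
from .evaluation import build_report_tables
from .features import Dataset, build_dataset
from .modeling import CVResult, ModelSpec, feature_importances, select_features

logger = logging.getLogger(__name__)

FEATURE_SETS = ("base", "acdc", "selected")
ALL_COMBOS = ("R", "G", "B", "RG", "RB", "GB", "RGB")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    lpf_cutoff_hz: float = preprocess.LPF_CUTOFF_HZ
    hpf_cutoff_hz: float = preprocess.HPF_CUTOFF_HZ
    filter_order: int = preprocess.FILTER_ORDER
    window_s: float = preprocess.WINDOW_S
    drift_cutoff_hz: float = preprocess.DRIFT_CUTOFF_HZ
    # AC/DC extraction
    dc_mode: str = "dc2"
    min_beat_interval_s: float = acdc_mod.MIN_BEAT_INTERVAL_S
    min_prominence: float = acdc_mod.MIN_PROMINENCE
    acdc_level: str = "subject"
    # sweep
    combos: tuple[str, ...] = ALL_COMBOS
    feature_sets: tuple[str, ...] = ("base", "acdc")
    families: tuple[str, ...] = modeling.FAMILIES
    grids: dict[str, dict] = field(default_factory=dict)  # family -> grid
    include_external: bool = True
    aggregate: str = "mean"
    seed: int = 0

    def model_spec(self, family: str) -> ModelSpec:
        grid = self.grids.get(family) or modeling.default_grid(family)
        sub = np.random.SeedSequence([int(self.seed), modeling.FAMILIES.index(family)])
        return ModelSpec(family=family, grid=grid, seed=int(sub.generate_state(1)[0] % 2**31))

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**_tupled(payload.pop("cohort", {})))
        for key in ("combos", "feature_sets", "families"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(cohort=cohort, **payload)


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def validate_config(config: RunConfig) -> list[str]:
    """Collect every configuration violation (empty list means OK)."""
    problems: list[str] = []
    nyq = config.cohort.sampling_rate / 2.0
    for name, cutoff in (("lpf", config.lpf_cutoff_hz), ("hpf", config.hpf_cutoff_hz)):
        if not 0 < cutoff < nyq:
            problems.append(
                f"{name} cutoff {cutoff} Hz violates (0, Nyquist={nyq} Hz)"
            )
    if config.filter_order < 1:
        problems.append(f"filter order {config.filter_order} < 1")
    if config.window_s <= 0:
        problems.append("window_s must be positive")
    if config.dc_mode not in acdc_mod.DC_MODES:
        problems.append(f"unknown dc_mode {config.dc_mode!r}")
    for combo in config.combos:
        if not set(combo.upper()).issubset({"R", "G", "B"}) or not combo:
            problems.append(f"invalid wavelength combination {combo!r}")
    for fset in config.feature_sets:
        if fset not in FEATURE_SETS:
            problems.append(f"unknown feature set {fset!r}")
    for fam in config.families:
        if fam not in modeling.FAMILIES:
            problems.append(f"unknown model family {fam!r}")
        grid = config.grids.get(fam)
        if grid is not None and (not grid or any(len(v) == 0 for v in grid.values())):
            problems.append(f"empty hyperparameter grid for {fam}")
    if config.cohort.n_subjects < 2:
        problems.append("cohort needs at least 2 subjects")
    try:
        CohortConfig(**dataclasses.asdict(config.cohort))
    except (ConfigurationError, TypeError) as exc:
        problems.append(f"cohort config: {exc}")
    return problems


def _run_one(
    dataset: Dataset, config: RunConfig, combo: str, family: str, feature_set: str
) -> tuple[CVResult, pd.DataFrame]:
    """One (combo, family, feature-set) CV run; returns result + importances."""
    spec = config.model_spec(family)
    if feature_set == "base":
        X, groups, y = dataset.matrix(combo, include_acdc=False,
                                      include_external=config.include_external)
        cv = modeling.loso_cv(X, groups, y, spec, config.aggregate)
        return cv, feature_importances(cv)
    X, groups, y = dataset.matrix(combo, include_acdc=True,
                                  include_external=config.include_external)
    cv = modeling.loso_cv(X, groups, y, spec, config.aggregate)
    imp = feature_importances(cv)
    if feature_set == "acdc":
        return cv, imp
    # 'selected': re-run on the importance-selected subset of the AC/DC matrix
    cols = select_features(imp, combo, include_external=config.include_external)
    cv_sel = modeling.loso_cv(X[cols], groups, y, spec, config.aggregate)
    return cv_sel, feature_importances(cv_sel)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns a dict with the cohort metadata, the feature table, per-run CV
    results, and the report tables.  Identical config and seed reproduce
    identical artifacts.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    t0 = time.perf_counter()
    records, meta = generate_cohort(config.cohort)
    write_cohort(records, meta, outdir)
    logger.info("simulate: %d subjects (%.1fs)", len(records), time.perf_counter() - t0)

    t0 = time.perf_counter()
    acdc_rows = []
    for rec in records:
        for w in WAVELENGTHS:
            results = acdc_mod.channel_frame_results(
                rec.signals[w], rec.sampling_rate, config.dc_mode, config.window_s,
                config.min_beat_interval_s, config.min_prominence,
            )
            for i, res in enumerate(results):
                if res is None:
                    continue
                acdc_rows.append(
                    {
                        "subject_id": rec.subject_id, "frame_index": i, "wavelength": w,
                        "ac": res.ac, "dc1": res.dc1, "dc2": res.dc2, "acdc": res.acdc,
                    }
                )
    pd.DataFrame(acdc_rows).to_csv(outdir / "acdc_frames.csv", index=False)

    dataset = build_dataset(records, config.dc_mode, config.window_s, config.acdc_level)
    dataset.table.to_csv(outdir / "features.csv", index=False)
    logger.info(
        "features: %d rows x %d cols (%.1fs)",
        len(dataset.table), dataset.table.shape[1], time.perf_counter() - t0,
    )

    runs = []
    runs_dir = outdir / "runs"
    runs_dir.mkdir(exist_ok=True)
    for combo in config.combos:
        for family in config.families:
            for fset in config.feature_sets:
                t0 = time.perf_counter()
                cv, imp = _run_one(dataset, config, combo, family, fset)
                tag = f"{combo}_{family}_{fset}"
                pd.DataFrame(
                    {
                        "subject_id": cv.subject_ids,
                        "y_true": cv.subject_truth,
                        "y_pred": cv.subject_predictions,
                    }
                ).to_csv(runs_dir / f"{tag}_predictions.csv", index=False)
                imp.to_csv(runs_dir / f"{tag}_importances.csv", index=False)
                runs.append(
                    {
                        "combo": combo, "family": family, "feature_set": fset,
                        "pred": cv.subject_predictions, "truth": cv.subject_truth,
                        "cv": cv, "importances": imp,
                    }
                )
                logger.info(
                    "run %s: r=%.3f (%.1fs)",
                    tag, cv.pearson_r, time.perf_counter() - t0,
                )

    tables = build_report_tables(runs)
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    for name, tab in tables.items():
        tab.to_csv(report_dir / f"{name}.csv")
    summary = [
        f"wristppg pipeline report: {len(runs)} runs, "
        f"{config.cohort.n_subjects} subjects, seed {config.seed}"
    ]
    for fset in config.feature_sets:
        key = f"pearson_{fset}_flagged"
        if key in tables:
            summary.append(f"\nPearson's r ({fset} features, * = best per family):")
            summary.append(tables[key].to_string())
    (report_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return {"metadata": meta, "dataset": dataset, "runs": runs, "tables": tables}
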