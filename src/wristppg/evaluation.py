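"""Agreement and accuracy metrics for predicted vs reference HbA1c.

Regression metrics (Pearson's r, MSE, signed mean error, RMSE, R^2),
Bland-Altman bias and 95% limits of agreement, and Clarke error-grid
analysis (EGA).  The Clarke grid is defined on blood glucose (mg/dL); HbA1c
pairs are mapped onto it through the ADAG estimated-average-glucose
relation eAG = 28.7 * HbA1c - 46.7 before zoning, and the mapping is
configurable.  The sign convention throughout is predicted minus
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import WristPPGError

#: ADAG linear HbA1c(%) -> estimated average glucose (mg/dL)
EAG_SLOPE = 28.7
EAG_INTERCEPT = -46.7

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class EvaluationReport:
    pearson_r: float
    mse: float
    me: float
    rmse: float
    r2: float
    ega_zone_counts: dict[str, int]
    ega_zone_pct: dict[str, float]
    ba_bias: float
    ba_sd: float
    ba_loa: tuple[float, float]
    n_subjects: int = 0
    extra: dict = field(default_factory=dict)


def _check_pair(pred, truth, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise WristPPGError("pred and truth must be equal-length 1-D arrays")
    if pred.size < min_n:
        raise WristPPGError(f"need at least {min_n} paired values, got {pred.size}")
    return pred, truth


def regression_metrics(pred, truth) -> dict[str, float]:
    """Pearson's r, MSE, signed ME (pred - truth), RMSE and R^2."""
    pred, truth = _check_pair(pred, truth)
    if np.ptp(truth) == 0:
        raise WristPPGError("constant reference values: r and R^2 undefined")
    diff = pred - truth
    mse = float(np.mean(diff**2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    return {
        "pearson_r": float(stats.pearsonr(truth, pred).statistic),
        "mse": mse,
        "me": float(diff.mean()),
        "rmse": float(np.sqrt(mse)),
        "r2": float(1.0 - np.sum(diff**2) / ss_tot),
    }


def bland_altman(pred, truth) -> dict[str, object]:
    """Bias, sample SD (n-1), and 95% limits of agreement bias +/- 1.96 SD."""
    pred, truth = _check_pair(pred, truth)
    diff = pred - truth
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "ba_bias": bias,
        "ba_sd": sd,
        "ba_loa": (bias - 1.96 * sd, bias + 1.96 * sd),
    }


def hba1c_to_eag(hba1c) -> np.ndarray:
    """Map HbA1c (%) to estimated average glucose (mg/dL)."""
    return EAG_SLOPE * np.asarray(hba1c, dtype=float) + EAG_INTERCEPT


def clarke_zone(ref_mgdl: float, pred_mgdl: float) -> str:
    """Canonical Clarke error-grid zone for one (reference, predicted) pair.

    Standard piecewise-linear boundaries on the glucose plane: Zone A is
    within 20% of the reference (or both readings below 70 mg/dL), E the
    dangerous opposite-corner failures, C the over-correction triangles, D
    the failure-to-detect bands, and B everything else.
    """
    r, p = float(ref_mgdl), float(pred_mgdl)
    if r <= 0 or p < 0:
        raise WristPPGError("non-positive glucose after mapping")
    if (r <= 70 and p <= 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= (7.0 / 5.0) * r - 182):
        return "C"
    if (r >= 240 and 70 <= p <= 180) or (r <= 175.0 / 3.0 and 70 <= p <= 180) or (
        175.0 / 3.0 <= r <= 70 and p >= (6.0 / 5.0) * r
    ):
        return "D"
    return "B"


def ega_zones(
    pred_hba1c, truth_hba1c, mapping=hba1c_to_eag
) -> tuple[list[str], dict[str, int], dict[str, float]]:
    """Clarke zones for HbA1c pairs via the glucose mapping.

    Returns per-subject zone labels plus zone counts and percentages.
    """
    pred, truth = _check_pair(pred_hba1c, truth_hba1c, min_n=1)
    if np.any(truth <= 0):
        raise WristPPGError("reference HbA1c must be positive")
    ref_g = mapping(truth)
    pred_g = mapping(pred)
    labels = [clarke_zone(r, p) for r, p in zip(ref_g, pred_g)]
    counts = {z: labels.count(z) for z in ZONES}
    pct = {z: 100.0 * counts[z] / len(labels) for z in ZONES}
    return labels, counts, pct


def evaluate_predictions(pred, truth) -> EvaluationReport:
    """Full evaluation battery on per-subject predictions."""
    metrics = regression_metrics(pred, truth)
    ba = bland_altman(pred, truth)
    _, counts, pct = ega_zones(pred, truth)
    return EvaluationReport(
        pearson_r=metrics["pearson_r"],
        mse=metrics["mse"],
        me=metrics["me"],
        rmse=metrics["rmse"],
        r2=metrics["r2"],
        ega_zone_counts=counts,
        ega_zone_pct=pct,
        ba_bias=ba["ba_bias"],
        ba_sd=ba["ba_sd"],
        ba_loa=ba["ba_loa"],
        n_subjects=len(np.asarray(pred)),
    )


def build_report_tables(runs: list[dict]) -> dict[str, pd.DataFrame]:
    """Assemble sweep results into deterministic report tables.

    ``runs`` holds one dict per completed run with keys ``combo``,
    ``family``, ``feature_set``, ``pred``, ``truth``.  Produces one
    Pearson's-r table per feature set (rows R/G/B/RG/RB/GB/RGB, columns the
    families, best value per column flagged with '*'), a long-format
    metrics table, and EGA / Bland-Altman summary tables.  Missing cells
    are reported as NaN, never dropped.
    """
    combo_order = ["R", "G", "B", "RG", "RB", "GB", "RGB"]
    family_order = ["rf", "xgb", "lgbm", "gbdt"]
    by_set: dict[str, dict] = {}
    metric_rows, ega_rows, ba_rows = [], [], []
    for run in runs:
        combo = str(run["combo"]).upper()
        fam = run["family"]
        fset = run["feature_set"]
        rep = evaluate_predictions(run["pred"], run["truth"])
        by_set.setdefault(fset, {}).setdefault(combo, {})[fam] = rep.pearson_r
        metric_rows.append(
            {
                "feature_set": fset, "combo": combo, "family": fam,
                "pearson_r": rep.pearson_r, "mse": rep.mse, "me": rep.me,
                "rmse": rep.rmse, "r2": rep.r2,
            }
        )
        ega_rows.append(
            {
                "feature_set": fset, "combo": combo, "family": fam,
                **{f"zone_{z}_pct": rep.ega_zone_pct[z] for z in ZONES},
                **{f"zone_{z}_n": rep.ega_zone_counts[z] for z in ZONES},
            }
        )
        ba_rows.append(
            {
                "feature_set": fset, "combo": combo, "family": fam,
                "bias": rep.ba_bias, "sd": rep.ba_sd,
                "loa_low": rep.ba_loa[0], "loa_high": rep.ba_loa[1],
            }
        )

    tables: dict[str, pd.DataFrame] = {}
    for fset, cells in by_set.items():
        fams = [f for f in family_order if any(f in v for v in cells.values())]
        combos = [c for c in combo_order if c in cells]
        tab = pd.DataFrame(
            [[cells[c].get(f, np.nan) for f in fams] for c in combos],
            index=combos, columns=fams,
        )
        flagged = tab.copy().astype(object)
        for f in fams:
            col = tab[f]
            if col.notna().any():
                best = col.idxmax()
                for c in combos:
                    v = col[c]
                    flagged.loc[c, f] = (
                        "" if pd.isna(v) else f"{v:.3f}" + ("*" if c == best else "")
                    )
        tables[f"pearson_{fset}"] = tab
        tables[f"pearson_{fset}_flagged"] = flagged
    sort_cols = ["feature_set", "combo", "family"]
    tables["metrics"] = pd.DataFrame(metric_rows).sort_values(sort_cols).reset_index(drop=True)
    tables["ega"] = pd.DataFrame(ega_rows).sort_values(sort_cols).reset_index(drop=True)
    tables["bland_altman"] = pd.DataFrame(ba_rows).sort_values(sort_cols).reset_index(drop=True)
    return tables
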