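"""Leave-one-subject-out comparison of four tree-ensemble regressor families.

Families
--------
``rf``      bagged trees (scikit-learn RandomForestRegressor); impurity
            (Gini-style) importances.
``xgb``     regularised level-wise gradient boosting (XGBoost); gain
            importances.
``lgbm``    leaf-wise gradient boosting (LightGBM); split- and gain-based
            importances, each normalised then averaged.
``gbdt``    sequential least-squares gradient boosting (scikit-learn
            GradientBoostingRegressor); impurity importances.  When the
            optional CatBoost package is importable it backs this slot
            instead (ordered boosting with oblivious trees, gain
            importances).

Any backend exposing fit / predict / per-feature importance satisfies a
family slot, so the four-way comparison keeps its shape across
installations.

Cross-validation leaves one *subject* out per fold: all of a subject's
frames are predicted by a model trained on the other subjects' frames, and
frame predictions are aggregated (mean by default) to a single per-subject
HbA1c estimate.  Hyperparameters may be grid-searched inside each training
fold with grouped K-fold splits so no subject ever straddles an inner
split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GroupKFold

from .errors import WristPPGError
from .features import EXTERNAL_NAMES, canonical_combo

try:  # optional backend for the ordered-boosting slot
    from catboost import CatBoostRegressor  # pragma: no cover

    _HAVE_CATBOOST = True
except ImportError:
    _HAVE_CATBOOST = False

FAMILIES = ("rf", "xgb", "lgbm", "gbdt")

_DEFAULT_PARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 300, "max_depth": None},
    "xgb": {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.05},
    "lgbm": {"n_estimators": 300, "max_depth": -1, "learning_rate": 0.05},
    "gbdt": {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.05},
}


def default_grid(family: str) -> dict[str, list]:
    """Single-point grid (no inner search) with sensible defaults."""
    if family not in FAMILIES:
        raise WristPPGError(f"unknown model family {family!r}; choose from {FAMILIES}")
    return {k: [v] for k, v in _DEFAULT_PARAMS[family].items()}


def full_grid(family: str) -> dict[str, list]:
    """Small multi-point grid for grouped inner search."""
    if family == "rf":
        return {"n_estimators": [100, 300], "max_depth": [3, 5, None]}
    if family in ("xgb", "lgbm", "gbdt"):
        depth = [3, 5] if family != "lgbm" else [-1, 5]
        return {
            "n_estimators": [100, 300],
            "max_depth": depth,
            "learning_rate": [0.05, 0.1],
        }
    raise WristPPGError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise WristPPGError(
                f"unknown model family {self.family!r}; choose from {FAMILIES}"
            )
        grid = self.grid or default_grid(self.family)
        object.__setattr__(self, "grid", grid)
        if any(len(v) == 0 for v in grid.values()):
            raise WristPPGError("hyperparameter grid contains an empty value list")


def _make_estimator(family: str, params: dict, seed: int):
    if family == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, importance_type="gain",
            verbosity=0, **params,
        )
    if family == "lgbm":
        from lightgbm import LGBMRegressor

        # leaf constraint relaxed for cohort-scale (hundreds of rows) data
        return LGBMRegressor(
            random_state=seed, n_jobs=1, verbose=-1,
            **{"min_child_samples": 5, **params},
        )
    if family == "gbdt":
        if _HAVE_CATBOOST:  # pragma: no cover
            depth = params.get("max_depth", 6)
            return CatBoostRegressor(
                iterations=params.get("n_estimators", 300),
                learning_rate=params.get("learning_rate", 0.05),
                depth=6 if depth in (None, -1) else depth,
                random_seed=seed, verbose=False, allow_writing_files=False,
            )
        return GradientBoostingRegressor(random_state=seed, **params)
    raise WristPPGError(f"unknown model family {family!r}")


def _importances(family: str, model, columns: list[str]) -> np.ndarray:
    """Per-feature importances, normalised to sum 1 (zeros if no splits)."""
    if family == "lgbm":
        gain = model.booster_.feature_importance(importance_type="gain").astype(float)
        split = model.booster_.feature_importance(importance_type="split").astype(float)
        parts = []
        for arr in (gain, split):
            s = arr.sum()
            parts.append(arr / s if s > 0 else np.zeros_like(arr))
        imp = 0.5 * (parts[0] + parts[1])
    elif family == "gbdt" and _HAVE_CATBOOST:  # pragma: no cover
        imp = np.asarray(model.get_feature_importance(), dtype=float)
    else:
        imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.zeros_like(imp)
    if imp.size != len(columns):
        raise WristPPGError("importance vector does not match feature columns")
    return imp


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold subject predictions plus fold-averaged importances."""

    subject_ids: np.ndarray
    subject_truth: np.ndarray
    subject_predictions: np.ndarray
    importances: pd.Series            # index: feature names, sums to 1
    chosen_hyperparameters: list[dict]
    feature_set: list[str]
    folds: list[dict]                 # {'test_subject', 'train_subjects'}

    @property
    def pearson_r(self) -> float:
        return float(np.corrcoef(self.subject_truth, self.subject_predictions)[0, 1])


def _grid_points(grid: dict[str, list]):
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _inner_select(family, grid, seed, X, y, groups) -> dict:
    """Grouped K-fold grid search inside one training fold (MSE objective)."""
    points = list(_grid_points(grid))
    if len(points) == 1:
        return points[0]
    uniq = np.unique(groups)
    n_splits = int(min(5, uniq.size))
    if n_splits < 2:
        return points[0]
    gkf = GroupKFold(n_splits=n_splits)
    best_params, best_mse = points[0], np.inf
    for params in points:
        errs = []
        for tr, te in gkf.split(X, y, groups):
            est = _make_estimator(family, params, seed)
            est.fit(X.iloc[tr], y[tr])
            pred = est.predict(X.iloc[te])
            errs.append(float(np.mean((pred - y[te]) ** 2)))
        mse = float(np.mean(errs))
        if mse < best_mse:
            best_mse, best_params = mse, params
    return best_params


def loso_cv(
    X: pd.DataFrame,
    groups: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    aggregate: str = "mean",
) -> CVResult:
    """Leave-one-subject-out cross-validation for one model family."""
    if aggregate not in ("mean", "median"):
        raise WristPPGError("aggregate must be 'mean' or 'median'")
    X = pd.DataFrame(X)
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    bad = [c for c in X.columns if not np.isfinite(X[c].to_numpy(float)).all()]
    if bad:
        raise WristPPGError(f"non-finite values in feature column(s): {bad}")
    subjects = pd.unique(groups)
    if subjects.size < 2:
        raise WristPPGError("leave-one-subject-out needs at least 2 subjects")
    for s in subjects:
        if np.unique(y[groups == s]).size != 1:
            raise WristPPGError(f"label varies within subject {s!r}")

    agg = np.mean if aggregate == "mean" else np.median
    preds, truths, imps, chosen, folds = [], [], [], [], []
    for s in subjects:
        test_mask = groups == s
        Xtr, ytr, gtr = X[~test_mask], y[~test_mask], groups[~test_mask]
        params = _inner_select(spec.family, spec.grid, spec.seed, Xtr, ytr, gtr)
        model = _make_estimator(spec.family, params, spec.seed)
        model.fit(Xtr, ytr)
        frame_pred = np.asarray(model.predict(X[test_mask]), dtype=float)
        preds.append(float(agg(frame_pred)))
        truths.append(float(y[test_mask][0]))
        imps.append(_importances(spec.family, model, list(X.columns)))
        chosen.append(params)
        folds.append(
            {"test_subject": s, "train_subjects": set(np.unique(gtr).tolist())}
        )
    mean_imp = np.mean(imps, axis=0)
    total = mean_imp.sum()
    mean_imp = mean_imp / total if total > 0 else mean_imp
    return CVResult(
        subject_ids=np.asarray(subjects),
        subject_truth=np.asarray(truths),
        subject_predictions=np.asarray(preds),
        importances=pd.Series(mean_imp, index=list(X.columns)),
        chosen_hyperparameters=chosen,
        feature_set=list(X.columns),
        folds=folds,
    )


def feature_importances(cv: CVResult) -> pd.DataFrame:
    """Ranked importance table (descending, alphabetical tie-break)."""
    tab = (
        cv.importances.rename("importance")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["importance", "feature"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def select_features(
    importances: pd.DataFrame, combo, include_external: bool = True
) -> list[str]:
    """Per wavelength: the AC/DC column plus its top-4 other features by rank.

    The AC/DC column is always retained regardless of its own rank;
    externals (BMI, SpO2) are appended when requested.  Yields
    5 features per wavelength (+2 externals), e.g. 7 for one wavelength
    with externals and 15 for RGB without.
    """
    waves = canonical_combo(combo)
    ranked = importances.sort_values("rank")["feature"].tolist()
    selected: list[str] = []
    for w in waves:
        acdc_col = f"acdc_{w}"
        if acdc_col not in ranked:
            raise WristPPGError(f"importance table lacks {acdc_col}")
        others = [f for f in ranked if f.startswith(f"{w}_")]
        if len(others) < 4:
            raise WristPPGError(
                f"fewer than 4 non-AC/DC features available for wavelength {w}"
            )
        selected.append(acdc_col)
        selected.extend(others[:4])
    if include_external:
        selected.extend(EXTERNAL_NAMES)
    return selected
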