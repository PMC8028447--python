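"""Boosted-tree regression of chlorophyll content on JIP parameters.

For each canopy layer a gradient-boosted regression-tree ensemble
(additive trees with squared-error loss and a complexity penalty, 100 trees)
is fitted to predict leaf chlorophyll content (ug/cm2) from the full derived
JIP-test panel.  Hyperparameters (max tree depth, min child weight, learning
rate) are chosen by exhaustive grid search under 5-fold cross-validation on
an 80% training split; quality is the RMSE on the held-out 20%.  Gain-based
feature importance — each feature's total loss reduction across all splits,
normalised to sum 1 — ranks the parameters, and the per-layer rankings are
aggregated into cumulative lower-canopy vs upper-canopy totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from xgboost import XGBRegressor

from .errors import ValidationError

#: Default hyperparameter grid; small ranges bracketing typical optima at
#: field-trial sample sizes (tens to low hundreds of leaves per layer).
DEFAULT_PARAM_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4, 6],
    "min_child_weight": [1, 3, 5],
    "learning_rate": [0.05, 0.1, 0.3],
}

#: Minimal grid for quick, deterministic fits (smoke tests, repeated
#: recovery experiments) where hyperparameter search is not the point.
SMALL_PARAM_GRID: dict[str, list] = {
    "max_depth": [3],
    "min_child_weight": [1],
    "learning_rate": [0.1],
}

LOWER_LAYERS = ("L1", "L2")
UPPER_LAYERS = ("L3", "L4", "L5")


@dataclass
class ImportanceResult:
    """Per-layer model quality and gain-importance ranking."""

    layer: str
    rmse_test: float
    importance: dict[str, float]
    top_k: list[str]
    best_params: dict


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean square error; symmetric in its arguments."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValidationError("rmse needs at least one observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def fit_chl_model(
    features: pd.DataFrame,
    target: Sequence[float],
    *,
    split_seed: int = 0,
    cv_folds: int = 5,
    n_trees: int = 100,
    grid: Mapping[str, list] | None = None,
    stratify: Sequence | None = None,
) -> tuple[GridSearchCV, float]:
    """Fit the boosted-tree chlorophyll model and score it on a held-out 20%.

    ``stratify`` (e.g. nitrogen labels) stratifies the 80/20 split to keep
    treatments balanced at small n; pass ``None`` to disable.  Returns the
    fitted grid-search object (its ``best_estimator_`` is the final model
    refitted on the whole training split) and the test-set RMSE.
    """
    y = np.asarray(target, dtype=float)
    if len(features) != y.size:
        raise ValidationError("features and target lengths differ")
    if y.size < 20:
        raise ValidationError(f"need >= 20 samples, got {y.size}")
    if features.isna().to_numpy().any():
        raise ValidationError("features contain missing values")
    if np.ptp(y) == 0:
        raise ValidationError("constant target: nothing to regress")

    x_train, x_test, y_train, y_test = train_test_split(
        features, y, test_size=0.2, random_state=split_seed,
        stratify=None if stratify is None else list(stratify),
    )
    booster = XGBRegressor(
        n_estimators=n_trees,
        objective="reg:squarederror",
        random_state=split_seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    )
    search = GridSearchCV(
        booster,
        dict(grid if grid is not None else DEFAULT_PARAM_GRID),
        cv=KFold(n_splits=cv_folds, shuffle=True, random_state=split_seed),
        scoring="neg_root_mean_squared_error",
        n_jobs=1,
        refit=True,
    )
    search.fit(x_train, y_train)
    rmse_test = rmse(y_test, search.predict(x_test))
    return search, rmse_test


def rank_features(model, k: int = 7) -> tuple[dict[str, float], list[str]]:
    """Gain-based importance map (normalised to sum 1) and the top-k list.

    Features the ensemble never split on get importance 0; ties are broken
    alphabetically.  Raises on an unfitted model.
    """
    estimator = getattr(model, "best_estimator_", model)
    try:
        booster = estimator.get_booster()
        names = list(estimator.feature_names_in_)
    except Exception as exc:  # unfitted / not a boosted model
        raise ValidationError("rank_features requires a fitted boosted model") from exc
    gains = booster.get_score(importance_type="gain")
    raw = {name: float(gains.get(name, 0.0)) for name in names}
    total = sum(raw.values())
    if total <= 0:
        raise ValidationError("model has no splits: importance undefined")
    importance = {name: val / total for name, val in raw.items()}
    ordered = sorted(importance, key=lambda name: (-importance[name], name))
    return importance, ordered[:k]


def cumulative_importance(
    results: Mapping[str, Mapping[str, float]] | Mapping[str, ImportanceResult],
    lower: Sequence[str] = LOWER_LAYERS,
    upper: Sequence[str] = UPPER_LAYERS,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-parameter importance summed over the lower and upper canopy.

    ``results`` maps layer -> importance map (or :class:`ImportanceResult`).
    Raises if any named layer is missing.
    """
    def imap(layer: str) -> Mapping[str, float]:
        if layer not in results:
            raise ValidationError(f"missing importance result for layer {layer}")
        entry = results[layer]
        return entry.importance if isinstance(entry, ImportanceResult) else entry

    def total(layers: Sequence[str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for layer in layers:
            for name, val in imap(layer).items():
                out[name] = out.get(name, 0.0) + float(val)
        return out

    return total(lower), total(upper)
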