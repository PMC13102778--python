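"""Tabular baselines: shape-feature, pathology-score, and combined regressors.

Each baseline is a scikit-learn regressor trained on tabular inputs — the
classical shape/brightness features, the three ordinal pathologist scores,
or their concatenation.  Model selection runs 5-fold cross-validation over
decision trees, gradient-boosted trees, and MLPs; fixed presets reproduce
the gradient-boosting hyperparameters that win that selection for each
feature set.

Pathologist scores are three ordinal grades 0-4 (cytoplasmic changes,
nuclear changes, contour shape changes), stored in analysis-ready
orientation: 4 is control-like, 0 is marked change.  The raw grading
orientation (0 = no change) is the inverse; ``invert_scores`` converts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "PathologyScore",
    "BaselineResult",
    "PRESET_HYPERPARAMETERS",
    "MODEL_FAMILIES",
    "select_and_fit",
    "preset_fit",
    "score_space_analysis",
    "invert_scores",
    "N_SCORE_COMBINATIONS",
]

N_SCORE_LEVELS = 5
N_SCORE_COMBINATIONS = N_SCORE_LEVELS ** 3  # three properties, five levels


@dataclass(frozen=True)
class PathologyScore:
    """Ordinal grades, analysis-ready orientation (4 = control-like)."""

    cytoplasmic: int
    nuclear: int
    contour: int

    def __post_init__(self):
        for v in (self.cytoplasmic, self.nuclear, self.contour):
            if v not in range(N_SCORE_LEVELS):
                raise ValueError(f"score {v} outside 0-{N_SCORE_LEVELS - 1}")

    def to_tuple(self):
        return (self.cytoplasmic, self.nuclear, self.contour)


def invert_scores(scores):
    """Flip between the raw grading orientation and the analysis-ready one."""
    arr = np.asarray(scores, dtype=int)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("scores must lie in 0-4")
    return 4 - arr


# Gradient-boosting presets per feature set: the hyperparameters that win
# 5-fold cross-validation for each baseline.
PRESET_HYPERPARAMETERS = {
    "cve": dict(learning_rate=0.1, max_depth=2, min_samples_leaf=4,
                min_samples_split=2, n_estimators=50),
    "pathology": dict(learning_rate=0.1, max_depth=3, min_samples_leaf=2,
                      min_samples_split=6, n_estimators=50),
    "cve+pathology": dict(learning_rate=0.1, max_depth=2, min_samples_leaf=1,
                          min_samples_split=6, n_estimators=50),
}

PRESET_FEATURE_DIM = {"cve": 9, "pathology": 3, "cve+pathology": 12}

# ordered simple -> complex; ties in CV prefer the earlier family
MODEL_FAMILIES = ("tree", "boosted_trees", "mlp")

DEFAULT_GRIDS = {
    "tree": {"max_depth": [2, 3, 5, None], "min_samples_leaf": [1, 2, 4]},
    "boosted_trees": {
        "learning_rate": [0.1],
        "max_depth": [2, 3],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 6],
        "n_estimators": [50],
    },
    "mlp": {"hidden_layer_sizes": [(32,), (32, 32)], "alpha": [1e-4, 1e-2],
            "max_iter": [500]},
}


def _make_estimator(family, params, seed):
    if family == "tree":
        return DecisionTreeRegressor(random_state=seed, **params)
    if family == "boosted_trees":
        return GradientBoostingRegressor(random_state=seed, **params)
    if family == "mlp":
        return MLPRegressor(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def _grid_points(grid):
    keys = sorted(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _complexity(family, params):
    # tie-break: fewer/shallower components first, then first-listed order
    return (
        params.get("n_estimators", 1),
        params.get("max_depth") or 99,
        np.sum(params.get("hidden_layer_sizes", (0,))),
    )


@dataclass
class BaselineResult:
    estimator: object
    family: str
    hyperparameters: dict
    cv_table: pd.DataFrame
    feature_set: str = ""

    def predict(self, features):
        return self.estimator.predict(np.asarray(features, dtype=float))


def select_and_fit(features, labels, families=MODEL_FAMILIES, grids=None,
                   k_folds=5, seed=0) -> BaselineResult:
    """Grid search by mean k-fold CV MSE, then refit the winner on all data.

    Ties are broken toward the simpler family (in ``families`` order), then
    lower hyperparameter complexity, then first-listed grid point.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be 2-D and aligned with labels")
    if len(y) < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} samples for "
                         f"{k_folds}-fold cross-validation")
    grids = grids or DEFAULT_GRIDS
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(x))

    rows = []
    for fam_rank, family in enumerate(families):
        for params in _grid_points(grids[family]):
            fold_mse = []
            for tr, te in splits:
                est = _make_estimator(family, params, seed)
                est.fit(x[tr], y[tr])
                fold_mse.append(float(np.mean((est.predict(x[te]) - y[te]) ** 2)))
            rows.append({
                "family": family, "family_rank": fam_rank,
                "hyperparameters": params,
                "cv_mse": float(np.mean(fold_mse)),
                "cv_mse_sd": float(np.std(fold_mse)),
            })
    table = pd.DataFrame(rows)
    order = table.assign(
        complexity=[_complexity(r.family, r.hyperparameters)
                    for r in table.itertuples()]
    ).sort_values(["cv_mse", "family_rank", "complexity"],
                  kind="stable").index
    best = table.loc[order[0]]
    winner = _make_estimator(best["family"], best["hyperparameters"], seed)
    winner.fit(x, y)
    return BaselineResult(winner, best["family"], dict(best["hyperparameters"]),
                          table.drop(columns=["family_rank"]))


def preset_fit(feature_set, features, labels, seed=0) -> BaselineResult:
    """Fit the fixed gradient-boosting preset for a feature set."""
    if feature_set not in PRESET_HYPERPARAMETERS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; "
            f"choose from {sorted(PRESET_HYPERPARAMETERS)}")
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != PRESET_FEATURE_DIM[feature_set]:
        raise ValueError(
            f"feature set {feature_set!r} expects "
            f"{PRESET_FEATURE_DIM[feature_set]} columns, got "
            f"{x.shape[1] if x.ndim == 2 else 'non-2D'}")
    params = PRESET_HYPERPARAMETERS[feature_set]
    est = GradientBoostingRegressor(random_state=seed, **params)
    est.fit(x, np.asarray(labels, dtype=float))
    return BaselineResult(est, "boosted_trees", dict(params),
                          pd.DataFrame(), feature_set=feature_set)


def score_space_analysis(scores, viabilities=None, top_k=3):
    """Frequency table over the 125 possible score triplets.

    Returns a DataFrame with one row per combination (including unobserved
    ones), its count and share, and — when viabilities are given — the
    min/max/spread of viability within the combination.  The discreteness of
    this 5x5x5 space is what limits score-based viability regression: a
    single triplet can cover a wide viability range.
    """
    triplets = []
    for s in scores:
        t = s.to_tuple() if isinstance(s, PathologyScore) else tuple(int(v) for v in s)
        if any(v not in range(N_SCORE_LEVELS) for v in t) or len(t) != 3:
            raise ValueError(f"invalid score triplet {t}")
        triplets.append(t)
    v = None
    if viabilities is not None:
        v = np.asarray(viabilities, dtype=float)
        if len(v) != len(triplets):
            raise ValueError("scores and viabilities length mismatch")

    all_combos = list(product(range(N_SCORE_LEVELS), repeat=3))
    counts = {c: 0 for c in all_combos}
    members = {c: [] for c in all_combos}
    for i, t in enumerate(triplets):
        counts[t] += 1
        if v is not None:
            members[t].append(v[i])
    n = max(len(triplets), 1)
    rows = []
    for c in all_combos:
        row = {"cytoplasmic": c[0], "nuclear": c[1], "contour": c[2],
               "count": counts[c], "share": counts[c] / n}
        if v is not None and counts[c]:
            vals = np.array(members[c])
            row.update(viability_min=float(vals.min()),
                       viability_max=float(vals.max()),
                       viability_spread=float(vals.max() - vals.min()))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "count", ascending=False, kind="stable").reset_index(drop=True)
    table.attrs["n_combinations"] = N_SCORE_COMBINATIONS
    table.attrs["top_k_share"] = float(table["share"].head(top_k).sum())
    return table
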