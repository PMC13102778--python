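"""Control-median normalization of ATP labels and regression metrics.

Absolute ATP readouts carry strong multiplicative batch effects between
studies (reagent timing, seeding, equipment).  Dividing each sample's ATP by
the median ATP of the untreated control spheroids of the same study yields a
dimensionless viability where 1 means control level; the median makes the
reference robust to outlier control wells and cancels any per-study scale
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedViability",
    "RegressionReport",
    "control_normalize",
    "normalize_manifest",
    "r_squared",
    "mae",
    "evaluate_predictions",
]

MIN_CONTROLS_RECOMMENDED = 12


@dataclass(frozen=True)
class NormalizedViability:
    value: float           # 1 = control median
    source_atp_nM: float
    control_group_key: str  # study id (or study|plate when grouped by plate)
    n_controls: int

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("normalized viability must be >= 0")
        if self.n_controls < 1:
            raise ValueError("need at least one control")


def control_normalize(samples, controls):
    """Normalize ATP values by the median control ATP of their group.

    ``samples`` and ``controls`` are sequences of ``(group_key, atp)`` pairs;
    the group key is the study id.  Returns one :class:`NormalizedViability`
    per sample, in order.  A sample whose group has no controls raises;
    groups with fewer than 12 controls are allowed but warned about.
    Even-sized groups use the midpoint median convention.
    """
    groups: dict = {}
    for key, atp in controls:
        groups.setdefault(key, []).append(float(atp))
    medians = {}
    for key, vals in groups.items():
        if len(vals) < MIN_CONTROLS_RECOMMENDED:
            warnings.warn(
                f"group {key!r} has only {len(vals)} controls "
                f"(fewer than {MIN_CONTROLS_RECOMMENDED})",
                stacklevel=2,
            )
        med = float(np.median(vals))
        if med <= 0:
            raise ValueError(f"group {key!r}: non-positive control median {med}")
        medians[key] = med

    missing = {key for key, _ in samples} - set(medians)
    if missing:
        raise ValueError(
            "no control spheroids for group(s): " + ", ".join(sorted(map(str, missing)))
        )
    return [
        NormalizedViability(
            value=float(atp) / medians[key],
            source_atp_nM=float(atp),
            control_group_key=str(key),
            n_controls=len(groups[key]),
        )
        for key, atp in samples
    ]


def normalize_manifest(df: pd.DataFrame, group_by="study",
                       prefer_same_day=True) -> pd.DataFrame:
    """Add a ``viability`` column = Value / median control Value of the group.

    ``group_by`` is ``"study"`` (default) or ``"plate"`` (study|plate key).
    When ``prefer_same_day`` is set, controls imaged on the sample's own day
    are used if any exist, otherwise all of the group's controls.  Rows with
    missing ATP get NaN viability (usable for inference only).
    """
    if group_by not in ("study", "plate"):
        raise ValueError("group_by must be 'study' or 'plate'")
    out = df.copy()

    def key_of(row):
        k = str(row["Study"])
        return k if group_by == "study" else f"{k}|{row['Plate']}"

    is_ctrl = out["Treatment"].astype(str).str.strip().str.lower() == "control"
    has_atp = out["Value"].notna()
    keys = out.apply(key_of, axis=1)

    viability = np.full(len(out), np.nan)
    for key in keys.unique():
        in_group = (keys == key).to_numpy()
        ctrl = in_group & is_ctrl.to_numpy() & has_atp.to_numpy()
        if not ctrl.any():
            raise ValueError(f"no labeled control spheroids in group {key!r}")
        for day in out.loc[in_group, "Day"].unique():
            rows = in_group & (out["Day"] == day).to_numpy()
            ctrl_day = ctrl & (out["Day"] == day).to_numpy()
            use = ctrl_day if (prefer_same_day and ctrl_day.any()) else ctrl
            med = float(np.median(out.loc[use, "Value"]))
            viability[rows] = out.loc[rows, "Value"].to_numpy() / med
    out["viability"] = viability
    return out


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in y_true: R^2 undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size < 1:
        raise ValueError("need at least one observation")
    return float(np.abs(y_true - y_pred).mean())


@dataclass
class RegressionReport:
    """R^2 / MAE overall and per domain, optionally across model replicates."""

    r_squared: float
    mae: float
    n: int
    per_domain: dict
    replicate_r_squared: tuple = ()
    replicate_mae: tuple = ()

    @property
    def r_squared_sd(self):
        return float(np.std(self.replicate_r_squared)) if self.replicate_r_squared else 0.0

    @property
    def mae_sd(self):
        return float(np.std(self.replicate_mae)) if self.replicate_mae else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"domain": "all", "r_squared": self.r_squared,
                 "mae": self.mae, "n": self.n}]
        rows += [{"domain": d, **vals} for d, vals in self.per_domain.items()]
        return pd.DataFrame(rows)


def evaluate_predictions(y_true, y_pred, domains=None,
                         per_model=None) -> RegressionReport:
    """Build a :class:`RegressionReport`; ``per_model`` is an optional
    (n_models, n_samples) array of replicate predictions for mean +/- sd."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    per_domain = {}
    if domains is not None:
        domains = np.asarray(domains)
        for d in pd.unique(domains):
            sel = domains == d
            if sel.sum() >= 2 and np.var(y_true[sel]) > 0:
                per_domain[str(d)] = {
                    "r_squared": r_squared(y_true[sel], y_pred[sel]),
                    "mae": mae(y_true[sel], y_pred[sel]),
                    "n": int(sel.sum()),
                }
    rep_r2, rep_mae = (), ()
    if per_model is not None:
        per_model = np.atleast_2d(np.asarray(per_model, dtype=float))
        rep_r2 = tuple(r_squared(y_true, p) for p in per_model)
        rep_mae = tuple(mae(y_true, p) for p in per_model)
    return RegressionReport(
        r_squared=r_squared(y_true, y_pred),
        mae=mae(y_true, y_pred),
        n=int(y_true.size),
        per_domain=per_domain,
        replicate_r_squared=rep_r2,
        replicate_mae=rep_mae,
    )
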