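"""Dose-response IC50, margin of safety, and DILI classification.

Per drug and day, (predicted) control-normalized viabilities over a
concentration series are fitted with a four-parameter logistic
``v(c) = bottom + (top - bottom) / (1 + (c/x50)**h)`` with the top anchored
near 1 (labels are control-normalized).  The reported IC50 is the
concentration where the fitted curve crosses half the control level
(``0.5 * top``).  If the curve never reaches that level within the tested
range, the fit falls back to log-linear interpolation between the bracketing
concentrations; if no tested concentration halves viability at all, the IC50
is censored above the highest tested concentration.

The margin of safety is MOS = IC50 / Cmax (infinite for censored IC50, i.e.
the drug sorts as safest).  DILI classification sweeps thresholds over MOS —
lower MOS means toxicity at clinically relevant exposure — and is summarized
by the ROC curve and its trapezoid AUC, which equals the Mann-Whitney
concordance of the negated scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "MOSResult",
    "ROCResult",
    "fit_dose_response",
    "mos",
    "roc_from_mos",
    "daily_timecourse",
    "MIN_REPLICATES_RECOMMENDED",
]

MIN_REPLICATES_RECOMMENDED = 5


@dataclass(frozen=True)
class DoseResponseFit:
    drug: str
    day: int | None
    ic50: float          # uM; +inf when censored
    censored: bool       # True: no 50% reduction within tested range
    max_tested: float    # uM, upper censoring bound
    hill_slope: float
    fit_method: str      # four_param_logistic | log_linear_interp | censored
    residual_rmse: float
    n_points: int

    def __post_init__(self):
        if self.censored:
            if np.isfinite(self.ic50):
                raise ValueError("censored fit must carry an infinite ic50")
        elif not (self.ic50 > 0):
            raise ValueError("uncensored ic50 must be positive")


@dataclass(frozen=True)
class MOSResult:
    drug: str
    mos: float   # ic50 / cmax; +inf when ic50 censored
    cmax: float
    day: int | None

    def __post_init__(self):
        if not (self.mos > 0):
            raise ValueError("MOS must be positive")


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self):
        if np.any(np.diff(self.tpr) < -1e-12) or np.any(np.diff(self.fpr) < -1e-12):
            raise ValueError("TPR/FPR must be monotone along the sweep")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _4pl(c, bottom, top, x50_log, h):
    return bottom + (top - bottom) / (1.0 + (c / np.exp(x50_log)) ** h)


def _crossing_from_fit(bottom, top, x50, h):
    """Concentration where the 4PL curve reaches 0.5*top, or None."""
    target = 0.5 * top
    if bottom >= target:  # curve floor never halves the control level
        return None
    ratio = (top - bottom) / (target - bottom) - 1.0
    if ratio <= 0:
        return None
    return x50 * ratio ** (1.0 / h)


def _loglinear_ic50(conc, mean_v):
    """Log-linear interpolation at the first downward crossing of 0.5."""
    for i in range(1, len(conc)):
        v0, v1 = mean_v[i - 1], mean_v[i]
        if v0 >= 0.5 >= v1:
            if v0 == v1:
                return float(conc[i])
            t = (v0 - 0.5) / (v0 - v1)
            return float(np.exp(np.log(conc[i - 1])
                                + t * (np.log(conc[i]) - np.log(conc[i - 1]))))
    return None


def fit_dose_response(concentrations, viabilities, drug="", day=None,
                      top_bounds=(0.8, 1.2)) -> DoseResponseFit:
    """Estimate the IC50 from a concentration series of viabilities.

    ``concentrations`` and ``viabilities`` are aligned per-replicate arrays
    (replicates share a concentration value).  Requires at least 4 distinct
    positive concentrations.  See the module docstring for the fitting and
    censoring rules.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if c.shape != v.shape:
        raise ValueError("concentrations and viabilities length mismatch")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    distinct = np.unique(c)
    if distinct.size < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations, got {distinct.size}")
    max_tested = float(distinct.max())
    mean_v = np.array([v[c == ci].mean() for ci in distinct])

    if mean_v.min() > 0.5:
        return DoseResponseFit(drug, day, np.inf, True, max_tested,
                               np.nan, "censored", float("nan"),
                               int(c.size))

    # bounded 4PL least squares, IC50 parameterized on the log scale
    lo = np.log(distinct.min() / 100.0)
    hi = np.log(max_tested * 100.0)
    start = _loglinear_ic50(distinct, mean_v) or float(np.median(distinct))
    p0 = np.array([max(mean_v.min(), 0.0), np.clip(mean_v[0], *top_bounds),
                   np.log(start), 1.0])
    fit_ok, ic50, h, rmse = False, None, np.nan, np.nan
    try:
        res = least_squares(
            lambda p: _4pl(c, *p) - v, p0,
            bounds=([0.0, top_bounds[0], lo, 0.3],
                    [0.5, top_bounds[1], hi, 6.0]),
        )
        bottom, top, x50_log, h = res.x
        rmse = float(np.sqrt(np.mean(res.fun ** 2)))
        ic50 = _crossing_from_fit(bottom, top, float(np.exp(x50_log)), h)
        fit_ok = ic50 is not None and distinct.min() / 10 <= ic50 <= max_tested * 10
    except Exception:
        fit_ok = False
    if fit_ok:
        return DoseResponseFit(drug, day, float(ic50), False, max_tested,
                               float(h), "four_param_logistic", rmse,
                               int(c.size))

    interp = _loglinear_ic50(distinct, mean_v)
    if interp is None:
        return DoseResponseFit(drug, day, np.inf, True, max_tested,
                               np.nan, "censored", float("nan"), int(c.size))
    rmse = float(np.sqrt(np.mean((mean_v - 0.5) ** 2)))  # nominal
    return DoseResponseFit(drug, day, interp, False, max_tested, np.nan,
                           "log_linear_interp", rmse, int(c.size))


def mos(fit: DoseResponseFit, cmax) -> MOSResult:
    """Margin of safety = IC50 / Cmax; censored IC50 maps to +inf."""
    cmax = float(cmax)
    if cmax <= 0:
        raise ValueError("cmax must be positive")
    value = np.inf if fit.censored else fit.ic50 / cmax
    return MOSResult(fit.drug, float(value), cmax, fit.day)


def roc_from_mos(mos_values, dili_labels) -> ROCResult:
    """ROC over MOS cutoffs; lower MOS ranks as more likely DILI-positive.

    Sweeps every distinct finite MOS plus the two infinities as thresholds
    (predict positive when MOS <= threshold).  The AUC is the trapezoid
    integral, identical to the Mann-Whitney concordance of negated MOS with
    ties counted half.
    """
    m = np.asarray([r.mos if isinstance(r, MOSResult) else r
                    for r in mos_values], dtype=float)
    y = np.asarray(dili_labels, dtype=int)
    if m.shape != y.shape:
        raise ValueError("MOS values and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("need both DILI-positive and negative drugs")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())

    thresholds = np.concatenate(
        [[-np.inf], np.unique(m[np.isfinite(m)]), [np.inf]])
    tpr = np.array([(m[y == 1] <= t).mean() for t in thresholds])
    fpr = np.array([(m[y == 0] <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tpr, fpr, auc)


def daily_timecourse(panel: pd.DataFrame, min_replicates=MIN_REPLICATES_RECOMMENDED):
    """Median per-day viability plus per-day IC50/MOS for each drug.

    ``panel`` columns: drug, concentration_uM, day, replicate, viability,
    cmax_uM (and optionally dili_label).  Returns ``(medians, fits)``:
    ``medians`` has one row per (drug, concentration, day) with the median
    viability across replicates; ``fits`` has one row per (drug, day) with
    the IC50, censoring flag, and MOS.  Groups with fewer replicates than
    ``min_replicates`` are used but warned about.
    """
    required = {"drug", "concentration_uM", "day", "viability", "cmax_uM"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing column(s): {sorted(missing)}")

    grouped = panel.groupby(["drug", "concentration_uM", "day"])["viability"]
    sizes = grouped.size()
    low = sizes[sizes < min_replicates]
    if len(low):
        warnings.warn(
            f"{len(low)} (drug, concentration, day) group(s) have fewer than "
            f"{min_replicates} replicates", stacklevel=2)
    medians = grouped.median().reset_index(name="median_viability")

    rows = []
    for (drug, day), sub in medians.groupby(["drug", "day"]):
        cmax = float(panel.loc[panel["drug"] == drug, "cmax_uM"].iloc[0])
        fit = fit_dose_response(sub["concentration_uM"].to_numpy(),
                                sub["median_viability"].to_numpy(),
                                drug=drug, day=int(day))
        result = mos(fit, cmax)
        rows.append({
            "drug": drug, "day": int(day), "ic50_uM": fit.ic50,
            "censored": fit.censored, "fit_method": fit.fit_method,
            "mos": result.mos, "cmax_uM": cmax,
        })
    return medians, pd.DataFrame(rows)
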