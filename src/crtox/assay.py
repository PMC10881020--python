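"""Assay-level computations: growth-curve AUC screening and TBARS calibration.

The compound screen summarises each growth curve by its area under the
curve (AUC, trapezoid on the linear CFU/ml scale), compares every
(compound, concentration) condition against the carbon-free control via
log2 fold changes of per-replicate AUCs, and attaches a Welch two-sample
t-test with the conventional star categories.

The TBARS side fits a straight calibration line to blank-subtracted
absorbances of MDA-TBA2 standards and inverts it to convert sample
absorbances into MDA concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc_trapezoid",
    "auc_table",
    "fold_change_table",
    "star_category",
    "CalibrationCurve",
    "fit_calibration",
    "mda_concentration",
]


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under a growth curve (CFU·h/ml), linear CFU scale."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two time points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing (sorted, no duplicates)")
    return float(np.trapezoid(v, t))


def auc_table(growth_df: pd.DataFrame, log_scale: bool = False,
              value_col: str = "cfu_per_ml") -> pd.DataFrame:
    """Per-replicate AUC records from tidy growth curves.

    ``log_scale=True`` integrates log10(CFU) instead — offered for
    sensitivity analysis, not the default.
    """
    keys = ["species", "compound", "concentration_au", "replicate"]
    rows = []
    for key, g in growth_df.groupby(keys, sort=True):
        g = g.sort_values("time_h")
        v = g[value_col].to_numpy(dtype=float)
        if log_scale:
            v = np.log10(np.maximum(v, 1.0))
        rows.append(dict(zip(keys, key)) | {
            "auc": auc_trapezoid(g["time_h"].to_numpy(dtype=float), v)})
    return pd.DataFrame(rows)


def star_category(p: float) -> str:
    """Conventional significance stars: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fold_change_table(aucs: pd.DataFrame, control_compound: str = "MM") -> pd.DataFrame:
    """log2 fold change of each replicate AUC against the control mean.

    For every (species, compound, concentration) the fold change is
    ``log2(auc_replicate / mean(control aucs))`` with the control being the
    same species' carbon-free replicates; a Welch two-sided t-test compares
    the condition's replicate AUCs with the control's.  Non-positive AUCs
    yield an undefined (NaN) fold change and are flagged.
    """
    out = []
    for species, g in aucs.groupby("species"):
        ctrl = g[g["compound"] == control_compound]["auc"].to_numpy(dtype=float)
        if ctrl.size == 0:
            raise ValueError(f"no control ({control_compound!r}) AUCs for species {species!r}")
        ctrl_mean = float(np.mean(ctrl))
        for (compound, conc), cond in g.groupby(["compound", "concentration_au"]):
            if compound == control_compound:
                continue
            vals = cond["auc"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.where(vals > 0, np.log2(vals / ctrl_mean), np.nan)
            if np.all(vals == ctrl_mean) and np.all(ctrl == ctrl_mean):
                p = 1.0  # identical groups: no evidence of any difference
            else:
                p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
            for rep, f, v in zip(cond["replicate"], fc, vals):
                out.append({
                    "species": species, "compound": compound,
                    "concentration_au": conc, "replicate": rep,
                    "log2_fold_change": float(f) if np.isfinite(f) else np.nan,
                    "undefined_fc": bool(v <= 0),
                    "p_value": p, "stars": star_category(p),
                })
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """Straight-line MDA-TBA2 calibration on blank-subtracted absorbance.

    ``slope`` in absorbance per μM, ``intercept`` in absorbance units
    (both on the blank-subtracted scale); ``blank`` is the mean raw
    absorbance of the 0 μM standard.
    """

    slope: float
    intercept: float
    blank: float
    r_squared: float
    n_standards: int

    def predict_absorbance(self, conc_um) -> np.ndarray:
        """Forward model: expected blank-subtracted absorbance."""
        return self.intercept + self.slope * np.asarray(conc_um, dtype=float)


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Least-squares line through blank-subtracted standard absorbances.

    ``standards`` has columns ``concentration_um`` and ``absorbance``; the
    0 μM rows define the blank.  Requires at least two distinct
    concentrations; a valid assay has positive slope (not enforced, but
    reported for diagnostics).
    """
    conc = standards["concentration_um"].to_numpy(dtype=float)
    a = standards["absorbance"].to_numpy(dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("calibration needs at least two distinct standard concentrations")
    blank = float(np.mean(a[conc == 0.0])) if np.any(conc == 0.0) else 0.0
    res = stats.linregress(conc, a - blank)
    return CalibrationCurve(slope=float(res.slope), intercept=float(res.intercept),
                            blank=blank, r_squared=float(res.rvalue ** 2),
                            n_standards=int(np.unique(conc).size))


def mda_concentration(absorbance, curve: CalibrationCurve,
                      blank_subtracted: bool = False, with_flags: bool = False):
    """Invert the calibration: absorbance (532 nm) -> MDA-TBA2 μM.

    Raw absorbances are blank-subtracted first unless ``blank_subtracted``.
    Negative inferred concentrations are clamped to 0; pass
    ``with_flags=True`` to also get the boolean clamp mask.
    """
    a = np.asarray(absorbance, dtype=float)
    if not blank_subtracted:
        a = a - curve.blank
    if curve.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    conc = (a - curve.intercept) / curve.slope
    clamped = conc < 0
    conc = np.maximum(conc, 0.0)
    if np.ndim(absorbance) == 0:
        conc, clamped = float(conc), bool(clamped)
    return (conc, clamped) if with_flags else conc
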