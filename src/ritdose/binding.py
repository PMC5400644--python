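"""Binding assays: Lindmo immunoreactive fraction and competition curves.

The Lindmo method estimates the immunoreactive fraction (IRF) of a
radiolabeled antibody preparation — the fraction able to bind antigen at
infinite antigen excess — from a cell-binding titration.  Plotting the
total-to-bound count ratio T/B against 1/(cell count) linearizes the
saturation binding model; the IRF is the inverse of the intercept of the
ordinary-least-squares line (a double-inverse plot akin to
Lineweaver-Burk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.stats import t as student_t

__all__ = [
    "LindmoAssay",
    "IRFEstimate",
    "NonphysicalFitError",
    "lindmo_irf",
    "competition_curve",
    "fit_ic50",
]


class NonphysicalFitError(RuntimeError):
    """The double-inverse regression produced a nonpositive intercept."""


@dataclass(frozen=True)
class LindmoAssay:
    """Cell-binding titration: per-tube cell count, bound and supernatant counts."""

    cell_counts: np.ndarray
    bound: np.ndarray
    supernatant: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cell_counts, dtype=float)
        b = np.asarray(self.bound, dtype=float)
        s = np.asarray(self.supernatant, dtype=float)
        if not (c.shape == b.shape == s.shape) or c.ndim != 1:
            raise ValueError("assay arrays must be 1-D and equal length")
        if np.any(c <= 0) or np.any(b < 0) or np.any(s < 0):
            raise ValueError("cell counts must be > 0 and counts nonnegative")
        if np.unique(c).size < 3:
            raise ValueError("need >= 3 distinct cell counts")
        if np.any(b + s <= 0):
            raise ValueError("total counts T = B + Sn must be > 0 in every tube")
        object.__setattr__(self, "cell_counts", c)
        object.__setattr__(self, "bound", b)
        object.__setattr__(self, "supernatant", s)

    @property
    def total(self) -> np.ndarray:
        """Total counts per tube, T = B + Sn."""
        return self.bound + self.supernatant


@dataclass(frozen=True)
class IRFEstimate:
    """Result of the double-inverse regression."""

    slope: float
    intercept: float
    irf: float
    ci95: tuple[float, float]
    r_squared: float
    nonphysical: bool  # IRF > 1 (kept, flagged, never clamped)


def lindmo_irf(assay: LindmoAssay, weighted: bool = False) -> IRFEstimate:
    """IRF = 1/intercept of OLS T/B vs 1/(cell count).

    ``weighted`` uses 1/x weights (low-cell-count tubes are noisier); the
    default is plain OLS.  The 95% CI on the IRF comes from the delta method
    applied to the intercept.
    """
    if np.any(assay.bound <= 0):
        raise ValueError("every tube needs bound counts > 0 for the T/B ratio")
    x = 1.0 / assay.cell_counts
    y = assay.total / assay.bound
    design = sm.add_constant(x)
    if weighted:
        model = sm.WLS(y, design, weights=1.0 / x)
    else:
        model = sm.OLS(y, design)
    res = model.fit()
    intercept = float(res.params[0])
    slope = float(res.params[1])
    if intercept <= 0:
        raise NonphysicalFitError(
            f"intercept {intercept:.4g} <= 0: no finite immunoreactive fraction"
        )
    irf = 1.0 / intercept
    se_b = float(res.bse[0])
    # delta method: Var(1/b) ~= Var(b)/b^4
    se_irf = se_b / intercept**2
    tcrit = float(student_t.ppf(0.975, df=res.df_resid)) if res.df_resid > 0 else np.inf
    ci = (irf - tcrit * se_irf, irf + tcrit * se_irf)
    if res.centered_tss > 0:
        r_squared = float(res.rsquared)
    else:  # all y identical (perfect binder): the flat line is an exact fit
        r_squared = 1.0
    return IRFEstimate(
        slope=slope,
        intercept=intercept,
        irf=irf,
        ci95=ci,
        r_squared=r_squared,
        nonphysical=irf > 1.0,
    )


def competition_curve(points: pd.DataFrame) -> pd.DataFrame:
    """Normalize competition-binding counts to the zero-competitor binding.

    ``points`` needs columns ``competitor_mol_per_l`` and ``bound_counts``
    (replicate rows allowed).  Percent binding is 100 x bound / mean bound at
    zero competitor.  A non-monotone mean curve is flagged in the
    ``monotone_decreasing`` attribute of the result, not enforced.
    """
    required = {"competitor_mol_per_l", "bound_counts"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"competition data missing columns: {sorted(missing)}")
    zero = points.loc[points["competitor_mol_per_l"] == 0.0, "bound_counts"]
    if zero.empty:
        raise ValueError("competition normalization needs a zero-competitor point")
    b0 = float(zero.mean())
    if b0 <= 0:
        raise ValueError("zero-competitor binding must be positive")
    out = points.copy()
    out["percent_binding"] = 100.0 * out["bound_counts"] / b0
    means = out.groupby("competitor_mol_per_l")["percent_binding"].mean().sort_index()
    out.attrs["monotone_decreasing"] = bool(np.all(np.diff(means.to_numpy()) <= 1e-9))
    return out


def _four_pl(c: np.ndarray, top: float, bottom: float, ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(curve: pd.DataFrame) -> dict:
    """Diagnostic 4-parameter logistic fit of a normalized competition curve.

    Returns dict with top, bottom, ic50 [mol/L], hill.  Zero-competitor rows
    anchor the top plateau but are excluded from the log-concentration term.
    """
    conc = curve["competitor_mol_per_l"].to_numpy(dtype=float)
    pct = curve["percent_binding"].to_numpy(dtype=float)
    pos = conc > 0
    if pos.sum() < 4:
        raise ValueError("IC50 fit needs >= 4 positive-concentration points")
    c_fit, y_fit = conc[pos], pct[pos]
    p0 = (float(pct[~pos].mean()) if np.any(~pos) else float(y_fit.max()),
          float(y_fit.min()),
          float(np.exp(np.mean(np.log(c_fit)))),
          1.0)
    popt, _ = optimize.curve_fit(
        _four_pl,
        c_fit,
        y_fit,
        p0=p0,
        bounds=([0.0, 0.0, c_fit.min() / 100.0, 0.1], [200.0, 100.0, c_fit.max() * 100.0, 10.0]),
        maxfev=20000,
    )
    return {"top": popt[0], "bottom": popt[1], "ic50": popt[2], "hill": popt[3]}
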