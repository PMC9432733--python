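"""Four-parameter logistic dose-response fitting for normalized MBR.

The model is ``R(d) = floor + (ceiling - floor) / (1 + (d / d50)^h)``:
``R`` falls from ``ceiling`` at zero dose toward ``floor`` at saturating
dose, halving the span at the half-effect dose ``d50`` with Hill slope
``h``.  Agonist concentration fits run on a log10 dose axis, RF SAR fits
on a linear axis; the model itself is axis-invariant, the axis choice
only steers the deterministic multi-start initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

__all__ = ["DoseResponseFit", "FitError", "fit_dose_response", "pearson_gof"]


class FitError(RuntimeError):
    """No multi-start converged to a usable fit."""


@dataclass
class DoseResponseFit:
    floor: float
    ceiling: float
    d50: float          # half-effect dose, same units as the dose axis
    hill: float
    residuals: np.ndarray
    doses: np.ndarray
    values: np.ndarray
    cost: float

    def predict(self, dose) -> np.ndarray:
        return _model(np.asarray(dose, dtype=float), self.floor, self.ceiling,
                      self.d50, self.hill)

    def dose_at(self, response: float) -> float:
        """Dose at which the fitted curve crosses a response level."""
        span = self.ceiling - self.floor
        frac = (response - self.floor) / span
        if not (0.0 < frac < 1.0):
            raise ValueError("response level outside the fitted range")
        return float(self.d50 * (1.0 / frac - 1.0) ** (1.0 / self.hill))


def _model(d, floor, ceiling, d50, hill):
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (d / d50) ** hill, 0.0)
    return floor + (ceiling - floor) / (1.0 + ratio)


def fit_dose_response(
    doses,
    values,
    log_dose: bool = False,
    fix_floor: float | None = None,
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit.

    Five deterministic initializations (d50 spread over the positive dose
    range, paired with a ladder of Hill slopes) are tried and the best
    converged fit kept.  ``fix_floor`` pins the lower asymptote (useful
    for agonists expected to fully suppress activity).  Requires at least
    four distinct doses.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(d).size < 4:
        raise FitError("need at least 4 distinct doses")
    pos = d[d > 0]
    lo, hi = float(np.min(pos)), float(np.max(pos))
    if log_dose:
        d50_grid = 10.0 ** np.linspace(np.log10(lo), np.log10(hi), 5)
    else:
        d50_grid = np.linspace(lo, hi, 5)
    hill_grid = [1.0, 1.5, 2.0, 4.0, 8.0]
    y_lo, y_hi = float(np.min(y)), float(np.max(y))

    def residual(p):
        if fix_floor is None:
            floor, ceiling, ld50, hill = p
        else:
            ceiling, ld50, hill = p
            floor = fix_floor
        return _model(d, floor, ceiling, 10.0 ** ld50, hill) - y

    best, best_cost = None, np.inf
    for d50_0, h0 in zip(d50_grid, hill_grid):
        if fix_floor is None:
            p0 = [y_lo, y_hi, np.log10(d50_0), h0]
            bounds = ([-np.inf, -np.inf, np.log10(lo) - 4, 0.05],
                      [np.inf, np.inf, np.log10(hi) + 4, 50.0])
        else:
            p0 = [y_hi, np.log10(d50_0), h0]
            bounds = ([-np.inf, np.log10(lo) - 4, 0.05],
                      [np.inf, np.log10(hi) + 4, 50.0])
        try:
            res = least_squares(residual, p0, bounds=bounds, max_nfev=2000)
        except Exception:
            continue
        if res.success and res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise FitError("no initialization converged; check the dose panel")
    if fix_floor is None:
        floor, ceiling, ld50, hill = best.x
    else:
        ceiling, ld50, hill = best.x
        floor = fix_floor
    if floor > ceiling:  # canonicalize: descending curve with floor <= ceiling
        floor, ceiling, hill = ceiling, floor, -hill
    return DoseResponseFit(float(floor), float(ceiling), float(10.0 ** ld50),
                           float(hill), best.fun.copy(), d, y, float(best.cost))


def pearson_gof(fit: DoseResponseFit) -> tuple[float, float]:
    """Pearson-style chi-square goodness of fit of a dose-response fit.

    Residuals are standardized by the replicate variance pooled over
    doses (falling back to the overall residual variance when no dose has
    replicates) and summed; degrees of freedom are the number of points
    minus the four model parameters.  Returns ``(statistic, p_value)``;
    a perfect fit gives statistic 0 and p = 1.
    """
    scale = max(1.0, float(np.max(np.abs(fit.values))))
    if np.max(np.abs(fit.residuals)) < 1e-8 * scale:  # perfect fit
        return 0.0, 1.0
    df = pd.DataFrame({"dose": fit.doses, "resid": fit.residuals, "y": fit.values})
    rep = df.groupby("dose")["y"].agg(["count", "var"])
    rep = rep[rep["count"] >= 2].dropna()
    if len(rep) and float((rep["count"] - 1).sum()) > 0:
        var = float((rep["var"] * (rep["count"] - 1)).sum() / (rep["count"] - 1).sum())
    else:
        var = float(np.var(fit.residuals, ddof=0))
    n_bins = df["dose"].nunique()
    dof = max(len(df) - 4, 1)
    if var <= 0:
        stat = 0.0 if np.allclose(fit.residuals, 0) else np.inf
    else:
        stat = float(np.sum(fit.residuals ** 2) / var)
    p = float(chi2.sf(stat, dof)) if np.isfinite(stat) else 0.0
    if np.isclose(stat, 0.0):
        p = 1.0
    if n_bins < 5:
        import warnings

        warnings.warn("fewer than 5 dose bins: goodness-of-fit p is unreliable")
    return stat, p
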