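"""Concentration-response analysis with the four-parameter logistic (Hill)
equation, for IC50/EC50/ECf estimation.

Inhibition orientation (the antagonist convention used throughout):

    R(c) = bottom + (top - bottom) / (1 + (c / xc50)^n)

so the response falls from ``top`` toward ``bottom`` with increasing
concentration, and R(xc50) = (top + bottom)/2.  Activation flips the ratio
to (xc50/c)^n.  Fits are parameterized on log10(xc50) and multi-started over
a log-spaced midpoint grid; a fitted midpoint beyond the highest tested
concentration is reported as a censored bound ("xc50 > c_max") rather than a
point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["HillFit", "hill_curve", "normalize_responses", "fit_hill", "ecf"]


@dataclass
class HillFit:
    top: float
    bottom: float
    xc50: float
    slope: float
    orientation: str = "inhibition"
    se: dict = field(default_factory=dict)
    converged: bool = True
    censored: bool = False
    censor_note: str = ""
    rss: float = float("nan")

    def predict(self, concentrations) -> np.ndarray:
        return hill_curve(
            concentrations, self.top, self.bottom, self.xc50, self.slope,
            self.orientation,
        )

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "xc50": self.xc50,
            "slope": self.slope,
            "orientation": self.orientation,
            "se": self.se,
            "converged": self.converged,
            "censored": self.censored,
            "censor_note": self.censor_note,
            "rss": self.rss,
        }


def hill_curve(c, top, bottom, xc50, slope, orientation="inhibition"):
    """Four-parameter logistic response at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    if orientation == "inhibition":
        ratio = (c / xc50) ** slope
    elif orientation == "activation":
        ratio = (xc50 / c) ** slope
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return bottom + (top - bottom) / (1.0 + ratio)


def normalize_responses(responses, control_responses):
    """Per-cell normalization: response divided by the same cell's control.

    Values may exceed 1 (responses larger than control).  A non-positive
    control is an error: the normalization is undefined.
    """
    r = np.asarray(responses, dtype=float)
    ctl = np.asarray(control_responses, dtype=float)
    r, ctl = np.broadcast_arrays(r, ctl)
    if np.any(ctl <= 0):
        raise ValueError("control responses must be > 0")
    return r / ctl


def _residual_fn(conc, resp, orientation, fix_bottom):
    logc = np.log10(conc)

    def resid(params):
        if fix_bottom is None:
            top, bottom, logx, slope = params
        else:
            top, logx, slope = params
            bottom = fix_bottom
        pred = hill_curve(10.0**logc, top, bottom, 10.0**logx, slope, orientation)
        return pred - resp

    return resid


def fit_hill(
    concentrations,
    responses,
    orientation: str = "inhibition",
    fix_bottom: float | None = 0.0,
    slope_bounds: tuple[float, float] = (0.1, 10.0),
    n_starts: int = 7,
    seed=None,
) -> HillFit:
    """Least-squares Hill fit with multi-start initialization.

    ``fix_bottom=0.0`` (default) fits a 3-parameter antagonist curve with
    the floor pinned at zero and the top free; pass ``fix_bottom=None`` for
    the full 4-parameter fit (requires >= 4 distinct concentrations).

    Midpoints are estimated on log10 concentration.  If the best fit places
    xc50 above the highest tested concentration, the result is censored:
    ``censored=True`` with a note like "xc50 > 300.0" and the point estimate
    retained only as a lower bound.
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    resp = np.asarray(responses, dtype=float).ravel()
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    n_params = 4 if fix_bottom is None else 3
    n_distinct = np.unique(conc).size
    if n_distinct < n_params:
        raise ValueError(
            f"need >= {n_params} distinct concentrations for a "
            f"{n_params}-parameter fit (got {n_distinct})"
        )

    cmin, cmax = conc.min(), conc.max()
    # multi-start grid for the midpoint, spanning beyond the tested range
    logx_grid = np.linspace(np.log10(cmin) - 1.0, np.log10(cmax) + 1.0, n_starts)
    top0 = float(np.max(resp))
    bottom0 = float(np.min(resp))
    resid = _residual_fn(conc, resp, orientation, fix_bottom)

    lo_logx = np.log10(cmin) - 4.0
    hi_logx = np.log10(cmax) + 4.0
    best = None
    for logx0 in logx_grid:
        if fix_bottom is None:
            x0 = [top0, bottom0, logx0, 1.0]
            lb = [-np.inf, -np.inf, lo_logx, slope_bounds[0]]
            ub = [np.inf, np.inf, hi_logx, slope_bounds[1]]
        else:
            x0 = [top0, logx0, 1.0]
            lb = [-np.inf, lo_logx, slope_bounds[0]]
            ub = [np.inf, hi_logx, slope_bounds[1]]
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not best.success:
        return HillFit(
            top=float("nan"), bottom=float("nan"), xc50=float("nan"),
            slope=float("nan"), orientation=orientation, converged=False,
            censor_note="fit did not converge",
        )

    if fix_bottom is None:
        top, bottom, logx, slope = best.x
    else:
        top, logx, slope = best.x
        bottom = fix_bottom
    xc50 = 10.0**logx
    rss = float(2.0 * best.cost)

    # parameter standard errors from the Gauss-Newton covariance
    se: dict = {}
    dof = conc.size - best.x.size
    if dof > 0:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * (rss / dof)
            errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
            if fix_bottom is None:
                names = ["top", "bottom", "log10_xc50", "slope"]
            else:
                names = ["top", "log10_xc50", "slope"]
            se = dict(zip(names, (float(e) for e in errs)))
        except np.linalg.LinAlgError:
            se = {}

    censored = bool(xc50 > cmax)
    note = f"xc50 > {cmax:g}" if censored else ""
    return HillFit(
        top=float(top), bottom=float(bottom), xc50=float(xc50),
        slope=float(slope), orientation=orientation, se=se,
        converged=True, censored=censored, censor_note=note, rss=rss,
    )


def ecf(fit: HillFit, f: float) -> float:
    """Concentration producing f% of maximal effect (activation convention).

    ECf = xc50 * (f / (100 - f))^(1/n); EC50 is the midpoint itself,
    and for n=1 EC80 = 4 x EC50.
    """
    if not 0 < f < 100:
        raise ValueError("f must be strictly between 0 and 100")
    if fit.censored:
        raise ValueError(f"cannot derive ECf from a censored fit ({fit.censor_note})")
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise ValueError("fitted Hill slope must be nonzero")
    return float(fit.xc50 * (f / (100.0 - f)) ** (1.0 / fit.slope))
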