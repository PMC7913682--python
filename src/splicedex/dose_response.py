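"""Four-parameter logistic (4PL) PSI response curves and their classification.

Individual splice events respond differently to graded loss of splicing
factor activity.  With the composite splicing index (mDSI) as the activity
proxy x >= 0, each event's PSI is modeled by a four-parameter logistic
curve

    PSI(x) = psi_init + (psi_final - psi_init) * x^h / (x^h + ec50^h)

with initial PSI (value at x = 0), final (asymptotic) PSI, EC50 (the x at
half-maximal shift) and Hill coefficient h > 0.  This parameterization is
defined at x = 0 and is monotone in x.  Events are classified as
*sigmoidal* when the 4PL fit significantly outperforms a straight line by
the extra-sum-of-squares F test (2 extra parameters), otherwise *linear*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FourPLFit", "ResponseClass", "four_pl", "fit_4pl", "classify_response", "fit_events"]

#: Bounds on the PSI asymptotes; slightly outside [0, 1] to absorb noise.
PSI_BOUNDS = (-0.2, 1.2)
_HILL_STARTS = (0.5, 1.0, 2.0, 4.0)
_EC50_QUANTILES = (0.25, 0.50, 0.75)


def four_pl(x, psi_init: float, psi_final: float, ec50: float, hill: float):
    """Evaluate the 4PL curve; defined for x >= 0, equals psi_init at x=0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        xh = np.power(x, hill)
        frac = np.where(np.isinf(xh), 1.0, xh / (xh + ec50**hill))
    return psi_init + (psi_final - psi_init) * frac


@dataclass(frozen=True)
class FourPLFit:
    psi_init: float
    psi_final: float
    ec50: float
    hill: float
    rss: float
    n: int
    status: str  # "converged", "degenerate" or "failed"

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def predict(self, x):
        if self.status == "degenerate":
            return np.full_like(np.asarray(x, dtype=float), self.psi_init)
        return four_pl(x, self.psi_init, self.psi_final, self.ec50, self.hill)


def _residuals(params, x, y):
    return four_pl(x, *params) - y


def fit_4pl(x: Sequence[float], y: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit with a deterministic multi-start strategy.

    Starting points combine Hill coefficients {0.5, 1, 2, 4} with EC50 at
    the 25th/50th/75th percentiles of the positive x values; the start with
    the lowest residual sum of squares wins.  Asymptotes are bounded to
    [-0.2, 1.2].  A constant response is reported as ``degenerate`` with
    both asymptotes at that constant (EC50/Hill unidentifiable); if no
    start converges the least-squares line is recorded as a ``failed``
    fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(x < 0):
        raise ValueError("activity proxy x must be non-negative")
    if len(np.unique(x)) < 6:
        raise ValueError("need at least 6 distinct x values to fit a 4PL")

    n = len(x)
    if np.ptp(y) < 1e-12:
        c = float(np.mean(y))
        return FourPLFit(c, c, np.nan, np.nan, float(np.sum((y - c) ** 2)), n, "degenerate")

    xpos = x[x > 0]
    ec50_starts = np.quantile(xpos, _EC50_QUANTILES) if len(xpos) else np.array([1.0])
    ec50_starts = np.unique(np.clip(ec50_starts, 1e-6, None))
    x_lo, x_hi = y[np.argmin(x)], y[np.argmax(x)]
    lower = [PSI_BOUNDS[0], PSI_BOUNDS[0], 1e-9, 1e-6]
    upper = [PSI_BOUNDS[1], PSI_BOUNDS[1], 10.0 * max(float(np.max(x)), 1e-6), 100.0]

    best = None
    for hill0 in _HILL_STARTS:
        for ec0 in ec50_starts:
            p0 = [
                float(np.clip(x_lo, *PSI_BOUNDS)),
                float(np.clip(x_hi, *PSI_BOUNDS)),
                float(ec0),
                hill0,
            ]
            try:
                res = optimize.least_squares(
                    _residuals,
                    p0,
                    args=(x, y),
                    bounds=(lower, upper),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res.x)
    if best is None:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        return FourPLFit(
            float(intercept), float(intercept + slope * np.max(x)),
            np.nan, np.nan, float(np.sum(resid**2)), n, "failed",
        )
    rss, (pi, pf, ec50, hill) = best
    return FourPLFit(float(pi), float(pf), float(ec50), float(hill), rss, n, "converged")


@dataclass(frozen=True)
class ResponseClass:
    event_id: str
    response: str  # "sigmoidal" or "linear"
    f_statistic: float
    p_value: float
    note: str = ""


def classify_response(
    fit: FourPLFit,
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    event_id: str = ".",
) -> ResponseClass:
    """Sigmoidal-vs-linear call by the extra-sum-of-squares F test.

    Compares the 4PL fit (4 parameters) against the least-squares straight
    line (2 parameters); F = ((RSS_line - RSS_4pl)/2) / (RSS_4pl/(n-4)).
    The event is sigmoidal when p < alpha.  Degenerate (flat) fits are
    linear by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if fit.status == "degenerate":
        return ResponseClass(event_id, "linear", 0.0, 1.0, "flat response")
    if fit.status == "failed":
        return ResponseClass(event_id, "linear", np.nan, np.nan, "4PL fit failed")
    slope, intercept = np.polyfit(x, y, 1)
    rss_line = float(np.sum((y - (slope * x + intercept)) ** 2))
    rss_4pl = fit.rss
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("need n > 4 points for the extra-sum-of-squares test")
    # numerically perfect fits: guard the 0/0 case (a perfect line is also
    # fit perfectly by the 4PL)
    tiny = 1e-14 * max(1.0, float(np.sum(y**2)))
    if rss_4pl < tiny:
        if rss_line < tiny:
            return ResponseClass(event_id, "linear", 0.0, 1.0, "perfect linear fit")
        return ResponseClass(event_id, "sigmoidal", np.inf, 0.0)
    f_stat = max(0.0, (rss_line - rss_4pl) / 2.0 / (rss_4pl / df2))
    p = float(stats.f.sf(f_stat, 2, df2))
    return ResponseClass(
        event_id, "sigmoidal" if p < alpha else "linear", float(f_stat), p
    )


def fit_events(
    psi: pd.DataFrame,
    mdsi: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit and classify a 4PL response per event (row of ``psi``).

    ``mdsi`` is indexed by sample id and joined to the PSI matrix columns;
    samples missing either value are dropped per event.  Slightly negative
    index values (samples scoring below the wild-type median) are clipped
    to 0, the domain boundary of the 4PL form.
    """
    samples = psi.columns.intersection(mdsi.index)
    if len(samples) == 0:
        raise ValueError("no overlapping samples between PSI matrix and mDSI series")
    x_all = mdsi.loc[samples].astype(float).clip(lower=0.0)
    rows = []
    for event in psi.index:
        pair = pd.DataFrame(
            {"x": x_all, "y": psi.loc[event, samples].astype(float)}
        ).dropna()
        fit = fit_4pl(pair["x"].to_numpy(), pair["y"].to_numpy())
        cls = classify_response(fit, pair["x"].to_numpy(), pair["y"].to_numpy(), alpha, event)
        rows.append(
            dict(
                event=event, psi_init=fit.psi_init, psi_final=fit.psi_final,
                ec50=fit.ec50, hill=fit.hill, rss=fit.rss, n=fit.n,
                status=fit.status, response=cls.response, F=cls.f_statistic,
                p=cls.p_value,
            )
        )
    return pd.DataFrame(rows).set_index("event")
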