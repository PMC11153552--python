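"""Cosinor rhythmometry and rhythmicity classification.

The cosinor model is ``y(t) = M + A * cos(2*pi*(t - phi)/tau)`` with mesor M,
amplitude A >= 0, acrophase phi (hours, in ``[0, tau)``) and period tau.  For
fixed tau the model is linear in ``(M, A*cos, A*sin)``, so the least-squares
optimum is computed exactly by ordinary least squares on the cos/sin design —
the same optimum an iterative nonlinear fit converges to, without
initialization concerns.  A free-period variant profiles tau over the
circadian band deterministically.

Classification follows the standard population-record rules: a well is
"Synchronized" when a 24-h cosinor on the entrained epoch reaches R^2 >= 0.5,
and "Circadian" when the free-run fit at the Lomb-Scargle period reaches
R^2 >= 0.5 with the period inside the 18-35 h band.  Both thresholds are
inclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .plate_io import TimeSeries
from .spectral import PeriodEstimate

__all__ = [
    "CosinorFit",
    "Category",
    "RhythmCall",
    "cosinor_fit_fixed",
    "cosinor_fit_free",
    "classify_synchronized",
    "classify_circadian",
    "PERIOD_BAND_H",
    "RSQUARED_THRESHOLD",
]

PERIOD_BAND_H = (18.0, 35.0)
RSQUARED_THRESHOLD = 0.5


@dataclass
class CosinorFit:
    """Least-squares cosine fit at a given period.

    ``r_squared`` is defined against the mean model, ``1 - ss_res/ss_tot``;
    it can be negative for fits worse than a constant.
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    r_squared: float
    ss_res: float
    ss_tot: float


class Category(str, enum.Enum):
    SYNCHRONIZED = "SYNCHRONIZED"
    CIRCADIAN = "CIRCADIAN"
    ARRHYTHMIC = "ARRHYTHMIC"


@dataclass
class RhythmCall:
    category: Category
    period_h: float | None
    r_squared: float
    fit: CosinorFit | None = None


def _design_checks(t: np.ndarray, period_h: float) -> None:
    if t.size < 4:
        raise ValueError(f"cosinor fit needs >= 4 points, got {t.size}")
    if float(t[-1] - t[0]) < period_h - 1e-9:
        raise ValueError(
            f"data span {float(t[-1] - t[0]):.2f} h must cover one period ({period_h} h)"
        )
    phases = np.unique(np.round(np.mod(t, period_h), 6))
    if phases.size < 3:
        raise ValueError(
            "degenerate design: fewer than 3 distinct sampling phases modulo the period"
        )


def cosinor_fit_fixed(ts: TimeSeries, period_h: float) -> CosinorFit:
    """Exact OLS cosinor fit at a fixed period."""
    if not period_h > 0:
        raise ValueError("period_h must be positive")
    t, y = ts.finite()
    _design_checks(t, period_h)
    omega = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ybar = y.mean()
    ss_tot = float((y - ybar) @ (y - ybar))
    if ss_tot <= 0:
        raise ValueError("zero-variance series cannot be fitted")
    mesor, bc, bs = (float(b) for b in beta)
    amplitude = math.hypot(bc, bs)
    acrophase = (period_h / (2.0 * np.pi)) * math.atan2(bs, bc) % period_h
    if acrophase >= period_h:  # float mod can round -eps % tau up to tau
        acrophase = 0.0
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase_h=acrophase,
        period_h=float(period_h),
        r_squared=1.0 - ss_res / ss_tot,
        ss_res=ss_res,
        ss_tot=ss_tot,
    )


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, a: float, b: float, tol: float) -> float:
    """Deterministic golden-section minimizer on [a, b]."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def cosinor_fit_free(
    ts: TimeSeries,
    period_band: tuple[float, float] = PERIOD_BAND_H,
    init_period: float = 24.0,
    *,
    grid_step_h: float = 0.05,
    refine_tol_h: float = 1e-3,
) -> CosinorFit:
    """Profile-likelihood period search: fixed-period fits on a fine grid
    over the band, then golden-section refinement around the grid optimum.

    Deterministic by construction.  ``init_period`` is accepted for interface
    compatibility with iterative fitters; the exhaustive profile search does
    not depend on it.
    """
    lo, hi = period_band
    if not (PERIOD_BAND_H[0] - 1e-9 <= lo < hi <= PERIOD_BAND_H[1] + 1e-9):
        raise ValueError(f"period_band must lie within {PERIOD_BAND_H}")
    if not lo <= init_period <= hi:
        raise ValueError("init_period must be inside period_band")

    def ss_res_at(tau: float) -> float:
        return cosinor_fit_fixed(ts, tau).ss_res

    grid = np.arange(lo, hi + grid_step_h / 2, grid_step_h)
    grid[-1] = min(grid[-1], hi)
    losses = np.array([ss_res_at(tau) for tau in grid])
    k = int(np.argmin(losses))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    tau_star = _golden_section(ss_res_at, float(a), float(b), refine_tol_h)
    candidates = [float(grid[k]), tau_star]
    fits = [cosinor_fit_fixed(ts, tau) for tau in candidates]
    return min(fits, key=lambda f: f.ss_res)


def _threshold_call(category_if_pass: Category, passes: bool, period_h: float,
                    fit: CosinorFit) -> RhythmCall:
    if passes:
        return RhythmCall(category_if_pass, float(period_h), fit.r_squared, fit)
    return RhythmCall(Category.ARRHYTHMIC, None, fit.r_squared, fit)


def classify_synchronized(ts_cyclic_epoch: TimeSeries) -> RhythmCall:
    """Entrained-epoch call: 24-h cosinor with R^2 >= 0.5 -> SYNCHRONIZED."""
    fit = cosinor_fit_fixed(ts_cyclic_epoch, 24.0)
    return _threshold_call(
        Category.SYNCHRONIZED, fit.r_squared >= RSQUARED_THRESHOLD, 24.0, fit
    )


def classify_circadian(ts_fr_epoch: TimeSeries, ls_period: PeriodEstimate) -> RhythmCall:
    """Free-run call: cosinor at the Lomb-Scargle period; CIRCADIAN when the
    period lies in [18, 35] h and R^2 >= 0.5.  The reported period is the
    Lomb-Scargle estimate."""
    tau = ls_period.period_h
    fit = cosinor_fit_fixed(ts_fr_epoch, tau)
    in_band = PERIOD_BAND_H[0] <= tau <= PERIOD_BAND_H[1]
    return _threshold_call(
        Category.CIRCADIAN, in_band and fit.r_squared >= RSQUARED_THRESHOLD, tau, fit
    )
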