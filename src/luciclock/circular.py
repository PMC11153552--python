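"""Peak-phase extraction and circular statistics for Rayleigh plots.

Each well contributes one phase per context — the clock-controlled
luminescence peak within the last entrained cycle, or the first peak after
release into constant conditions.  A set of such phases is summarized by its
mean direction and mean resultant length R (0 = uniform, 1 = perfectly
clustered), and tested against circular uniformity with the Rayleigh test.

The Rayleigh p-value uses Zar's second-order approximation

    Z = n * R^2
    p = exp( sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n) )

which is the convention of standard chronobiology toolkits.  It is accurate
to a few per mil for moderate n but overestimates tail probabilities for
very small samples at extreme clustering (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .plate_io import TimeSeries

__all__ = [
    "PhaseSet",
    "CircularSummary",
    "BoundaryPeakWarning",
    "peak_phase",
    "circular_mean",
    "rayleigh_p",
    "rayleigh_test",
    "rayleigh_critical_R",
    "summarize_phases",
]

_DEGENERATE_R = 1e-9


class BoundaryPeakWarning(UserWarning):
    """The window maximum sits on the window edge (peak may lie outside)."""


@dataclass
class PhaseSet:
    """Peak phases (hours in ``[0, cycle_h)``) from one group and context."""

    phases_h: np.ndarray
    cycle_h: float = 24.0
    context: str = ""

    def __post_init__(self) -> None:
        self.phases_h = np.asarray(self.phases_h, dtype=float)
        if not self.cycle_h > 0:
            raise ValueError("cycle_h must be positive")
        if self.phases_h.size and (
            self.phases_h.min() < 0 or self.phases_h.max() >= self.cycle_h
        ):
            raise ValueError("phases must lie in [0, cycle_h)")

    @property
    def n(self) -> int:
        return int(self.phases_h.size)


@dataclass
class CircularSummary:
    """Mean direction, clustering strength, and Rayleigh uniformity p."""

    mean_phase_h: float | None
    resultant_R: float
    n: int
    cycle_h: float = 24.0
    rayleigh_p: float | None = None


def peak_phase(
    ts: TimeSeries,
    window: tuple[float, float],
    cycle_h: float = 24.0,
    anchor: float | None = None,
) -> float:
    """Phase (hours mod ``cycle_h``) of the global maximum within a window.

    ``anchor`` is the reference time of phase zero: ZT0 of the containing
    cycle for entrained epochs, or the release time for free-run epochs.  It
    defaults to the window start.  Ties resolve to the earliest maximum; a
    maximum on the first or last in-window sample raises
    :class:`BoundaryPeakWarning`.
    """
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("window start must precede window end")
    if w1 - w0 > 1.5 * cycle_h + 1e-9:
        raise ValueError("window length must not exceed 1.5 cycles")
    sub = ts.window(w0, w1)
    t, v = sub.finite()
    if t.size == 0:
        raise ValueError(f"no data in window [{w0}, {w1}] h")
    k = int(np.argmax(v))  # argmax returns the first (earliest) maximum
    if k == 0 or k == t.size - 1:
        warnings.warn(
            f"peak at window boundary (t = {t[k]:.2f} h); the true peak may "
            "lie outside the window",
            BoundaryPeakWarning,
            stacklevel=2,
        )
    if anchor is None:
        anchor = w0
    return float(np.mod(t[k] - anchor, cycle_h))


def circular_mean(ps: PhaseSet) -> CircularSummary:
    """Mean direction and resultant length of a phase set (no p-value).

    For degenerate sets (R ~ 0, e.g. antipodal pairs) the mean direction is
    undefined and reported as None.
    """
    if ps.n == 0:
        raise ValueError("cannot summarize an empty phase set")
    theta = 2.0 * np.pi * ps.phases_h / ps.cycle_h
    C = float(np.cos(theta).mean())
    S = float(np.sin(theta).mean())
    R = math.hypot(C, S)
    if R < _DEGENERATE_R:
        return CircularSummary(None, R, ps.n, ps.cycle_h)
    mean = (ps.cycle_h / (2.0 * np.pi)) * math.atan2(S, C) % ps.cycle_h
    if mean >= ps.cycle_h:  # float mod can round -eps % c up to c
        mean = 0.0
    return CircularSummary(mean, R, ps.n, ps.cycle_h)


def rayleigh_p(n: int, R: float) -> float:
    """Rayleigh uniformity p-value (Zar approximation), clipped to (0, 1]."""
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    if not 0 <= R <= 1 + 1e-12:
        raise ValueError("R must lie in [0, 1]")
    nR = n * min(R, 1.0)
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - nR * nR)) - (1.0 + 2.0 * n))
    return min(max(p, math.ulp(0.0)), 1.0)


def rayleigh_test(cs: CircularSummary) -> float:
    """p-value for the summary's (n, R)."""
    return rayleigh_p(cs.n, cs.resultant_R)


def rayleigh_critical_R(n: int, alpha: float = 0.05) -> float:
    """Smallest R whose Rayleigh p is <= alpha, by bisection to 1e-6.

    This is the radius of the significance circle drawn on Rayleigh plots.
    """
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = 0.0, 1.0  # p is decreasing in R
    for _ in range(64):
        mid = (lo + hi) / 2.0
        if rayleigh_p(n, mid) <= alpha:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-6:
            break
    return hi


def summarize_phases(ps: PhaseSet) -> CircularSummary:
    """Mean direction + R + Rayleigh p (p only when n >= 2)."""
    cs = circular_mean(ps)
    if cs.n >= 2:
        cs.rayleigh_p = rayleigh_test(cs)
    return cs
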