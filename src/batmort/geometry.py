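"""Search-plot geometry for square carcass-search plots.

Carcass searches are conducted on a square plot of side ``2a`` centred on
the turbine base.  Every point within distance ``a`` of the turbine is
searched; between ``a`` and the corner distance ``a*sqrt(2)`` only the
corners of the square intersect the circle of that radius, so the searched
fraction of an annulus falls from 1 to 0.  These fractions drive both the
inclusion-probability weights of the truncated weighted likelihood fit and
the annulus-sum area correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SquarePlot",
    "corner_truncation_distance",
    "circle_inclusion_fraction",
    "disc_area_inside_square",
    "annulus_searched_fraction",
    "annuli",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SquarePlot:
    """Axis-aligned square search plot centred on the turbine base.

    Parameters
    ----------
    half_width : float
        Half the side length ``a`` in metres (40 m for an 80 m x 80 m plot).
    """

    half_width: float = 40.0
    truncation_distance: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError(f"half_width must be positive, got {self.half_width}")
        object.__setattr__(self, "truncation_distance", self.half_width * _SQRT2)


def corner_truncation_distance(plot: SquarePlot) -> float:
    """Distance from plot centre to a corner, ``a * sqrt(2)``.

    Observed carcass distances are right-truncated at this radius.
    """
    return plot.half_width * _SQRT2


def circle_inclusion_fraction(d, plot: SquarePlot):
    """Fraction of the circle of radius ``d`` lying inside the square.

    This is the inclusion probability of a carcass at distance ``d`` under a
    uniform fall direction: 1 for ``d <= a``, ``1 - (4/pi) * arccos(a/d)``
    for ``a < d <= a*sqrt(2)`` and 0 beyond the corners.  Accepts scalars or
    arrays.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    a = plot.half_width
    tau = plot.truncation_distance
    with np.errstate(invalid="ignore", over="ignore"):
        ratio = np.clip(a / np.where(d_arr > 0, d_arr, np.inf), -1.0, 1.0)
        frac = 1.0 - (4.0 / np.pi) * np.arccos(ratio)
    frac = np.where(d_arr <= a, 1.0, frac)
    frac = np.where(d_arr >= tau, 0.0, frac)
    if np.ndim(d) == 0:
        return float(frac)
    return frac


def disc_area_inside_square(radius, plot: SquarePlot):
    """Area of the disc of given radius intersected with the square plot."""
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    a = plot.half_width
    tau = plot.truncation_distance
    full = np.pi * r**2
    with np.errstate(invalid="ignore"):
        rc = np.where(r > a, r, a + 1.0)  # placeholder keeps sqrt/arccos valid
        lens = 4.0 * (rc**2 * np.arccos(np.clip(a / rc, -1.0, 1.0)) - a * np.sqrt(rc**2 - a**2))
    area = np.where(r <= a, full, full - lens)
    area = np.where(r >= tau, 4.0 * a**2, area)
    if np.ndim(radius) == 0:
        return float(area)
    return area


def annulus_searched_fraction(d_lo: float, d_hi: float, plot: SquarePlot) -> float:
    """Searched (area) fraction of the annulus ``[d_lo, d_hi)``.

    Ratio of the annulus area inside the square to the full annulus area.
    """
    if not 0 <= d_lo < d_hi:
        raise ValueError(f"need 0 <= d_lo < d_hi, got [{d_lo}, {d_hi})")
    inside = disc_area_inside_square(d_hi, plot) - disc_area_inside_square(d_lo, plot)
    total = np.pi * (d_hi**2 - d_lo**2)
    return float(inside / total)


def annuli(plot: SquarePlot, width: float = 1.0) -> list[tuple[float, float]]:
    """Half-open annulus bins ``[i, i+width)`` out to the corner distance.

    The final annulus is truncated at ``a*sqrt(2)``.
    """
    tau = plot.truncation_distance
    edges = list(np.arange(0.0, tau, width)) + [tau]
    return [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
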