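"""Closed-form growth models and growth-zone point selection.

Two generating models are supported: pure exponential growth scaled by the
dilution step, ``y = y0 * E**x / D**j``, and a logistic curve whose per-cycle
efficiency declines smoothly from its baseline-region value ``E0`` toward 1
as the signal approaches the plateau ``ymax``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import NoGrowthZoneDataError
from .io import DilutionSeries

logger = logging.getLogger(__name__)

DEFAULT_GROWTH_ZONE = (20.0, 180.0)


@dataclass
class ExpModelParams:
    """Parameters of the dilution-scaled exponential model."""

    y0: float
    E: float
    D: float = 2.0

    def __post_init__(self) -> None:
        if self.y0 <= 0:
            raise ValueError("y0 must be > 0")
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if self.D <= 1:
            raise ValueError("dilution factor D must be > 1")


@dataclass
class LogisticParams:
    """Parameters of the logistic growth model."""

    y0: float
    ymax: float
    E0: float

    def __post_init__(self) -> None:
        if not 0 < self.y0 < self.ymax:
            raise ValueError("require 0 < y0 < ymax")
        if self.E0 <= 1:
            raise ValueError("baseline efficiency E0 must be > 1")


@dataclass
class GrowthPoint:
    """A single growth-zone observation.

    ``curve_index`` is the position of the source curve within the series,
    ``j`` its dilution exponent, ``x`` the (absolute) cycle number and ``y``
    the baselined fluorescence.
    """

    curve_index: int
    j: int
    x: int
    y: float


@dataclass
class GrowthZone:
    """Inclusive fluorescence window assumed to be still exponential."""

    lo: float = DEFAULT_GROWTH_ZONE[0]
    hi: float = DEFAULT_GROWTH_ZONE[1]

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("growth zone requires 0 < lo < hi")


def exp_model_value(params: ExpModelParams, x, j):
    """Evaluate ``y0 * E**x / D**j`` (vectorized in ``x`` and ``j``)."""
    x = np.asarray(x, dtype=float)
    j = np.asarray(j, dtype=float)
    return params.y0 * params.E**x / params.D**j


def logistic_model_value(params: LogisticParams, x):
    """Evaluate ``y0*ymax*E0**x / (y0*E0**x + ymax - y0)`` (vectorized).

    Equals ``y0`` at ``x = 0`` and tends to ``ymax`` for large ``x``.
    Computed in a form that avoids overflow of ``E0**x`` for large ``x``.
    """
    x = np.asarray(x, dtype=float)
    # ymax / (1 + ((ymax - y0)/y0) * E0**-x): E0**-x underflows harmlessly
    q = (params.ymax - params.y0) / params.y0
    return params.ymax / (1.0 + q * params.E0 ** (-x))


def select_growth_zone(
    series: DilutionSeries, zone: GrowthZone | Sequence[float] | None = None
) -> list[GrowthPoint]:
    """Select, per curve, the first rising run of points inside the zone.

    For each curve the returned points are the first contiguous run of
    cycles with ``lo <= y <= hi`` that is entered from below (the preceding
    point, if any, has ``y < lo``).  Points recorded after the curve first
    exceeds ``hi`` are never included, so plateau re-entry cannot
    contaminate the selection.  The result is ordered by
    ``(curve_index, x)``.

    A curve contributing no points is skipped with a warning; if every curve
    is empty a :class:`NoGrowthZoneDataError` is raised.
    """
    if zone is None:
        zone = GrowthZone()
    elif not isinstance(zone, GrowthZone):
        zone = GrowthZone(*zone)

    points: list[GrowthPoint] = []
    for ci, curve in enumerate(series.curves):
        y = curve.fluorescence
        x = curve.cycles
        # index of first sample above the zone: nothing beyond it counts
        above = np.nonzero(y > zone.hi)[0]
        cap = int(above[0]) if above.size else y.size

        run: list[int] = []
        for k in range(cap):
            if zone.lo <= y[k] <= zone.hi:
                run.append(k)
            elif run:
                break  # left the zone downward: first run is over
            else:
                continue
        # entering from below: the sample before the run must lie under lo
        if run and run[0] > 0 and y[run[0] - 1] >= zone.lo:
            run = []
        if not run:
            warnings.warn(
                f"curve {curve.well_id!r} contributes no growth-zone points; skipped",
                stacklevel=2,
            )
            continue
        points.extend(
            GrowthPoint(
                curve_index=ci,
                j=curve.dilution_exponent,
                x=int(x[k]),
                y=float(y[k]),
            )
            for k in run
        )
    if not points:
        raise NoGrowthZoneDataError("no growth-zone data in any curve")
    logger.info(
        "growth zone [%g, %g]: selected %d points from %d curves",
        zone.lo,
        zone.hi,
        len(points),
        len(series.curves),
    )
    return points
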