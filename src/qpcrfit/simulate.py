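"""Synthetic dilution-series data with additive constant-sigma Gaussian noise.

Two generators are provided: :func:`simulate_points` draws noisy replicates
of a fixed growth-zone point design (for estimator-precision studies), and
:func:`simulate_curves` builds full logistic amplification curves with a
linear baseline (for Cq-calibration pipelines).

The default point design has 3 curves at dilution exponents 0, 1, 2 with
cycles {14,15,16}, {15,16,17}, {16,17,18} (a one-cycle stagger, close to the
dilution-factor-2 shift at E around 1.85).  ``y0`` is chosen so the nine
exact values lie inside the 20-180 RFU growth window (they span about
44-175 RFU).  This layout yields 36 pairwise differences of which 5 share a
cycle, leaving 31 ratio estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AmplificationCurve, DilutionSeries
from .models import (
    ExpModelParams,
    GrowthPoint,
    LogisticParams,
    exp_model_value,
    logistic_model_value,
)

DEFAULT_LAYOUT = (
    (0, 14), (0, 15), (0, 16),
    (1, 15), (1, 16), (1, 17),
    (2, 16), (2, 17), (2, 18),
)


@dataclass
class PointDesign:
    """A fixed layout of (dilution exponent, cycle) slots plus noise level."""

    layout: tuple
    params: ExpModelParams
    sigma_y: float

    def __post_init__(self) -> None:
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be >= 0")
        if len(self.layout) < 3:
            raise ValueError("point design needs >= 3 slots")

    def exact_values(self) -> np.ndarray:
        j = np.array([slot[0] for slot in self.layout], dtype=float)
        x = np.array([slot[1] for slot in self.layout], dtype=float)
        return np.asarray(exp_model_value(self.params, x, j), dtype=float)

    def points(self, y: np.ndarray) -> list[GrowthPoint]:
        """Wrap one noisy value vector as GrowthPoint objects."""
        return [
            GrowthPoint(curve_index=int(j), j=int(j), x=int(x), y=float(v))
            for (j, x), v in zip(self.layout, y)
        ]


def default_point_design(
    E: float = 1.85,
    sigma_y: float = 2.4,
    D: float = 2.0,
    target_max: float = 175.0,
) -> PointDesign:
    """The 9-point, 3-curve design used throughout the precision study."""
    j = np.array([slot[0] for slot in DEFAULT_LAYOUT], dtype=float)
    x = np.array([slot[1] for slot in DEFAULT_LAYOUT], dtype=float)
    peak = float(np.max(E**x / D**j))
    y0 = target_max / peak
    return PointDesign(
        layout=DEFAULT_LAYOUT,
        params=ExpModelParams(y0=y0, E=E, D=D),
        sigma_y=sigma_y,
    )


def simulate_points(design: PointDesign, n_sim: int, seed: int):
    """Draw ``n_sim`` independent noisy realizations of the point design.

    Returns ``(values, exact)`` where ``values`` has shape
    ``(n_sim, n_slots)`` and ``exact`` is the noiseless value vector.  The
    generator state is fully determined by ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    exact = design.exact_values()
    noise = rng.normal(0.0, design.sigma_y, size=(n_sim, exact.size)) \
        if design.sigma_y > 0 else np.zeros((n_sim, exact.size))
    return exact + noise, exact


@dataclass
class CurveDesign:
    """Design of a full simulated dilution series of logistic curves."""

    n_concentrations: int = 6
    dilution_factor: float = 2.0
    params: LogisticParams = field(
        default_factory=lambda: LogisticParams(y0=0.04, ymax=600.0, E0=1.9)
    )
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    n_cycles: int = 40
    sigma_y: float = 2.4

    def __post_init__(self) -> None:
        if self.n_concentrations < 1:
            raise ValueError("need >= 1 concentration")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must be > 1")
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be >= 0")
        top = float(logistic_model_value(self.params, self.n_cycles))
        if top < 0.99 * self.params.ymax:
            raise ValueError(
                f"plateau not reached within {self.n_cycles} cycles for the most "
                f"concentrated curve (reaches {top:.3g} of {self.params.ymax:g})"
            )

    def exact_series(self) -> DilutionSeries:
        """The noiseless series (baseline + logistic growth)."""
        curves = []
        x = np.arange(1, self.n_cycles + 1)
        for j in range(self.n_concentrations):
            pj = LogisticParams(
                y0=self.params.y0 / self.dilution_factor**j,
                ymax=self.params.ymax,
                E0=self.params.E0,
            )
            y = (
                self.baseline_intercept
                + self.baseline_slope * x
                + logistic_model_value(pj, x)
            )
            curves.append(
                AmplificationCurve(
                    well_id=f"W{j}", dilution_exponent=j, cycles=x, fluorescence=y
                )
            )
        return DilutionSeries(curves=curves, dilution_factor=self.dilution_factor)


def simulate_curves(
    design: CurveDesign, n_replicate_sets: int, seed: int
) -> list[DilutionSeries]:
    """Simulate full noisy dilution series (one per replicate set)."""
    if n_replicate_sets < 1:
        raise ValueError("n_replicate_sets must be >= 1")
    rng = np.random.default_rng(seed)
    exact = design.exact_series()
    out = []
    for _ in range(n_replicate_sets):
        curves = []
        for c in exact.curves:
            noise = (
                rng.normal(0.0, design.sigma_y, size=c.fluorescence.size)
                if design.sigma_y > 0
                else 0.0
            )
            curves.append(
                AmplificationCurve(
                    well_id=c.well_id,
                    dilution_exponent=c.dilution_exponent,
                    cycles=c.cycles.copy(),
                    fluorescence=c.fluorescence + noise,
                )
            )
        out.append(DilutionSeries(curves=curves, dilution_factor=design.dilution_factor))
    return out
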