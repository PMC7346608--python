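"""Monte Carlo comparison of estimator precision and histogram diagnostics.

For each simulated replicate of a fixed growth-zone point design, every
requested estimator is run on the *same* noisy data.  The ensemble SD of the
point estimates ("actual" precision) is compared with the mean of the
per-replicate a priori SEs ("apparent" precision).  For correlated-data
estimators the apparent SE is falsely small, which is the effect the study
quantifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .estimators import (
    estimate_pairwise,
    fit_differences_naive,
    fit_direct,
    make_difference_pairs,
)
from .simulate import PointDesign, default_point_design, simulate_points

logger = logging.getLogger(__name__)

ESTIMATOR_NAMES = ("direct", "naive_diffs", "pairwise_ratio")


@dataclass
class MCConfig:
    """Design, size, seed and estimator selection of one MC run."""

    design: PointDesign = field(default_factory=default_point_design)
    n_sim: int = 40_000
    seed: int = 0
    estimators: tuple = ESTIMATOR_NAMES

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        unknown = set(self.estimators) - set(ESTIMATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")


@dataclass
class EstimatorEnsemble:
    """Per-estimator ensemble of point estimates and apparent SEs."""

    name: str
    e_hats: np.ndarray
    apparent_ses: np.ndarray
    n_dropped: int

    @property
    def actual_sd(self) -> float:
        return float(np.std(self.e_hats, ddof=1))

    @property
    def mean_apparent_se(self) -> float:
        return float(np.mean(self.apparent_ses))

    @property
    def sd_ratio(self) -> float:
        """Actual over apparent precision; 1 means honest error bars."""
        return self.actual_sd / self.mean_apparent_se


@dataclass
class MCResult:
    """Aggregated output of :func:`run_mc_comparison`."""

    config_seed: int
    n_sim: int
    ensembles: dict
    sd_pairs_over_direct: float
    mean_e: dict

    def summary(self) -> dict:
        """Flat, serialization-friendly view of the headline numbers."""
        out = {"seed": self.config_seed, "n_sim": self.n_sim}
        for name, ens in self.ensembles.items():
            out[name] = {
                "mean_E": float(np.mean(ens.e_hats)),
                "actual_sd": ens.actual_sd,
                "mean_apparent_se": ens.mean_apparent_se,
                "sd_ratio": ens.sd_ratio,
                "n_dropped": ens.n_dropped,
            }
        out["sd_pairs_over_direct"] = self.sd_pairs_over_direct
        return out


@dataclass
class NormalFitResult:
    """Weighted LS fit of histogram counts to a normal bell curve."""

    mu: float
    sigma: float
    amplitude: float
    chisq: float
    nu: int
    bin_edges: np.ndarray
    counts: np.ndarray


def run_mc_comparison(config: MCConfig) -> MCResult:
    """Run all requested estimators on each of ``n_sim`` noisy replicates.

    Non-convergent fits are dropped and counted; more than 1% of them in any
    estimator aborts the study (the design is too noisy to compare fairly).
    """
    design = config.design
    values, _ = simulate_points(design, config.n_sim, config.seed)
    D = design.params.D

    collect = {name: ([], []) for name in config.estimators}
    dropped = {name: 0 for name in config.estimators}

    for row in values:
        points = design.points(row)
        if "direct" in collect or "pairwise_ratio" in collect:
            direct = fit_direct(points, D=D)
        if "direct" in collect:
            if direct.converged:
                collect["direct"][0].append(direct.E_hat)
                collect["direct"][1].append(direct.se_E)
            else:
                dropped["direct"] += 1
        if "naive_diffs" in collect:
            diffs = make_difference_pairs(points)
            naive = fit_differences_naive(diffs, points, D=D)
            if naive.converged:
                collect["naive_diffs"][0].append(naive.E_hat)
                collect["naive_diffs"][1].append(naive.se_E)
            else:
                dropped["naive_diffs"] += 1
        if "pairwise_ratio" in collect:
            if direct.converged and direct.s_y > 0:
                _, summary = estimate_pairwise(points, D=D, sigma_y=direct.s_y)
                collect["pairwise_ratio"][0].append(summary.E_bar_weighted)
                collect["pairwise_ratio"][1].append(summary.se_apriori)
            else:
                dropped["pairwise_ratio"] += 1

    ensembles = {}
    for name, (e_hats, ses) in collect.items():
        if dropped[name] > 0.01 * config.n_sim:
            raise RuntimeError(
                f"estimator {name!r}: {dropped[name]} of {config.n_sim} replicates "
                "failed to converge (> 1%); design too noisy"
            )
        ensembles[name] = EstimatorEnsemble(
            name=name,
            e_hats=np.asarray(e_hats),
            apparent_ses=np.asarray(ses),
            n_dropped=dropped[name],
        )
        logger.info(
            "MC %s: actual_sd=%.5g mean_apparent_se=%.5g ratio=%.3f",
            name,
            ensembles[name].actual_sd,
            ensembles[name].mean_apparent_se,
            ensembles[name].sd_ratio,
        )

    sd_pairs_over_direct = math.nan
    if "direct" in ensembles and "pairwise_ratio" in ensembles:
        sd_pairs_over_direct = (
            ensembles["pairwise_ratio"].actual_sd / ensembles["direct"].actual_sd
        )
    return MCResult(
        config_seed=config.seed,
        n_sim=config.n_sim,
        ensembles=ensembles,
        sd_pairs_over_direct=sd_pairs_over_direct,
        mean_e={name: float(np.mean(e.e_hats)) for name, e in ensembles.items()},
    )


def histogram_normal_fit(values, n_bins: int = 30) -> NormalFitResult:
    """Fit histogram counts to ``A*exp(-(v-mu)^2 / 2 sigma^2)``, weights 1/count.

    Equal-width bins span mean +/- 4 sample SDs; empty bins are excluded
    (the Poisson weight 1/count is undefined there).  ``nu`` is the number
    of used bins minus the 3 fitted parameters.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 500:
        raise ValueError("histogram fit needs >= 500 values")
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("degenerate binning: all values identical")
    mean = float(np.mean(v))
    edges = np.linspace(mean - 4 * sd, mean + 4 * sd, n_bins + 1)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    used = counts > 0
    if used.sum() < 4:
        raise ValueError(f"only {int(used.sum())} non-empty bins; need >= 4")
    c = counts[used].astype(float)
    t = centers[used]
    sigma_w = np.sqrt(c)  # weight 1/count  <=>  per-bin SD sqrt(count)

    def resid(p):
        a, mu, s = p
        return (a * np.exp(-0.5 * ((t - mu) / s) ** 2) - c) / sigma_w

    p0 = np.array([float(c.max()), mean, sd])
    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    chisq = float(sol.fun @ sol.fun)
    nu = int(used.sum()) - 3
    return NormalFitResult(
        mu=float(sol.x[1]),
        sigma=float(abs(sol.x[2])),
        amplitude=float(sol.x[0]),
        chisq=chisq,
        nu=nu,
        bin_edges=edges,
        counts=counts,
    )
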