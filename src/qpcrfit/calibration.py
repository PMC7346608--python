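"""Cq-marker extraction, standard-curve calibration, and ensemble statistics.

Full amplification curves are fitted to a log-logistic sigmoid with an
adjustable asymmetry exponent plus a sloping linear baseline (the baseline
compensates for systematic errors left by upstream baselining):

    f(x) = a + b*x + ymax * (1 + exp(-k*(x - xm)))**(-s)

with rate ``k = ln(E0_like)``, midpoint ``xm`` and asymmetry ``s`` (s = 1
gives the symmetric logistic).  Cq markers — absolute threshold, first- and
second-derivative maxima (FDM/SDM) and Cy0 (x-intercept of the tangent at
the FDM) — are evaluated on the fitted, baseline-subtracted curve with
analytic derivatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .exceptions import CqUndefinedError, DegenerateDesignError, FlatCurveError
from .io import AmplificationCurve

logger = logging.getLogger(__name__)

CQ_MARKERS = ("threshold", "FDM", "SDM", "Cy0")


@dataclass
class SigmoidFit:
    """Fitted sigmoid-plus-baseline parameters for one curve."""

    ymax: float
    midpoint: float
    rate: float  # per-cycle growth factor in the baseline region (E0-like)
    asymmetry: float
    baseline_intercept: float
    baseline_slope: float
    cov: np.ndarray
    chisq: float
    nu: int
    s_y: float
    converged: bool
    x_min: float
    x_max: float

    @property
    def scale_y0(self) -> float:
        """Baseline-subtracted fitted signal extrapolated to cycle 0."""
        return float(self._growth(0.0))

    # -- analytic growth part and derivatives -------------------------------
    def _u(self, x):
        k = math.log(self.rate)
        arg = -k * (np.asarray(x, dtype=float) - self.midpoint)
        return np.exp(np.clip(arg, -700.0, 700.0))

    def _growth(self, x):
        return self.ymax * (1.0 + self._u(x)) ** (-self.asymmetry)

    def _growth_d1(self, x):
        k = math.log(self.rate)
        u = self._u(x)
        return self.ymax * self.asymmetry * k * u * (1.0 + u) ** (-self.asymmetry - 1)

    def _growth_d2(self, x):
        k = math.log(self.rate)
        s = self.asymmetry
        u = self._u(x)
        return self.ymax * s * k**2 * u * (1.0 + u) ** (-s - 2) * (s * u - 1.0)

    def baseline(self, x):
        return self.baseline_intercept + self.baseline_slope * np.asarray(x, float)

    def predict(self, x):
        return self.baseline(x) + self._growth(x)


@dataclass
class CqEstimate:
    """A fractional-cycle quantification marker for one well."""

    well_id: str
    marker: str
    cq: float
    threshold_value: float | None = None


@dataclass
class CalibrationFit:
    """Linear fit of Cq against log(N0): slope = -1/log(E)."""

    slope: float
    intercept: float
    E_hat: float
    se_slope: float
    se_E: float
    chisq: float
    nu: int
    log_base: float


@dataclass
class EnsembleStats:
    """Weighted-mean statistics across replicate-set estimates."""

    mean_weighted: float
    se_apriori: float
    post_se: float
    chisq: float
    nu: int
    mean_unweighted: float
    se_unweighted: float
    effective_sd: float
    n_sets: int


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------


def _sigmoid_model(p, x):
    ymax, xm, logk, s, a, b = p
    k = math.exp(min(logk, 5.0))
    u = np.exp(np.clip(-k * (x - xm), -700.0, 700.0))
    return a + b * x + ymax * (1.0 + u) ** (-math.exp(min(s, 5.0)))


def fit_sigmoid_curve(curve: AmplificationCurve) -> SigmoidFit:
    """Fit the sigmoid + sloping-baseline model to a full curve.

    Initialization: baseline from a linear fit to the early cycles, plateau
    from the curve maximum, midpoint from the half-maximum crossing.  A curve
    whose rise above the median is below five early-cycle noise SDs raises
    :class:`FlatCurveError`.
    """
    x = np.asarray(curve.cycles, dtype=float)
    y = np.asarray(curve.fluorescence, dtype=float)
    if x.size < 8:
        raise DegenerateDesignError("sigmoid fit needs at least 8 cycles")

    n_early = max(5, x.size // 5)
    eb, ea = np.polyfit(x[:n_early], y[:n_early], 1)
    early_sd = float(np.std(y[:n_early] - (ea + eb * x[:n_early]), ddof=2))
    rise = float(np.max(y) - np.median(y[:n_early]))
    if rise < 5.0 * max(early_sd, 1e-12):
        raise FlatCurveError(
            f"curve {curve.well_id!r}: rise {rise:.3g} below 5 x early noise "
            f"SD {early_sd:.3g}"
        )

    ymax0 = float(np.max(y) - np.median(y[:n_early]))
    half = np.median(y[:n_early]) + 0.5 * ymax0
    above = np.nonzero(y >= half)[0]
    xm0 = float(x[above[0]]) if above.size else float(np.median(x))
    p0 = np.array([ymax0, xm0, math.log(math.log(1.9)), 0.0, ea, eb])

    def resid(p):
        return _sigmoid_model(p, x) - y

    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=5000)
    p = sol.x
    r = sol.fun
    nu = x.size - 6
    chisq = float(r @ r)
    s_y = math.sqrt(chisq / nu) if nu > 0 else math.nan
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s_y**2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((6, 6), np.nan)
    converged = bool(sol.status > 0)
    logger.info(
        "sigmoid fit %r: n=%d nu=%d chisq=%.6g s_y=%.4g converged=%s",
        curve.well_id, x.size, nu, chisq, s_y, converged,
    )
    return SigmoidFit(
        ymax=float(p[0]),
        midpoint=float(p[1]),
        rate=float(math.exp(math.exp(p[2]))),
        asymmetry=float(math.exp(p[3])),
        baseline_intercept=float(p[4]),
        baseline_slope=float(p[5]),
        cov=cov,
        chisq=chisq,
        nu=nu,
        s_y=s_y,
        converged=converged,
        x_min=float(x[0]),
        x_max=float(x[-1]),
    )


# ---------------------------------------------------------------------------
# Cq markers
# ---------------------------------------------------------------------------

_CQ_XTOL = 1e-9


def _fdm(fit: SigmoidFit) -> float:
    res = minimize_scalar(
        lambda t: -fit._growth_d1(t),
        bounds=(fit.x_min, fit.x_max),
        method="bounded",
        options={"xatol": _CQ_XTOL},
    )
    return float(res.x)


def compute_cq(
    fit: SigmoidFit,
    curve: AmplificationCurve,
    marker: str,
    threshold: float | None = None,
    interpolate: str = "fit",
) -> CqEstimate:
    """Evaluate a Cq marker on the fitted, baseline-subtracted curve.

    * ``threshold`` — fractional cycle where the fitted growth part crosses
      the given RFU level (bisection; ``interpolate="raw"`` instead
      log-linearly interpolates the raw baseline-subtracted points).
    * ``FDM`` / ``SDM`` — argmax of the first / second analytic derivative.
    * ``Cy0`` — x-intercept of the tangent at the FDM:
      ``Cy0 = x_FDM - y(x_FDM) / y'(x_FDM)``.
    """
    if marker not in CQ_MARKERS:
        raise ValueError(f"unknown marker {marker!r}; choose from {CQ_MARKERS}")
    if marker != "threshold" and not fit.converged:
        raise CqUndefinedError("sigmoid fit did not converge; derivative markers unavailable")

    lo, hi = fit.x_min, fit.x_max
    if marker == "threshold":
        if threshold is None:
            raise ValueError("threshold marker requires a threshold value")
        if not 0 < threshold < fit.ymax:
            raise CqUndefinedError(
                f"threshold {threshold:g} outside (0, ymax={fit.ymax:g})"
            )
        if interpolate == "raw":
            yb = curve.fluorescence - np.asarray(fit.baseline(curve.cycles))
            above = np.nonzero(yb >= threshold)[0]
            if above.size == 0 or above[0] == 0:
                raise CqUndefinedError("threshold never crossed within the raw data")
            k = above[0]
            y1, y2 = max(yb[k - 1], 1e-12), yb[k]
            x1, x2 = curve.cycles[k - 1], curve.cycles[k]
            cq = x1 + (x2 - x1) * (math.log(threshold / y1) / math.log(y2 / y1))
        else:
            g = fit._growth
            if not g(lo) < threshold < g(hi):
                raise CqUndefinedError("threshold never crossed by the fitted curve")
            a, b = lo, hi
            while b - a > 1e-7:
                m = 0.5 * (a + b)
                if g(m) < threshold:
                    a = m
                else:
                    b = m
            cq = 0.5 * (a + b)
        return CqEstimate(curve.well_id, marker, float(cq), threshold_value=threshold)

    x_fdm = _fdm(fit)
    if marker == "FDM":
        cq = x_fdm
    elif marker == "SDM":
        res = minimize_scalar(
            lambda t: -fit._growth_d2(t),
            bounds=(lo, x_fdm),
            method="bounded",
            options={"xatol": _CQ_XTOL},
        )
        cq = float(res.x)
        if cq - lo < 1e-3:
            raise CqUndefinedError("SDM lies at or below the start of the data range")
    else:  # Cy0
        cq = x_fdm - float(fit._growth(x_fdm)) / float(fit._growth_d1(x_fdm))
    if not lo - 1.0 <= cq <= hi:
        raise CqUndefinedError(f"marker {marker} at cycle {cq:.3f} outside data range")
    return CqEstimate(curve.well_id, marker, float(cq))


# ---------------------------------------------------------------------------
# standard curve and ensembles
# ---------------------------------------------------------------------------


def standard_curve_fit(
    cqs,
    log_n0,
    weights=None,
    log_base: float = 2.0,
) -> CalibrationFit:
    """(Weighted) linear LS of Cq against log(N0); ``E = base**(-1/slope)``.

    ``cqs`` may be :class:`CqEstimate` objects or plain numbers.  ``log_n0``
    must be expressed in ``log_base``; the efficiency estimate is invariant
    to that choice when applied consistently.  With ``weights`` given they
    are used as absolute inverse variances of the Cq values; otherwise the
    per-point variance is estimated from the fit scatter.
    """
    cq = np.array([c.cq if isinstance(c, CqEstimate) else float(c) for c in cqs])
    ln0 = np.asarray(log_n0, dtype=float)
    if cq.size != ln0.size:
        raise ValueError("cqs and log_n0 lengths differ")
    if np.unique(ln0).size < 2:
        raise DegenerateDesignError("all concentrations equal: slope not identifiable")
    if cq.size < 3:
        raise DegenerateDesignError("standard curve needs >= 3 points")

    w = np.ones_like(cq) if weights is None else np.asarray(weights, dtype=float)
    X = np.column_stack((ln0, np.ones_like(ln0)))
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ cq)
    r = cq - X @ beta
    chisq = float(np.sum(w * r**2))
    nu = cq.size - 2
    cov_unscaled = np.linalg.inv(XtW @ X)
    if weights is None:
        cov = (chisq / nu) * cov_unscaled
    else:
        cov = cov_unscaled
    slope, intercept = float(beta[0]), float(beta[1])
    se_slope = float(math.sqrt(max(cov[0, 0], 0.0)))
    if slope == 0:
        raise DegenerateDesignError("zero slope: E undefined")
    e_hat = float(log_base ** (-1.0 / slope))
    se_e = abs(math.log(log_base) * e_hat / slope**2) * se_slope
    logger.info(
        "standard curve: n=%d slope=%.6g E=%.6g chisq=%.4g", cq.size, slope, e_hat, chisq
    )
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        E_hat=e_hat,
        se_slope=se_slope,
        se_E=se_e,
        chisq=chisq,
        nu=nu,
        log_base=log_base,
    )


def ensemble_stats(values, ses) -> EnsembleStats:
    """Weighted-mean statistics over per-set estimates with their SEs.

    ``post_se = se_apriori * sqrt(chisq/nu)`` converts the a priori SE to a
    scatter-based one; ``effective_sd = post_se * sqrt(n_sets)`` recovers the
    implied single-set SD.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if v.size != s.size:
        raise ValueError("values and ses lengths differ")
    if v.size < 2:
        raise DegenerateDesignError("ensemble statistics need >= 2 sets")
    if np.any(s <= 0):
        raise ValueError("all SEs must be > 0")
    w = 1.0 / s**2
    mean_w = float(np.sum(w * v) / np.sum(w))
    se_apriori = float(np.sum(w) ** -0.5)
    nu = v.size - 1
    chisq = float(np.sum(w * (v - mean_w) ** 2))
    post_se = se_apriori * math.sqrt(chisq / nu)
    return EnsembleStats(
        mean_weighted=mean_w,
        se_apriori=se_apriori,
        post_se=post_se,
        chisq=chisq,
        nu=nu,
        mean_unweighted=float(np.mean(v)),
        se_unweighted=float(np.std(v, ddof=1) / math.sqrt(v.size)),
        effective_sd=effective_sd(post_se, v.size),
        n_sets=int(v.size),
    )


def effective_sd(post_se: float, n_sets: int) -> float:
    """Convert a weighted-mean post-SE into the implied single-set SD."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return float(post_se * math.sqrt(n_sets))


def sd_relative_sd(nu: int) -> float:
    """Relative SD of a sampling estimate of an SD: ``(2*nu)**-0.5``."""
    if nu < 1:
        raise ValueError("nu must be >= 1")
    return float((2.0 * nu) ** -0.5)
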