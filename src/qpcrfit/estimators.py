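"""Estimators of the amplification efficiency E from growth-zone points.

Four routes are implemented side by side:

* :func:`fit_direct` — unweighted nonlinear least squares of the points
  against ``y0 * E**x / D**j``; the statistically correct treatment.
* :func:`fit_differences_naive` — NLS of all pairwise differences treated
  *as if* they were independent observations.  This is deliberately the
  fallacious estimator whose apparent standard errors are too small.
* :func:`fit_differences_gls` — generalized least squares on a spanning set
  of differences plus one anchor value, weighting by the inverse Gram matrix
  of the transformation; reproduces the direct fit exactly.
* :func:`pairwise_ratio_estimates` and friends — the per-pair ratio
  estimator with error-propagation weights and weighted averaging.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateDesignError,
    DisconnectedPairsError,
    SingularGramError,
)
from .models import GrowthPoint

logger = logging.getLogger(__name__)

DEFAULT_OUTLIER_ZONE = (1.60, 2.15)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class ExpFitResult:
    """Least-squares estimates of (y0, E) with a priori error statistics.

    ``chisq`` is the (weighted) sum of squared residuals, ``nu = n_obs - 2``
    the degrees of freedom, ``s_y = sqrt(chisq/nu)`` the residual noise
    estimate, and ``cov`` the parameter covariance ``s_y**2 * (J^T J)^-1``
    from which the a priori standard errors derive.
    """

    y0_hat: float
    E_hat: float
    se_y0: float
    se_E: float
    cov: np.ndarray
    chisq: float
    nu: int
    s_y: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    method: str = "direct"
    independence_assumed: bool = True


@dataclass
class DifferenceSet:
    """All (or a subset of) pairwise differences of an ordered point list.

    ``L`` has one row per difference with +1 at the first index and -1 at
    the second, so ``d = L @ y`` exactly.
    """

    rows: list[tuple[int, int]]
    L: np.ndarray
    d: np.ndarray
    n_points: int

    def subset(self, indices) -> "DifferenceSet":
        """A new :class:`DifferenceSet` restricted to the given rows."""
        rows = [self.rows[i] for i in indices]
        return DifferenceSet(
            rows=rows, L=self.L[list(indices)], d=self.d[list(indices)],
            n_points=self.n_points,
        )


@dataclass
class PairwiseEstimate:
    """One per-pair efficiency estimate with its propagated uncertainty."""

    idx_i: int
    idx_j: int
    x_i: int
    x_j: int
    y_i: float
    y_j: float
    D1: int
    D2: int
    E_ij: float
    Z: float
    sigma_Z: float = math.nan
    sigma_E: float = math.nan
    weight: float = math.nan
    norm_resid: float = math.nan
    flagged: bool = False


@dataclass
class PairwiseSummary:
    """Weighted (and unweighted) average of the per-pair estimates."""

    E_bar_weighted: float
    se_apriori: float
    E_bar_unweighted: float
    se_unweighted: float
    chisq: float
    nu: int
    post_se: float
    n_pairs: int
    n_flagged: int = 0
    n_excluded_same_cycle: int = 0


@dataclass
class OutlierZone:
    """Efficiency interval outside of which estimates are flagged."""

    lo_E: float = DEFAULT_OUTLIER_ZONE[0]
    hi_E: float = DEFAULT_OUTLIER_ZONE[1]

    def __post_init__(self) -> None:
        if self.lo_E >= self.hi_E:
            raise ValueError("outlier zone requires lo_E < hi_E")


@dataclass
class OutlierDiagnostics:
    """Weight-based insignificance diagnostics for flagged estimates."""

    n_flagged: int
    max_flagged_weight: float
    max_weight: float


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core
# ---------------------------------------------------------------------------

_XTOL = 1e-10
_MAX_ITER = 200


def _levmar(resid_jac, p0):
    """Damped Gauss-Newton with Marquardt diagonal scaling.

    ``resid_jac(p)`` returns ``(r, J)`` with ``r = model - obs``.
    Converges when the largest relative parameter change falls below 1e-10,
    capped at 200 iterations.  Returns ``(p, cov_unscaled, chisq, converged,
    n_iter, r)`` where ``cov_unscaled = (J^T J)^-1`` at the solution.
    """
    p = np.asarray(p0, dtype=float)
    r, J = resid_jac(p)
    cost = float(r @ r)
    lam = 1e-3
    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        A = J.T @ J
        g = J.T @ r
        dA = np.clip(np.diag(A), 1e-300, None)
        accepted = False
        for _ in range(60):
            try:
                step = np.linalg.solve(A + lam * np.diag(dA), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            p_new = p + step
            r_new, J_new = resid_jac(p_new)
            cost_new = float(r_new @ r_new)
            if np.isfinite(cost_new) and cost_new <= cost * (1 + 1e-14):
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        rel = np.max(np.abs(step) / np.maximum(np.abs(p_new), 1e-300))
        p, r, J, cost = p_new, r_new, J_new, cost_new
        lam = max(lam / 10.0, 1e-14)
        if rel < _XTOL:
            converged = True
            break
    A = J.T @ J
    try:
        cov_unscaled = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(f"singular normal matrix: {exc}") from exc
    return p, cov_unscaled, cost, converged, n_iter, r


def _finish(p, cov_unscaled, chisq, converged, n_iter, r, n_obs, method,
            independence=True):
    nu = n_obs - 2
    s_y = math.sqrt(chisq / nu) if nu > 0 else math.nan
    cov = s_y**2 * cov_unscaled
    # symmetrize against round-off
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    logger.info(
        "%s fit: n=%d nu=%d chisq=%.6g s_y=%.4g iter=%d converged=%s",
        method, n_obs, nu, chisq, s_y, n_iter, converged,
    )
    return ExpFitResult(
        y0_hat=float(p[0]),
        E_hat=float(p[1]),
        se_y0=float(se[0]),
        se_E=float(se[1]),
        cov=cov,
        chisq=float(chisq),
        nu=nu,
        s_y=s_y,
        residuals=r.copy(),
        converged=bool(converged),
        n_iter=int(n_iter),
        n_obs=int(n_obs),
        method=method,
        independence_assumed=independence,
    )


def _point_arrays(points: list[GrowthPoint]):
    x = np.array([p.x for p in points], dtype=float)
    j = np.array([p.j for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    return x, j, y


def _init_loglinear(x, j, y, D):
    """Start values from the log-linear regression ln(y) + j*ln(D) on x."""
    if np.any(y <= 0):
        # fall back to magnitude-based guess; optimizer does the rest
        return max(np.max(np.abs(y)), 1.0) / 2.0**np.max(x) if np.max(x) else 1.0, 1.9
    z = np.log(y) + j * np.log(D)
    slope, intercept = np.polyfit(x, z, 1)
    return float(np.exp(intercept)), float(np.exp(slope))


def fit_direct(points: list[GrowthPoint], D: float = 2.0) -> ExpFitResult:
    """Unweighted NLS of growth-zone points against ``y0*E**x / D**j``.

    Requires at least 3 points spanning at least 2 distinct cycles.  A priori
    SEs come from ``s_y**2 * (J^T J)^-1``; initialization is the log-linear
    regression of ``ln(y) + j*ln(D)`` on ``x``.
    """
    if len(points) < 3:
        raise DegenerateDesignError("fit_direct needs at least 3 points")
    x, j, y = _point_arrays(points)
    if np.unique(x).size < 2:
        raise DegenerateDesignError(
            "all points share a single cycle: (y0, E) not identifiable"
        )
    scale = D ** (-j)

    def resid_jac(p):
        y0, E = p
        Ex = E**x
        f = y0 * Ex * scale
        r = f - y
        J = np.column_stack((Ex * scale, y0 * x * E ** (x - 1) * scale))
        return r, J

    p0 = _init_loglinear(x, j, y, D)
    out = _levmar(resid_jac, p0)
    return _finish(*out, n_obs=len(points), method="direct")


# ---------------------------------------------------------------------------
# differences
# ---------------------------------------------------------------------------


def make_difference_pairs(points: list[GrowthPoint]) -> DifferenceSet:
    """All unordered pairwise differences, ordered by (idx_a, idx_b), a < b."""
    n = len(points)
    if n < 2:
        raise DegenerateDesignError("need at least 2 points to form differences")
    _, _, y = _point_arrays(points)
    rows = list(itertools.combinations(range(n), 2))
    L = np.zeros((len(rows), n))
    for k, (a, b) in enumerate(rows):
        L[k, a] = 1.0
        L[k, b] = -1.0
    d = L @ y
    return DifferenceSet(rows=rows, L=L, d=d, n_points=n)


def fit_differences_naive(
    diffs: DifferenceSet, points: list[GrowthPoint], D: float = 2.0
) -> ExpFitResult:
    """NLS of pairwise differences treated as independent unit-weight data.

    Deliberately fallacious: each difference re-uses raw points, so the
    a priori SEs (computed as if the ``n_pairs`` differences were independent
    with common variance) overstate the true precision.  The result records
    ``independence_assumed=True`` and ``n_obs = n_pairs``.
    """
    n_pairs = len(diffs.rows)
    if n_pairs < 3 or diffs.n_points < 3:
        raise DegenerateDesignError(
            "naive difference fit needs differences from >= 3 points"
        )
    x, j, y = _point_arrays(points)
    scale = D ** (-j)
    ia = np.array([a for a, _ in diffs.rows])
    ib = np.array([b for _, b in diffs.rows])
    d = diffs.d

    def resid_jac(p):
        y0, E = p
        Ex = E**x
        f = y0 * Ex * scale
        dy0 = Ex * scale
        dE = y0 * x * E ** (x - 1) * scale
        r = (f[ia] - f[ib]) - d
        J = np.column_stack((dy0[ia] - dy0[ib], dE[ia] - dE[ib]))
        return r, J

    p0 = _init_loglinear(x, j, y, D)
    out = _levmar(resid_jac, p0)
    return _finish(*out, n_obs=n_pairs, method="naive_diffs")


def _check_spanning(rows: list[tuple[int, int]], n_points: int) -> bool:
    """Union-find connectivity of the pair graph over all points."""
    parent = list(range(n_points))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in rows:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in range(n_points)}) == 1


def fit_differences_gls(
    diffs: DifferenceSet,
    anchor: int,
    points: list[GrowthPoint],
    D: float = 2.0,
) -> ExpFitResult:
    """Correlated-data GLS on ``n - 1`` spanning differences plus one anchor.

    The ``n - 1`` difference rows and one identity row for the anchor point
    are stacked into an invertible transform ``M``; the fit minimizes
    ``r^T (M M^T)^-1 r`` for the transformed residuals.  Because ``M`` is
    invertible this is algebraically identical to the direct fit, and the
    returned parameters *and* SEs match :func:`fit_direct`.

    Supplying ``n`` or more difference rows makes the Gram matrix
    ``L L^T`` singular (:class:`SingularGramError`); a row set that fails to
    span all points raises :class:`DisconnectedPairsError`.
    """
    n = diffs.n_points
    n_rows = len(diffs.rows)
    if n_rows >= n:
        det = float(np.linalg.det(diffs.L @ diffs.L.T))
        raise SingularGramError(
            f"{n_rows} difference rows from {n} points: det(L L^T) = {det:.3g} "
            "(singular; at most n-1 differences carry independent information)"
        )
    if n_rows != n - 1 or not _check_spanning(diffs.rows, n):
        raise DisconnectedPairsError(
            f"{n_rows} difference rows do not form a spanning set over {n} points"
        )
    if not 0 <= anchor < n:
        raise DegenerateDesignError(f"anchor index {anchor} out of range")

    x, j, y = _point_arrays(points)
    scale = D ** (-j)

    M = np.zeros((n, n))
    M[: n - 1] = diffs.L
    M[n - 1, anchor] = 1.0
    W = np.linalg.inv(M @ M.T)
    # whitener T with T^T T = W, so ||T r||^2 = r^T W r
    T = np.linalg.cholesky(W).T
    TM = T @ M
    z = TM @ y

    def resid_jac(p):
        y0, E = p
        Ex = E**x
        f = y0 * Ex * scale
        J = np.column_stack((Ex * scale, y0 * x * E ** (x - 1) * scale))
        return TM @ f - z, TM @ J

    p0 = _init_loglinear(x, j, y, D)
    out = _levmar(resid_jac, p0)
    return _finish(*out, n_obs=n, method="gls_diffs", independence=False)


# ---------------------------------------------------------------------------
# pairwise ratio estimator
# ---------------------------------------------------------------------------


def pairwise_ratio_estimates(points: list[GrowthPoint]) -> list[PairwiseEstimate]:
    """Per-pair ratio estimates of E from every pair with distinct cycles.

    For each unordered pair, oriented so the second point has the larger
    cycle number,

        log2(E_ij) = [log2(y_j) - log2(y_i) + (D2 - D1)] / (x_j - x_i)

    where D1, D2 are the dilution exponents (powers of the dilution factor).
    Pairs sharing a cycle number are excluded (the denominator vanishes);
    pairs involving a non-positive signal are dropped with a warning.
    The same-cycle exclusion count is attached as ``.n_excluded_same_cycle``.
    """
    n = len(points)
    estimates: list[PairwiseEstimate] = []
    n_same = 0
    for a, b in itertools.combinations(range(n), 2):
        pi, pj = points[a], points[b]
        if pi.x == pj.x:
            n_same += 1
            continue
        ii, jj = (a, b) if pj.x > pi.x else (b, a)
        pi, pj = points[ii], points[jj]
        if pi.y <= 0 or pj.y <= 0:
            warnings.warn(
                f"pair ({ii}, {jj}) dropped: non-positive signal", stacklevel=2
            )
            continue
        dx = pj.x - pi.x
        log2_e = (math.log2(pj.y) - math.log2(pi.y) + (pj.j - pi.j)) / dx
        e_ij = 2.0**log2_e
        estimates.append(
            PairwiseEstimate(
                idx_i=ii,
                idx_j=jj,
                x_i=pi.x,
                x_j=pj.x,
                y_i=pi.y,
                y_j=pj.y,
                D1=pi.j,
                D2=pj.j,
                E_ij=e_ij,
                Z=math.log(e_ij),
            )
        )
    estimates_count = len(estimates)
    logger.info(
        "pairwise ratios: %d estimates (%d same-cycle pairs excluded)",
        estimates_count, n_same,
    )
    # stash exclusion count for summaries
    for est in estimates:
        est.n_excluded_same_cycle = n_same  # type: ignore[attr-defined]
    return estimates


def pairwise_sigma_weights(
    estimates: list[PairwiseEstimate], sigma_y: float, E_ref: float
) -> list[PairwiseEstimate]:
    """Fill propagated uncertainties and averaging weights (in place).

    Error propagation on ``Z = ln(E_ij)`` with constant signal noise gives
    ``sigma_Z**2 = sigma_y**2/(dx)**2 * (1/y_j**2 + 1/y_i**2)`` and
    ``sigma_E = E_ref * sigma_Z``.  The stored ``weight`` is the
    common-factor-free form ``(dx)**2 * y_i**2 * y_j**2 / (y_i**2 + y_j**2)``,
    symmetric in the two points and strictly increasing in ``|dx|``.
    """
    if sigma_y <= 0:
        raise ValueError("sigma_y must be > 0")
    if E_ref <= 0:
        raise ValueError("E_ref must be > 0")
    # y values are recoverable from Z only jointly; carry via x/j lookup
    for est in estimates:
        dx = est.x_j - est.x_i
        y_i, y_j = est.y_i, est.y_j
        est.sigma_Z = abs(sigma_y / dx) * math.sqrt(1.0 / y_j**2 + 1.0 / y_i**2)
        est.sigma_E = E_ref * est.sigma_Z
        est.weight = dx**2 * y_i**2 * y_j**2 / (y_i**2 + y_j**2)
    return estimates


def weighted_mean_pairwise(estimates: list[PairwiseEstimate]) -> PairwiseSummary:
    """Inverse-variance weighted mean of the per-pair estimates.

    Uses ``w = 1/sigma_E**2``; ``se_apriori = (sum w)**-0.5``;
    ``chisq = sum w (E - Ebar)**2``; ``post_se = se_apriori *
    sqrt(chisq/nu)`` with ``nu = n - 1``.  Also fills each estimate's
    normalized residual ``(E_ij - Ebar)/sigma_E`` and reports the unweighted
    mean with its SE.
    """
    if len(estimates) < 2:
        raise DegenerateDesignError("weighted mean needs >= 2 estimates (nu = 0)")
    e = np.array([est.E_ij for est in estimates])
    sig = np.array([est.sigma_E for est in estimates])
    if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
        raise ValueError("sigma_E not filled; run pairwise_sigma_weights first")
    w = 1.0 / sig**2
    e_bar = float(np.sum(w * e) / np.sum(w))
    se_apriori = float(np.sum(w) ** -0.5)
    nu = len(estimates) - 1
    chisq = float(np.sum(w * (e - e_bar) ** 2))
    post_se = se_apriori * math.sqrt(chisq / nu)
    e_unw = float(np.mean(e))
    se_unw = float(np.std(e, ddof=1) / math.sqrt(len(e)))
    for est in estimates:
        est.norm_resid = (est.E_ij - e_bar) / est.sigma_E
    return PairwiseSummary(
        E_bar_weighted=e_bar,
        se_apriori=se_apriori,
        E_bar_unweighted=e_unw,
        se_unweighted=se_unw,
        chisq=chisq,
        nu=nu,
        post_se=post_se,
        n_pairs=len(estimates),
        n_flagged=sum(est.flagged for est in estimates),
        n_excluded_same_cycle=getattr(estimates[0], "n_excluded_same_cycle", 0),
    )


def flag_outlier_zone(
    estimates: list[PairwiseEstimate], zone: OutlierZone | None = None
) -> OutlierDiagnostics:
    """Flag estimates outside the efficiency zone; never delete them.

    Returns weight diagnostics: with proper weighting, flagged values carry
    weights far below the overall maximum and are therefore insignificant in
    the average regardless of deletion.
    """
    if zone is None:
        zone = OutlierZone()
    for est in estimates:
        est.flagged = est.E_ij < zone.lo_E or est.E_ij > zone.hi_E
    if not estimates:
        return OutlierDiagnostics(n_flagged=0, max_flagged_weight=0.0, max_weight=0.0)
    weights = np.array([est.weight for est in estimates])
    flagged = np.array([est.flagged for est in estimates])
    max_flagged = float(weights[flagged].max()) if flagged.any() else 0.0
    return OutlierDiagnostics(
        n_flagged=int(flagged.sum()),
        max_flagged_weight=max_flagged,
        max_weight=float(weights.max()),
    )


def estimate_pairwise(
    points: list[GrowthPoint],
    D: float = 2.0,
    sigma_y: float | None = None,
) -> tuple[list[PairwiseEstimate], PairwiseSummary]:
    """Full pairwise pipeline: ratios, weights, weighted average.

    ``sigma_y`` defaults to the residual noise ``s_y`` of the direct fit on
    the same points.  The reference efficiency for ``sigma_E`` starts at the
    unweighted mean and is refined by a single re-weighting pass with the
    weighted mean (the estimates are narrowly distributed, so further passes
    change nothing material).
    """
    if sigma_y is None:
        sigma_y = fit_direct(points, D=D).s_y
    estimates = pairwise_ratio_estimates(points)
    if len(estimates) < 2:
        raise DegenerateDesignError("pairwise pipeline needs >= 2 usable pairs")
    e_ref = float(np.mean([est.E_ij for est in estimates]))
    pairwise_sigma_weights(estimates, sigma_y, e_ref)
    first = weighted_mean_pairwise(estimates)
    pairwise_sigma_weights(estimates, sigma_y, first.E_bar_weighted)
    summary = weighted_mean_pairwise(estimates)
    return estimates, summary


# ---------------------------------------------------------------------------
# combinatorial helpers
# ---------------------------------------------------------------------------


def max_disjoint_pairs(n_points: int) -> int:
    """Maximum number of pairs from ``n_points`` items with no item reused.

    Computed by exhaustive enumeration of disjoint pairings for small n
    (the answer is floor(n/2), but it is derived, not assumed).
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    if n_points > 12:
        return n_points // 2

    def best(avail: frozenset) -> int:
        if len(avail) < 2:
            return 0
        first = min(avail)
        rest = avail - {first}
        # either skip `first`, or pair it with any partner
        top = best(rest)
        for partner in rest:
            top = max(top, 1 + best(rest - {partner}))
        return top

    return best(frozenset(range(n_points)))
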