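"""Zero-one inflated beta-binomial mixture model for per-cell methylation counts.

A cell's methylation fraction ``p`` in a region is modelled as a three-component
mixture: a point mass ``pi0`` at 0 (fully unmethylated), a point mass ``pi1`` at
1 (fully methylated), and a Beta(alpha, beta) density on (0, 1) with the
remaining weight.  Given ``p`` and the cell's total read count ``n``, the
methylated read count ``x`` is Binomial(n, p); marginally the continuous
component is beta-binomial.  This captures the excess of all-zero / all-one
cells and the over-dispersion typical of single-cell bisulfite sequencing.

Parameters are estimated per region and per group with an EM algorithm over the
latent component membership of each cell; the observed information of the
marginal log-likelihood (in the block-diagonal form used downstream) feeds the
delta-method Wald test of equal mean methylation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, polygamma, psi

__all__ = [
    "ZoibParams",
    "RegionCounts",
    "FitResult",
    "log_betabinom",
    "zoib_logpmf",
    "region_loglik",
    "em_fit",
    "information_blocks",
    "zoib_mean",
    "zoib_mean_grad",
]

# numerical bounds for the beta shapes; estimates are clipped into this box
ALPHA_MIN = 1e-3
ALPHA_MAX = 1e4
_LOG_A_MIN = math.log(ALPHA_MIN)
_LOG_A_MAX = math.log(ALPHA_MAX)

EM_TOL = 1e-8
EM_MAX_ITER = 500


@dataclass(frozen=True)
class ZoibParams:
    """Parameters (pi0, pi1, alpha, beta) of the zero-one inflated beta law."""

    pi0: float
    pi1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.pi0 >= 0.0 and self.pi1 >= 0.0):
            raise ValueError("pi0 and pi1 must be non-negative")
        if self.pi0 + self.pi1 > 1.0 + 1e-12:
            raise ValueError("pi0 + pi1 must not exceed 1")
        if not (self.alpha > 0.0 and self.beta > 0.0):
            raise ValueError("alpha and beta must be positive")

    @property
    def w_beta(self) -> float:
        """Weight of the continuous beta component."""
        return max(0.0, 1.0 - self.pi0 - self.pi1)

    def as_array(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.alpha, self.beta])


@dataclass
class RegionCounts:
    """Per-cell (methylated, total) read counts of one group in one region.

    Cells with zero total coverage carry no likelihood information (their pmf is
    identically 1) and are dropped at construction.
    """

    x: np.ndarray
    n: np.ndarray
    group_id: int = 1
    region_id: object = None
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.int64)
        n = np.asarray(self.n, dtype=np.int64)
        if x.shape != n.shape or x.ndim != 1:
            raise ValueError("x and n must be 1-D arrays of equal length")
        if np.any(x < 0) or np.any(x > n):
            raise ValueError("counts must satisfy 0 <= x <= n")
        keep = n >= 1
        self.x = x[keep]
        self.n = n[keep]
        if self.cell_ids is not None:
            if len(self.cell_ids) != keep.size:
                raise ValueError("cell_ids length mismatch")
            self.cell_ids = [c for c, k in zip(self.cell_ids, keep) if k]

    @property
    def n_cells(self) -> int:
        return int(self.x.size)

    @property
    def total_x(self) -> int:
        return int(self.x.sum())

    @property
    def total_n(self) -> int:
        return int(self.n.sum())


@dataclass
class FitResult:
    """Outcome of fitting the mixture to one group's region counts."""

    params: ZoibParams
    loglik: float
    loglik_trace: np.ndarray
    info_pi: np.ndarray
    info_ab: np.ndarray
    converged: bool
    n_cells: int
    degenerate: bool = False


def log_betabinom(x, n, alpha, beta):
    """Log pmf of the beta-binomial: log[C(n,x) B(x+a, n-x+b) / B(a,b)].

    Vectorised over ``x`` and ``n``; computed through log-gamma differences so
    it stays finite for large counts.  ``log_betabinom(0, 0, a, b) == 0``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    if not (np.all(np.asarray(alpha) > 0) and np.all(np.asarray(beta) > 0)):
        raise ValueError("alpha and beta must be positive")
    out = (
        gammaln(n + 1.0)
        - gammaln(x + 1.0)
        - gammaln(n - x + 1.0)
        + betaln(x + alpha, n - x + beta)
        - betaln(alpha, beta)
    )
    if out.ndim == 0:
        return float(out)
    return out


def zoib_logpmf(x, n, theta: ZoibParams):
    """Log pmf of counts under the zero-one inflated beta-binomial mixture.

    f(x | n) = pi0*1{x=0} + pi1*1{x=n} + (1-pi0-pi1)*BetaBin(x; n, alpha, beta)
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n < 1):
        raise ValueError("zoib_logpmf requires n >= 1")
    lb = log_betabinom(x, n, theta.alpha, theta.beta)
    point = np.where(x == 0, theta.pi0, 0.0) + np.where(x == n, theta.pi1, 0.0)
    w = theta.w_beta
    with np.errstate(divide="ignore"):
        log_point = np.log(point)
        log_cont = (math.log(w) if w > 0 else -np.inf) + lb
    out = np.logaddexp(log_point, log_cont)
    if out.ndim == 0:
        return float(out)
    return out


def region_loglik(counts: RegionCounts, theta: ZoibParams) -> float:
    """Marginal log-likelihood of one group's region counts under ``theta``."""
    if counts.n_cells == 0:
        raise ValueError("region_loglik requires at least one covered cell")
    return float(np.sum(zoib_logpmf(counts.x, counts.n, theta)))


def zoib_mean(theta: ZoibParams) -> float:
    """Expected methylation rate g(theta) = pi1 + (1-pi0-pi1)*alpha/(alpha+beta)."""
    return theta.pi1 + theta.w_beta * theta.alpha / (theta.alpha + theta.beta)


def zoib_mean_grad(theta: ZoibParams) -> np.ndarray:
    """Gradient of g(theta) with respect to (pi0, pi1, alpha, beta)."""
    a, b = theta.alpha, theta.beta
    w = theta.w_beta
    mu = a / (a + b)
    return np.array(
        [
            -mu,
            1.0 - mu,
            w * b / (a + b) ** 2,
            -w * a / (a + b) ** 2,
        ]
    )


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def _default_init(x: np.ndarray, n: np.ndarray) -> tuple[float, float, float, float]:
    # Half the zero/one cell fractions go to the spikes; beta shapes by method
    # of moments on interior empirical rates, falling back to (1, 1).
    f0 = float(np.mean(x == 0))
    f1 = float(np.mean(x == n))
    pi0, pi1 = 0.5 * f0, 0.5 * f1
    a0 = b0 = 1.0
    interior = (x > 0) & (x < n)
    if int(interior.sum()) >= 3:
        r = x[interior] / n[interior]
        m = float(r.mean())
        v = float(r.var(ddof=1))
        if 0.0 < v < m * (1.0 - m):
            k = m * (1.0 - m) / v - 1.0
            a0, b0 = m * k, (1.0 - m) * k
    a0 = min(max(a0, ALPHA_MIN), ALPHA_MAX)
    b0 = min(max(b0, ALPHA_MIN), ALPHA_MAX)
    return pi0, pi1, a0, b0


def _candidate_inits(x: np.ndarray, n: np.ndarray) -> list[tuple]:
    """Deterministic start points for the EM short-run selection."""
    f0 = float(np.mean(x == 0))
    f1 = float(np.mean(x == n))
    default = _default_init(x, n)
    m = float(np.clip(x.sum() / n.sum(), 0.05, 0.95))

    def clip(v):
        return min(max(v, ALPHA_MIN), ALPHA_MAX)

    interior = (x > 0) & (x < n)
    mi = float(np.mean(x[interior] / n[interior])) if interior.any() else m
    mi = float(np.clip(mi, 0.05, 0.95))
    starts = [
        default,
        # spike-light: let the beta component absorb the boundary cells
        (0.02 * f0, 0.02 * f1, default[2], default[3]),
        # spike-heavy with a flat beta
        (0.9 * f0, 0.9 * f1, 1.0, 1.0),
        # concentrated beta at the pooled rate
        (0.25 * f0, 0.25 * f1, clip(20.0 * m), clip(20.0 * (1.0 - m))),
        # spikes take all boundary cells, beta concentrated on interior rates
        (0.95 * f0, 0.95 * f1, clip(20.0 * mi), clip(20.0 * (1.0 - mi))),
    ]
    uniq = []
    for s in starts:
        if not any(np.allclose(s, u) for u in uniq):
            uniq.append(s)
    return uniq


def _grid_seeds(x: np.ndarray, n: np.ndarray, top: int = 2) -> list[tuple]:
    """Best points of a coarse likelihood grid, used as extra EM starts on
    small low-depth groups (their surfaces carry several near-tied maxima)."""
    pis = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
    ab = np.array([0.05, 0.3, 1.0, 3.0, 20.0, 150.0, 1000.0])
    aa, bb = np.meshgrid(ab, ab, indexing="ij")
    aa, bb = aa.ravel(), bb.ravel()
    lb = (
        betaln(x[None, :] + aa[:, None], (n - x)[None, :] + bb[:, None])
        - betaln(aa, bb)[:, None]
    )
    B = np.exp(lb)  # combinatorial factor omitted: constant in theta
    is0 = (x == 0).astype(float)
    is1 = (x == n).astype(float)
    scored = []
    for p0 in pis:
        for p1 in pis:
            if p0 + p1 > 1.0 - 1e-9:
                continue
            f = p0 * is0[None, :] + p1 * is1[None, :] + (1.0 - p0 - p1) * B
            ll = np.log(np.maximum(f, 1e-300)).sum(axis=1)
            k = int(np.argmax(ll))
            scored.append((float(ll[k]), (p0, p1, float(aa[k]), float(bb[k]))))
    scored.sort(key=lambda t: -t[0])
    return [s for _, s in scored[:top]]


def _wq(xs, ns, ws, a, b) -> float:
    """Responsibility-weighted beta-binomial log-likelihood (shape part only)."""
    return float(ws @ (betaln(xs + a, ns - xs + b) - betaln(a, b)))


def _weighted_bb_mle(xs, ns, ws, a, b, max_iter=40, gtol=1e-9):
    """Maximise the weighted beta-binomial log-likelihood over (log a, log b).

    Damped Newton with analytic gradient/Hessian (digamma/trigamma); steps that
    do not improve the objective are halved; a coarse log-grid refinement is the
    fallback when no Newton/gradient step improves.  Never returns a point with
    a lower objective than the input.
    """
    u, v = math.log(a), math.log(b)
    q = _wq(xs, ns, ws, a, b)
    q_in = q
    for _ in range(max_iter):
        a, b = math.exp(u), math.exp(v)
        s_a = psi(xs + a) - psi(ns + a + b) - psi(a) + psi(a + b)
        s_b = psi(ns - xs + b) - psi(ns + a + b) - psi(b) + psi(a + b)
        ga = float(ws @ s_a)
        gb = float(ws @ s_b)
        gu, gv = a * ga, b * gb
        if max(abs(gu), abs(gv)) < gtol * (1.0 + abs(q)):
            break
        t_aa = polygamma(1, xs + a) - polygamma(1, ns + a + b) - polygamma(1, a) + polygamma(1, a + b)
        t_bb = polygamma(1, ns - xs + b) - polygamma(1, ns + a + b) - polygamma(1, b) + polygamma(1, a + b)
        t_ab = -polygamma(1, ns + a + b) + polygamma(1, a + b)
        huu = a * a * float(ws @ t_aa) + gu
        hvv = b * b * float(ws @ t_bb) + gv
        huv = a * b * float(ws @ t_ab)
        det = huu * hvv - huv * huv
        if huu < 0.0 and det > 0.0:
            du = -(hvv * gu - huv * gv) / det
            dv = -(huu * gv - huv * gu) / det
        else:  # Hessian not negative definite: scaled ascent direction
            sc = 1.0 / (1.0 + abs(gu) + abs(gv))
            du, dv = gu * sc, gv * sc
        step = 1.0
        improved = False
        for _ls in range(30):
            u1 = min(max(u + step * du, _LOG_A_MIN), _LOG_A_MAX)
            v1 = min(max(v + step * dv, _LOG_A_MIN), _LOG_A_MAX)
            q1 = _wq(xs, ns, ws, math.exp(u1), math.exp(v1))
            if q1 > q:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        gain = q1 - q
        u, v, q = u1, v1, q1
        if gain < 1e-12 * (abs(q) + 1.0):
            break
    # active-set refinement: with one shape pinned at its bound (gradient
    # pointing outward) the projected 2-D step degrades badly; finish with a
    # 1-D Newton on the free coordinate
    for _pass in range(2):
        a, b = math.exp(u), math.exp(v)
        gu = a * float(ws @ (psi(xs + a) - psi(ns + a + b) - psi(a) + psi(a + b)))
        gv = b * float(ws @ (psi(ns - xs + b) - psi(ns + a + b) - psi(b) + psi(a + b)))
        at_u = (u >= _LOG_A_MAX - 1e-12 and gu > 0) or (u <= _LOG_A_MIN + 1e-12 and gu < 0)
        at_v = (v >= _LOG_A_MAX - 1e-12 and gv > 0) or (v <= _LOG_A_MIN + 1e-12 and gv < 0)
        if at_u == at_v:
            break
        free = "v" if at_u else "u"
        for _ in range(40):
            a, b = math.exp(u), math.exp(v)
            if free == "u":
                g1 = a * float(ws @ (psi(xs + a) - psi(ns + a + b) - psi(a) + psi(a + b)))
                t = polygamma(1, xs + a) - polygamma(1, ns + a + b) - polygamma(1, a) + polygamma(1, a + b)
                h1 = a * a * float(ws @ t) + g1
            else:
                g1 = b * float(ws @ (psi(ns - xs + b) - psi(ns + a + b) - psi(b) + psi(a + b)))
                t = polygamma(1, ns - xs + b) - polygamma(1, ns + a + b) - polygamma(1, b) + polygamma(1, a + b)
                h1 = b * b * float(ws @ t) + g1
            if abs(g1) < gtol * (1.0 + abs(q)):
                break
            d = -g1 / h1 if h1 < 0 else math.copysign(0.5, g1)
            step = 1.0
            moved = False
            for _ls in range(30):
                u1, v1 = (u + step * d, v) if free == "u" else (u, v + step * d)
                u1 = min(max(u1, _LOG_A_MIN), _LOG_A_MAX)
                v1 = min(max(v1, _LOG_A_MIN), _LOG_A_MAX)
                q1 = _wq(xs, ns, ws, math.exp(u1), math.exp(v1))
                if q1 > q:
                    u, v, q = u1, v1, q1
                    moved = True
                    break
                step *= 0.5
            if not moved:
                break
    if q <= q_in + 1e-15:
        # coarse log-grid refinement around the incoming point
        facs = np.exp(np.linspace(-2.0, 2.0, 9))
        best = (q, u, v)
        a0, b0 = math.exp(u), math.exp(v)
        for fa in facs:
            for fb in facs:
                aa = min(max(a0 * fa, ALPHA_MIN), ALPHA_MAX)
                bb = min(max(b0 * fb, ALPHA_MIN), ALPHA_MAX)
                qq = _wq(xs, ns, ws, aa, bb)
                if qq > best[0]:
                    best = (qq, math.log(aa), math.log(bb))
        q, u, v = best
    return math.exp(u), math.exp(v)


def _boundary_fit(counts: RegionCounts, theta: ZoibParams, degenerate: bool) -> FitResult:
    if counts.n_cells > 0:
        ll = region_loglik(counts, theta)
        info_pi, info_ab = information_blocks(theta, counts)
    else:
        ll = 0.0
        info_pi = np.zeros((2, 2))
        info_ab = np.zeros((2, 2))
    return FitResult(
        params=theta,
        loglik=ll,
        loglik_trace=np.array([ll]),
        info_pi=info_pi,
        info_ab=info_ab,
        converged=True,
        n_cells=counts.n_cells,
        degenerate=degenerate,
    )


def em_fit(
    counts: RegionCounts,
    init: ZoibParams | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> FitResult:
    """Fit the zero-one inflated beta-binomial mixture by EM.

    The E-step assigns each cell responsibilities for the zero-spike, one-spike
    and beta components (a spike is only reachable by cells with x = 0, resp.
    x = n).  The M-step sets the spike weights to mean responsibilities and
    updates (alpha, beta) by maximising the responsibility-weighted
    beta-binomial log-likelihood on the log scale.  Iteration stops when the
    relative change of the marginal log-likelihood drops below ``tol``.

    Boundary inputs short-circuit the EM: a group with every cell fully
    unmethylated (resp. methylated) gets the point-mass fit pi0 = 1 (resp.
    pi1 = 1); with at least two covered cells this is an informative fit (the
    downstream Wald test uses its boundary information, so an all-zero versus
    all-one comparison is decisively called).  Fewer than two covered cells
    leaves the group untestable: the fit is flagged ``degenerate=True`` and
    the downstream test reports P = 1.
    """
    x = counts.x.astype(np.float64)
    n = counts.n.astype(np.float64)
    m = x.size
    if m == 0:
        raise ValueError("em_fit requires at least one covered cell")
    if np.all(counts.x == 0):
        return _boundary_fit(counts, ZoibParams(1.0, 0.0, 1.0, 1.0), degenerate=m < 2)
    if np.all(counts.x == counts.n):
        return _boundary_fit(counts, ZoibParams(0.0, 1.0, 1.0, 1.0), degenerate=m < 2)
    if m < 2:
        pbar = counts.total_x / counts.total_n
        a = min(max(2.0 * pbar, ALPHA_MIN), ALPHA_MAX)
        b = min(max(2.0 * (1.0 - pbar), ALPHA_MIN), ALPHA_MAX)
        return _boundary_fit(counts, ZoibParams(0.0, 0.0, a, b), degenerate=True)

    is0 = (counts.x == 0).astype(np.float64)
    is1 = (counts.x == counts.n).astype(np.float64)

    def em_run(state, iters):
        pi0, pi1, a, b = state
        trace: list[float] = []
        ll_prev = -np.inf
        converged = False
        for _it in range(iters):
            lb = (
                gammaln(n + 1.0)
                - gammaln(x + 1.0)
                - gammaln(n - x + 1.0)
                + betaln(x + a, n - x + b)
                - betaln(a, b)
            )
            pb = np.exp(lb)
            w = 1.0 - pi0 - pi1
            f = np.maximum(pi0 * is0 + pi1 * is1 + w * pb, 1e-300)
            ll = float(np.sum(np.log(f)))
            trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
            # E-step
            r0 = pi0 * is0 / f
            r1 = pi1 * is1 / f
            rb = np.clip(1.0 - r0 - r1, 0.0, 1.0)
            # M-step
            pi0 = float(r0.mean())
            pi1 = float(r1.mean())
            if rb.sum() > 1e-10:
                idx = rb > 1e-12
                a, b = _weighted_bb_mle(x[idx], n[idx], rb[idx], a, b)
        return (pi0, pi1, a, b), trace, converged

    if init is not None:
        starts = [(init.pi0, init.pi1, init.alpha, init.beta)]
    else:
        # the likelihood is multimodal on small low-depth groups: burn in a few
        # deterministic starts briefly and continue only the best one
        starts = _candidate_inits(counts.x, counts.n)

    if len(starts) == 1:
        state, trace, converged = em_run(starts[0], max_iter)
    elif x.size < 10 or float(n.mean()) < 8.0:
        # low-depth or tiny groups have genuinely multimodal likelihoods whose
        # basins burn in deceptively slowly: run every start (plus coarse-grid
        # seeds) to convergence
        finished = []
        for s in starts + _grid_seeds(x, n):
            state, trace, converged = em_run(s, max_iter)
            finished.append((trace[-1], state, trace, converged))
        _, state, trace, converged = max(finished, key=lambda t: t[0])
    else:
        # at realistic aggregated depths the surface is effectively unimodal:
        # burn every start in briefly, run the two most promising to
        # convergence and keep the higher likelihood
        burn = 12
        burned = [em_run(s, burn) for s in starts]
        order = sorted(range(len(burned)), key=lambda i: -burned[i][1][-1])
        finished = []
        for i in order[:2]:
            state, trace, converged = burned[i]
            if not converged:
                state, trace2, converged = em_run(state, max_iter - burn)
                trace = trace + trace2
            finished.append((trace[-1], state, trace, converged))
        _, state, trace, converged = max(finished, key=lambda t: t[0])

    # boundary polish: EM shrinks a vanishing spike only geometrically, so a
    # vestigial pi < 0.01 can stall below the maximum; try flushing tiny
    # spikes exactly to zero (they stay zero under EM) and keep the best
    p0_, p1_, a_, b_ = state
    flushes = []
    if 0.0 < p0_ < 0.01:
        flushes.append((0.0, p1_))
    if 0.0 < p1_ < 0.01:
        flushes.append((p0_, 0.0))
    if 0.0 < p0_ < 0.01 and 0.0 < p1_ < 0.01:
        flushes.append((0.0, 0.0))
    for f0_, f1_ in flushes:
        state2, trace2, conv2 = em_run((f0_, f1_, a_, b_), max_iter)
        if trace2[-1] > trace[-1]:
            state, trace, converged = state2, trace2, conv2

    pi0, pi1, a, b = state
    theta = ZoibParams(pi0, pi1, a, b)
    info_pi, info_ab = information_blocks(theta, counts)
    return FitResult(
        params=theta,
        loglik=trace[-1],
        loglik_trace=np.asarray(trace),
        info_pi=info_pi,
        info_ab=info_ab,
        converged=converged,
        n_cells=m,
    )


def information_blocks(theta: ZoibParams, counts: RegionCounts):
    """Observed information of the marginal log-likelihood, block-diagonal form.

    Returns the negative Hessian restricted to the (pi0, pi1) block and to the
    (alpha, beta) block; the cross-blocks are taken to be zero, matching the
    block structure assumed by the downstream Wald variance.  Both blocks are
    exact analytic second derivatives (no finite differencing).
    """
    if counts.n_cells == 0:
        raise ValueError("information_blocks requires at least one covered cell")
    x = counts.x.astype(np.float64)
    n = counts.n.astype(np.float64)
    a, b = theta.alpha, theta.beta
    pi0, pi1 = theta.pi0, theta.pi1
    w = 1.0 - pi0 - pi1
    is0 = (counts.x == 0).astype(np.float64)
    is1 = (counts.x == counts.n).astype(np.float64)
    lb = log_betabinom(x, n, a, b)
    B = np.exp(lb)
    f = np.maximum(pi0 * is0 + pi1 * is1 + w * B, 1e-300)

    # pi block: f is linear in (pi0, pi1), so -H is an outer-product sum
    g0 = (is0 - B) / f
    g1 = (is1 - B) / f
    info_pi = np.array(
        [
            [float(np.sum(g0 * g0)), float(np.sum(g0 * g1))],
            [float(np.sum(g0 * g1)), float(np.sum(g1 * g1))],
        ]
    )

    # (alpha, beta) block via first/second derivatives of the beta-binomial pmf
    s_a = psi(x + a) - psi(n + a + b) - psi(a) + psi(a + b)
    s_b = psi(n - x + b) - psi(n + a + b) - psi(b) + psi(a + b)
    t_aa = polygamma(1, x + a) - polygamma(1, n + a + b) - polygamma(1, a) + polygamma(1, a + b)
    t_bb = polygamma(1, n - x + b) - polygamma(1, n + a + b) - polygamma(1, b) + polygamma(1, a + b)
    t_ab = -polygamma(1, n + a + b) + polygamma(1, a + b)
    fa = w * B * s_a
    fb = w * B * s_b
    faa = w * B * (s_a * s_a + t_aa)
    fbb = w * B * (s_b * s_b + t_bb)
    fab = w * B * (s_a * s_b + t_ab)
    h_aa = float(np.sum((faa * f - fa * fa) / (f * f)))
    h_bb = float(np.sum((fbb * f - fb * fb) / (f * f)))
    h_ab = float(np.sum((fab * f - fa * fb) / (f * f)))
    info_ab = -np.array([[h_aa, h_ab], [h_ab, h_bb]])
    return info_pi, info_ab
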