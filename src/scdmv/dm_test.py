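"""Two-group test of equal mean methylation and DMR calling.

For each region the mixture is fitted separately to the two cell groups; the
null hypothesis of equal expected methylation rate g(theta1) = g(theta2) is
tested with a delta-method Wald statistic

    T = (g(theta1_hat) - g(theta2_hat)) / sqrt(v1 + v2),

where v_g combines the (pi0, pi1) and (alpha, beta) blocks of the inverse
observed information with the corresponding blocks of the gradient of g.
Under the null, T is asymptotically standard normal.  A region is called a DMR
when its two-sided P-value falls at or below the P cutoff AND the absolute
difference of the groups' weighted methylation levels (Delta) reaches the
Delta cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model_core import (
    FitResult,
    RegionCounts,
    em_fit,
    zoib_mean,
    zoib_mean_grad,
)

__all__ = [
    "RegionTestResult",
    "wald_statistic",
    "wald_pvalue",
    "weighted_level",
    "test_region",
    "call_dmrs",
    "bh_adjust",
]


@dataclass
class RegionTestResult:
    region_id: object
    chrom: str | None
    start: int | None
    end: int | None
    n_sites: int | None
    fit1: FitResult | None
    fit2: FitResult | None
    T: float
    p_value: float
    m1: float
    m2: float
    delta_signed: float
    delta: float
    n_cells1: int
    n_cells2: int


def _delta_method_variance(fit: FitResult) -> float:
    """Blockwise delta-method variance of g(theta_hat) for one group."""
    grad = zoib_mean_grad(fit.params)
    g_pi, g_ab = grad[:2], grad[2:]
    try:
        v = float(
            g_pi @ np.linalg.pinv(fit.info_pi) @ g_pi
            + g_ab @ np.linalg.pinv(fit.info_ab) @ g_ab
        )
    except np.linalg.LinAlgError:
        return np.nan
    return v


def wald_statistic(fit1: FitResult, fit2: FitResult) -> float:
    """Delta-method Wald statistic for H0: g(theta1) = g(theta2).

    Returns NaN to signal degeneracy (boundary fits, or a non-positive /
    non-finite variance); callers map that to P = 1.
    """
    if fit1.degenerate or fit2.degenerate:
        return float("nan")
    v = _delta_method_variance(fit1) + _delta_method_variance(fit2)
    if not np.isfinite(v) or v <= 0.0:
        return float("nan")
    return float((zoib_mean(fit1.params) - zoib_mean(fit2.params)) / np.sqrt(v))


def wald_pvalue(T: float) -> float:
    """Two-sided standard-normal tail probability 2*(1 - Phi(|T|))."""
    if not np.isfinite(T):
        raise ValueError("wald_pvalue requires a finite statistic")
    return float(2.0 * norm.sf(abs(T)))


def weighted_level(counts: RegionCounts) -> float:
    """Weighted methylation level: pooled reads sum(x)/sum(n) of the group."""
    if counts.total_n == 0:
        raise ValueError("weighted_level requires positive total coverage")
    return counts.total_x / counts.total_n


def test_region(
    counts1: RegionCounts,
    counts2: RegionCounts,
    *,
    region_id: object = None,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    n_sites: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> RegionTestResult:
    """Fit both groups, compute the Wald test and the weighted-level Delta.

    Degenerate groups (all-zero, all-one, or <2 covered cells) yield P = 1;
    Delta is still reported from the raw pooled counts when coverage permits.
    """
    if region_id is None:
        region_id = counts1.region_id if counts1.region_id is not None else counts2.region_id
    fit1 = em_fit(counts1, tol=tol, max_iter=max_iter) if counts1.n_cells else None
    fit2 = em_fit(counts2, tol=tol, max_iter=max_iter) if counts2.n_cells else None

    m1 = weighted_level(counts1) if counts1.total_n > 0 else float("nan")
    m2 = weighted_level(counts2) if counts2.total_n > 0 else float("nan")
    delta_signed = m1 - m2
    delta = abs(delta_signed)

    if fit1 is None or fit2 is None:
        T = float("nan")
    else:
        T = wald_statistic(fit1, fit2)
    p_value = 1.0 if not np.isfinite(T) else wald_pvalue(T)

    return RegionTestResult(
        region_id=region_id,
        chrom=chrom,
        start=start,
        end=end,
        n_sites=n_sites,
        fit1=fit1,
        fit2=fit2,
        T=T,
        p_value=p_value,
        m1=m1,
        m2=m2,
        delta_signed=delta_signed,
        delta=delta,
        n_cells1=counts1.n_cells,
        n_cells2=counts2.n_cells,
    )


def test_bundle(bundle, tol: float = 1e-8, max_iter: int = 500) -> list[RegionTestResult]:
    """Run test_region over every record of a region bundle, in order."""
    results = []
    for rec in bundle:
        results.append(
            test_region(
                rec.counts1,
                rec.counts2,
                region_id=rec.region_id,
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                n_sites=rec.n_sites,
                tol=tol,
                max_iter=max_iter,
            )
        )
    return results


def is_called(result: RegionTestResult, p_cutoff: float, delta_cutoff: float) -> bool:
    """Joint DMR predicate: P <= p_cutoff and Delta >= delta_cutoff (inclusive)."""
    return bool(result.p_value <= p_cutoff and result.delta >= delta_cutoff)


def call_dmrs(results, p_cutoff: float, delta_cutoff: float):
    """Return, in input order, the results passing the joint P/Delta predicate."""
    if not (0.0 <= p_cutoff <= 1.0 and 0.0 <= delta_cutoff <= 1.0):
        raise ValueError("cutoffs must lie in [0, 1]")
    return [r for r in results if is_called(r, p_cutoff, delta_cutoff)]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (informational column;
    DMR calling itself uses raw P)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
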