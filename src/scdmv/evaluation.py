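"""Evaluation metrics for DMR callers on labelled (simulated or split) data.

Difference experiments treat every region as a true DMR; indifference
experiments treat every call as a false positive.  Sensitivity, precision, FPR
and FDR are computed from the confusion counts at each (P, Delta) cutoff pair;
the default grids match the evaluation protocol:
P in {0.001, 0.005, 0.01, 0.05} and Delta in {0, 0.1, 0.15, 0.2}.

For real data without ground truth, the split-half design compares a
between-group run (calls assumed true) with a within-group run on one group
split into random halves (calls assumed false), giving the precision
P' = TP' / (TP' + FP').
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dm_test import is_called

__all__ = [
    "P_CUTOFFS",
    "DELTA_CUTOFFS",
    "ConfusionCounts",
    "Metrics",
    "confusion_counts",
    "metrics",
    "fdr_sensitivity_curve",
    "split_precision",
    "split_half",
]

P_CUTOFFS = (0.001, 0.005, 0.01, 0.05)
DELTA_CUTOFFS = (0.0, 0.1, 0.15, 0.2)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    precision: float
    fpr: float
    fdr: float


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_counts(results, truth, p_cutoff: float, delta_cutoff: float) -> ConfusionCounts:
    """Classify each region by the joint call predicate against its truth label.

    ``truth`` maps region_id -> "difference" | "indifference" (a SimTruth's
    ``as_dict`` or any mapping); region ids missing from it raise.
    """
    if hasattr(truth, "as_dict"):
        truth = truth.as_dict()
    tp = fp = tn = fn = 0
    for r in results:
        try:
            label = truth[r.region_id]
        except KeyError:
            raise ValueError(f"region {r.region_id!r} missing from truth") from None
        called = is_called(r, p_cutoff, delta_cutoff)
        if label == "difference":
            if called:
                tp += 1
            else:
                fn += 1
        elif label == "indifference":
            if called:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unknown truth label {label!r}")
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, precision, FPR and FDR; 0/0 yields NaN, not an exception."""
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    return Metrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        precision=precision,
        fpr=_ratio(counts.fp, counts.fp + counts.tn),
        fdr=1.0 - precision if np.isfinite(precision) else float("nan"),
    )


def fdr_sensitivity_curve(
    results_diff,
    results_indiff,
    p_cutoffs=P_CUTOFFS,
    delta_cutoffs=DELTA_CUTOFFS,
) -> pd.DataFrame:
    """One row per cutoff pair: confusion counts and metrics for the paired
    difference/indifference experiments (difference regions are the positives)."""
    rows = []
    n_diff = len(results_diff)
    n_ind = len(results_indiff)
    for pc in p_cutoffs:
        for dc in delta_cutoffs:
            tp = sum(is_called(r, pc, dc) for r in results_diff)
            fp = sum(is_called(r, pc, dc) for r in results_indiff)
            cc = ConfusionCounts(tp, fp, n_ind - fp, n_diff - tp)
            m = metrics(cc)
            rows.append(
                {
                    "p_cutoff": pc,
                    "delta_cutoff": dc,
                    "tp": cc.tp,
                    "fp": cc.fp,
                    "tn": cc.tn,
                    "fn": cc.fn,
                    "sensitivity": m.sensitivity,
                    "precision": m.precision,
                    "fpr": m.fpr,
                    "fdr": m.fdr,
                }
            )
    return pd.DataFrame(rows)


def split_precision(calls_between: int, calls_within: int) -> float:
    """Real-data precision P' = TP'/(TP'+FP'): between-group calls are assumed
    true, within-group (split-half) calls assumed false; 0/0 gives NaN."""
    if calls_between < 0 or calls_within < 0:
        raise ValueError("call counts must be non-negative")
    return _ratio(calls_between, calls_between + calls_within)


def paired_simulation_study(seed: int, n_regions: int = 1000, config=None):
    """Run one matched difference/indifference experiment pair.

    Simulates a difference experiment and its null twin (both groups from
    theta1) with the given seed, tests every region, and returns
    (results_diff, results_indiff, bundle_diff).
    """
    import dataclasses

    from .dm_test import test_bundle
    from .simulator import SimConfig, simulate_experiment

    if config is None:
        config = SimConfig()
    config = dataclasses.replace(config, n_regions=n_regions, seed=seed)
    bundle_diff, _ = simulate_experiment(config)
    # distinct stream for the null twin so the two experiments are independent
    bundle_ind, _ = simulate_experiment(
        dataclasses.replace(config.as_indifference(), seed=config.seed + 500_000_000)
    )
    return test_bundle(bundle_diff), test_bundle(bundle_ind), bundle_diff


def split_half(cell_ids, rng: np.random.Generator):
    """Seeded random equal partition of an even-sized cell set into two halves."""
    cells = list(cell_ids)
    if len(cells) % 2 != 0:
        raise ValueError("split_half requires an even number of cells")
    perm = rng.permutation(len(cells))
    half = len(cells) // 2
    g1 = [cells[i] for i in perm[:half]]
    g2 = [cells[i] for i in perm[half:]]
    return g1, g2
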