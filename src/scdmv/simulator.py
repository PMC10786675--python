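"""Model-faithful synthetic scBS-seq data generator.

The generator emulates the structure of the study design the package targets:
two cell groups of 48 and 25 cells, 1000 regions of 10 consecutive CpG sites,
per-site read depths resampled from an empirical low-coverage pool, and
per-cell methylation fractions drawn from the zero-one inflated beta law.
One fraction p is drawn per (cell, region) and shared by the region's sites,
so region-level aggregation of a cell's counts stays exactly binomial given p.

Two experiment kinds mirror the evaluation protocol: *difference* experiments
draw the groups from distinct parameter vectors (every region is a true DMR);
*indifference* experiments draw both groups from the group-1 law (every call
is a false positive).

Default parameters
------------------
The defaults were calibrated, then frozen, so that the synthetic data matches
the headline features of real low-input scBS-seq comparisons: the fraction of
per-site per-cell methylation rates exactly 0 or 1 is ~0.66 (driven by 1-3x
site depth plus the spiky group-2 law), and the groups' expected methylation
rates differ by 0.25.  Group 1 (48 cells) uses a concentrated law —
within-group methylation of cells at the same developmental stage is stable,
which is what makes within-group (null) comparisons nearly call-free — while
group 2 (25 cells) is strongly zero-one inflated and over-dispersed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .model_core import RegionCounts, ZoibParams
from .segmentation import RegionBundle, RegionRecord

__all__ = [
    "DEFAULT_THETA1",
    "DEFAULT_THETA2",
    "DEFAULT_DEPTH_POOL",
    "SimConfig",
    "SimTruth",
    "sample_depths",
    "simulate_region",
    "simulate_experiment",
]

DEFAULT_THETA1 = ZoibParams(pi0=0.015, pi1=0.015, alpha=50.0, beta=50.0)
DEFAULT_THETA2 = ZoibParams(pi0=0.40, pi1=0.10, alpha=0.9, beta=2.1)


def _default_pool() -> np.ndarray:
    # empirical-style depth pool: geometric decay over 1..30 reads,
    # mean ~3.2 reads/site (scBS-seq sites are mostly covered 1-3x)
    d = np.arange(1, 31)
    mult = np.maximum(1, np.round(200 * 0.62 ** (d - 1))).astype(int)
    return np.repeat(d, mult)


DEFAULT_DEPTH_POOL = _default_pool()

_SIM_CHROM = "simchr"
_REGION_STRIDE = 1000  # bp between region starts; keeps regions well separated
_SITE_STEP = 30  # bp between sites; 10 sites span 271 bp <= 300


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one synthetic experiment."""

    n_cells_group1: int = 48
    n_cells_group2: int = 25
    n_regions: int = 1000
    sites_per_region: int = 10
    theta1: ZoibParams = DEFAULT_THETA1
    theta2: ZoibParams = DEFAULT_THETA2
    depth_source: object = "empirical"  # "empirical", "poisson:<mean>", or a pool array
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells_group1", "n_cells_group2", "sites_per_region"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_regions < 0:
            raise ValueError("n_regions must be non-negative")

    @property
    def is_indifference(self) -> bool:
        return self.theta1 == self.theta2

    def as_indifference(self) -> "SimConfig":
        """The matched null experiment: both groups drawn from theta1."""
        return replace(self, theta2=self.theta1)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("n_cells_group1", "n_cells_group2", "n_regions", "sites_per_region", "n_replicates", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("theta1", "theta2"):
            if key in raw:
                v = raw[key]
                kwargs[key] = ZoibParams(float(v["pi0"]), float(v["pi1"]), float(v["alpha"]), float(v["beta"]))
        if "depth_source" in raw:
            kwargs["depth_source"] = raw["depth_source"]
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Per-region ground truth labels with the generating parameters."""

    region_ids: list
    labels: list  # "difference" | "indifference"
    theta1: ZoibParams
    theta2: ZoibParams

    def as_dict(self) -> dict:
        return dict(zip(self.region_ids, self.labels))


def sample_depths(source, size, rng: np.random.Generator) -> np.ndarray:
    """Draw strictly positive integer read depths.

    ``source`` is "empirical" (packaged pool), an explicit pool array resampled
    with replacement, or "poisson:<mean>" giving 1 + Poisson(mean - 1).
    """
    if isinstance(source, str):
        if source == "empirical":
            pool = DEFAULT_DEPTH_POOL
        elif source.startswith("poisson:"):
            mean = float(source.split(":", 1)[1])
            if mean < 1.0:
                raise ValueError("poisson depth mean must be >= 1")
            return 1 + rng.poisson(mean - 1.0, size=size)
        else:
            raise ValueError(f"unknown depth source {source!r}")
    else:
        pool = np.asarray(source)
        if pool.size == 0:
            raise ValueError("empirical depth pool is empty")
        if np.any(pool <= 0):
            raise ValueError("depth pool must be strictly positive")
    return rng.choice(pool, size=size, replace=True)


def simulate_region(
    theta: ZoibParams,
    n_cells: int,
    sites_per_region: int,
    depth_source,
    rng: np.random.Generator,
):
    """Site-level (x, n) block of one group in one region.

    Per cell: a mixture component is drawn with probabilities (pi0, pi1,
    1-pi0-pi1) giving p = 0, 1, or a Beta(alpha, beta) draw; p is shared by all
    the region's sites.  Per site: n from the depth source, x ~ Binomial(n, p).
    Returns (x, n) with shape (sites_per_region, n_cells).
    """
    comp = rng.choice(3, size=n_cells, p=[theta.pi0, theta.pi1, theta.w_beta])
    p = np.where(comp == 0, 0.0, np.where(comp == 1, 1.0, 0.5))
    in_beta = comp == 2
    if in_beta.any():
        p[in_beta] = rng.beta(theta.alpha, theta.beta, size=int(in_beta.sum()))
    n = sample_depths(depth_source, (sites_per_region, n_cells), rng)
    x = rng.binomial(n, p[None, :])
    return x, n


def _region_rng(seed: int, region_index: int) -> np.random.Generator:
    # child stream k is invariant to n_regions: spawn_key pins the lineage
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(region_index,)))


def simulate_experiment(config: SimConfig):
    """Generate a full experiment: (RegionBundle, SimTruth).

    Region k is reproducible from (seed, k) alone, so datasets with the same
    seed are identical and region k does not depend on n_regions.  The bundle
    records keep their site-level blocks, so the dataset can be exported to
    per-cell TSV files and re-segmented for end-to-end runs.
    """
    label = "indifference" if config.is_indifference else "difference"
    cell_ids = [f"g1c{i:03d}" for i in range(config.n_cells_group1)] + [
        f"g2c{i:03d}" for i in range(config.n_cells_group2)
    ]
    groups = np.array([1] * config.n_cells_group1 + [2] * config.n_cells_group2)
    bundle = RegionBundle()
    region_ids = []
    for j in range(config.n_regions):
        rng = _region_rng(config.seed, j)
        x1, n1 = simulate_region(
            config.theta1, config.n_cells_group1, config.sites_per_region, config.depth_source, rng
        )
        x2, n2 = simulate_region(
            config.theta2, config.n_cells_group2, config.sites_per_region, config.depth_source, rng
        )
        start = 1 + j * _REGION_STRIDE
        positions = start + _SITE_STEP * np.arange(config.sites_per_region)
        region_id = f"{_SIM_CHROM}:{positions[0]}-{positions[-1]}"
        x = np.hstack([x1, x2])
        n = np.hstack([n1, n2])
        c1 = RegionCounts(
            x1.sum(0), n1.sum(0), group_id=1, region_id=region_id,
            cell_ids=cell_ids[: config.n_cells_group1],
        )
        c2 = RegionCounts(
            x2.sum(0), n2.sum(0), group_id=2, region_id=region_id,
            cell_ids=cell_ids[config.n_cells_group1:],
        )
        bundle.records.append(
            RegionRecord(
                region_id=region_id,
                chrom=_SIM_CHROM,
                start=int(positions[0]),
                end=int(positions[-1]),
                n_sites=config.sites_per_region,
                counts1=c1,
                counts2=c2,
                site_positions=positions,
                site_x=x,
                site_n=n,
                cell_ids=cell_ids,
                groups=groups,
            )
        )
        region_ids.append(region_id)
    truth = SimTruth(
        region_ids=region_ids,
        labels=[label] * config.n_regions,
        theta1=config.theta1,
        theta2=config.theta2,
    )
    return bundle, truth


def zero_one_rate_fraction(bundle: RegionBundle) -> float:
    """Fraction of per-site per-cell methylation rates x/n exactly 0 or 1,
    among covered (n > 0) observations — the zero/one inflation of the data."""
    boundary = 0
    covered = 0
    for rec in bundle:
        if rec.site_x is None:
            raise ValueError("bundle lacks site-level blocks")
        m = rec.site_n > 0
        x, n = rec.site_x[m], rec.site_n[m]
        covered += int(m.sum())
        boundary += int(np.sum((x == 0) | (x == n)))
    if covered == 0:
        raise ValueError("no covered observations")
    return boundary / covered
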