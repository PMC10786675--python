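"""Site filtering, region segmentation and per-region count aggregation.

Raw scBS-seq count matrices are filtered (sites uncovered in more than half of
the cells are dropped), then each chromosome is scanned left to right and cut
into disjoint regions spanning at most 300 bp and containing at least 3 CpG
sites.  Within a region, each cell's site-level counts are summed: sites of one
cell share the cell's methylation fraction, so the sum stays binomial given it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import RegionCounts

__all__ = [
    "SiteCountMatrix",
    "Region",
    "RegionRecord",
    "RegionBundle",
    "filter_sites",
    "build_regions",
    "aggregate_region_counts",
    "bundle_from_matrix",
]

MAX_SPAN_BP = 300
MIN_SITES = 3


@dataclass
class SiteCountMatrix:
    """Per-site, per-cell methylation counts with genomic positions.

    ``chrom`` is one label per site; sites must be grouped by chromosome with
    strictly increasing positions inside each chromosome.  ``x`` and ``n`` are
    (sites x cells) arrays; absent (cell, site) observations carry n = 0.
    """

    chrom: np.ndarray
    positions: np.ndarray
    x: np.ndarray
    n: np.ndarray
    cell_ids: list
    group_of_cell: dict

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        s = self.positions.size
        if not (self.chrom.size == s and self.x.shape == (s, len(self.cell_ids)) == self.n.shape):
            raise ValueError("inconsistent matrix shapes")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("counts must satisfy 0 <= x <= n")
        for c in np.unique(self.chrom):
            pos = self.positions[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        missing = set(self.cell_ids) - set(self.group_of_cell)
        if missing:
            raise ValueError(f"cells without group label: {sorted(missing)}")
        groups = {self.group_of_cell[c] for c in self.cell_ids}
        if not groups <= {1, 2}:
            raise ValueError("group labels must be 1 or 2")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def group_columns(self, group: int) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.cell_ids) if self.group_of_cell[c] == group])

    def subset_sites(self, keep: np.ndarray) -> "SiteCountMatrix":
        return SiteCountMatrix(
            chrom=self.chrom[keep],
            positions=self.positions[keep],
            x=self.x[keep],
            n=self.n[keep],
            cell_ids=list(self.cell_ids),
            group_of_cell=dict(self.group_of_cell),
        )


@dataclass
class Region:
    """A segmented genomic interval; start/end are first/last site positions."""

    chrom: str
    start: int
    end: int
    site_indices: np.ndarray

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        if self.end < self.start or self.site_indices.size == 0:
            raise ValueError("invalid region")

    @property
    def n_sites(self) -> int:
        return int(self.site_indices.size)

    @property
    def span(self) -> int:
        return int(self.end - self.start + 1)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RegionRecord:
    """One testable region: metadata plus the two groups' aggregated counts."""

    region_id: object
    chrom: str
    start: int
    end: int
    n_sites: int
    counts1: RegionCounts
    counts2: RegionCounts
    # site-level blocks are kept when produced by the simulator (for export)
    site_positions: np.ndarray | None = None
    site_x: np.ndarray | None = None
    site_n: np.ndarray | None = None
    cell_ids: list | None = None
    groups: np.ndarray | None = None


@dataclass
class RegionBundle:
    """Ordered collection of RegionRecord, the unit consumed by the tester."""

    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def filter_sites(matrix: SiteCountMatrix, max_missing_frac: float = 0.5) -> SiteCountMatrix:
    """Drop sites whose zero-coverage fraction over all cells strictly exceeds
    ``max_missing_frac`` (both groups pooled); order of survivors preserved."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    missing_frac = (matrix.n == 0).mean(axis=1)
    return matrix.subset_sites(missing_frac <= max_missing_frac)


def build_regions(
    matrix: SiteCountMatrix,
    max_span: int = MAX_SPAN_BP,
    min_sites: int = MIN_SITES,
) -> list[Region]:
    """Greedy left-to-right segmentation per chromosome.

    A region opens at the first unassigned site and extends while the 1-based
    inclusive span (next_pos - first_pos + 1) stays within ``max_span``; closed
    fragments with fewer than ``min_sites`` sites are discarded.
    """
    regions: list[Region] = []
    # preserve first-appearance chromosome order
    seen: dict = {}
    for c in matrix.chrom:
        seen.setdefault(c, None)
    for c in seen:
        idx = np.flatnonzero(matrix.chrom == c)
        pos = matrix.positions[idx]
        cur: list[int] = []
        start_pos = None
        for k, p in zip(idx, pos):
            if not cur:
                cur = [k]
                start_pos = p
                continue
            if p - start_pos + 1 <= max_span:
                cur.append(k)
            else:
                if len(cur) >= min_sites:
                    regions.append(
                        Region(c, int(matrix.positions[cur[0]]), int(matrix.positions[cur[-1]]), np.array(cur))
                    )
                cur = [k]
                start_pos = p
        if len(cur) >= min_sites:
            regions.append(
                Region(c, int(matrix.positions[cur[0]]), int(matrix.positions[cur[-1]]), np.array(cur))
            )
    return regions


def aggregate_region_counts(matrix: SiteCountMatrix, region: Region):
    """Sum each cell's site counts over the region and split by group.

    Cells with zero summed coverage are dropped (RegionCounts construction).
    Returns the (group 1, group 2) pair of RegionCounts.
    """
    xs = matrix.x[region.site_indices].sum(axis=0)
    ns = matrix.n[region.site_indices].sum(axis=0)
    out = []
    for g in (1, 2):
        cols = matrix.group_columns(g)
        if cols.size:
            rc = RegionCounts(
                x=xs[cols],
                n=ns[cols],
                group_id=g,
                region_id=region.region_id,
                cell_ids=[matrix.cell_ids[i] for i in cols],
            )
        else:
            rc = RegionCounts(x=np.array([], dtype=int), n=np.array([], dtype=int), group_id=g, region_id=region.region_id)
        out.append(rc)
    return tuple(out)


def bundle_from_matrix(
    matrix: SiteCountMatrix,
    max_span: int = MAX_SPAN_BP,
    min_sites: int = MIN_SITES,
    max_missing_frac: float = 0.5,
) -> RegionBundle:
    """Filter sites, segment, aggregate: matrix -> testable region bundle."""
    filtered = filter_sites(matrix, max_missing_frac)
    bundle = RegionBundle()
    for region in build_regions(filtered, max_span=max_span, min_sites=min_sites):
        c1, c2 = aggregate_region_counts(filtered, region)
        bundle.records.append(
            RegionRecord(
                region_id=region.region_id,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                n_sites=region.n_sites,
                counts1=c1,
                counts2=c2,
            )
        )
    return bundle
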