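"""Readers and writers: coverage files, sample sheets, region bundles, DMR tables.

Supported per-cell count inputs are the Bismark coverage format
(chrom, start, end, methylation %, count methylated, count unmethylated; tab
separated, optionally gzipped) and a minimal ``xn_tsv`` dialect
(chrom, pos, x, n).  Internal coordinates are 1-based inclusive; BED export is
0-based half-open.
"""
from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dm_test import RegionTestResult, bh_adjust, is_called
from .model_core import RegionCounts
from .segmentation import RegionBundle, RegionRecord, SiteCountMatrix
from .simulator import SimTruth

__all__ = [
    "SampleSheet",
    "read_coverage_file",
    "read_sample_sheet",
    "assemble_matrix",
    "write_xn_tsv",
    "results_to_frame",
    "write_dmr_outputs",
    "write_region_bundle",
    "read_region_bundle",
    "write_truth",
    "read_truth",
    "export_bundle_tsv",
]

DMR_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "n_sites",
    "n_cells1",
    "n_cells2",
    "m1",
    "m2",
    "delta_signed",
    "delta_abs",
    "T",
    "p_value",
    "p_bh",
    "is_dmr",
]


@dataclass
class SampleSheet:
    """Cell-to-file-to-group assignment; CSV with header cell_id,path,group."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "path", "group"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if self.frame["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in sample sheet")
        groups = set(self.frame["group"].astype(int))
        if groups != {1, 2}:
            raise ValueError("sample sheet must contain exactly the two groups 1 and 2")

    def __len__(self) -> int:
        return len(self.frame)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path)
    frame["group"] = frame["group"].astype(int)
    return SampleSheet(frame)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_dialect(path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                ncol = len(line.rstrip("\n").split("\t"))
                if ncol == 6:
                    return "bismark_cov"
                if ncol == 4:
                    return "xn_tsv"
                raise ValueError(f"{path}: cannot sniff dialect from {ncol} columns")
    raise ValueError(f"{path}: empty file")


def read_coverage_file(path, dialect: str | None = None) -> pd.DataFrame:
    """Parse one cell's counts into a (chrom, pos, x, n) frame.

    Bismark rows map to pos=start (1-based), x=count_meth,
    n=count_meth+count_unmeth; a methylation percentage disagreeing with the
    counts by more than 0.5 points triggers a warning.  Malformed rows raise
    with their line number.
    """
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in ("bismark_cov", "xn_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    chroms, poss, xs, ns = [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                if dialect == "bismark_cov":
                    if len(fields) != 6:
                        raise ValueError("expected 6 columns")
                    chrom, start, _end, pct, cm, cu = fields
                    x, u = int(cm), int(cu)
                    n = x + u
                    pos = int(start)
                    if n > 0 and abs(float(pct) - 100.0 * x / n) > 0.5:
                        warnings.warn(
                            f"{path}:{lineno}: methylation % {pct} disagrees with counts {x}/{n}"
                        )
                else:
                    if len(fields) != 4:
                        raise ValueError("expected 4 columns")
                    chrom, pos_s, x_s, n_s = fields
                    pos, x, n = int(pos_s), int(x_s), int(n_s)
                if x < 0 or n < 0 or x > n:
                    raise ValueError(f"invalid counts x={x} n={n}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            chroms.append(chrom)
            poss.append(pos)
            xs.append(x)
            ns.append(n)
    return pd.DataFrame({"chrom": chroms, "pos": poss, "x": xs, "n": ns})


def write_xn_tsv(records: pd.DataFrame, path) -> None:
    records[["chrom", "pos", "x", "n"]].to_csv(path, sep="\t", header=False, index=False)


def assemble_matrix(sheet: SampleSheet) -> SiteCountMatrix:
    """Outer-join all cells' records on (chrom, pos) into a SiteCountMatrix.

    Absent (cell, site) entries get x = n = 0; duplicate positions within one
    cell raise.
    """
    frames = []
    for row in sheet.frame.itertuples(index=False):
        rec = read_coverage_file(row.path)
        if rec.duplicated(subset=["chrom", "pos"]).any():
            dup = rec[rec.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValueError(f"{row.path}: duplicate site {dup.chrom}:{dup.pos}")
        rec = rec.assign(cell_id=row.cell_id)
        frames.append(rec)
    allrec = pd.concat(frames, ignore_index=True)
    cell_ids = list(sheet.frame["cell_id"])
    x = allrec.pivot(index=["chrom", "pos"], columns="cell_id", values="x").reindex(columns=cell_ids)
    n = allrec.pivot(index=["chrom", "pos"], columns="cell_id", values="n").reindex(columns=cell_ids)
    x = x.fillna(0).astype(np.int64).sort_index()
    n = n.fillna(0).astype(np.int64).sort_index()
    chrom = np.array([c for c, _ in x.index], dtype=object)
    positions = np.array([p for _, p in x.index], dtype=np.int64)
    group_of_cell = dict(zip(sheet.frame["cell_id"], sheet.frame["group"].astype(int)))
    return SiteCountMatrix(
        chrom=chrom,
        positions=positions,
        x=x.to_numpy(),
        n=n.to_numpy(),
        cell_ids=cell_ids,
        group_of_cell=group_of_cell,
    )


def results_to_frame(results, p_cutoff: float, delta_cutoff: float) -> pd.DataFrame:
    """Tabulate RegionTestResult rows; p_bh is informational (calls use raw P)."""
    rows = []
    for r in results:
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_sites": r.n_sites,
                "n_cells1": r.n_cells1,
                "n_cells2": r.n_cells2,
                "m1": r.m1,
                "m2": r.m2,
                "delta_signed": r.delta_signed,
                "delta_abs": r.delta,
                "T": r.T,
                "p_value": r.p_value,
            }
        )
    frame = pd.DataFrame(rows, columns=[c for c in DMR_COLUMNS if c not in ("p_bh", "is_dmr")])
    if len(frame):
        frame["p_bh"] = bh_adjust(frame["p_value"].to_numpy())
        frame["is_dmr"] = [is_called(r, p_cutoff, delta_cutoff) for r in results]
    else:
        frame["p_bh"] = []
        frame["is_dmr"] = []
    return frame[DMR_COLUMNS]


def _bed_score(p: float) -> int:
    if p <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p))))


def write_dmr_outputs(results, p_cutoff: float, delta_cutoff: float, out_prefix) -> dict:
    """Write the full TSV table and a BED6 of called DMRs.

    BED uses 0-based half-open coordinates (start-1, end), name=region_id and
    score=min(1000, round(-10*log10(p))).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results, p_cutoff, delta_cutoff)
    tsv_path = Path(f"{out_prefix}.dmr.tsv")
    frame.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    bed_path = Path(f"{out_prefix}.dmr.bed")
    with open(bed_path, "w") as fh:
        for r in results:
            if is_called(r, p_cutoff, delta_cutoff):
                fh.write(
                    f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t{_bed_score(r.p_value)}\t.\n"
                )
    return {"tsv": tsv_path, "bed": bed_path}


# ---------------------------------------------------------------------------
# Region bundle serialization: a region index plus one counts table per
# chromosome (columns region_id, cell_id, group, x, n)
# ---------------------------------------------------------------------------


def write_region_bundle(bundle: RegionBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    per_chrom: dict[str, list] = {}
    for rec in bundle:
        index_rows.append(
            {
                "region_id": rec.region_id,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "n_sites": rec.n_sites,
            }
        )
        rows = per_chrom.setdefault(rec.chrom, [])
        for rc in (rec.counts1, rec.counts2):
            cells = rc.cell_ids if rc.cell_ids is not None else [f"cell{i}" for i in range(rc.n_cells)]
            for cell, x, n in zip(cells, rc.x, rc.n):
                rows.append((rec.region_id, cell, rc.group_id, int(x), int(n)))
    pd.DataFrame(index_rows).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    for chrom, rows in per_chrom.items():
        pd.DataFrame(rows, columns=["region_id", "cell_id", "group", "x", "n"]).to_csv(
            outdir / f"counts_{chrom}.tsv", sep="\t", index=False
        )
    return outdir


def read_region_bundle(indir) -> RegionBundle:
    indir = Path(indir)
    index = pd.read_csv(indir / "regions.tsv", sep="\t")
    counts = []
    for f in sorted(indir.glob("counts_*.tsv")):
        counts.append(pd.read_csv(f, sep="\t"))
    if counts:
        counts = pd.concat(counts, ignore_index=True)
        by_region = dict(tuple(counts.groupby("region_id", sort=False)))
    else:
        by_region = {}
    bundle = RegionBundle()
    for row in index.itertuples(index=False):
        sub = by_region.get(row.region_id)
        rcs = {}
        for g in (1, 2):
            if sub is not None:
                gsub = sub[sub["group"] == g]
                rcs[g] = RegionCounts(
                    x=gsub["x"].to_numpy(),
                    n=gsub["n"].to_numpy(),
                    group_id=g,
                    region_id=row.region_id,
                    cell_ids=list(gsub["cell_id"]),
                )
            else:
                rcs[g] = RegionCounts(np.array([], int), np.array([], int), group_id=g, region_id=row.region_id)
        bundle.records.append(
            RegionRecord(
                region_id=row.region_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                n_sites=int(row.n_sites),
                counts1=rcs[1],
                counts2=rcs[2],
            )
        )
    return bundle


def write_truth(truth: SimTruth, path) -> None:
    frame = pd.DataFrame({"region_id": truth.region_ids, "label": truth.labels})
    for g, theta in (("1", truth.theta1), ("2", truth.theta2)):
        for fieldname in ("pi0", "pi1", "alpha", "beta"):
            frame[f"theta{g}_{fieldname}"] = getattr(theta, fieldname)
    frame.to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["region_id"], frame["label"]))


def export_bundle_tsv(bundle: RegionBundle, outdir) -> Path:
    """Export site-level simulated data as per-cell xn_tsv files + sample sheet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_cell: dict[str, list] = {}
    groups: dict[str, int] = {}
    for rec in bundle:
        if rec.site_x is None:
            raise ValueError("bundle lacks site-level blocks; cannot export")
        for ci, cell in enumerate(rec.cell_ids):
            groups[cell] = int(rec.groups[ci])
            rows = per_cell.setdefault(cell, [])
            for si, pos in enumerate(rec.site_positions):
                n = int(rec.site_n[si, ci])
                if n > 0:
                    rows.append((rec.chrom, int(pos), int(rec.site_x[si, ci]), n))
    sheet_rows = []
    for cell, rows in per_cell.items():
        path = outdir / f"{cell}.tsv"
        pd.DataFrame(rows, columns=["chrom", "pos", "x", "n"]).to_csv(
            path, sep="\t", header=False, index=False
        )
        sheet_rows.append({"cell_id": cell, "path": str(path), "group": groups[cell]})
    sheet_path = outdir / "samples.csv"
    pd.DataFrame(sheet_rows).to_csv(sheet_path, index=False)
    return sheet_path
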