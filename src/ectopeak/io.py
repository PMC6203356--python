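"""Readers and writers for the formats the pipeline touches.

SAM (text) input goes through pysam; a plain TSV alignment dialect with the
same fields is accepted alongside it so small fixtures stay human-readable.
BED3 and bedGraph output are plain tab-delimited text; imaging cell tables
are CSV.

The alignment reader applies the mapping-quality filter (default MAPQ >= 10)
used to suppress spurious calls in repetitive sequence; unmapped, secondary
and supplementary records are dropped before the filter.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .calling import CoverageTrack
from .intervals import GenomicInterval, PeakSet
from .genome import GenomeSpec
from .reads import COLUMNS, ReadSet

DEFAULT_MIN_MAPQ = 10

CELL_TABLE_COLUMNS = (
    "cell_id",
    "experiment_id",
    "condition",
    "object_class",
    "probe",
    "x_um",
    "y_um",
)

OBJECT_CLASSES = ("fish_locus", "if_mark", "centromere_point")


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _looks_like_sam(path: str) -> bool:
    if str(path).endswith(".sam"):
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("@") and "\t" in first and not first.startswith(
        "read_id"
    )


def read_alignments(path, min_mapq: int = DEFAULT_MIN_MAPQ) -> ReadSet:
    """Read SAM or TSV alignments, keeping mapped records with mapq >= min_mapq.

    Input order is preserved. Unmapped, secondary and supplementary SAM
    records are dropped before the quality filter.
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _looks_like_sam(path):
        return _read_sam(path, min_mapq)
    return _read_tsv_alignments(path, min_mapq)


def _read_sam(path, min_mapq: int) -> ReadSet:
    rows = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                end = rec.reference_end
                if end is None:
                    end = rec.reference_start + (rec.query_length or 0)
                rows.append(
                    (
                        rec.query_name,
                        rec.reference_name,
                        rec.reference_start,
                        end,
                        "-" if rec.is_reverse else "+",
                        rec.mapping_quality,
                        rec.is_paired,
                        rec.is_paired and rec.is_read1,
                    )
                )
    except ValueError as exc:
        raise FormatError(f"unparseable SAM {path}: {exc}") from exc
    if not rows:
        return ReadSet.empty()
    return ReadSet(pd.DataFrame(rows, columns=list(COLUMNS)))


def _read_tsv_alignments(path, min_mapq: int) -> ReadSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    except Exception as exc:
        raise FormatError(f"unparseable alignment TSV {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col, check in [
        ("start", lambda s: s < 0),
        ("mapq", lambda s: (s < 0) | (s > 255)),
    ]:
        bad = check(df[col])
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise FormatError(f"{path}:{line}: invalid {col} value")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}:{line}: invalid strand")
    rs = ReadSet(df)
    return rs.filter_mapq(min_mapq)


def write_alignments_tsv(reads: ReadSet, path) -> None:
    reads.df.to_csv(path, sep="\t", index=False)


def write_sam(reads: ReadSet, genome: GenomeSpec, path) -> None:
    """Write a minimal text SAM (no sequence/qualities) for a ReadSet."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in genome.chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(genome.chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in reads.df.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            length = max(int(row.end - row.start), 1)
            a.cigarstring = f"{length}M"
            flag = 0
            if row.strand == "-":
                flag |= 16
            if row.is_paired:
                flag |= 1
                flag |= 64 if row.is_first_of_pair else 128
            a.flag = flag
            out.write(a)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read a 3+ column BED (0-based half-open); track/comment lines skipped."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
                )
            out.append(GenomicInterval(fields[0], start, end))
    return out


def write_bed(intervals: "Iterable[GenomicInterval] | PeakSet", path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero runs of a coverage track as bedGraph lines."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chroms:
            values = track.data[chrom]
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            bounds = np.concatenate(([0], change, [len(values)]))
            length = track.chrom_lengths[chrom]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                val = values[lo]
                if val == 0:
                    continue
                start = int(lo) * bs
                end = min(int(hi) * bs, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{val:g}\n")


# ---------------------------------------------------------------------------
# imaging cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell object table (CSV) with one row per imaged object."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "probe" in df.columns:
        df["probe"] = df["probe"].fillna("")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = ~df["object_class"].isin(OBJECT_CLASSES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}:{line}: unknown object_class")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise FormatError(f"{path}: non-finite coordinates")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
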