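"""Genomic interval algebra: merging, base-level set operations, replicate
consensus and the centromere-exclusion ("ectopic") filter.

All coordinates are 0-based half-open (BED convention). A :class:`PeakSet`
is the universal currency of the pipeline: per-chromosome, sorted,
non-overlapping intervals plus a provenance label. "Peak coverage" is the
total number of bases inside a peak set, reported in kilobases
(1 kb = 1000 bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CoveragePartition",
    "merge_intervals",
    "intersect_bases",
    "subtract_bases",
    "peak_coverage",
    "replicated_peaks",
    "ectopic_filter",
    "common_new_partition",
    "default_min_support",
]


class GenomicInterval(NamedTuple):
    """Half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_interval(chrom: str, start: int, end: int, context: str = "") -> None:
    if start < 0 or end <= start:
        raise ValueError(
            f"invalid interval {chrom}:{start}-{end}"
            f"{' (' + context + ')' if context else ''}: require 0 <= start < end"
        )


class PeakSet:
    """Sorted, per-chromosome non-overlapping intervals with a provenance label.

    Construct via :func:`merge_intervals` (arbitrary input) or
    :meth:`PeakSet.from_intervals` (input already disjoint and sorted).
    """

    def __init__(self, per_chrom: dict[str, np.ndarray], label: str = "peaks"):
        self.label = label
        self._per_chrom: dict[str, np.ndarray] = {}
        for chrom in sorted(per_chrom):
            arr = np.asarray(per_chrom[chrom], dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                continue
            if np.any(arr[:, 0] < 0) or np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"invalid interval on {chrom}: require 0 <= start < end")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(
                    f"intervals on {chrom} overlap or are unsorted; merge first"
                )
            self._per_chrom[chrom] = arr

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple], label: str = "peaks"
    ) -> "PeakSet":
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            _validate_interval(chrom, start, end)
            by.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: np.array(v, dtype=np.int64) for c, v in by.items()}, label)

    @classmethod
    def empty(cls, label: str = "peaks") -> "PeakSet":
        return cls({}, label)

    # -- basic protocol ----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._per_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for one chromosome (empty if absent)."""
        return self._per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> list[GenomicInterval]:
        return list(self)

    def __len__(self) -> int:
        return sum(len(a) for a in self._per_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, arr in self._per_chrom.items():
            for s, e in arr:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self._per_chrom[c], other._per_chrom[c]) for c in self.chroms
        )

    def __repr__(self) -> str:
        return (
            f"PeakSet(label={self.label!r}, n={len(self)}, "
            f"coverage={self.coverage} bases)"
        )

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    # -- queries -----------------------------------------------------------

    @property
    def coverage(self) -> int:
        """Total bases inside the set: sum of (end - start)."""
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._per_chrom.values())
        )

    @property
    def coverage_kb(self) -> float:
        return self.coverage / 1000.0

    def overlaps(self, interval: tuple) -> bool:
        """True iff any interval in the set shares >= 1 base with `interval`."""
        chrom, start, end = interval[0], int(interval[1]), int(interval[2])
        arr = self._per_chrom.get(chrom)
        if arr is None:
            return False
        # first interval whose end > start
        i = int(np.searchsorted(arr[:, 1], start, side="right"))
        return i < len(arr) and arr[i, 0] < end

    def relabel(self, label: str) -> "PeakSet":
        return PeakSet(self._per_chrom, label)


def merge_intervals(
    intervals: Iterable[tuple], gap: int = 0, label: str = "merged"
) -> PeakSet:
    """Merge arbitrary intervals into a minimal disjoint set.

    Intervals separated by <= `gap` bases are joined. Idempotent and
    order-invariant; with gap=0 this is the "single reference peak set"
    merge applied to pooled replicate peaks.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        _validate_interval(chrom, int(start), int(end))
        by.setdefault(chrom, []).append((int(start), int(end)))
    per: dict[str, np.ndarray] = {}
    for chrom, pairs in by.items():
        pairs.sort()
        out: list[tuple[int, int]] = []
        cs, ce = pairs[0]
        for s, e in pairs[1:]:
            if s <= ce + gap:
                ce = max(ce, e)
            else:
                out.append((cs, ce))
                cs, ce = s, e
        out.append((cs, ce))
        per[chrom] = np.array(out, dtype=np.int64)
    return PeakSet(per, label)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    i = j = 0
    out: list[tuple[int, int]] = []
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return out


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj, 0] < e:
            if b[jj, 0] > cur:
                out.append((cur, int(b[jj, 0])))
            cur = max(cur, int(b[jj, 1]))
            jj += 1
            if cur >= e:
                break
        if cur < int(e):
            out.append((cur, int(e)))
    return out


def intersect_bases(a: PeakSet, b: PeakSet) -> tuple[PeakSet, int]:
    """Bases present in both sets. Returns (interval set, base count)."""
    per: dict[str, np.ndarray] = {}
    for chrom in a.chroms:
        pairs = _intersect_arrays(a.arrays(chrom), b.arrays(chrom))
        if pairs:
            per[chrom] = np.array(pairs, dtype=np.int64)
    res = PeakSet(per, f"{a.label}&{b.label}")
    return res, res.coverage


def subtract_bases(a: PeakSet, b: PeakSet) -> tuple[PeakSet, int]:
    """Bases of `a` not in `b`. Returns (interval set, base count)."""
    per: dict[str, np.ndarray] = {}
    for chrom in a.chroms:
        pairs = _subtract_arrays(a.arrays(chrom), b.arrays(chrom))
        if pairs:
            per[chrom] = np.array(pairs, dtype=np.int64)
    res = PeakSet(per, f"{a.label}-{b.label}")
    return res, res.coverage


def peak_coverage(p: "PeakSet | Sequence[tuple]") -> int:
    """Total bases within peaks (sum of end - start over the merged set)."""
    if not isinstance(p, PeakSet):
        log.info("peak_coverage received unmerged intervals; merging with gap=0")
        p = merge_intervals(p, gap=0)
    return p.coverage


def default_min_support(n_replicates: int) -> int:
    """Replication rule: require 3 replicates when n >= 3, else all n."""
    return 3 if n_replicates >= 3 else n_replicates


def replicated_peaks(
    replicate_sets: Sequence[PeakSet], min_support: int
) -> PeakSet:
    """Consensus peaks: merged reference intervals supported by enough replicates.

    The reference set is merge(union of all replicate peaks, gap=0). Each
    reference interval is kept whole iff at least `min_support` distinct
    replicates contribute a peak sharing >= 1 base with it; otherwise it is
    dropped whole.
    """
    n = len(replicate_sets)
    if n < 1:
        raise ValueError("need at least one replicate peak set")
    if not 1 <= min_support <= n:
        raise ValueError(f"min_support={min_support} out of range [1, {n}]")
    all_ivs = [iv for ps in replicate_sets for iv in ps]
    if not all_ivs:
        return PeakSet.empty("replicated")
    reference = merge_intervals(all_ivs, gap=0, label="reference")
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in reference:
        support = sum(1 for ps in replicate_sets if ps.overlaps(iv))
        if support >= min_support:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return PeakSet(
        {c: np.array(v, dtype=np.int64) for c, v in per.items()}, "replicated"
    )


def ectopic_filter(p: PeakSet, mask: PeakSet) -> PeakSet:
    """Keep only peaks falling completely outside the centromere mask.

    A peak sharing even a single base with the mask — including peaks
    straddling a centromere boundary — is removed whole, never trimmed.
    Chromosomes absent from the mask count as fully ectopic territory.
    """
    per: dict[str, list[tuple[int, int]]] = {}
    n_masked = 0
    for iv in p:
        if mask.overlaps(iv):
            n_masked += 1
            continue
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    if n_masked:
        log.debug("ectopic_filter removed %d centromere-overlapping peaks", n_masked)
    return PeakSet(
        {c: np.array(v, dtype=np.int64) for c, v in per.items()},
        f"{p.label}_ectopic",
    )


@dataclass(frozen=True)
class CoveragePartition:
    """Base-level split of treatment peak coverage against a control set.

    common + new = treatment total, exactly (enforced at construction).
    """

    common_bases: int
    new_bases: int
    control_only_bases: int
    treatment_total_bases: int

    def __post_init__(self) -> None:
        if min(
            self.common_bases,
            self.new_bases,
            self.control_only_bases,
            self.treatment_total_bases,
        ) < 0:
            raise ValueError("partition fields must be non-negative")
        if self.common_bases + self.new_bases != self.treatment_total_bases:
            raise ValueError(
                "partition conservation violated: "
                f"{self.common_bases} + {self.new_bases} != {self.treatment_total_bases}"
            )

    @property
    def common_kb(self) -> float:
        return self.common_bases / 1000.0

    @property
    def new_kb(self) -> float:
        return self.new_bases / 1000.0

    @property
    def control_only_kb(self) -> float:
        return self.control_only_bases / 1000.0


def common_new_partition(control: PeakSet, treatment: PeakSet) -> CoveragePartition:
    """Split treatment coverage into bases common with control vs newly acquired."""
    _, common = intersect_bases(treatment, control)
    _, new = subtract_bases(treatment, control)
    _, control_only = subtract_bases(control, treatment)
    return CoveragePartition(
        common_bases=common,
        new_bases=new,
        control_only_bases=control_only,
        treatment_total_bases=treatment.coverage,
    )
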