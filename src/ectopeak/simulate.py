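"""Synthetic data with planted truth: toy genomes, feature sets, ChIP/input
read sets, and imaging cell tables.

The read simulator emulates a native (MNase) histone-variant ChIP
experiment: fragment 5' starts drawn from a uniform background mixed with
excess mass over planted features — strong enrichment over annotated
centromere intervals, sharp ~1 kb "ectopic" peaks at promoter/DHS-like
sites, and one broad subtelomeric domain. Replicates differ in depth (the
real experiments spanned roughly a 3x range); a configurable fraction of
reads carries low mapping quality to exercise the MAPQ filter; paired mode
duplicates each fragment into first/second mates.

The cell simulator emulates IF/FISH scoring: per-cell centromere point
clouds, FISH loci placed at designated radii from the cloud centre
(monopolar-spindle geometry), IF marks planted on a locus in a truth-known
fraction of cells, and Poisson loci counts per cell.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CentromereMask, GenomeSpec
from .intervals import GenomicInterval, PeakSet, merge_intervals
from .reads import COLUMNS, ReadSet

__all__ = [
    "FeatureFolds",
    "TruthSet",
    "SimulationParams",
    "MonastrolGeometry",
    "CellTable",
    "make_genome",
    "plant_features",
    "simulate_reads",
    "simulate_cells",
]


@dataclass(frozen=True)
class FeatureFolds:
    """Enrichment of ChIP sampling density over each feature class,
    relative to background (exercise parameters, not estimates)."""

    centromere: float = 20.0
    sharp: float = 10.0
    domain: float = 5.0

    def __post_init__(self) -> None:
        if min(self.centromere, self.sharp, self.domain) <= 0:
            raise ValueError("enrichment folds must be positive")


@dataclass(frozen=True)
class TruthSet:
    """Planted occupancy classes with known coordinates."""

    centromeric_domains: tuple[GenomicInterval, ...]
    ectopic_sharp_peaks: tuple[GenomicInterval, ...]
    subtelomeric_domain: GenomicInterval | None
    folds: FeatureFolds = field(default_factory=FeatureFolds)

    def ectopic_peakset(self) -> PeakSet:
        ivs = list(self.ectopic_sharp_peaks)
        if self.subtelomeric_domain is not None:
            ivs.append(self.subtelomeric_domain)
        if not ivs:
            return PeakSet.empty("planted_ectopic")
        return merge_intervals(ivs, gap=0, label="planted_ectopic")

    @property
    def ectopic_coverage_bases(self) -> int:
        return self.ectopic_peakset().coverage

    def all_features(self) -> list[tuple[GenomicInterval, float]]:
        feats = [(iv, self.folds.centromere) for iv in self.centromeric_domains]
        feats += [(iv, self.folds.sharp) for iv in self.ectopic_sharp_peaks]
        if self.subtelomeric_domain is not None:
            feats.append((self.subtelomeric_domain, self.folds.domain))
        return feats


@dataclass(frozen=True)
class SimulationParams:
    """Read-simulation settings.

    depth is fragments per replicate before the depth_factors multiplier;
    paired mode emits two mate records per fragment. background_rate, if
    set, overrides depth with (rate x weighted genome length) fragments.
    mapq_low_fraction of reads draw MAPQ < 10 so the quality filter has
    something to remove.
    """

    depth: int = 500_000
    n_replicates: int = 3
    fragment_length: int = 147
    read_length: int = 76
    paired: bool = False
    background_rate: float | None = None
    depth_factors: tuple[float, ...] | None = None
    mapq_low_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.fragment_length <= 0 or self.read_length <= 0:
            raise ValueError("fragment_length and read_length must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.mapq_low_fraction < 1:
            raise ValueError("mapq_low_fraction must lie in [0, 1)")

    def replicate_depths(self) -> list[int]:
        """Per-replicate fragment counts (default heterogeneity x1..x3)."""
        if self.depth_factors is not None:
            if len(self.depth_factors) != self.n_replicates:
                raise ValueError("depth_factors length must equal n_replicates")
            factors = self.depth_factors
        elif self.n_replicates == 1:
            factors = (1.0,)
        else:
            factors = tuple(
                1.0 + 2.0 * i / (self.n_replicates - 1)
                for i in range(self.n_replicates)
            )
        return [max(1, int(round(self.depth * f))) for f in factors]


def make_genome(n_chroms: int = 4, chrom_length: int = 2_500_000,
                centromere_fraction: float = 0.1, seed: int = 0) -> GenomeSpec:
    """Toy genome with one centrally placed centromere per chromosome."""
    if n_chroms < 1 or chrom_length <= 0:
        raise ValueError("n_chroms and chrom_length must be positive")
    if not 0 < centromere_fraction < 0.5:
        raise ValueError("centromere_fraction must lie in (0, 0.5)")
    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    cen_len = int(round(centromere_fraction * chrom_length))
    cens = []
    for chrom in lengths:
        start = (chrom_length - cen_len) // 2
        cens.append((chrom, start, start + cen_len))
    return GenomeSpec(lengths, PeakSet.from_intervals(cens, label="centromeres"))


def plant_features(genome: GenomeSpec, n_sharp: int = 50, domain_kb: float = 50.0,
                   folds: FeatureFolds | None = None, seed=0,
                   sharp_length: int = 1000, margin: int = 2000,
                   max_tries: int = 20_000,
                   base: TruthSet | None = None) -> TruthSet:
    """Plant sharp ectopic peaks and one broad subtelomeric domain.

    Features are placed uniformly outside the centromere mask, keeping
    `margin` bp clear of the mask and of each other so downstream peak
    merging and whole-peak centromere exclusion act on well-separated
    features. The subtelomeric domain sits near the right end of the last
    chromosome (8q24-like).

    When `base` is given (e.g. a knockdown condition building on the
    control's occupancy), its features are inherited and `n_sharp` counts
    *additional* sharp peaks placed clear of them; an inherited domain
    takes precedence over `domain_kb`.
    """
    folds = folds or FeatureFolds()
    rng = np.random.default_rng(seed)
    if n_sharp < 0 or domain_kb < 0 or sharp_length <= 0:
        raise ValueError("invalid feature parameters")
    mask = genome.centromeres
    placed: list[GenomicInterval] = []
    inherited_sharp: list[GenomicInterval] = []
    if base is not None:
        inherited_sharp = list(base.ectopic_sharp_peaks)
        placed.extend(inherited_sharp)

    domain: GenomicInterval | None = None
    if base is not None and base.subtelomeric_domain is not None:
        domain = base.subtelomeric_domain
        placed.append(domain)
    elif domain_kb > 0:
        dlen = int(round(domain_kb * 1000))
        chrom = genome.chroms[-1]
        length = genome.chrom_lengths[chrom]
        pad = min(10_000, length // 20)
        start, end = length - pad - dlen, length - pad
        domain = GenomicInterval(chrom, start, end)
        if start < 0 or mask.overlaps(domain):
            raise ValueError("genome too small to place the subtelomeric domain")
        placed.append(domain)

    chroms = genome.chroms
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    sharp: list[GenomicInterval] = []
    tries = 0
    while len(sharp) < n_sharp:
        if tries > max_tries:
            raise ValueError(
                "could not place all sharp features without mask overlap; "
                "genome too small or too crowded"
            )
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = genome.chrom_lengths[chrom]
        if length <= sharp_length + 2 * margin:
            continue
        start = int(rng.integers(margin, length - sharp_length - margin))
        cand = GenomicInterval(chrom, start, start + sharp_length)
        grown = GenomicInterval(chrom, max(0, start - margin),
                                min(length, cand.end + margin))
        if mask.overlaps(grown):
            continue
        if any(p.chrom == chrom and p.start < grown.end and grown.start < p.end
               for p in placed):
            continue
        sharp.append(cand)
        placed.append(cand)

    truth = TruthSet(
        centromeric_domains=tuple(GenomicInterval(*iv) for iv in mask),
        ectopic_sharp_peaks=tuple(sorted(inherited_sharp + sharp)),
        subtelomeric_domain=domain,
        folds=folds,
    )
    # planted ectopic truth must never overlap the centromere mask
    from .intervals import intersect_bases

    _, overlap = intersect_bases(truth.ectopic_peakset(), mask)
    assert overlap == 0, "planted ectopic features overlap the centromere mask"
    return truth


def _segments_for_channel(genome: GenomeSpec, truth: TruthSet, channel: str):
    """Per-chromosome (start, end, weight-multiplier) segments."""
    feats: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome.chroms}
    if channel == "chip":
        for iv, fold in truth.all_features():
            feats[iv.chrom].append((iv.start, iv.end, fold))
    segs: list[tuple[str, int, int, float]] = []
    for chrom, length in genome.chrom_lengths.items():
        pos = 0
        for s, e, fold in sorted(feats[chrom]):
            if s > pos:
                segs.append((chrom, pos, s, 1.0))
            segs.append((chrom, s, e, fold))
            pos = e
        if pos < length:
            segs.append((chrom, pos, length, 1.0))
    return segs


def simulate_reads(genome: GenomeSpec, truth: TruthSet, params: SimulationParams,
                   channel: str) -> list[ReadSet]:
    """Simulate one ReadSet per replicate for the given channel.

    channel='chip' adds excess fragment mass over truth features in
    proportion to their enrichment fold; channel='input' ignores the truth
    and is uniform. Fragments are placed wholly inside the chromosome;
    strand is random and the read covers read_length bases at the
    fragment's corresponding end.
    """
    if channel not in ("chip", "input"):
        raise ValueError("channel must be 'chip' or 'input'")
    segs = _segments_for_channel(genome, truth, channel)
    frag = params.fragment_length
    rlen = min(params.read_length, frag)
    seg_arr = [(c, s, min(e, genome.chrom_lengths[c] - frag), w)
               for c, s, e, w in segs]
    seg_arr = [(c, s, e, w) for c, s, e, w in seg_arr if e > s]
    weights = np.array([(e - s) * w for _, s, e, w in seg_arr], dtype=float)
    probs = weights / weights.sum()

    out: list[ReadSet] = []
    chan_code = 0 if channel == "chip" else 1
    for rep, depth in enumerate(params.replicate_depths()):
        if params.background_rate is not None:
            # interpret as uniform-background fragment density (reads/bp)
            depth = max(1, int(round(params.background_rate * genome.total_length)))
        rng = np.random.default_rng([params.seed, chan_code, rep])
        counts = rng.multinomial(depth, probs)
        frag_chrom = np.repeat([c for c, *_ in seg_arr], counts)
        lo = np.repeat([s for _, s, _, _ in seg_arr], counts)
        hi = np.repeat([e for _, _, e, _ in seg_arr], counts)
        f = lo + np.floor(rng.random(depth) * (hi - lo)).astype(np.int64)
        strand = np.where(rng.random(depth) < 0.5, "+", "-")
        low = rng.random(depth) < params.mapq_low_fraction
        mapq = np.where(low, rng.integers(0, 10, depth), rng.integers(30, 61, depth))
        start = np.where(strand == "+", f, f + frag - rlen)
        end = start + rlen
        ids = np.char.add(f"{channel}{rep}_", np.arange(depth).astype("U9"))
        if params.paired:
            # mate record at the opposite fragment end, opposite strand
            m_strand = np.where(strand == "+", "-", "+")
            m_start = np.where(m_strand == "+", f, f + frag - rlen)
            m_end = m_start + rlen
            df = pd.DataFrame(
                {
                    "read_id": np.concatenate([ids, ids]),
                    "chrom": np.concatenate([frag_chrom, frag_chrom]),
                    "start": np.concatenate([start, m_start]),
                    "end": np.concatenate([end, m_end]),
                    "strand": np.concatenate([strand, m_strand]),
                    "mapq": np.concatenate([mapq, mapq]),
                    "is_paired": True,
                    "is_first_of_pair": np.concatenate(
                        [np.ones(depth, bool), np.zeros(depth, bool)]
                    ),
                }
            )
        else:
            df = pd.DataFrame(
                {
                    "read_id": ids,
                    "chrom": frag_chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "mapq": mapq,
                    "is_paired": False,
                    "is_first_of_pair": False,
                }
            )
        # segment sampling emits reads in genome order already (per mate block)
        out.append(ReadSet(df[list(COLUMNS)], validate=False))
    return out


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonastrolGeometry:
    """Monopolar-spindle radii: spindle-attached loci sit near the
    centromere-cloud centre, unattached loci at the periphery."""

    inner_radius_um: float = 3.4
    outer_radius_um: float = 4.5
    radial_sd_um: float = 0.3

    def __post_init__(self) -> None:
        if min(self.inner_radius_um, self.outer_radius_um) < 0:
            raise ValueError("radii must be non-negative")
        if self.radial_sd_um < 0:
            raise ValueError("radial_sd_um must be non-negative")


@dataclass
class CellTable:
    """objects: one row per imaged object; cells: per-cell truth labels."""

    objects: pd.DataFrame
    cells: pd.DataFrame

    def __len__(self) -> int:
        return len(self.cells)


def simulate_cells(n_cells: int = 200, n_experiments: int = 3,
                   coloc_rate: float = 0.26, loci_mean: float = 12.4,
                   monastrol: MonastrolGeometry | None = None, seed=0,
                   condition: str = "control", locus_probe: str = "8q24",
                   n_centromere_points: int = 25) -> CellTable:
    """Simulate per-cell imaging object tables with planted truth.

    Each cell carries an isotropic centromere point cloud around a per-cell
    centre; Poisson(loci_mean) FISH loci at monopolar radii (the one marked
    locus, if any, at the inner radius, others at the outer radius); an IF
    mark planted on a locus in a coloc_rate fraction of cells, with a decoy
    mark near the cloud centre otherwise. Truth labels are stored per cell.
    """
    if not 0 <= coloc_rate <= 1:
        raise ValueError("coloc_rate must lie in [0, 1]")
    if loci_mean < 0:
        raise ValueError("loci_mean must be >= 0")
    monastrol = monastrol or MonastrolGeometry()
    rng = np.random.default_rng(seed)
    obj_rows: list[tuple] = []
    cell_rows: list[tuple] = []
    for e in range(1, n_experiments + 1):
        exp = f"exp{e}"
        for i in range(n_cells):
            cell = f"{condition}_{exp}_c{i:04d}"
            cx, cy = rng.uniform(10.0, 40.0, size=2)
            pts = rng.normal([cx, cy], 1.5, size=(n_centromere_points, 2))
            for x, y in pts:
                obj_rows.append(
                    (cell, exp, condition, "centromere_point", "", x, y)
                )
            colocalized = bool(rng.random() < coloc_rate)
            k = int(rng.poisson(loci_mean))
            if colocalized and k == 0:
                k = 1
            attached = np.zeros(k, dtype=bool)
            if colocalized:
                attached[int(rng.integers(0, k))] = True
            radii = np.where(
                attached,
                rng.normal(monastrol.inner_radius_um, monastrol.radial_sd_um, k),
                rng.normal(monastrol.outer_radius_um, monastrol.radial_sd_um, k),
            )
            radii = np.maximum(radii, 0.6)
            angles = rng.uniform(0, 2 * np.pi, k)
            lx = cx + radii * np.cos(angles)
            ly = cy + radii * np.sin(angles)
            for j in range(k):
                obj_rows.append(
                    (cell, exp, condition, "fish_locus", locus_probe, lx[j], ly[j])
                )
            if colocalized:
                j = int(np.flatnonzero(attached)[0])
                mx, my = rng.normal([lx[j], ly[j]], 0.05)
            else:
                mx, my = rng.normal([cx, cy], 0.3)
            obj_rows.append((cell, exp, condition, "if_mark", "", mx, my))
            cell_rows.append((cell, exp, condition, colocalized, k, cx, cy))
    objects = pd.DataFrame(
        obj_rows,
        columns=[
            "cell_id", "experiment_id", "condition", "object_class",
            "probe", "x_um", "y_um",
        ],
    )
    cells = pd.DataFrame(
        cell_rows,
        columns=[
            "cell_id", "experiment_id", "condition", "truth_colocalized",
            "truth_n_loci", "center_x_um", "center_y_um",
        ],
    )
    return CellTable(objects=objects, cells=cells)
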