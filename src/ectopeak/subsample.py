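"""Equal-depth random-subsampling normalization.

Sequencing depth, single- vs paired-end chemistry, and replicate number
are technical differences that confound peak-coverage comparisons. The
procedure here removes them: first-of-mate reads are extracted from
paired-end sets, the highest-depth replicates are pooled per condition,
fixed-depth random subsamples are drawn without replacement, peaks are
called on each subsample, and ectopic peak coverage is summarised as
mean ± SD across trials with pairwise Student t-tests between conditions.

The real-data procedure used 75 M reads per IP trial and 100 M per input;
those are configuration values — defaults here are scaled to the toy
genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import PeakCallParams, call_peaks, peaks_to_peakset
from .genome import CentromereMask, GenomeSpec
from .intervals import ectopic_filter, peak_coverage
from .reads import ReadSet
from .stats import student_t

__all__ = [
    "SubsampleResult",
    "first_of_mate",
    "pool_top_replicates",
    "draw_subsamples",
    "equalized_coverage",
    "compare_conditions",
]


@dataclass
class SubsampleResult:
    """Per-trial ectopic peak coverage (bases) with mean and sample SD."""

    condition: str
    trial_coverage: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.trial_coverage) < 1:
            raise ValueError("need at least one trial")

    @property
    def mean(self) -> float:
        return float(np.mean(self.trial_coverage))

    @property
    def sd(self) -> float:
        if len(self.trial_coverage) < 2:
            return 0.0
        return float(np.std(self.trial_coverage, ddof=1))

    @property
    def mean_kb(self) -> float:
        return self.mean / 1000.0

    @property
    def sd_kb(self) -> float:
        return self.sd / 1000.0


def first_of_mate(reads: ReadSet) -> ReadSet:
    """Keep first-of-mate records from pairs; single-end records pass through."""
    df = reads.df
    keep = ~df["is_paired"] | df["is_first_of_pair"]
    return ReadSet(df[keep], validate=False)


def pool_top_replicates(replicates: list[ReadSet], k: int) -> ReadSet:
    """Concatenate the k highest-depth replicates (ties keep input order)."""
    n = len(replicates)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    sizes = np.array([len(r) for r in replicates])
    order = np.argsort(-sizes, kind="stable")[:k]
    return ReadSet.concat([replicates[i] for i in sorted(order)])


def draw_subsamples(pool: ReadSet, n_reads: int, trials: int, seed: int
                    ) -> list[ReadSet]:
    """Uniform without-replacement subsamples of exactly n_reads each.

    Trials are independent given distinct sub-seeds (seed + trial index);
    reruns with the same seed are identical.
    """
    if n_reads > len(pool):
        raise ValueError(
            f"requested {n_reads} reads but pool holds only {len(pool)}"
        )
    out = []
    for t in range(trials):
        rng = np.random.default_rng(seed + t)
        idx = rng.choice(len(pool), size=n_reads, replace=False)
        out.append(pool.subset(np.sort(idx)))
    return out


def equalized_coverage(chip_reps: list[ReadSet], input_reps: list[ReadSet],
                       genome: GenomeSpec, mask: CentromereMask,
                       ip_depth: int, input_depth: int, trials: int = 3,
                       peak_params: PeakCallParams | None = None, seed: int = 0,
                       condition: str = "condition", pool_k: int = 2,
                       ) -> SubsampleResult:
    """Depth-equalized ectopic peak coverage across random subsampling trials.

    Per trial: subsample the pooled IP to ip_depth and the pooled input to
    input_depth (input redrawn each trial), call peaks, keep peaks
    completely outside the centromere mask, and sum their bases. Returns
    per-trial coverages with mean and sample SD (n-1).
    """
    chip_pool = pool_top_replicates(
        [first_of_mate(r) for r in chip_reps], min(pool_k, len(chip_reps))
    )
    input_pool = pool_top_replicates(
        [first_of_mate(r) for r in input_reps], min(pool_k, len(input_reps))
    )
    ip_draws = draw_subsamples(chip_pool, ip_depth, trials, seed)
    input_draws = draw_subsamples(input_pool, input_depth, trials, seed + trials)
    coverages = []
    for chip, inp in zip(ip_draws, input_draws):
        peaks = call_peaks(chip, inp, genome, peak_params)
        ectopic = ectopic_filter(peaks_to_peakset(peaks, condition), mask)
        coverages.append(peak_coverage(ectopic))
    return SubsampleResult(condition=condition, trial_coverage=tuple(coverages))


def compare_conditions(a: SubsampleResult, b: SubsampleResult,
                       welch: bool = False) -> tuple[float, float]:
    """Two-sample Student t-test on per-trial coverages: (t, two-sided p)."""
    return student_t(a.trial_coverage, b.trial_coverage, welch=welch)
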