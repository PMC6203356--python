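"""Shared fixtures and per-base boolean-array oracles.

The oracle functions materialise interval sets as boolean arrays over a
small chromosome and perform set algebra elementwise; every interval
operation in the package is checked against them.
"""

from __future__ import annotations

import mpmath
import numpy as np
import pytest
from hypothesis import settings

import ectopeak as ep

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# boolean-array oracles
# ---------------------------------------------------------------------------

def bool_mask(intervals, chrom_len: int, chrom: str = "chr1") -> np.ndarray:
    """Per-base occupancy array for a single-chromosome interval list."""
    mask = np.zeros(chrom_len, dtype=bool)
    for c, s, e in intervals:
        if c == chrom:
            mask[s:e] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str = "chr1"):
    """Back-convert a boolean occupancy array to sorted disjoint intervals."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [ep.GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def random_intervals(rng, n: int, chrom_len: int, max_len: int = 500,
                     chrom: str = "chr1"):
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [
        ep.GenomicInterval(chrom, int(s), int(min(s + l, chrom_len)))
        for s, l in zip(starts, lengths)
    ]


def mp_poisson_tail(k: int, lam: float) -> float:
    """Oracle: upper-tail pmf summation sum_{j>=k} e^-lam lam^j / j!,
    term by term in 60-digit arithmetic, independent of the
    incomplete-gamma path used by the implementation."""
    mpmath.mp.dps = 60
    if k == 0:
        return 1.0
    lam_mp = mpmath.mpf(lam)
    if lam_mp == 0:
        return 0.0
    term = mpmath.e ** (-lam_mp) * lam_mp**k / mpmath.factorial(k)
    total = mpmath.mpf(0)
    j = k
    while j < k + 10_000:
        total += term
        j += 1
        term = term * lam_mp / j
        if total > 0 and term < total * mpmath.mpf("1e-45"):
            break
    return float(total)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def toy_genome():
    """300 kb single-chromosome genome with a 30 kb central centromere."""
    return ep.make_genome(n_chroms=1, chrom_length=300_000,
                          centromere_fraction=0.1)


@pytest.fixture
def toy_truth(toy_genome):
    return ep.plant_features(toy_genome, n_sharp=8, domain_kb=15.0, seed=42)


@pytest.fixture
def toy_reads(toy_genome, toy_truth):
    params = ep.SimulationParams(depth=40_000, n_replicates=1, seed=42)
    chip = ep.simulate_reads(toy_genome, toy_truth, params, "chip")[0]
    inp = ep.simulate_reads(toy_genome, toy_truth, params, "input")[0]
    return chip, inp
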