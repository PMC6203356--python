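"""Figure helpers: coverage bar charts and proportional two-set Venn
diagrams of common/new peak coverage (areas in kb)."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .intervals import CoveragePartition


def coverage_barplot(labels, coverages_kb, errors_kb=None, path=None, ax=None):
    """Bar chart of replicated ectopic peak coverage per condition (kb)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(labels)), coverages_kb, yerr=errors_kb, capsize=3,
           color="#4878a8")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_ylabel("ectopic peak coverage (kb)")
    plt.tight_layout()
    if path:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def proportional_venn(partition: CoveragePartition, labels=("control", "treatment"),
                      path=None, ax=None):
    """Two-circle proportional Venn of control/treatment peak coverage.

    Circle areas are proportional to total coverage; the centre distance is
    chosen so the lens area approximates the common coverage. Newly
    acquired treatment coverage is the unshaded treatment-only region.
    """
    a = partition.control_only_bases + partition.common_bases
    b = partition.treatment_total_bases
    ab = partition.common_bases
    ra, rb = math.sqrt(max(a, 1) / math.pi), math.sqrt(max(b, 1) / math.pi)

    def lens_area(d):
        if d >= ra + rb:
            return 0.0
        if d <= abs(ra - rb):
            return math.pi * min(ra, rb) ** 2
        t1 = ra**2 * math.acos((d**2 + ra**2 - rb**2) / (2 * d * ra))
        t2 = rb**2 * math.acos((d**2 + rb**2 - ra**2) / (2 * d * rb))
        t3 = 0.5 * math.sqrt(
            max((-d + ra + rb) * (d + ra - rb) * (d - ra + rb) * (d + ra + rb), 0)
        )
        return t1 + t2 - t3

    lo, hi = abs(ra - rb), ra + rb
    for _ in range(60):  # bisection on the centre distance
        mid = (lo + hi) / 2
        if lens_area(mid) > ab:
            lo = mid
        else:
            hi = mid
    d = (lo + hi) / 2
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.add_patch(Circle((0, 0), ra, alpha=0.4, color="#888888"))
    ax.add_patch(Circle((d, 0), rb, alpha=0.4, color="#ffffff", ec="black"))
    pad = max(ra, rb) * 1.2
    ax.set_xlim(-pad, d + pad)
    ax.set_ylim(-pad, pad)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(
        f"{labels[0]}-only {partition.control_only_kb:.1f} kb | "
        f"common {partition.common_kb:.1f} kb | "
        f"new {partition.new_kb:.1f} kb"
    , fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
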