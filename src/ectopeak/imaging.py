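"""Imaging quantifications from per-cell object tables.

Three readouts, all computed from (cell_id, object class, probe, x, y)
tables rather than pixels:

* **Colocalization** — a cell is scored positive when at least one FISH
  locus of the probe has an IF mark within a distance criterion (default
  0.5 μm, a sub-diffraction proximity surrogate for pixel-overlap
  scoring). Percentages are summarised per independent experiment, with
  SEM across experiments and a Student t-test between conditions.
* **Monopolar-spindle distances** — the centromere point cloud of each
  cell is enclosed in a minimal-area ellipse (Khachiyan iteration) and
  the distance from its centre to each FISH locus is measured; loci are
  grouped by whether they carry an IF mark (ectopic-kinetochore-positive
  vs negative).
* **Loci counts** — FISH loci per cell, averaged per condition with SEM
  across experiments.

All statistics are invariant under rigid rotation/translation of each
cell's coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CellTable
from .stats import sem, student_t

log = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 0.5

__all__ = [
    "ColocalizationSummary",
    "GroupComparison",
    "score_colocalization",
    "summarize_colocalization",
    "fit_center",
    "minimal_enclosing_ellipse",
    "locus_center_distance",
    "monopolar_distance_summary",
    "count_loci",
]


def _objects(table) -> pd.DataFrame:
    if isinstance(table, CellTable):
        return table.objects
    return table


def score_colocalization(cell: pd.DataFrame, locus_probe: str,
                         marker_class: str = "if_mark",
                         radius: float = DEFAULT_RADIUS_UM) -> bool:
    """True iff >= 1 locus of `locus_probe` has a marker within `radius` μm."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    loci = cell[(cell["object_class"] == "fish_locus")
                & (cell["probe"] == locus_probe)]
    if loci.empty:
        log.debug("cell lacks probe %s entirely; scored not colocalized",
                  locus_probe)
        return False
    marks = cell[cell["object_class"] == marker_class]
    if marks.empty:
        return False
    lx = loci[["x_um", "y_um"]].to_numpy()
    mx = marks[["x_um", "y_um"]].to_numpy()
    d2 = ((lx[:, None, :] - mx[None, :, :]) ** 2).sum(axis=2)
    return bool((d2 <= radius * radius).any())


@dataclass
class GroupComparison:
    t: float
    p: float


@dataclass
class ColocalizationSummary:
    """Per-experiment fractions plus condition-level mean %, SEM and t-test."""

    per_experiment: pd.DataFrame  # condition, experiment_id, n_cells, fraction
    condition_stats: pd.DataFrame  # condition, mean_pct, sem_pct, n_experiments
    comparison: GroupComparison | None = None

    def mean_pct(self, condition: str) -> float:
        row = self.condition_stats.set_index("condition").loc[condition]
        return float(row["mean_pct"])


def _per_cell_coloc(objects: pd.DataFrame, locus_probe: str, marker_class: str,
                    radius: float) -> pd.DataFrame:
    rows = []
    for (cond, exp, cell), grp in objects.groupby(
        ["condition", "experiment_id", "cell_id"], sort=True
    ):
        rows.append(
            (cond, exp, cell,
             score_colocalization(grp, locus_probe, marker_class, radius))
        )
    return pd.DataFrame(
        rows, columns=["condition", "experiment_id", "cell_id", "colocalized"]
    )


def summarize_colocalization(table, locus_probe: str = "8q24",
                             marker_class: str = "if_mark",
                             radius: float = DEFAULT_RADIUS_UM
                             ) -> ColocalizationSummary:
    """Percent of cells colocalized, per experiment and per condition.

    SEM is taken across experiments (sd/sqrt(n_experiments)); the t-test
    compares per-experiment fractions between the two conditions when
    exactly two are present (error if either has < 2 experiments).
    """
    objects = _objects(table)
    per_cell = _per_cell_coloc(objects, locus_probe, marker_class, radius)
    per_exp = (
        per_cell.groupby(["condition", "experiment_id"], sort=True)
        .agg(n_cells=("colocalized", "size"), fraction=("colocalized", "mean"))
        .reset_index()
    )
    stats_rows = []
    for cond, grp in per_exp.groupby("condition", sort=True):
        fr = grp["fraction"].to_numpy()
        stats_rows.append(
            (cond, 100 * fr.mean(), 100 * sem(fr), len(fr))
        )
    condition_stats = pd.DataFrame(
        stats_rows, columns=["condition", "mean_pct", "sem_pct", "n_experiments"]
    )
    comparison = None
    conds = list(condition_stats["condition"])
    if len(conds) == 2:
        a = per_exp.loc[per_exp["condition"] == conds[0], "fraction"]
        b = per_exp.loc[per_exp["condition"] == conds[1], "fraction"]
        t, p = student_t(a, b)
        comparison = GroupComparison(t, p)
    return ColocalizationSummary(per_exp, condition_stats, comparison)


# ---------------------------------------------------------------------------
# minimal-area enclosing ellipse
# ---------------------------------------------------------------------------

def minimal_enclosing_ellipse(points, tol: float = 1e-3, max_iter: int = 10_000
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Khachiyan iteration for the minimum-volume enclosing ellipsoid.

    Returns (center, A) with the ellipse {x : (x-c)^T A (x-c) <= 1}.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    if n < d + 1:
        raise ValueError("need at least d+1 points")
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = P.T @ u
    cov = (P.T @ (u[:, None] * P)) - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return center, A


def fit_center(centromere_points, tol: float = 1e-3) -> tuple[float, float]:
    """Centre of the minimal-area ellipse enclosing a centromere point cloud.

    Requires >= 3 points; for 3-4 points the centroid is used (flagged in
    the log) since the enclosing ellipse is poorly conditioned there.
    Translation-equivariant.
    """
    pts = np.asarray(centromere_points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("fit_center requires at least 3 points")
    if len(pts) < 5:
        log.info("fewer than 5 centromere points; falling back to centroid")
        c = pts.mean(axis=0)
        return float(c[0]), float(c[1])
    center, _ = minimal_enclosing_ellipse(pts, tol=tol)
    return float(center[0]), float(center[1])


def locus_center_distance(center: tuple[float, float],
                          locus: tuple[float, float]) -> float:
    """Euclidean distance (μm) between the ellipse centre and a locus."""
    cx, cy = center
    x, y = locus
    return float(np.hypot(x - cx, y - cy))


@dataclass
class DistanceSummary:
    """Per-locus distances plus per-group (attached vs not) statistics."""

    per_locus: pd.DataFrame  # cell_id, experiment_id, condition, attached, distance
    group_stats: pd.DataFrame  # attached, mean_um, sem_um, n_experiments, n_loci
    comparison: GroupComparison | None

    def mean_um(self, attached: bool) -> float:
        row = self.group_stats.set_index("attached").loc[attached]
        return float(row["mean_um"])


def monopolar_distance_summary(table, locus_probe: str = "8q24",
                               marker_class: str = "if_mark",
                               radius: float = DEFAULT_RADIUS_UM
                               ) -> DistanceSummary:
    """Distance of each FISH locus from the centromere-cloud centre, grouped
    by marker (ectopic-kinetochore) status.

    Group means and SEM are computed across experiments (mean of per-locus
    distances within each experiment); the t-test compares per-experiment
    means between the two groups.
    """
    objects = _objects(table)
    rows = []
    for (cond, exp, cell), grp in objects.groupby(
        ["condition", "experiment_id", "cell_id"], sort=True
    ):
        cen = grp[grp["object_class"] == "centromere_point"][["x_um", "y_um"]]
        if len(cen) < 3:
            continue
        center = fit_center(cen.to_numpy())
        loci = grp[(grp["object_class"] == "fish_locus")
                   & (grp["probe"] == locus_probe)]
        marks = grp[grp["object_class"] == marker_class][["x_um", "y_um"]].to_numpy()
        for _, locus in loci.iterrows():
            pos = (locus["x_um"], locus["y_um"])
            if len(marks):
                d2 = ((marks - np.asarray(pos)) ** 2).sum(axis=1)
                attached = bool((d2 <= radius * radius).any())
            else:
                attached = False
            rows.append(
                (cell, exp, cond, attached, locus_center_distance(center, pos))
            )
    per_locus = pd.DataFrame(
        rows, columns=["cell_id", "experiment_id", "condition", "attached",
                       "distance_um"]
    )
    stats_rows = []
    per_exp_means: dict[bool, np.ndarray] = {}
    for attached, grp in per_locus.groupby("attached", sort=True):
        means = grp.groupby("experiment_id")["distance_um"].mean().to_numpy()
        per_exp_means[bool(attached)] = means
        stats_rows.append(
            (bool(attached), means.mean(), sem(means), len(means), len(grp))
        )
    group_stats = pd.DataFrame(
        stats_rows,
        columns=["attached", "mean_um", "sem_um", "n_experiments", "n_loci"],
    )
    comparison = None
    if len(per_exp_means) == 2 and all(len(v) >= 2 for v in per_exp_means.values()):
        t, p = student_t(per_exp_means[True], per_exp_means[False])
        comparison = GroupComparison(t, p)
    return DistanceSummary(per_locus, group_stats, comparison)


@dataclass
class LociCountSummary:
    per_cell: pd.DataFrame  # cell_id, experiment_id, condition, n_loci
    condition_stats: pd.DataFrame  # condition, mean, sem, n_experiments, n_cells
    comparison: GroupComparison | None

    def mean(self, condition: str) -> float:
        row = self.condition_stats.set_index("condition").loc[condition]
        return float(row["mean"])


def count_loci(table, probe: str = "8q24") -> LociCountSummary:
    """FISH loci per cell by condition: mean, SEM across experiments, t-test.

    Cells with zero loci of the probe count as 0 (the cell universe is all
    cells present in the table, not just cells carrying the probe).
    """
    objects = _objects(table)
    cells = objects[["cell_id", "experiment_id", "condition"]].drop_duplicates()
    loci = objects[(objects["object_class"] == "fish_locus")
                   & (objects["probe"] == probe)]
    counts = loci.groupby("cell_id").size().rename("n_loci")
    per_cell = cells.merge(counts, left_on="cell_id", right_index=True,
                           how="left").fillna({"n_loci": 0})
    per_cell["n_loci"] = per_cell["n_loci"].astype(int)
    stats_rows = []
    per_exp_means: dict[str, np.ndarray] = {}
    for cond, grp in per_cell.groupby("condition", sort=True):
        means = grp.groupby("experiment_id")["n_loci"].mean().to_numpy()
        per_exp_means[cond] = means
        stats_rows.append((cond, grp["n_loci"].mean(), sem(means), len(means),
                           len(grp)))
    condition_stats = pd.DataFrame(
        stats_rows, columns=["condition", "mean", "sem", "n_experiments",
                             "n_cells"]
    )
    comparison = None
    conds = list(condition_stats["condition"])
    if len(conds) == 2 and all(len(per_exp_means[c]) >= 2 for c in conds):
        t, p = student_t(per_exp_means[conds[0]], per_exp_means[conds[1]])
        comparison = GroupComparison(t, p)
    return LociCountSummary(per_cell, condition_stats, comparison)
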