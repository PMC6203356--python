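"""Imaging quantifications: colocalization scoring, enclosing-ellipse
centres, monopolar distances, loci counts, and rigid-motion invariance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import ectopeak as ep
from ectopeak.imaging import (
    count_loci,
    fit_center,
    locus_center_distance,
    minimal_enclosing_ellipse,
    monopolar_distance_summary,
    score_colocalization,
    summarize_colocalization,
)


def cell_df(objects):
    """objects: list of (class, probe, x, y) for one cell."""
    return pd.DataFrame(
        [("c1", "e1", "ctrl", cls, probe, x, y) for cls, probe, x, y in objects],
        columns=["cell_id", "experiment_id", "condition", "object_class",
                 "probe", "x_um", "y_um"],
    )


def mvee_center_oracle(points):
    """Independent oracle: solve the dual D-optimal design problem
    max log det sum u_i q_i q_i^T with SLSQP, center = sum u_i x_i."""
    P = np.asarray(points, float)
    n = len(P)
    Q = np.column_stack([P, np.ones(n)])

    def neg_logdet(u):
        X = Q.T @ (u[:, None] * Q)
        sign, ld = np.linalg.slogdet(X)
        return -ld if sign > 0 else 1e9

    cons = [{"type": "eq", "fun": lambda u: u.sum() - 1}]
    res = minimize(neg_logdet, np.full(n, 1.0 / n), method="SLSQP",
                   bounds=[(0, 1)] * n, constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    return P.T @ res.x


class TestScoreColocalization:
    def test_marker_at_locus_position(self):
        cell = cell_df([("fish_locus", "8q24", 5.0, 5.0),
                        ("if_mark", "", 5.0, 5.0)])
        assert score_colocalization(cell, "8q24", radius=0.5)

    def test_marker_at_twice_radius(self):
        cell = cell_df([("fish_locus", "8q24", 5.0, 5.0),
                        ("if_mark", "", 6.0, 5.0)])
        assert not score_colocalization(cell, "8q24", radius=0.5)

    def test_missing_probe_scores_false(self):
        cell = cell_df([("if_mark", "", 5.0, 5.0)])
        assert not score_colocalization(cell, "8q24", radius=0.5)

    def test_invalid_radius_rejected(self):
        cell = cell_df([("fish_locus", "8q24", 5.0, 5.0)])
        with pytest.raises(ValueError):
            score_colocalization(cell, "8q24", radius=0)

    def test_matches_all_pairs_distance_oracle(self, rng):
        for _ in range(30):
            n_loci = int(rng.integers(1, 6))
            n_marks = int(rng.integers(0, 4))
            loci = rng.uniform(0, 10, size=(n_loci, 2))
            marks = rng.uniform(0, 10, size=(n_marks, 2))
            objs = [("fish_locus", "8q24", x, y) for x, y in loci]
            objs += [("if_mark", "", x, y) for x, y in marks]
            cell = cell_df(objs)
            radius = float(rng.uniform(0.2, 3.0))
            expected = any(
                np.hypot(*(l - m)) <= radius for l in loci for m in marks
            )
            assert score_colocalization(cell, "8q24", radius=radius) == expected

    def test_monotone_in_radius(self, rng):
        table = ep.simulate_cells(n_cells=40, n_experiments=1,
                                  coloc_rate=0.5, seed=8)
        fracs = []
        for radius in [0.1, 0.5, 1.0, 3.0]:
            s = summarize_colocalization(table, radius=radius)
            fracs.append(s.per_experiment["fraction"].iloc[0])
        assert fracs == sorted(fracs)


class TestSummarizeColocalization:
    def test_all_cells_colocalized(self):
        table = ep.simulate_cells(n_cells=20, n_experiments=3, coloc_rate=1.0,
                                  seed=2)
        s = summarize_colocalization(table)
        assert s.mean_pct("control") == 100.0
        row = s.condition_stats.iloc[0]
        assert row["sem_pct"] == 0.0
        assert row["n_experiments"] == 3

    def test_planted_rates_recovered_and_separated(self):
        tables = [
            ep.simulate_cells(n_cells=200, n_experiments=3, coloc_rate=0.26,
                              seed=1, condition="control"),
            ep.simulate_cells(n_cells=200, n_experiments=3, coloc_rate=0.53,
                              seed=2, condition="knockdown"),
        ]
        objects = pd.concat([t.objects for t in tables], ignore_index=True)
        s = summarize_colocalization(objects)
        assert abs(s.mean_pct("control") - 26) < 8
        assert abs(s.mean_pct("knockdown") - 53) < 8
        assert s.comparison is not None and s.comparison.p < 0.05

    def test_scoring_agrees_with_truth_labels(self):
        table = ep.simulate_cells(n_cells=100, n_experiments=1,
                                  coloc_rate=0.4, seed=5)
        s = summarize_colocalization(table)
        truth_frac = table.cells["truth_colocalized"].mean()
        got = s.per_experiment["fraction"].iloc[0]
        assert got == pytest.approx(truth_frac, abs=0.02)


class TestFitCenter:
    def test_symmetric_cloud_centre_at_origin(self):
        pts = [(1, 0), (-1, 0), (0, 2), (0, -2), (1, 1), (-1, -1)]
        cx, cy = fit_center(pts)
        # exact centre is the origin; accuracy limited by iteration tol
        assert abs(cx) < 5e-3 and abs(cy) < 5e-3

    def test_translation_equivariance(self, rng):
        pts = rng.normal(0, 2, size=(30, 2))
        c0 = np.array(fit_center(pts))
        shift = np.array([13.7, -4.2])
        c1 = np.array(fit_center(pts + shift))
        assert np.allclose(c1, c0 + shift, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_center([(0, 0), (1, 1)])

    def test_centroid_fallback_below_five_points(self):
        pts = [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0), (4.0, 4.0)]
        cx, cy = fit_center(pts)
        assert (cx, cy) == pytest.approx((1.5, 1.5))

    def test_matches_convex_optimization_oracle(self, rng):
        """Khachiyan centre within 0.1 um of an SLSQP dual solve."""
        for _ in range(5):
            n = int(rng.integers(8, 50))
            pts = rng.normal(rng.uniform(-5, 5, 2), rng.uniform(0.5, 3),
                             size=(n, 2))
            ours = np.array(fit_center(pts, tol=1e-4))
            oracle = mvee_center_oracle(pts)[:2]
            assert np.linalg.norm(ours - oracle) < 0.1

    def test_all_points_inside_fitted_ellipse(self, rng):
        pts = rng.normal(0, 2, size=(40, 2))
        c, A = minimal_enclosing_ellipse(pts, tol=1e-5)
        d = pts - c
        vals = np.einsum("ij,jk,ik->i", d, A, d)
        assert np.all(vals <= 1 + 1e-3)


class TestDistances:
    def test_three_four_five(self):
        assert locus_center_distance((0, 0), (3, 4)) == 5.0
        assert locus_center_distance((2, 2), (2, 2)) == 0.0

    def test_monopolar_geometry_recovered(self):
        table = ep.simulate_cells(
            n_cells=60, n_experiments=3, coloc_rate=0.5, loci_mean=4,
            monastrol=ep.MonastrolGeometry(3.4, 4.5), seed=6,
        )
        s = monopolar_distance_summary(table)
        inner = s.mean_um(True)
        outer = s.mean_um(False)
        assert abs(inner - 3.4) < 0.3
        assert abs(outer - 4.5) < 0.3
        assert s.comparison is not None and s.comparison.p < 0.01


class TestCountLoci:
    def test_constant_counts(self):
        rows = []
        for e in ("e1", "e2"):
            for c in range(5):
                for _ in range(4):
                    rows.append((f"{e}c{c}", e, "ctrl", "fish_locus", "8q24",
                                 1.0, 1.0))
        objects = pd.DataFrame(
            rows, columns=["cell_id", "experiment_id", "condition",
                           "object_class", "probe", "x_um", "y_um"])
        s = count_loci(objects)
        assert s.mean("ctrl") == 4.0
        assert s.condition_stats.iloc[0]["sem"] == 0.0

    def test_cells_without_probe_count_zero(self):
        objects = pd.DataFrame(
            [
                ("c1", "e1", "ctrl", "fish_locus", "8q24", 1.0, 1.0),
                ("c2", "e1", "ctrl", "centromere_point", "", 2.0, 2.0),
            ],
            columns=["cell_id", "experiment_id", "condition", "object_class",
                     "probe", "x_um", "y_um"])
        s = count_loci(objects)
        assert s.mean("ctrl") == 0.5

    def test_poisson_means_recovered(self):
        tables = [
            ep.simulate_cells(n_cells=200, n_experiments=3, loci_mean=12.4,
                              coloc_rate=0.0, seed=3, condition="control"),
            ep.simulate_cells(n_cells=200, n_experiments=3, loci_mean=15.2,
                              coloc_rate=0.0, seed=4, condition="knockdown"),
        ]
        objects = pd.concat([t.objects for t in tables], ignore_index=True)
        s = count_loci(objects)
        se = np.sqrt(12.4 / 600)
        assert abs(s.mean("control") - 12.4) < 4 * se
        assert abs(s.mean("knockdown") - 15.2) < 4 * np.sqrt(15.2 / 600)
        assert s.comparison is not None and s.comparison.p < 0.01


class TestRigidMotionInvariance:
    def test_statistics_invariant_under_rotation_translation(self, rng):
        table = ep.simulate_cells(n_cells=30, n_experiments=2,
                                  coloc_rate=0.5, seed=9)
        objects = table.objects.copy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        xy = objects[["x_um", "y_um"]].to_numpy() @ R.T + np.array([5.0, -3.0])
        moved = objects.copy()
        moved[["x_um", "y_um"]] = xy

        s0 = summarize_colocalization(objects)
        s1 = summarize_colocalization(moved)
        pd.testing.assert_frame_equal(s0.per_experiment, s1.per_experiment)

        d0 = monopolar_distance_summary(objects)
        d1 = monopolar_distance_summary(moved)
        assert np.allclose(
            d0.per_locus["distance_um"], d1.per_locus["distance_um"], atol=1e-6
        )

        c0 = count_loci(objects)
        c1 = count_loci(moved)
        pd.testing.assert_frame_equal(c0.condition_stats, c1.condition_stats)
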