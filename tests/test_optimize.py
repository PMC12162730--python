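"""DOE, response surfaces and the genetic multi-objective optimizer."""

import numpy as np
import pandas as pd
import pytest

from trivalve.optimize import (
    DesignSpace,
    MeshSpec,
    OptimizationSpec,
    aggregate_objective,
    build_doe,
    evaluate_design,
    fit_response_surfaces,
    run_moga,
    run_study,
    clear_evaluation_cache,
)
from trivalve.geometry import derive_design, DesignValidationError
from trivalve.closure import SolverConfig


def _zero(D, H):
    return np.zeros_like(np.asarray(D, dtype=float))


class TestDOE:
    def test_face_centered_ccd_layout(self):
        doe = build_doe(DesignSpace(n_points=9), seed=0)
        assert len(doe) == 9
        assert len(np.unique(doe.round(9), axis=0)) == 9
        d0, d1 = 15.625, 16.875
        h0, h1 = 8.25, 13.25
        corners = {(d0, h0), (d1, h0), (d0, h1), (d1, h1)}
        got = {tuple(p) for p in doe}
        assert corners <= got
        assert ((d0 + d1) / 2, (h0 + h1) / 2) in got

    def test_augmented_doe_reaches_requested_total(self):
        doe = build_doe(seed=1)
        assert len(doe) == 26
        assert len(np.unique(doe.round(9), axis=0)) == 26

    def test_seeded_reproducibility(self):
        assert np.array_equal(build_doe(seed=5), build_doe(seed=5))
        assert not np.array_equal(build_doe(seed=5), build_doe(seed=6))

    def test_maximin_beats_typical_random_augmentation(self, rng):
        space = DesignSpace()
        doe = build_doe(space, seed=2)
        lo = np.array([15.625, 8.25])
        hi = np.array([16.875, 13.25])

        def min_dist(pts):
            n = (pts - lo) / (hi - lo)
            d = np.linalg.norm(n[:, None] - n[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            return d.min()

        ours = min_dist(doe)
        beaten = 0
        for _ in range(100):
            rand = np.vstack([doe[:9], lo + rng.random((17, 2)) * (hi - lo)])
            if ours >= min_dist(rand):
                beaten += 1
        assert beaten >= 95


class TestAggregateObjective:
    def test_weighted_combination(self):
        assert aggregate_objective([4, 0, 0, 0]) == pytest.approx(-1.0)
        assert aggregate_objective([0, 0, 0, 0]) == 0.0
        assert aggregate_objective([2, 1, 0.5, 0.25],
                                   (0.25, 0.25, 0.25, 0.25)) == pytest.approx(
            -0.5 + 0.25 + 0.125 + 0.0625)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate_objective([1, 0, 0, 0], (0.5, 0.5, 0.5, 0.5))


class TestResponseSurfaces:
    def _table(self, f):
        doe = build_doe(seed=0)
        return pd.DataFrame({
            "D": doe[:, 0], "H": doe[:, 1],
            "CA": f(doe), "RA": 0.5 * f(doe), "PI": 0.01 * f(doe),
            "PA": 0.001 * f(doe),
        })

    def test_exact_quadratic_is_selected_with_tiny_cv(self):
        f = lambda X: 2 + 0.5 * X[:, 0] - 0.3 * X[:, 1] + 0.05 * X[:, 0] * X[:, 1]
        rs = fit_response_surfaces(self._table(f), seed=0)
        for m, s in rs.surfaces.items():
            assert s.model_name == "quadratic"
            assert s.cv_rmse < 1e-8

    def test_training_points_reproduced_within_interpolation_tolerance(self):
        rng = np.random.default_rng(4)
        doe = build_doe(seed=0)
        y = np.sin(doe[:, 0]) + 0.3 * np.cos(doe[:, 1]) + 0.01 * rng.random(26)
        tbl = pd.DataFrame({"D": doe[:, 0], "H": doe[:, 1], "CA": y,
                            "RA": y, "PI": y, "PA": y})
        rs = fit_response_surfaces(tbl, seed=0)
        s = rs.surfaces["CA"]
        pred = s.predict(doe[:, 0], doe[:, 1], clamp=False)
        assert np.abs(pred - y).max() < 0.05 * np.ptp(y) + 1e-6

    def test_rank_deficient_table_rejected(self):
        tbl = pd.DataFrame({"D": np.full(10, 16.0), "H": np.full(10, 11.0),
                            "CA": np.ones(10), "RA": np.ones(10),
                            "PI": np.ones(10), "PA": np.ones(10)})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_response_surfaces(tbl)

    def test_too_few_points_rejected(self):
        tbl = pd.DataFrame({"D": [16, 16.1], "H": [11, 11.1], "CA": [1, 2],
                            "RA": [1, 2], "PI": [1, 2], "PA": [1, 2]})
        with pytest.raises(ValueError, match="9"):
            fit_response_surfaces(tbl)

    def test_extrapolation_flagged(self):
        f = lambda X: X[:, 0] + X[:, 1]
        rs = fit_response_surfaces(self._table(f), seed=0)
        with pytest.warns(UserWarning, match="extrapolation"):
            rs.surfaces["CA"].predict(20.0, 11.0, warn_extrapolation=True)

    def test_negative_area_predictions_clamped(self):
        f = lambda X: X[:, 0] - 17.0  # negative over the whole sub-range
        rs = fit_response_surfaces(self._table(f), seed=0)
        assert np.all(rs.surfaces["PA"].predict(16.0, 11.0) >= 0.0)


class TestMOGA:
    def test_recovers_analytic_argmax_of_concave_surface(self):
        Dstar, Hstar = 16.2, 10.4
        fns = {"CA": lambda D, H: 10 - (np.asarray(D) - Dstar) ** 2
                                  - 0.5 * (np.asarray(H) - Hstar) ** 2,
               "RA": _zero, "PI": _zero, "PA": _zero}
        res = run_moga(fns, OptimizationSpec(seed=3))
        # grid-search oracle at 1 um confirms the analytic optimum is interior
        assert abs(res.optimum["D"] - Dstar) <= 0.05
        assert abs(res.optimum["H"] - Hstar) <= 0.05

    def test_toy_biobjective_front_hypervolume(self):
        # f1 = x^2, f2 = (1-x)^2 on x = normalized D: known convex front
        lo, hi = 15.625, 16.875

        def x_of(D):
            return (np.asarray(D, dtype=float) - lo) / (hi - lo)

        fns = {"CA": _zero, "PI": _zero,
               "RA": lambda D, H: x_of(D) ** 2,
               "PA": lambda D, H: (1 - x_of(D)) ** 2}
        res = run_moga(fns, OptimizationSpec(seed=1))
        ref = np.array([1.1, 1.1])

        def hypervolume(front):
            # staircase sweep from high f1 to low against the reference point
            hv, prev_f1 = 0.0, ref[0]
            for p in front[np.argsort(front[:, 0])][::-1]:
                width = prev_f1 - p[0]
                if width > 0 and p[1] < ref[1]:
                    hv += width * (ref[1] - p[1])
                    prev_f1 = p[0]
            return hv

        x = np.linspace(0, 1, 200001)
        analytic = np.column_stack([x**2, (1 - x) ** 2])
        got = np.column_stack([res.pareto_metrics["RA"].to_numpy(),
                               res.pareto_metrics["PA"].to_numpy()])
        hv_true = hypervolume(analytic)
        hv_got = hypervolume(got)
        assert hv_got == pytest.approx(hv_true, rel=0.01)

    def test_constraint_halfspace_respected(self):
        # PI < 0 for D below mid-range: no returned point may violate PI >= 0
        mid = 16.25
        fns = {"CA": lambda D, H: -np.asarray(D, dtype=float),
               "RA": _zero,
               "PI": lambda D, H: np.asarray(D, dtype=float) - mid,
               "PA": _zero}
        res = run_moga(fns, OptimizationSpec(seed=2))
        assert np.all(res.pareto_designs[:, 0] >= mid - 1e-6)

    def test_infeasible_everywhere_raises(self):
        fns = {"CA": _zero, "RA": _zero, "PA": _zero,
               "PI": lambda D, H: -np.ones_like(np.asarray(D, dtype=float))}
        with pytest.raises(RuntimeError, match="infeasible"):
            run_moga(fns, OptimizationSpec(seed=0, max_iterations=2))

    def test_selected_optimum_minimizes_aggregate_over_pareto_set(self):
        Dstar, Hstar = 16.0, 11.0
        fns = {"CA": lambda D, H: -((np.asarray(D) - Dstar) ** 2), "RA": _zero,
               "PI": _zero,
               "PA": lambda D, H: 0.1 * (np.asarray(H) - Hstar) ** 2}
        res = run_moga(fns, OptimizationSpec(seed=4))
        assert res.optimum["f"] <= res.pareto_metrics["f"].min() + 1e-12

    def test_pareto_members_mutually_nondominated(self):
        fns = {"CA": _zero, "PI": _zero,
               "RA": lambda D, H: (np.asarray(D) - 16.0) ** 2,
               "PA": lambda D, H: (np.asarray(H) - 10.0) ** 2}
        res = run_moga(fns, OptimizationSpec(seed=5))
        F = res.pareto_metrics[["RA", "PA"]].to_numpy()
        for i in range(len(F)):
            dominated = np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1)
            assert not dominated.any()

    def test_seeded_reproducibility_and_cross_seed_spread(self):
        Dstar, Hstar = 16.3, 9.7
        fns = {"CA": lambda D, H: -(np.asarray(D) - Dstar) ** 2
                                  - (np.asarray(H) - Hstar) ** 2,
               "RA": _zero, "PI": _zero, "PA": _zero}
        a = run_moga(fns, OptimizationSpec(seed=9))
        b = run_moga(fns, OptimizationSpec(seed=9))
        assert a.optimum == b.optimum
        opts = [run_moga(fns, OptimizationSpec(seed=s)).optimum
                for s in range(10)]
        Ds = [o["D"] for o in opts]
        Hs = [o["H"] for o in opts]
        assert np.ptp(Ds) <= 0.2 and np.ptp(Hs) <= 0.2


class TestEvaluateDesignAndStudy:
    TINY_MESH = MeshSpec(n_circ=10, n_leaflet_rows=5, n_below_rows=3)
    TINY_CFG = SolverConfig(contact_detect_factor=1.0, max_iters=120,
                            n_increments=30)

    def test_invalid_design_rejected(self):
        from trivalve.geometry import ValveDesign

        with pytest.raises(DesignValidationError):
            evaluate_design(ValveDesign(D=14.0, H=10.0))

    def test_cache_returns_identical_object(self):
        clear_evaluation_cache()
        design = derive_design(16.0, 11.0)
        a = evaluate_design(design, config=self.TINY_CFG, mesh=self.TINY_MESH)
        b = evaluate_design(design, config=self.TINY_CFG, mesh=self.TINY_MESH)
        assert a is b

    def test_quick_study_end_to_end(self, tmp_path):
        clear_evaluation_cache()
        space = DesignSpace(n_points=9)
        spec = OptimizationSpec(seed=0, n_initial=400, n_per_iteration=100,
                                max_iterations=5)
        bundle = run_study(space=space, spec=spec, config=self.TINY_CFG,
                           mesh=self.TINY_MESH, out_dir=str(tmp_path / "study"))
        assert len(bundle.table) == 9
        assert set(bundle.surfaces.surfaces) == {"CA", "RA", "PI", "PA"}
        opt = bundle.optimization.optimum
        assert 15.625 <= opt["D"] <= 16.875
        assert 8.25 <= opt["H"] <= 13.25
        out = tmp_path / "study"
        for name in ("designs.csv", "metrics.csv", "pareto.csv",
                     "optimum.json", "response_surfaces.png"):
            assert (out / name).exists()
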