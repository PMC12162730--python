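"""Design-of-experiments, response surfaces and multi-objective optimization
over the (tube diameter D, leaflet height H) design space.

The study follows the response-surface-optimization pattern: a face-centered
central composite design (CCD) augmented with maximin Latin-hypercube points
samples the design space; each design point is run through construction,
closure and metric time-averaging; one surrogate per metric is selected from
an ensemble (full quadratic polynomial, kriging, thin-plate RBF) by
leave-one-out cross-validation; and an elitist non-dominated-sorting genetic
algorithm (NSGA-II style) searches the surrogates for the Pareto set of

    maximize CA,  minimize RA,  minimize PI,  minimize PA,

subject to PI >= 0 and PA >= 0.  The reported optimum minimizes the weighted
aggregate f = -w1 CA + w2 RA + w3 PI + w4 PA (weights sum to one; targets act
as aspiration levels for reporting, not constraints).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constitutive import AhyperParams, AHYPER_PRINTED
from .geometry import ValveDesign, derive_design, build_constructed_valve, validate_design
from .closure import PressureRamp, SolverConfig, simulate_closure
from .metrics import DesignEvaluation, metric_samples, time_average

__all__ = [
    "DesignSpace",
    "OptimizationSpec",
    "ResponseSurfaceSet",
    "OptimizationResult",
    "MeshSpec",
    "build_doe",
    "evaluate_design",
    "fit_response_surfaces",
    "aggregate_objective",
    "run_moga",
    "run_study",
    "StudyBundle",
]

METRIC_NAMES = ("CA", "RA", "PI", "PA")
METRIC_SENSE = {"CA": -1.0, "RA": 1.0, "PI": 1.0, "PA": 1.0}  # minimize sense * value


@dataclass(frozen=True)
class DesignSpace:
    """Admissible design ranges and the DOE sub-range actually sampled."""

    D_range: tuple[float, float] = (15.0, 16.875)
    H_range: tuple[float, float] = (7.0, 13.25)
    doe_D_range: tuple[float, float] = (15.625, 16.875)
    doe_H_range: tuple[float, float] = (8.25, 13.25)
    n_points: int = 26

    def __post_init__(self) -> None:
        for sub, full, name in ((self.doe_D_range, self.D_range, "D"),
                                (self.doe_H_range, self.H_range, "H")):
            if sub[0] < full[0] - 1e-12 or sub[1] > full[1] + 1e-12:
                raise ValueError(f"DOE {name} sub-range outside the design space")
        if self.n_points < 9:
            raise ValueError("need at least the 9 CCD points")


@dataclass(frozen=True)
class MeshSpec:
    """Meshing resolution used when evaluating designs."""

    n_circ: int = 18
    n_leaflet_rows: int = 9
    n_below_rows: int = 6


@dataclass(frozen=True)
class OptimizationSpec:
    """Weights, constraints, targets and genetic-algorithm settings."""

    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    targets: dict = field(default_factory=lambda: {"CA": 3.0, "RA": 0.0,
                                                   "PI": 0.0, "PA": 0.0})
    n_initial: int = 2000
    n_per_iteration: int = 400
    max_iterations: int = 20
    pareto_fraction: float = 0.7
    stability: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        for name in ("n_initial", "n_per_iteration", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def aggregate_objective(metrics: Sequence[float] | dict,
                        weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> float:
    """Weighted aggregate f = -w1 CA + w2 RA + w3 PI + w4 PA (to minimize)."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    if isinstance(metrics, dict):
        metrics = [metrics[n] for n in METRIC_NAMES]
    ca, ra, pi, pa = metrics
    w1, w2, w3, w4 = weights
    return float(-w1 * ca + w2 * ra + w3 * pi + w4 * pa)


# ---------------------------------------------------------------------------
# design of experiments
# ---------------------------------------------------------------------------


def _ccd_points(space: DesignSpace) -> np.ndarray:
    d0, d1 = space.doe_D_range
    h0, h1 = space.doe_H_range
    dm, hm = 0.5 * (d0 + d1), 0.5 * (h0 + h1)
    pts = [(d0, h0), (d1, h0), (d0, h1), (d1, h1),   # corners
           (d0, hm), (d1, hm), (dm, h0), (dm, h1),   # face centers
           (dm, hm)]                                  # center
    return np.array(pts)


def build_doe(space: DesignSpace = DesignSpace(), seed: int = 0,
              n_candidates: int = 100) -> np.ndarray:
    """Face-centered CCD augmented with maximin Latin-hypercube points.

    Among ``n_candidates`` seeded Latin-hypercube draws, the augmentation
    maximizing the minimum pairwise distance (in normalized coordinates,
    jointly with the CCD points) is kept.  Deterministic under ``seed``.
    """
    from scipy.stats import qmc

    ccd = _ccd_points(space)
    n_extra = space.n_points - len(ccd)
    if n_extra == 0:
        return ccd
    lo = np.array([space.doe_D_range[0], space.doe_H_range[0]])
    hi = np.array([space.doe_D_range[1], space.doe_H_range[1]])
    span = hi - lo
    ccd_n = (ccd - lo) / span
    best, best_score = None, -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_candidates):
        sampler = qmc.LatinHypercube(d=2, seed=rng.integers(2**31 - 1))
        cand = sampler.random(n_extra)
        pts = np.vstack([ccd_n, cand])
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(dists, np.inf)
        score = dists.min()
        if score > best_score:
            best, best_score = cand, score
    return np.vstack([ccd, lo + best * span])


# ---------------------------------------------------------------------------
# design evaluation (construction -> closure -> metrics)
# ---------------------------------------------------------------------------

_EVAL_CACHE: dict[str, DesignEvaluation] = {}


def _config_hash(*objs) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else default(o)
                       for o in objs], sort_keys=True, default=default)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def evaluate_design(
    design: ValveDesign,
    material: AhyperParams = AHYPER_PRINTED,
    ramp: PressureRamp = PressureRamp(),
    config: SolverConfig = SolverConfig(contact_detect_factor=1.0, max_iters=600),
    mesh: MeshSpec = MeshSpec(),
    n_average: int = 20,
    use_cache: bool = True,
) -> DesignEvaluation:
    """Time-averaged closure metrics of one design (cached by configuration)."""
    violations = validate_design(design.D, design.H)
    if violations:
        from .geometry import DesignValidationError

        raise DesignValidationError(violations)
    key = _config_hash(design, material, ramp, config, mesh, n_average)
    if use_cache and key in _EVAL_CACHE:
        return _EVAL_CACHE[key]
    surface = build_constructed_valve(
        design, n_circ=mesh.n_circ, n_leaflet_rows=mesh.n_leaflet_rows,
        n_below_rows=mesh.n_below_rows,
    )
    result = simulate_closure(surface, material, ramp, config)
    ev = time_average(metric_samples(result), n=n_average, design=design,
                      provenance=key)
    if use_cache:
        _EVAL_CACHE[key] = ev
    return ev


def clear_evaluation_cache() -> None:
    _EVAL_CACHE.clear()


# ---------------------------------------------------------------------------
# response surfaces
# ---------------------------------------------------------------------------


class _QuadraticSurrogate:
    """Full quadratic polynomial in (D, H), least squares."""

    name = "quadratic"

    def fit(self, X, y):
        self.coef, *_ = np.linalg.lstsq(self._basis(X), y, rcond=None)
        return self

    @staticmethod
    def _basis(X):
        d, h = X[:, 0], X[:, 1]
        return np.column_stack([np.ones_like(d), d, h, d * h, d**2, h**2])

    def predict(self, X):
        return self._basis(np.atleast_2d(X)) @ self.coef


class _KrigingSurrogate:
    """Gaussian-process regression with an RBF kernel."""

    name = "kriging"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        import warnings

        from sklearn.exceptions import ConvergenceWarning
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
            length_scale=[1.0, 2.0], length_scale_bounds=(1e-2, 1e2)
        ) + WhiteKernel(1e-8, (1e-12, 1e-1))
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=2,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            # hyperparameter bounds hitting their limits is acceptable here;
            # the ensemble CV decides whether the kriging member is used
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp.fit(X, y)
        return self

    def predict(self, X):
        return self.gp.predict(np.atleast_2d(X))


class _RBFSurrogate:
    """Thin-plate-spline radial basis interpolant."""

    name = "rbf"

    def fit(self, X, y):
        from scipy.interpolate import RBFInterpolator

        self.rbf = RBFInterpolator(X, y, kernel="thin_plate_spline", smoothing=1e-10)
        return self

    def predict(self, X):
        return self.rbf(np.atleast_2d(X))


def _loo_rmse(maker: Callable, X: np.ndarray, y: np.ndarray) -> float:
    errs = []
    for i in range(len(X)):
        m = np.ones(len(X), dtype=bool)
        m[i] = False
        try:
            model = maker().fit(X[m], y[m])
            errs.append(float(model.predict(X[i:i + 1])[0] - y[i]))
        except Exception:
            errs.append(np.inf)
    return float(np.sqrt(np.mean(np.square(errs))))


@dataclass
class ResponseSurface:
    metric: str
    model: object
    model_name: str
    cv_rmse: float
    cv_rmse_all: dict
    train_X: np.ndarray
    train_y: np.ndarray
    doe_D_range: tuple[float, float]
    doe_H_range: tuple[float, float]

    def predict(self, D, H, clamp: bool = True,
                warn_extrapolation: bool = False) -> np.ndarray:
        X = np.column_stack([np.atleast_1d(D), np.atleast_1d(H)])
        out = np.asarray(self.model.predict(X), dtype=float)
        if warn_extrapolation:
            inside = ((X[:, 0] >= self.doe_D_range[0]) & (X[:, 0] <= self.doe_D_range[1])
                      & (X[:, 1] >= self.doe_H_range[0]) & (X[:, 1] <= self.doe_H_range[1]))
            if not inside.all():
                import warnings

                warnings.warn(f"{self.metric} surrogate evaluated outside the "
                              "DOE sub-range (extrapolation)", stacklevel=2)
        if clamp and self.metric in ("CA", "RA", "PA"):
            out = np.maximum(out, 0.0)
        return out

    def training_residual(self) -> float:
        pred = np.asarray(self.model.predict(self.train_X))
        return float(np.max(np.abs(pred - self.train_y)))


@dataclass
class ResponseSurfaceSet:
    surfaces: dict
    table: pd.DataFrame

    def predict_all(self, D, H, clamp: bool = True) -> dict:
        return {m: self.surfaces[m].predict(D, H, clamp=clamp)
                for m in METRIC_NAMES}


def fit_response_surfaces(table: pd.DataFrame, seed: int = 0) -> ResponseSurfaceSet:
    """One CV-selected surrogate per metric from a (D, H, CA, RA, PI, PA) table.

    Candidate surrogates (quadratic polynomial, kriging, thin-plate RBF) are
    ranked by leave-one-out RMSE; the best is kept and all scores reported.
    """
    if len(table) < 9:
        raise ValueError("at least 9 training points required")
    X = table[["D", "H"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(_QuadraticSurrogate._basis(X)) < 6:
        raise ValueError("design table is rank-deficient for a quadratic fit")
    surfaces = {}
    for m in METRIC_NAMES:
        y = table[m].to_numpy(dtype=float)
        makers = {
            "quadratic": lambda: _QuadraticSurrogate(),
            "kriging": lambda: _KrigingSurrogate(seed),
            "rbf": lambda: _RBFSurrogate(),
        }
        scores = {name: _loo_rmse(mk, X, y) for name, mk in makers.items()}
        best = min(scores, key=scores.get)
        model = makers[best]().fit(X, y)
        surfaces[m] = ResponseSurface(
            metric=m, model=model, model_name=best, cv_rmse=scores[best],
            cv_rmse_all=scores, train_X=X, train_y=y,
            doe_D_range=(X[:, 0].min(), X[:, 0].max()),
            doe_H_range=(X[:, 1].min(), X[:, 1].max()),
        )
    return ResponseSurfaceSet(surfaces=surfaces, table=table.copy())


# ---------------------------------------------------------------------------
# NSGA-II multi-objective genetic optimization
# ---------------------------------------------------------------------------


def _nondominated_sort(F: np.ndarray, cv: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sorting with feasibility dominance.

    i dominates j if (both feasible and i is Pareto-better), or i is feasible
    and j is not, or both are infeasible and i violates less.
    """
    n = len(F)
    feas = cv <= 1e-12
    dominates = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if feas[i]:
            better = (F[i] <= F).all(axis=1) & (F[i] < F).any(axis=1)
            dominates[i] = (feas & better) | ~feas
        else:
            dominates[i] = (~feas) & (cv > cv[i])
        dominates[i, i] = False
    n_dominators = dominates.sum(axis=0)
    fronts: list[np.ndarray] = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        front = np.where((n_dominators == 0) & ~assigned)[0]
        if len(front) == 0:  # numerical safety net
            front = np.where(~assigned)[0]
        fronts.append(front)
        assigned[front] = True
        n_dominators = n_dominators - dominates[front].sum(axis=0)
        n_dominators[assigned] = -1
    return fronts


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j])
        span = F[order[-1], j] - F[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        dist[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return dist


@dataclass
class OptimizationResult:
    pareto_designs: np.ndarray       # (n_p, 2)
    pareto_metrics: pd.DataFrame     # columns CA RA PI PA f
    candidates: pd.DataFrame         # top candidate points incl. optimum
    optimum: dict                    # D, H, metrics, aggregate f
    n_evaluations: int
    n_iterations: int
    converged_by: str
    seed: int


def run_moga(
    surfaces: ResponseSurfaceSet | dict,
    spec: OptimizationSpec = OptimizationSpec(),
    space: DesignSpace = DesignSpace(),
    search_full_space: bool = False,
) -> OptimizationResult:
    """Elitist non-dominated-sorting genetic optimization on the surrogates.

    ``surfaces`` is a ResponseSurfaceSet or a dict of callables
    ``{metric: f(D, H) -> value}``.  The search covers the DOE sub-range by
    default (surrogate validity), optionally the full design space.
    Constraints PI >= 0 and PA >= 0 enter through feasibility dominance.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if search_full_space:
        lo = np.array([space.D_range[0], space.H_range[0]])
        hi = np.array([space.D_range[1], space.H_range[1]])
    else:
        lo = np.array([space.doe_D_range[0], space.doe_H_range[0]])
        hi = np.array([space.doe_D_range[1], space.doe_H_range[1]])

    def evaluate(X: np.ndarray):
        if isinstance(surfaces, ResponseSurfaceSet):
            vals = {m: surfaces.surfaces[m].predict(X[:, 0], X[:, 1], clamp=False)
                    for m in METRIC_NAMES}
        else:
            vals = {m: np.asarray(surfaces[m](X[:, 0], X[:, 1]), dtype=float)
                    for m in METRIC_NAMES}
        F = np.column_stack([METRIC_SENSE[m] * vals[m] for m in METRIC_NAMES])
        cv = np.maximum(0.0, -vals["PI"]) + np.maximum(0.0, -vals["PA"])
        return vals, F, cv

    n_eval = 0
    X = lo + rng.random((spec.n_initial, 2)) * (hi - lo)
    vals, F, cv = evaluate(X)
    n_eval += len(X)
    pop = spec.n_per_iteration

    def select(Xa, Fa, cva, k):
        fronts = _nondominated_sort(Fa, cva)
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + len(front) <= k:
                chosen.extend(front.tolist())
            else:
                crowd = _crowding(Fa[front])
                order = front[np.argsort(-crowd)]
                chosen.extend(order[: k - len(chosen)].tolist())
                break
        return np.array(chosen, dtype=int)

    idx = select(X, F, cv, pop)
    X, F, cv = X[idx], F[idx], cv[idx]

    eta_c, eta_m = 15.0, 20.0
    prev_score = None
    converged_by = "max_iterations"
    it = 0
    for it in range(1, spec.max_iterations + 1):
        # tournament selection on rank proxy (aggregate of front status + crowding)
        fronts = _nondominated_sort(F, cv)
        rank = np.empty(len(X), dtype=int)
        for r, fr in enumerate(fronts):
            rank[fr] = r
        crowd = np.zeros(len(X))
        for fr in fronts:
            crowd[fr] = _crowding(F[fr])

        def tournament(n):
            a = rng.integers(0, len(X), n)
            b = rng.integers(0, len(X), n)
            take_a = (rank[a] < rank[b]) | ((rank[a] == rank[b]) & (crowd[a] >= crowd[b]))
            return np.where(take_a, a, b)

        p1 = tournament(pop)
        p2 = tournament(pop)
        # SBX crossover
        u = rng.random((pop, 2))
        beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta_c + 1)),
                        (1 / (2 * (1 - u))) ** (1 / (eta_c + 1)))
        child = 0.5 * ((1 + beta) * X[p1] + (1 - beta) * X[p2])
        # polynomial mutation
        do_mut = rng.random((pop, 2)) < 0.2
        um = rng.random((pop, 2))
        delta = np.where(um < 0.5, (2 * um) ** (1 / (eta_m + 1)) - 1,
                         1 - (2 * (1 - um)) ** (1 / (eta_m + 1)))
        child = np.where(do_mut, child + delta * (hi - lo), child)
        child = np.clip(child, lo, hi)
        cvals, cF, ccv = evaluate(child)
        n_eval += len(child)
        Xa = np.vstack([X, child])
        Fa = np.vstack([F, cF])
        cva = np.concatenate([cv, ccv])
        idx = select(Xa, Fa, cva, pop)
        X, F, cv = Xa[idx], Fa[idx], cva[idx]

        fronts = _nondominated_sort(F, cv)
        pareto_frac = len(fronts[0]) / len(X)
        feasible = cv <= 1e-12
        score = float(np.mean(F[feasible].sum(axis=1))) if feasible.any() else float(
            np.mean(F.sum(axis=1)))
        if pareto_frac >= spec.pareto_fraction:
            converged_by = "pareto_fraction"
            break
        if prev_score is not None and abs(score - prev_score) <= spec.stability * max(
                abs(prev_score), 1e-12):
            converged_by = "stability"
            break
        prev_score = score

    fronts = _nondominated_sort(F, cv)
    front = fronts[0]
    feasible_front = front[cv[front] <= 1e-12]
    if len(feasible_front) == 0:
        if (cv <= 1e-12).any():
            feasible_front = np.where(cv <= 1e-12)[0]
        else:
            raise RuntimeError("constraints infeasible everywhere: empty Pareto set")
    Xp = X[feasible_front]
    vals, Fp, _ = evaluate(Xp)
    metrics = {m: np.maximum(vals[m], 0.0) if m in ("CA", "RA", "PA") else vals[m]
               for m in METRIC_NAMES}
    f_agg = np.array([
        aggregate_objective([metrics["CA"][i], metrics["RA"][i], metrics["PI"][i],
                             metrics["PA"][i]], spec.weights)
        for i in range(len(Xp))
    ])
    order = np.argsort(f_agg)
    pareto_df = pd.DataFrame({
        "D": Xp[:, 0], "H": Xp[:, 1],
        **{m: metrics[m] for m in METRIC_NAMES}, "f": f_agg,
    }).iloc[order].reset_index(drop=True)
    n_cand = min(3, len(pareto_df))
    candidates = pareto_df.head(n_cand).copy()
    for m, tgt in OptimizationSpec().targets.items():
        candidates[f"target_{m}"] = tgt
    best = pareto_df.iloc[0]
    optimum = {"D": float(best.D), "H": float(best.H), "f": float(best.f),
               **{m: float(best[m]) for m in METRIC_NAMES}}
    return OptimizationResult(
        pareto_designs=Xp[order],
        pareto_metrics=pareto_df,
        candidates=candidates,
        optimum=optimum,
        n_evaluations=n_eval,
        n_iterations=it,
        converged_by=converged_by,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    doe: np.ndarray
    evaluations: list[DesignEvaluation]
    table: pd.DataFrame
    surfaces: ResponseSurfaceSet
    optimization: OptimizationResult


def run_study(
    space: DesignSpace = DesignSpace(),
    material: AhyperParams = AHYPER_PRINTED,
    spec: OptimizationSpec = OptimizationSpec(),
    ramp: PressureRamp = PressureRamp(),
    config: SolverConfig = SolverConfig(contact_detect_factor=1.0, max_iters=600),
    mesh: MeshSpec = MeshSpec(),
    out_dir: str | None = None,
    progress: bool = False,
) -> StudyBundle:
    """DOE -> closure evaluations -> response surfaces -> genetic optimization.

    Evaluations are cached by configuration hash, so an interrupted study
    resumes from completed designs.  With ``out_dir`` the study writes
    designs.csv, metrics.csv, pareto.csv, optimum.json and per-metric
    response-surface plots.
    """
    doe = build_doe(space, seed=spec.seed)
    evals = []
    for i, (d, h) in enumerate(doe):
        if progress:
            print(f"[{i + 1}/{len(doe)}] evaluating D={d:.3f} H={h:.3f}")
        evals.append(evaluate_design(derive_design(d, h), material, ramp, config, mesh))
    table = pd.DataFrame([{"D": e.design.D, "H": e.design.H, "CA": e.CA,
                           "RA": e.RA, "PI": e.PI, "PA": e.PA} for e in evals])
    surfaces = fit_response_surfaces(table, seed=spec.seed)
    result = run_moga(surfaces, spec, space)
    bundle = StudyBundle(doe=doe, evaluations=evals, table=table,
                         surfaces=surfaces, optimization=result)
    if out_dir is not None:
        _write_study(bundle, out_dir, spec)
    return bundle


def _write_study(bundle: StudyBundle, out_dir: str, spec: OptimizationSpec) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(bundle.doe, columns=["D", "H"]).to_csv(
        os.path.join(out_dir, "designs.csv"), index=False)
    bundle.table.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    bundle.optimization.pareto_metrics.to_csv(
        os.path.join(out_dir, "pareto.csv"), index=False)
    with open(os.path.join(out_dir, "optimum.json"), "w") as fh:
        json.dump({**bundle.optimization.optimum,
                   "n_evaluations": bundle.optimization.n_evaluations,
                   "converged_by": bundle.optimization.converged_by,
                   "seed": spec.seed,
                   "surrogates": {m: s.model_name
                                  for m, s in bundle.surfaces.surfaces.items()},
                   "cv_rmse": {m: s.cv_rmse
                               for m, s in bundle.surfaces.surfaces.items()}},
                  fh, indent=2)
    _plot_surfaces(bundle, os.path.join(out_dir, "response_surfaces.png"))


def _plot_surfaces(bundle: StudyBundle, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = bundle.table[["D", "H"]].to_numpy()
    fig, axes = plt.subplots(2, 2, figsize=(10, 8), constrained_layout=True)
    d = np.linspace(X[:, 0].min(), X[:, 0].max(), 60)
    h = np.linspace(X[:, 1].min(), X[:, 1].max(), 60)
    DD, HH = np.meshgrid(d, h)
    opt = bundle.optimization.optimum
    for ax, m in zip(axes.ravel(), METRIC_NAMES):
        Z = bundle.surfaces.surfaces[m].predict(DD.ravel(), HH.ravel()).reshape(DD.shape)
        im = ax.contourf(DD, HH, Z, levels=20, cmap="viridis")
        ax.plot(X[:, 0], X[:, 1], "k.", ms=4)
        ax.plot(opt["D"], opt["H"], "r*", ms=14)
        ax.set_title(m)
        ax.set_xlabel("D [mm]")
        ax.set_ylabel("H [mm]")
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=110)
    plt.close(fig)
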