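"""Hyperelastic constitutive models for biologically-engineered tissue tubes.

Two strain-energy densities are provided:

* An anisotropic hyperelastic model ("AHYPER") combining a third-order
  reduced-polynomial isotropic matrix term, two exponential fiber families
  (circumferential and axial), and a quadratic volumetric penalty:

      W = sum_i a_i (I1 - 3)^i
        + c1/(2 c2) [exp(c2 (I4 - 1)^2) - 1]
        + e1/(2 e2) [exp(e2 (I6 - 1)^2) - 1]
        + (1/d) (J - 1)^2

  with I1 = tr(C), I4 = a0.C.a0, I6 = b0.C.b0 and J = det F.  The fiber
  families default to the tube circumferential (x) and axial (y) axes.

* A one-term compressible Ogden-foam model ("HYPERFOAM"):

      W = mu/alpha (lam1^a + lam2^a + lam3^a - 3)
        + mu/(alpha beta) (J^(-alpha beta) - 1)

  whose small-strain limit (true-stress vs true-strain) has shear modulus
  G0 = mu alpha / 2, Poisson ratio nu = beta / (1 + 2 beta) and Young's
  modulus E0 = mu alpha (1 + nu).

Units are MPa for stresses/energies throughout; strains are true (logarithmic)
strains and stretches are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, root

__all__ = [
    "AhyperParams",
    "HyperfoamParams",
    "DeformationState",
    "StressStrainCurve",
    "InvalidDeformationError",
    "AHYPER_PRINTED",
    "HYPERFOAM_PURPLE",
    "HYPERFOAM_ORANGE",
    "ahyper_energy",
    "hyperfoam_energy",
    "cauchy_stress",
    "mode_response",
    "incompressibility_error",
    "fit_model",
    "engineering_to_true",
    "true_to_engineering",
]

Mode = Literal["equibiaxial_tension", "uniaxial_tension", "unconfined_compression"]
Direction = Literal["circumferential", "axial", "through_thickness"]


class InvalidDeformationError(ValueError):
    """Raised for non-physical deformation states (non-positive stretch, det F <= 0)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AhyperParams:
    """Constants of the anisotropic hyperelastic energy.

    a1..a3 : isotropic polynomial coefficients [MPa]
    c1, c2 : circumferential fiber prefactor [MPa] and exponent [-]
    e1, e2 : axial fiber prefactor [MPa] and exponent [-]
    d      : incompressibility parameter [1/MPa]; d = 0 means the volumetric
             term is dropped and incompressibility must be enforced externally.
    """

    a1: float
    a2: float
    a3: float
    c1: float
    c2: float
    e1: float
    e2: float
    d: float

    def __post_init__(self) -> None:
        if self.c2 <= 0 or self.e2 <= 0:
            raise ValueError("fiber exponents c2, e2 must be positive")
        if self.d < 0:
            raise ValueError("incompressibility parameter d must be >= 0")

    @property
    def names(self) -> tuple[str, ...]:
        return ("a1", "a2", "a3", "c1", "c2", "e1", "e2", "d")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names])


@dataclass(frozen=True)
class HyperfoamParams:
    """Constants of the one-term Ogden-foam energy.

    mu    : shear modulus [MPa]
    alpha : stiffening exponent [-]
    beta  : volumetric coupling constant [-]; Poisson ratio nu = beta/(1+2 beta)
    """

    mu: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("shear modulus mu must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def poisson(self) -> float:
        return self.beta / (1.0 + 2.0 * self.beta)

    @property
    def shear_modulus_0(self) -> float:
        """Initial shear modulus of the energy as written: G0 = mu * alpha / 2."""
        return 0.5 * self.mu * self.alpha

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus (true-stress/true-strain slope),
        E0 = 2 G0 (1 + nu) = mu * alpha * (1 + nu)."""
        return 2.0 * self.shear_modulus_0 * (1.0 + self.poisson)

    @property
    def names(self) -> tuple[str, ...]:
        return ("mu", "alpha", "beta")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.alpha, self.beta])


#: Equibiaxial-tension fit of the engineered tubes (high strain rate).
AHYPER_PRINTED = AhyperParams(
    a1=0.0001, a2=0.2, a3=0.34, c1=0.44, c2=7.6, e1=0.000001, e2=3.5, d=0.002
)

#: Ogden-foam fit focused on unconfined-compression data.
HYPERFOAM_PURPLE = HyperfoamParams(mu=0.01, alpha=14.5, beta=0.0689)

#: Ogden-foam fit including direction-averaged tension data.
HYPERFOAM_ORANGE = HyperfoamParams(mu=0.01, alpha=27.8, beta=0.274)

PRESETS = {
    "ahyper_printed": AHYPER_PRINTED,
    "hyperfoam_purple": HYPERFOAM_PURPLE,
    "hyperfoam_orange": HYPERFOAM_ORANGE,
}


# ---------------------------------------------------------------------------
# deformation state
# ---------------------------------------------------------------------------


@dataclass
class DeformationState:
    """Homogeneous deformation described by its gradient F and reference fibers.

    ``fiber_circ`` and ``fiber_axial`` are unit vectors in the reference frame
    (defaults: x and y).  Invariants are derived properties.
    """

    F: np.ndarray
    fiber_circ: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    fiber_axial: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        if np.linalg.det(self.F) <= 0:
            raise InvalidDeformationError("det F must be positive")
        for name in ("fiber_circ", "fiber_axial"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be a nonzero vector")
            setattr(self, name, v / n)

    @classmethod
    def from_stretches(
        cls,
        l1: float,
        l2: float,
        l3: float,
        fiber_circ: Sequence[float] = (1.0, 0.0, 0.0),
        fiber_axial: Sequence[float] = (0.0, 1.0, 0.0),
    ) -> "DeformationState":
        if min(l1, l2, l3) <= 0:
            raise InvalidDeformationError("principal stretches must be positive")
        return cls(np.diag([l1, l2, l3]), np.asarray(fiber_circ), np.asarray(fiber_axial))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I4(self) -> float:
        return float(self.fiber_circ @ self.C @ self.fiber_circ)

    @property
    def I6(self) -> float:
        return float(self.fiber_axial @ self.C @ self.fiber_axial)

    @property
    def principal_stretches(self) -> np.ndarray:
        return np.sqrt(np.linalg.eigvalsh(self.C))


@dataclass
class StressStrainCurve:
    """A single test curve: true strain vs true (Cauchy) stress [MPa]."""

    mode: Mode
    direction: Direction
    strain: np.ndarray
    stress: np.ndarray
    strain_rate: str = "unspecified"

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if len(self.strain) > 1 and not np.all(np.diff(self.strain) != 0):
            raise ValueError("strain abscissa must be strictly monotone")


def engineering_to_true(eng_strain, eng_stress):
    """Convert engineering strain/stress to true measures (incompressible rod)."""
    eng_strain = np.asarray(eng_strain, dtype=float)
    eng_stress = np.asarray(eng_stress, dtype=float)
    return np.log1p(eng_strain), eng_stress * (1.0 + eng_strain)


def true_to_engineering(true_strain, true_stress):
    true_strain = np.asarray(true_strain, dtype=float)
    lam = np.exp(true_strain)
    return lam - 1.0, np.asarray(true_stress, dtype=float) / lam


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def ahyper_energy(
    state: DeformationState,
    params: AhyperParams,
    *,
    printed_form: bool = False,
    fiber_compression: bool = True,
) -> float:
    """Strain-energy density [MPa] of the anisotropic model.

    Invariants enter as printed (unscaled I1, I4 = lambda1^2, I6 =
    lambda2^2); the model therefore carries a negligible rest stress
    2 a1 = 2e-4 MPa at the identity while its energy is exactly zero.

    ``printed_form=True`` switches the fiber terms to exp(c2 (I4-1)^2 - 1)
    (nonzero rest energy) for comparison purposes; the default form subtracts
    one outside the exponential so that W(identity) = 0.
    ``fiber_compression=False`` deactivates the fiber terms when the fiber
    family is shorter than its reference length (I < 1).
    """
    I1, I4, I6, J = state.I1, state.I4, state.I6, state.J
    x = I1 - 3.0
    w = params.a1 * x + params.a2 * x**2 + params.a3 * x**3
    for pre, expo, inv in ((params.c1, params.c2, I4), (params.e1, params.e2, I6)):
        if not fiber_compression and inv < 1.0:
            continue
        q = expo * (inv - 1.0) ** 2
        if printed_form:
            w += pre / (2.0 * expo) * np.exp(q - 1.0)
        else:
            w += pre / (2.0 * expo) * np.expm1(q)
    if params.d > 0:
        w += (J - 1.0) ** 2 / params.d
    return float(w)


def hyperfoam_energy(state: DeformationState, params: HyperfoamParams) -> float:
    """Strain-energy density [MPa] of the Ogden-foam model.

    Written in terms of isochoric stretches, J^(alpha/3) * lam_bar_i^alpha
    collapses to lam_i^alpha, which is the form evaluated here.
    """
    lam = state.principal_stretches
    J = state.J
    mu, a, b = params.mu, params.alpha, params.beta
    return float(mu / a * (np.sum(lam**a) - 3.0) + mu / (a * b) * (J ** (-a * b) - 1.0))


# ---------------------------------------------------------------------------
# stresses
# ---------------------------------------------------------------------------


def _ahyper_w_derivs(I1: float, I4: float, I6: float, p: AhyperParams,
                     fiber_compression: bool = True) -> tuple[float, float, float]:
    """Partial derivatives (dW/dI1, dW/dI4, dW/dI6)."""
    x = I1 - 3.0
    w1 = p.a1 + 2.0 * p.a2 * x + 3.0 * p.a3 * x**2
    w4 = p.c1 * (I4 - 1.0) * np.exp(p.c2 * (I4 - 1.0) ** 2)
    w6 = p.e1 * (I6 - 1.0) * np.exp(p.e2 * (I6 - 1.0) ** 2)
    if not fiber_compression:
        if I4 < 1.0:
            w4 = 0.0
        if I6 < 1.0:
            w6 = 0.0
    return w1, w4, w6


def cauchy_stress(
    state: DeformationState,
    params: AhyperParams | HyperfoamParams,
    *,
    fiber_compression: bool = True,
) -> np.ndarray:
    """True (Cauchy) stress tensor [MPa], sigma = (1/J) F (2 dW/dC) F^T.

    For the AHYPER model with d = 0 the volumetric term is absent and the
    returned stress is the constitutively determinate part only (a pressure
    must be supplied by the boundary-value problem).
    """
    F = state.F
    J = state.J
    if isinstance(params, AhyperParams):
        w1, w4, w6 = _ahyper_w_derivs(state.I1, state.I4, state.I6, params,
                                      fiber_compression)
        a0, b0 = state.fiber_circ, state.fiber_axial
        S = 2.0 * (w1 * np.eye(3) + w4 * np.outer(a0, a0) + w6 * np.outer(b0, b0))
        sig = (F @ S @ F.T) / J
        if params.d > 0:
            # volumetric: dW/dJ * J * C^{-1} pushed forward gives an isotropic term
            sig += (2.0 / params.d) * (J - 1.0) * np.eye(3)
    elif isinstance(params, HyperfoamParams):
        C = state.C
        evals, evecs = np.linalg.eigh(C)
        lam = np.sqrt(evals)
        mu, a, b = params.mu, params.alpha, params.beta
        sig_p = (mu / J) * (lam**a - J ** (-a * b))
        sig = np.zeros((3, 3))
        for s, v in zip(sig_p, evecs.T):
            n = F @ v
            n /= np.linalg.norm(n)
            sig += s * np.outer(n, n)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return 0.5 * (sig + sig.T)


def _diag_stress(lams: np.ndarray, params, incompressible: bool) -> np.ndarray:
    """Diagonal Cauchy stress for an axis-aligned stretch state.

    Fibers along axes 0 (circumferential) and 1 (axial).  When
    ``incompressible`` the volumetric contribution is omitted (pressure handled
    by the caller via stress differences).
    """
    l1, l2, l3 = lams
    J = l1 * l2 * l3
    if isinstance(params, AhyperParams):
        I1 = l1**2 + l2**2 + l3**2
        w1, w4, w6 = _ahyper_w_derivs(I1, l1**2, l2**2, params)
        sig = (2.0 / J) * np.array(
            [l1**2 * (w1 + w4), l2**2 * (w1 + w6), l3**2 * w1]
        )
        if not incompressible and params.d > 0:
            sig += (2.0 / params.d) * (J - 1.0)
        return sig
    mu, a, b = params.mu, params.alpha, params.beta
    lam = np.array([l1, l2, l3])
    return (mu / J) * (lam**a - J ** (-a * b))


class SolverError(RuntimeError):
    """Root-finding failure in a deformation-mode driver."""


_BRACKET = (0.3, 3.0)


def _solve_transverse(prescribed: dict[int, float], params, incompressible: bool,
                      guess: dict[int, float] | None = None) -> np.ndarray:
    """Solve for the free principal stretches with zero transverse stress.

    ``prescribed`` maps axis index -> stretch.  Free axes carry sigma = 0.
    Incompressible: J = 1 enforced, pressure eliminated through stress
    differences; this leaves at most one free unknown for the modes used here.
    """
    free = [i for i in range(3) if i not in prescribed]
    lams = np.ones(3)
    for i, v in prescribed.items():
        lams[i] = v
    if guess:
        for i, v in guess.items():
            if i in free:
                lams[i] = v

    if incompressible:
        if len(free) == 1:
            i = free[0]
            prod = np.prod([lams[j] for j in prescribed])
            lams[i] = 1.0 / prod
            return lams
        # two free axes: J=1 ties them; solve the stress-difference equation
        i, k = free

        def eq(x: float) -> float:
            lam = lams.copy()
            lam[i] = x
            lam[k] = 1.0 / (x * np.prod([lam[j] for j in prescribed]))
            s = _diag_stress(lam, params, incompressible=True)
            return s[i] - s[k]

        lo, hi = _BRACKET
        try:
            xi = brentq(eq, lo, hi, xtol=1e-12, rtol=1e-12, maxiter=200)
        except ValueError as err:
            raise SolverError(
                f"no bracketed root for free stretch in {list(prescribed)} "
                f"mode: {err}"
            ) from err
        lams[i] = xi
        lams[k] = 1.0 / (xi * np.prod([lams[j] for j in prescribed]))
        return lams

    # compressible: solve sigma_free = 0 with a vector root find
    def eqs(x: np.ndarray) -> np.ndarray:
        lam = lams.copy()
        for idx, val in zip(free, x):
            lam[idx] = val
        s = _diag_stress(lam, params, incompressible=False)
        return np.array([s[idx] for idx in free])

    x0 = np.array([lams[idx] for idx in free])
    sol = root(eqs, x0, method="hybr")
    # accept on flag or residual: hybr may report tolerance exhaustion after
    # converging far below any mechanically relevant stress level
    scale = max(np.max(np.abs(_diag_stress(lams, params, False))), 1e-6)
    resid_ok = np.max(np.abs(eqs(sol.x))) <= 1e-6 * scale
    if np.any(sol.x <= 0) or not (sol.success or resid_ok):
        raise SolverError(
            f"transverse-stress root finding failed: {sol.message}; "
            f"prescribed={prescribed}, last x={sol.x}"
        )
    for idx, val in zip(free, sol.x):
        lams[idx] = val
    return lams


def mode_response(
    params: AhyperParams | HyperfoamParams,
    mode: Mode,
    strain_grid: np.ndarray,
    *,
    direction: Direction = "circumferential",
    compressibility: Literal["as_fitted", "incompressible"] = "as_fitted",
    strain_rate: str = "unspecified",
) -> StressStrainCurve:
    """True-stress response of a homogeneous test mode on a true-strain grid.

    equibiaxial_tension : in-plane stretches prescribed equal, thickness free
    uniaxial_tension    : stretch along ``direction`` prescribed, others free
    unconfined_compression : through-thickness stretch prescribed, others free

    The reported stress component follows ``direction``.
    """
    strain_grid = np.asarray(strain_grid, dtype=float)
    if np.any(strain_grid <= -1.0):
        raise ValueError("true strain grid must lie in (-1, inf)")
    axis = {"circumferential": 0, "axial": 1, "through_thickness": 2}[direction]
    incomp = compressibility == "incompressible"
    if isinstance(params, AhyperParams) and params.d == 0:
        incomp = True

    stresses = np.empty_like(strain_grid)
    guess: dict[int, float] = {}
    for i, eps in enumerate(strain_grid):
        lam = float(np.exp(eps))
        if mode == "equibiaxial_tension":
            prescribed = {0: lam, 1: lam}
        elif mode == "uniaxial_tension":
            prescribed = {axis: lam}
        elif mode == "unconfined_compression":
            prescribed = {2: lam}
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if eps == 0.0:
            stresses[i] = 0.0
            continue
        if not incomp:
            # warm start from the incompressible solution: with a stiff bulk
            # term the root finder needs to begin near J = 1
            li = _solve_transverse(prescribed, params, True, guess=guess)
            guess = {j: li[j] for j in range(3) if j not in prescribed}
        lams = _solve_transverse(prescribed, params, incomp, guess=guess)
        guess = {j: lams[j] for j in range(3) if j not in prescribed}
        if incomp:
            s = _diag_stress(lams, params, incompressible=True)
            free = [j for j in range(3) if j not in prescribed]
            # pressure from the (stress-free) free axis
            p = s[free[0]] if free else 0.0
            stresses[i] = s[axis] - p
        else:
            stresses[i] = _diag_stress(lams, params, incompressible=False)[axis]
    return StressStrainCurve(
        mode=mode, direction=direction, strain=strain_grid, stress=stresses,
        strain_rate=strain_rate,
    )


def incompressibility_error(
    params: AhyperParams,
    strain_max: float = 0.25,
    n: int = 25,
) -> float:
    """Max relative deviation [%] of uniaxial circumferential stress between the
    nearly-incompressible model (its own d) and the incompressible limit.

    Strains below 1% are excluded to avoid division by vanishing stress.
    """
    if strain_max > 0.25 + 1e-12:
        raise ValueError("strain_max exceeds the fitted range (0.25)")
    grid = np.linspace(0.01, strain_max, n)
    comp = mode_response(params, "uniaxial_tension", grid,
                         compressibility="as_fitted").stress
    inc = mode_response(params, "uniaxial_tension", grid,
                        compressibility="incompressible").stress
    return float(np.max(np.abs(comp - inc) / np.abs(inc)) * 100.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_AHYPER_DEFAULT_INIT = AhyperParams(1e-4, 0.1, 0.1, 0.1, 5.0, 1e-6, 3.5, 0.002)
_HYPERFOAM_DEFAULT_INIT = HyperfoamParams(0.01, 10.0, 0.1)


@dataclass
class FitResult:
    """Outcome of a least-squares material calibration."""

    params: AhyperParams | HyperfoamParams
    rmse_per_curve: list[float]
    total_rmse: float
    success: bool
    message: str
    n_points: int
    free_names: tuple[str, ...]


def _predict_curve(params, curve: StressStrainCurve,
                   compressibility="as_fitted") -> np.ndarray:
    return mode_response(
        params, curve.mode, curve.strain, direction=curve.direction,
        compressibility=compressibility,
    ).stress


def fit_model(
    curves: Sequence[StressStrainCurve],
    model: Literal["ahyper", "hyperfoam"] = "ahyper",
    *,
    init: AhyperParams | HyperfoamParams | None = None,
    free: Sequence[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    weights: Sequence[float] | None = None,
    compressibility: Literal["as_fitted", "incompressible"] = "incompressible",
) -> FitResult:
    """Least-squares calibration of a constitutive model to stress-strain curves.

    ``free`` restricts the optimized parameter subset (remaining values held at
    ``init``); by default the identifiable subset (a2, a3, c1, c2) is fitted
    for AHYPER and all three constants for HYPERFOAM.  Residuals are summed
    squared true-stress errors across curves, optionally weighted per curve.
    """
    if len(curves) == 0:
        raise ValueError("at least one curve is required")
    if model == "ahyper":
        p0 = init or _AHYPER_DEFAULT_INIT
        free = tuple(free) if free is not None else ("a2", "a3", "c1", "c2")
        default_bounds = {
            "a1": (0.0, 10.0), "a2": (0.0, 10.0), "a3": (0.0, 10.0),
            "c1": (1e-8, 10.0), "c2": (1e-3, 50.0),
            "e1": (0.0, 10.0), "e2": (1e-3, 50.0), "d": (0.0, 1.0),
        }
    elif model == "hyperfoam":
        p0 = init or _HYPERFOAM_DEFAULT_INIT
        free = tuple(free) if free is not None else ("mu", "alpha", "beta")
        default_bounds = {"mu": (1e-6, 10.0), "alpha": (0.5, 60.0),
                          "beta": (1e-4, 5.0)}
    else:
        raise ValueError(f"unknown model {model!r}")
    if bounds:
        default_bounds.update(bounds)

    n_points = int(sum(len(c.strain) for c in curves))
    if n_points <= len(free):
        raise ValueError(
            f"under-determined fit: {n_points} data points for {len(free)} "
            "free parameters"
        )
    w = np.ones(len(curves)) if weights is None else np.asarray(weights, float)
    if len(w) != len(curves):
        raise ValueError("one weight per curve required")

    x0 = np.array([getattr(p0, n) for n in free])
    lo = np.array([default_bounds[n][0] for n in free])
    hi = np.array([default_bounds[n][1] for n in free])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def make_params(x: np.ndarray):
        return replace(p0, **dict(zip(free, x)))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = make_params(x)
        res = []
        for curve, wi in zip(curves, w):
            try:
                pred = _predict_curve(p, curve, compressibility)
            except SolverError:
                pred = np.full_like(curve.stress, 1e3)
            res.append(np.sqrt(wi) * (pred - curve.stress))
        return np.concatenate(res)

    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12)
    fitted = make_params(sol.x)
    rmses = []
    for curve in curves:
        pred = _predict_curve(fitted, curve, compressibility)
        rmses.append(float(np.sqrt(np.mean((pred - curve.stress) ** 2))))
    total = float(np.sqrt(np.mean(np.concatenate([
        _predict_curve(fitted, c, compressibility) - c.stress for c in curves
    ]) ** 2)))
    return FitResult(
        params=fitted, rmse_per_curve=rmses, total_rmse=total,
        success=bool(sol.success), message=str(sol.message),
        n_points=n_points, free_names=free,
    )
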