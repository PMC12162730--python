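"""Quasi-static diastolic closure of the constructed valve.

The valve surface is treated as a thin anisotropic membrane (constant-strain
triangles carrying the plane-stress incompressible limit of the anisotropic
tissue model) with weak discrete-hinge bending.  Back pressure ramps linearly
to its peak over 1 s and holds for 0.5 s; at every load increment a static
equilibrium is found by dynamic relaxation with kinetic damping.  Leaflets
interact through frictionless penalty self-contact; both valve end rings are
fully fixed.

Units: mm - MPa - N; pressures are supplied in Pa and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.spatial import cKDTree

from .constitutive import AhyperParams, AHYPER_PRINTED
from .geometry import ValveSurface, LEAFLET_CODES, REGION_CODES

__all__ = [
    "PressureRamp",
    "SolverConfig",
    "ClosureResult",
    "pressure_at",
    "simulate_closure",
    "coaptation_length",
    "PA_TO_MPA",
]

PA_TO_MPA = 1e-6
MMHG_PER_PA = 1.0 / 133.322387415


@dataclass(frozen=True)
class PressureRamp:
    """Linear pressure ramp with hold: p(t) = peak * min(t / ramp, 1)."""

    peak_pa: float = 1000.0
    ramp_s: float = 1.0
    hold_s: float = 0.5

    @property
    def total_s(self) -> float:
        return self.ramp_s + self.hold_s

    @property
    def peak_mmhg(self) -> float:
        return self.peak_pa * MMHG_PER_PA


def pressure_at(t: float, ramp: PressureRamp) -> float:
    """Pressure [Pa] at pseudo-time t in [0, ramp + hold]."""
    if t < 0 or t > ramp.total_s + 1e-12:
        raise ValueError(f"t = {t} outside [0, {ramp.total_s}]")
    return ramp.peak_pa * min(t / ramp.ramp_s, 1.0)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the dynamic-relaxation closure solver.

    thickness            : wall thickness [mm] (None -> take from the surface)
    bending_modulus      : effective modulus for the hinge bending stiffness
                           k_b = E_b t^3 / 12 [MPa]
    contact_penalty      : penalty stiffness [N/mm^3]
    contact_detect_factor: detection distance as a fraction of thickness
    n_increments         : load increments along the pressure ramp (>= 30)
    n_hold_snapshots     : equilibrium snapshots inside the hold window (>= 20)
    residual_tol_rel     : equilibrium tolerance relative to the applied load
    max_iters            : relaxation iteration cap per increment
    dt_min               : floor for adaptive pseudo-time stepping [s]; the
                           dynamic relaxation itself advances in unit pseudo
                           steps with stiffness-proportional mass scaling, so
                           this acts only as a configuration record
    """

    thickness: float | None = None
    bending_modulus: float = 1.0
    membrane_scale: float = 1.0
    contact_penalty: float = 0.5
    contact_detect_factor: float = 0.5
    n_increments: int = 30
    n_hold_snapshots: int = 21
    residual_tol_rel: float = 0.02
    max_iters: int = 1200
    dt_min: float = 1e-4
    contact_every: int = 5
    wrinkling: bool = False
    record_energy: bool = False
    density: float = 1e-9  # nominal tissue density [N s^2 / mm^4]; statics-irrelevant
    seed: int = 0  # unused: the solver is deterministic

    def __post_init__(self) -> None:
        for name in ("bending_modulus", "membrane_scale", "contact_penalty",
                     "contact_detect_factor", "residual_tol_rel", "dt_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_increments < 1 or self.max_iters < 1:
            raise ValueError("iteration counts must be positive")


class ElementInversionError(RuntimeError):
    def __init__(self, faces: np.ndarray):
        self.faces = faces
        super().__init__(f"membrane elements inverted: faces {faces[:10].tolist()}"
                         + ("..." if len(faces) > 10 else ""))


@dataclass
class ClosureResult:
    """Time series of equilibrium states under the pressure ramp."""

    surface: ValveSurface
    times: np.ndarray
    pressures_pa: np.ndarray
    snapshots: list[np.ndarray]            # vertex arrays per snapshot
    contact_pairs: list[np.ndarray]        # (n_c, 4): vertex, face_a, face_b, gap
    residuals: np.ndarray                  # accepted residual per snapshot [N]
    load_norms: np.ndarray                 # applied-load norm per snapshot [N]
    reaction_force: np.ndarray             # (n_snap, 3) summed end reactions [N]
    applied_force: np.ndarray              # (n_snap, 3) integrated pressure load [N]
    converged: np.ndarray
    energy_history: list[np.ndarray]       # potential energy at damping restarts
    config: SolverConfig

    def surface_at(self, i: int) -> ValveSurface:
        return self.surface.with_vertices(self.snapshots[i])

    @property
    def hold_indices(self) -> np.ndarray:
        ramp_end = self.times[self.pressures_pa.argmax()]
        return np.where(self.times >= ramp_end - 1e-12)[0]

    def contact_face_mask(self, i: int) -> np.ndarray:
        mask = np.zeros(len(self.surface.faces), dtype=bool)
        pairs = self.contact_pairs[i]
        if len(pairs):
            mask[pairs[:, 1].astype(int)] = True
            mask[pairs[:, 2].astype(int)] = True
        return mask


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------


def _sym2_eig(m11, m12, m22):
    """Eigen-decomposition of symmetric 2x2 fields: (l1, l2, c, s) with
    eigenvector (c, s) for l1 and (-s, c) for l2."""
    tr = 0.5 * (m11 + m22)
    dd = 0.5 * (m11 - m22)
    rad = np.sqrt(dd**2 + m12**2)
    l1, l2 = tr + rad, tr - rad
    # eigenvector for l1
    c = np.where(rad > 1e-30, dd + rad, 1.0)
    s = np.where(rad > 1e-30, m12, 0.0)
    n = np.sqrt(c**2 + s**2)
    small = n < 1e-30
    c = np.where(small, 1.0, c / np.maximum(n, 1e-30))
    s = np.where(small, 0.0, s / np.maximum(n, 1e-30))
    return l1, l2, c, s


def _relax_compression(S11, S12, S22, c11, c12, c22):
    """Tension-field relaxation: zero the compressive principal part of the
    membrane stress.  Principal tensions are the eigenvalues of
    M = C^(1/2) S C^(1/2) (congruent to the surface Cauchy stress); the
    negative part of M is removed and S reassembled as C^(-1/2) M+ C^(-1/2).
    """
    # C^(1/2) for 2x2 SPD: (C + sqrt(det C) I) / sqrt(tr C + 2 sqrt(det C))
    sdet = np.sqrt(np.maximum(c11 * c22 - c12**2, 1e-30))
    tau = np.sqrt(np.maximum(c11 + c22 + 2.0 * sdet, 1e-30))
    h11, h12, h22 = (c11 + sdet) / tau, c12 / tau, (c22 + sdet) / tau
    # M = H S H
    t11 = h11 * S11 + h12 * S12
    t12 = h11 * S12 + h12 * S22
    t21 = h12 * S11 + h22 * S12
    t22 = h12 * S12 + h22 * S22
    m11 = t11 * h11 + t12 * h12
    m12 = t11 * h12 + t12 * h22
    m22 = t21 * h12 + t22 * h22
    l1, l2, c, s = _sym2_eig(m11, m12, m22)
    l1p, l2p = np.maximum(l1, 0.0), np.maximum(l2, 0.0)
    m11p = l1p * c**2 + l2p * s**2
    m12p = (l1p - l2p) * c * s
    m22p = l1p * s**2 + l2p * c**2
    # H^(-1)
    dh = np.maximum(h11 * h22 - h12**2, 1e-30)
    i11, i12, i22 = h22 / dh, -h12 / dh, h11 / dh
    u11 = i11 * m11p + i12 * m12p
    u12 = i11 * m12p + i12 * m22p
    u21 = i12 * m11p + i22 * m12p
    u22 = i12 * m12p + i22 * m22p
    return (u11 * i11 + u12 * i12,
            u11 * i12 + u12 * i22,
            u21 * i12 + u22 * i22)


def _scatter_matrix(rows: np.ndarray, n_vertices: int):
    """Sparse accumulator: (n_vertices x len(rows)) with unit entries."""
    from scipy.sparse import csr_matrix

    cols = np.arange(len(rows))
    return csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(n_vertices, len(rows)))


class _Membrane:
    """Precomputed reference quantities for CST membrane elements.

    With ``wrinkling`` enabled the membrane follows a tension-field response:
    compressive principal membrane stresses are relaxed to zero, which is the
    standard thin-film treatment - a membrane wrinkles out of plane instead of
    supporting in-plane compression.  Without it the taut-membrane response is
    the exact gradient of the stored energy.
    """

    def __init__(self, surface: ValveSurface, params: AhyperParams, thickness: float,
                 scale: float, wrinkling: bool = False):
        self.params = params
        self.thickness = thickness
        self.scale = scale
        self.wrinkling = wrinkling
        tri = surface.triangles()
        d1 = tri[:, 1] - tri[:, 0]
        d2 = tri[:, 2] - tri[:, 0]
        n = np.cross(d1, d2)
        self.area0 = 0.5 * np.linalg.norm(n, axis=1)
        e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        nn = n / np.linalg.norm(n, axis=1, keepdims=True)
        e2 = np.cross(nn, e1)
        # reference edge matrix in the local 2-D frame and its inverse
        Dm = np.empty((len(tri), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", d1, e1)
        Dm[:, 1, 0] = np.einsum("ij,ij->i", d1, e2)
        Dm[:, 0, 1] = np.einsum("ij,ij->i", d2, e1)
        Dm[:, 1, 1] = np.einsum("ij,ij->i", d2, e2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
        self.invDm = np.empty_like(Dm)
        self.invDm[:, 0, 0] = Dm[:, 1, 1] / det
        self.invDm[:, 0, 1] = -Dm[:, 0, 1] / det
        self.invDm[:, 1, 0] = -Dm[:, 1, 0] / det
        self.invDm[:, 1, 1] = Dm[:, 0, 0] / det
        # fiber directions projected into the local frame
        def project(v):
            a1 = np.einsum("ij,ij->i", v, e1)
            a2 = np.einsum("ij,ij->i", v, e2)
            norm = np.sqrt(a1**2 + a2**2)
            norm = np.maximum(norm, 1e-12)
            return a1 / norm, a2 / norm

        self.a1, self.a2 = project(surface.fiber_circ)
        self.b1, self.b2 = project(surface.fiber_axial)
        self.faces = surface.faces
        n_v = len(surface.vertices)
        self.scatter = _scatter_matrix(
            np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]]),
            n_v,
        )

    def _invariants(self, V: np.ndarray):
        tri = V[self.faces]
        Ds = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)
        F = np.einsum("fik,fkj->fij", Ds, self.invDm)  # (M, 3, 2)
        c11 = np.einsum("fi,fi->f", F[:, :, 0], F[:, :, 0])
        c12 = np.einsum("fi,fi->f", F[:, :, 0], F[:, :, 1])
        c22 = np.einsum("fi,fi->f", F[:, :, 1], F[:, :, 1])
        detC = c11 * c22 - c12**2
        return F, c11, c12, c22, detC

    def energy(self, V: np.ndarray) -> float:
        _, c11, c12, c22, detC = self._invariants(V)
        if np.any(detC <= 0):
            raise ElementInversionError(np.where(detC <= 0)[0])
        lam3sq = 1.0 / detC
        I1 = c11 + c22 + lam3sq
        I4 = self.a1**2 * c11 + 2 * self.a1 * self.a2 * c12 + self.a2**2 * c22
        I6 = self.b1**2 * c11 + 2 * self.b1 * self.b2 * c12 + self.b2**2 * c22
        p = self.params
        x = I1 - 3.0
        w = p.a1 * x + p.a2 * x**2 + p.a3 * x**3
        w = w + p.c1 / (2 * p.c2) * np.expm1(p.c2 * (I4 - 1.0) ** 2)
        w = w + p.e1 / (2 * p.e2) * np.expm1(p.e2 * (I6 - 1.0) ** 2)
        return float(np.sum(w * self.area0 * self.thickness * self.scale))

    def forces(self, V: np.ndarray, out: np.ndarray) -> None:
        F, c11, c12, c22, detC = self._invariants(V)
        if np.any(detC <= 0):
            raise ElementInversionError(np.where(detC <= 0)[0])
        lam3sq = 1.0 / detC
        I1 = c11 + c22 + lam3sq
        I4 = self.a1**2 * c11 + 2 * self.a1 * self.a2 * c12 + self.a2**2 * c22
        I6 = self.b1**2 * c11 + 2 * self.b1 * self.b2 * c12 + self.b2**2 * c22
        p = self.params
        x = I1 - 3.0
        w1 = p.a1 + 2 * p.a2 * x + 3 * p.a3 * x**2
        w4 = p.c1 * (I4 - 1.0) * np.exp(p.c2 * (I4 - 1.0) ** 2)
        w6 = p.e1 * (I6 - 1.0) * np.exp(p.e2 * (I6 - 1.0) ** 2)
        # S = 2 w1 (I2 - lam3^2 Cinv) + 2 w4 a x a + 2 w6 b x b  (2x2, symmetric)
        icd = lam3sq / detC  # lam3^2 / detC
        S11 = 2 * (w1 * (1.0 - icd * c22) + w4 * self.a1**2 + w6 * self.b1**2)
        S22 = 2 * (w1 * (1.0 - icd * c11) + w4 * self.a2**2 + w6 * self.b2**2)
        S12 = 2 * (w1 * (icd * c12) + w4 * self.a1 * self.a2 + w6 * self.b1 * self.b2)
        if self.wrinkling:
            S11, S12, S22 = _relax_compression(S11, S12, S22, c11, c12, c22)
        # P = F S ; nodal forces f_(1,2) = -t A P invDm^T, f_0 = -(f_1 + f_2)
        P1 = F[:, :, 0] * S11[:, None] + F[:, :, 1] * S12[:, None]
        P2 = F[:, :, 0] * S12[:, None] + F[:, :, 1] * S22[:, None]
        coef = (self.thickness * self.scale * self.area0)[:, None]
        g1 = -coef * (P1 * self.invDm[:, 0, 0, None] + P2 * self.invDm[:, 0, 1, None])
        g2 = -coef * (P1 * self.invDm[:, 1, 0, None] + P2 * self.invDm[:, 1, 1, None])
        g0 = -(g1 + g2)
        out += self.scatter @ np.concatenate([g0, g1, g2])

    def vertex_stiffness(self, V: np.ndarray) -> np.ndarray:
        """Per-vertex tangent-stiffness bound [N/mm] at the current state,
        used for dynamic-relaxation mass scaling."""
        _, c11, c12, c22, detC = self._invariants(V)
        detC = np.maximum(detC, 1e-12)
        lam3sq = 1.0 / detC
        I1 = c11 + c22 + lam3sq
        I4 = self.a1**2 * c11 + 2 * self.a1 * self.a2 * c12 + self.a2**2 * c22
        I6 = self.b1**2 * c11 + 2 * self.b1 * self.b2 * c12 + self.b2**2 * c22
        lam2max = 0.5 * (c11 + c22) + np.sqrt(0.25 * (c11 - c22) ** 2 + c12**2)
        lam2max = np.maximum(lam2max, lam3sq)
        p = self.params
        x = I1 - 3.0
        w1 = np.abs(p.a1 + 2 * p.a2 * x + 3 * p.a3 * x**2)
        w1p = np.abs(2 * p.a2 + 6 * p.a3 * x)
        q4 = p.c2 * (I4 - 1.0) ** 2
        q6 = p.e2 * (I6 - 1.0) ** 2
        w4t = p.c1 * np.exp(q4) * (1.0 + 2.0 * q4)
        w6t = p.e1 * np.exp(q6) * (1.0 + 2.0 * q6)
        e_tan = 4.0 * lam2max * (w1 + 2.0 * lam2max * w1p + w4t + w6t)
        ell2 = 4.0 * self.area0 / np.sqrt(3.0)  # characteristic edge length^2
        k_face = e_tan * self.thickness * self.scale * self.area0 / ell2
        k = np.zeros(len(V))
        np.add.at(k, self.faces[:, 0], k_face)
        np.add.at(k, self.faces[:, 1], k_face)
        np.add.at(k, self.faces[:, 2], k_face)
        return k


class _Hinges:
    """Discrete-hinge bending between adjacent triangles."""

    def __init__(self, surface: ValveSurface, stiffness: float):
        from collections import defaultdict

        edge_faces: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
        for fi, f in enumerate(surface.faces):
            for k in range(3):
                a, b = int(f[k]), int(f[(k + 1) % 3])
                edge_faces[(min(a, b), max(a, b))].append((fi, int(f[(k + 2) % 3])))
        quads = []  # x0, x1 shared; xa, xb opposite
        face_pairs = []
        for (a, b), lst in edge_faces.items():
            if len(lst) == 2:
                quads.append((a, b, lst[0][1], lst[1][1]))
                face_pairs.append((lst[0][0], lst[1][0]))
        self.quads = np.array(quads, dtype=int) if quads else np.zeros((0, 4), int)
        V = surface.vertices
        self.k_hinge = np.zeros(len(self.quads))
        self.theta0 = np.zeros(len(self.quads))
        if len(self.quads):
            fp = np.array(face_pairs, dtype=int)
            e_len = np.linalg.norm(V[self.quads[:, 1]] - V[self.quads[:, 0]], axis=1)
            areas = surface.face_areas()
            # stiffness k = E_b t^3 / 12 * 3 |e|^2 / (A1 + A2)  (discrete shells)
            area_sum = areas[fp[:, 0]] + areas[fp[:, 1]]
            self.k_hinge = stiffness * e_len**2 * 3.0 / area_sum
            self.theta0 = self._angles(V)
            self.scatter = _scatter_matrix(
                np.concatenate([self.quads[:, c] for c in range(4)]), len(V))

    def _geometry(self, V: np.ndarray):
        q = self.quads
        x0, x1, xa, xb = V[q[:, 0]], V[q[:, 1]], V[q[:, 2]], V[q[:, 3]]
        e0 = x1 - x0
        na = np.cross(e0, xa - x0)
        nb = np.cross(xb - x0, e0)
        return x0, x1, xa, xb, e0, na, nb

    def _angles(self, V: np.ndarray) -> np.ndarray:
        if not len(self.quads):
            return np.zeros(0)
        _, _, _, _, e0, na, nb = self._geometry(V)
        e_hat = e0 / np.linalg.norm(e0, axis=1, keepdims=True)
        na_h = na / np.linalg.norm(na, axis=1, keepdims=True)
        nb_h = nb / np.linalg.norm(nb, axis=1, keepdims=True)
        cos = np.einsum("ij,ij->i", na_h, nb_h)
        sin = np.einsum("ij,ij->i", np.cross(na_h, nb_h), e_hat)
        return np.arctan2(sin, cos)

    def energy(self, V: np.ndarray) -> float:
        if not len(self.quads):
            return 0.0
        th = self._angles(V)
        d = th - self.theta0
        # wrap to (-pi, pi]
        d = (d + np.pi) % (2 * np.pi) - np.pi
        return float(0.5 * np.sum(self.k_hinge * d**2))

    def forces(self, V: np.ndarray, out: np.ndarray) -> None:
        if not len(self.quads):
            return
        q = self.quads
        x0, x1, xa, xb, e0, na, nb = self._geometry(V)
        elen = np.linalg.norm(e0, axis=1)
        na2 = np.einsum("ij,ij->i", na, na)
        nb2 = np.einsum("ij,ij->i", nb, nb)
        # dihedral angle from the same geometry (avoid a second pass)
        cos = np.einsum("ij,ij->i", na, nb) / np.sqrt(na2 * nb2)
        sin = np.einsum("ij,ij->i", np.cross(na, nb), e0) / (
            np.sqrt(na2 * nb2) * elen)
        th = np.arctan2(sin, cos)
        d = (th - self.theta0 + np.pi) % (2 * np.pi) - np.pi
        # the ga/gb blocks below equal -grad(theta); force = -k d grad(theta)
        m = self.k_hinge * d
        ga = (elen / na2)[:, None] * na
        gb = (elen / nb2)[:, None] * nb
        ta = np.einsum("ij,ij->i", xa - x0, e0) / elen**2
        tb = np.einsum("ij,ij->i", xb - x0, e0) / elen**2
        g0 = -(1 - ta)[:, None] * ga - (1 - tb)[:, None] * gb
        g1 = -ta[:, None] * ga - tb[:, None] * gb
        mm = m[:, None]
        out += self.scatter @ np.concatenate([mm * g0, mm * g1, mm * ga, mm * gb])


class _Contact:
    """Frictionless penalty contact between leaflets (vertex vs. face)."""

    def __init__(self, surface: ValveSurface, penalty: float, detect: float):
        self.penalty = penalty
        self.detect = detect
        self.faces = surface.faces
        region = surface.region
        self.leaflet_of_face = np.full(len(self.faces), -1, dtype=int)
        for li, code in enumerate(LEAFLET_CODES):
            self.leaflet_of_face[region == code] = li
        self.leaflet_of_vertex = np.full(len(surface.vertices), -1, dtype=int)
        # boundary vertices shared with the wall stay out of contact (leaflet
        # interiors do the coapting); assign vertices on leaflet-only faces
        from collections import Counter

        owner: dict[int, set[int]] = {}
        for fi, f in enumerate(self.faces):
            li = self.leaflet_of_face[fi]
            for v in f:
                owner.setdefault(int(v), set()).add(li)
        for v, owners in owner.items():
            if -1 in owners:
                continue
            owners.discard(-1)
            if len(owners) == 1:
                self.leaflet_of_vertex[v] = owners.pop()
        self.candidate_vertices = np.where(self.leaflet_of_vertex >= 0)[0]
        areas = surface.face_areas()
        varea = np.zeros(len(surface.vertices))
        np.add.at(varea, self.faces[:, 0], areas / 3)
        np.add.at(varea, self.faces[:, 1], areas / 3)
        np.add.at(varea, self.faces[:, 2], areas / 3)
        self.vertex_area = varea
        self.leaflet_faces_idx = [
            np.where(self.leaflet_of_face == li)[0] for li in range(3)
        ]
        self._pairs: np.ndarray = np.zeros((0, 2), dtype=int)  # (vertex, face)

    def update_pairs(self, V: np.ndarray) -> None:
        """Refresh candidate vertex-face pairs with a centroid KD-tree."""
        pairs = []
        centroids = V[self.faces].mean(axis=1)
        # generous search radius: detection distance + face circumradius bound
        tri = V[self.faces]
        rad = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
        search = self.detect + float(rad.max())
        for li in range(3):
            verts = self.candidate_vertices[
                self.leaflet_of_vertex[self.candidate_vertices] == li
            ]
            if not len(verts):
                continue
            other = np.concatenate(
                [self.leaflet_faces_idx[lj] for lj in range(3) if lj != li]
            )
            tree = cKDTree(centroids[other])
            hits = tree.query_ball_point(V[verts], search)
            for v, hit in zip(verts, hits):
                for h in hit:
                    pairs.append((v, other[h]))
        self._pairs = (np.array(pairs, dtype=int) if pairs
                       else np.zeros((0, 2), dtype=int))

    def _closest(self, V: np.ndarray):
        """Closest points of candidate vertex-face pairs."""
        if not len(self._pairs):
            return None
        p = V[self._pairs[:, 0]]
        tri = V[self.faces[self._pairs[:, 1]]]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        ab, ac, ap = b - a, c - a, p - a
        d00 = np.einsum("ij,ij->i", ab, ab)
        d01 = np.einsum("ij,ij->i", ab, ac)
        d11 = np.einsum("ij,ij->i", ac, ac)
        d20 = np.einsum("ij,ij->i", ap, ab)
        d21 = np.einsum("ij,ij->i", ap, ac)
        denom = np.maximum(d00 * d11 - d01 * d01, 1e-30)
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0)
        s = v + w
        over = s > 1.0
        v[over] /= s[over]
        w[over] /= s[over]
        q = a + v[:, None] * ab + w[:, None] * ac
        diff = p - q
        dist = np.linalg.norm(diff, axis=1)
        return diff, dist

    def forces(self, V: np.ndarray, out: np.ndarray) -> np.ndarray:
        """Apply penalty forces; returns active (vertex, face_a, face_b, gap)
        rows, face_a being an incident face of the contacting vertex."""
        res = self._closest(V)
        if res is None:
            return np.zeros((0, 4))
        diff, dist = res
        active = dist < self.detect
        if not active.any():
            return np.zeros((0, 4))
        idx = np.where(active)[0]
        pen = self.detect - dist[idx]
        direction = diff[idx] / np.maximum(dist[idx], 1e-12)[:, None]
        varea = self.vertex_area[self._pairs[idx, 0]]
        fmag = self.penalty * pen * varea
        fvec = fmag[:, None] * direction
        np.add.at(out, self._pairs[idx, 0], fvec)
        # reaction spread over the face corners
        tgt = self.faces[self._pairs[idx, 1]]
        np.add.at(out, tgt[:, 0], -fvec / 3)
        np.add.at(out, tgt[:, 1], -fvec / 3)
        np.add.at(out, tgt[:, 2], -fvec / 3)
        vfaces = self._vertex_face_lookup()
        fa = vfaces[self._pairs[idx, 0]]
        return np.column_stack([self._pairs[idx, 0], fa,
                                self._pairs[idx, 1], dist[idx]])

    def energy(self, V: np.ndarray) -> float:
        res = self._closest(V)
        if res is None:
            return 0.0
        _, dist = res
        pen = np.maximum(self.detect - dist, 0.0)
        varea = self.vertex_area[self._pairs[:, 0]]
        return float(0.5 * self.penalty * np.sum(varea * pen**2))

    def _vertex_face_lookup(self) -> np.ndarray:
        if not hasattr(self, "_vface"):
            vface = np.zeros(len(self.leaflet_of_vertex), dtype=int)
            for fi, f in enumerate(self.faces):
                for v in f:
                    vface[int(v)] = fi
            self._vface = vface
        return self._vface


def _pressure_forces(surface: ValveSurface, V: np.ndarray, p_mpa: float,
                     loaded: np.ndarray, sign: np.ndarray,
                     out: np.ndarray) -> np.ndarray:
    """Follower pressure on the outflow faces; returns total applied force."""
    tri = V[surface.faces[loaded]]
    n = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
    fvec = (sign[:, None] * n) * p_mpa / 3.0
    total = 3.0 * fvec.sum(axis=0)
    f = surface.faces[loaded]
    np.add.at(out, f[:, 0], fvec)
    np.add.at(out, f[:, 1], fvec)
    np.add.at(out, f[:, 2], fvec)
    return total


def simulate_closure(
    surface: ValveSurface,
    material: AhyperParams = AHYPER_PRINTED,
    ramp: PressureRamp = PressureRamp(),
    config: SolverConfig = SolverConfig(),
) -> ClosureResult:
    """Quasi-static closure under the diastolic pressure ramp.

    Returns a :class:`ClosureResult` with at least ``n_hold_snapshots``
    equilibrium states inside the hold window for metric time-averaging.
    """
    thickness = config.thickness if config.thickness is not None else surface.thickness
    V = surface.vertices.copy()
    n_v = len(V)
    membrane = _Membrane(surface, material, thickness, config.membrane_scale,
                         wrinkling=config.wrinkling)
    k_bend = config.bending_modulus * thickness**3 / 12.0
    hinges = _Hinges(surface, k_bend)
    contact = _Contact(surface, config.contact_penalty,
                       config.contact_detect_factor * thickness)

    region = surface.region
    cz = surface.face_centroids()[:, 2]
    leaflet_mask = np.isin(region, LEAFLET_CODES)
    root_loaded = (region == REGION_CODES["root"]) & (cz > 19.0)
    loaded = np.where(leaflet_mask | root_loaded)[0]
    # leaflet outflow side faces the axis/top (traction -p n); the root's
    # outflow-wetted side is its inner wall (traction +p n outward)
    sign = np.where(leaflet_mask[loaded], -1.0, 1.0)

    free = np.ones(n_v, dtype=bool)
    free[surface.fixed_vertices] = False

    edge_len2 = np.maximum(4 * membrane.area0 / np.sqrt(3.0), 1e-6)
    k_base = contact.penalty * contact.vertex_area
    if len(hinges.quads):
        kb_vert = np.zeros(n_v)
        kh = hinges.k_hinge / np.maximum(edge_len2.mean(), 1e-9)
        for col in range(4):
            np.add.at(kb_vert, hinges.quads[:, col], kh)
        k_base = k_base + kb_vert

    def mass_at(Vc: np.ndarray) -> np.ndarray:
        # dynamic-relaxation mass scaling: m ~ 2 k dt^2 (dt = 1) keeps the
        # highest mode stable; the tangent bound adapts to fiber stiffening
        k_vert = membrane.vertex_stiffness(Vc) + k_base
        return 2.0 * np.maximum(k_vert, 1e-9)

    times_ramp = np.linspace(ramp.ramp_s / config.n_increments, ramp.ramp_s,
                             config.n_increments)
    times_hold = ramp.ramp_s + np.linspace(0.0, ramp.hold_s,
                                           config.n_hold_snapshots)[1:]
    schedule = np.concatenate([times_ramp, times_hold])
    snap_times = [0.0] + schedule.tolist()

    snapshots = [V.copy()]
    contact_sets = [np.zeros((0, 4))]
    residuals = [0.0]
    load_norms = [0.0]
    reactions = [np.zeros(3)]
    applied = [np.zeros(3)]
    converged = [True]
    energies: list[np.ndarray] = [np.zeros(0)]

    vel = np.zeros_like(V)

    def internal_energy(Vc: np.ndarray) -> float:
        return membrane.energy(Vc) + hinges.energy(Vc) + contact.energy(Vc)

    loaded_nodes = np.unique(surface.faces[loaded])

    for t in schedule:
        p_mpa = pressure_at(t, ramp) * PA_TO_MPA
        vel[:] = 0.0
        ke_prev = 0.0
        res_norm = np.inf
        tol = np.inf
        e_hist = []
        ext_work = 0.0  # external work along the relaxation trajectory
        pairs_rec = np.zeros((0, 4))
        contact.update_pairs(V)
        mass = mass_at(V)
        for it in range(config.max_iters):
            f = np.zeros_like(V)
            membrane.forces(V, f)
            hinges.forces(V, f)
            if it % config.contact_every == 0 and it > 0:
                contact.update_pairs(V)
            pairs_rec = contact.forces(V, f)
            f_ext = np.zeros_like(V)
            total_applied = _pressure_forces(surface, V, p_mpa, loaded, sign, f_ext)
            f += f_ext
            f[~free] = 0.0
            res_norm = float(np.linalg.norm(f[free], axis=1).max()) if free.any() else 0.0
            load_scale = float(
                np.linalg.norm(f_ext[loaded_nodes], axis=1).mean()
            ) if len(loaded_nodes) else 0.0
            tol = max(config.residual_tol_rel * load_scale, 1e-9)
            if res_norm <= tol:
                break
            vel += f / mass[:, None]
            ke = float(np.einsum("ij,ij->", mass[:, None] * vel, vel))
            if ke < ke_prev:  # kinetic-damping restart at the energy peak
                vel[:] = 0.0
                ke = 0.0
                if config.record_energy:
                    # total energy: stored + contact penalty minus the work
                    # fed in by the (follower) pressure; kinetic damping must
                    # dissipate it monotonically at restarts
                    e_hist.append(internal_energy(V) - ext_work)
                mass = mass_at(V)
            ke_prev = ke
            if config.record_energy:
                ext_work += float(np.einsum("ij,ij->", f_ext[free], vel[free]))
            V[free] += vel[free]
        # accepted state bookkeeping
        f_int = np.zeros_like(V)
        membrane.forces(V, f_int)
        hinges.forces(V, f_int)
        contact.forces(V, f_int)
        f_ext = np.zeros_like(V)
        total_applied = _pressure_forces(surface, V, p_mpa, loaded, sign, f_ext)
        reaction = -(f_int + f_ext)[~free].sum(axis=0)
        snapshots.append(V.copy())
        contact_sets.append(pairs_rec)
        residuals.append(res_norm)
        load_norms.append(float(np.linalg.norm(total_applied)))
        reactions.append(reaction)
        applied.append(total_applied)
        converged.append(res_norm <= tol)
        energies.append(np.array(e_hist))

    return ClosureResult(
        surface=surface,
        times=np.array(snap_times),
        pressures_pa=np.array([pressure_at(t, ramp) for t in snap_times]),
        snapshots=snapshots,
        contact_pairs=contact_sets,
        residuals=np.array(residuals),
        load_norms=np.array(load_norms),
        reaction_force=np.array(reactions),
        applied_force=np.array(applied),
        converged=np.array(converged, dtype=bool),
        energy_history=energies,
        config=config,
    )


# ---------------------------------------------------------------------------
# coaptation length
# ---------------------------------------------------------------------------


def coaptation_length(
    state: ValveSurface,
    contact_pairs: np.ndarray | None = None,
    azimuth: float | None = None,
    gap_tol: float | None = None,
    merge_tol: float | None = None,
) -> dict[tuple[int, int], float]:
    """Coaptation length [mm] per leaflet pair on a long-axis cut plane.

    The cut plane contains the valve axis at the given azimuth (default: the
    shared commissure azimuth of each pair).  Contacting vertex positions of
    the pair near the plane are projected and their heights merged into
    contiguous bands; the longest contiguous band length is reported.

    Without solver contact pairs, contact is inferred from vertex-face gaps
    below ``gap_tol`` (default half the wall thickness).
    """
    if gap_tol is None:
        gap_tol = 0.5 * state.thickness
    contact = _Contact(state, penalty=1.0, detect=gap_tol)
    contact.update_pairs(state.vertices)
    res = contact._closest(state.vertices)
    out: dict[tuple[int, int], float] = {(0, 1): 0.0, (1, 2): 0.0, (0, 2): 0.0}
    if res is None:
        return out
    _, dist = res
    active = dist <= gap_tol
    if not active.any():
        return out
    pairs = contact._pairs[active]
    v_leaf = contact.leaflet_of_vertex[pairs[:, 0]]
    f_leaf = contact.leaflet_of_face[pairs[:, 1]]
    pts = state.vertices[pairs[:, 0]]
    edges = state.vertices[state.faces[:, 0]] - state.vertices[state.faces[:, 1]]
    h = float(np.median(np.linalg.norm(edges, axis=1)))
    if merge_tol is None:
        merge_tol = 2.0 * h
    for (la, lb) in out:
        sel = ((v_leaf == la) & (f_leaf == lb)) | ((v_leaf == lb) & (f_leaf == la))
        if not sel.any():
            continue
        p = pts[sel]
        if azimuth is None:
            # shared commissure azimuth: leaflet k spans [k, k+1] * 120 deg
            az = {(0, 1): 1, (1, 2): 2, (0, 2): 3}[(la, lb)] * 2.0 * np.pi / 3.0
        else:
            az = azimuth
        nrm = np.array([-np.sin(az), np.cos(az)])  # normal of the cut plane
        dist_plane = np.abs(p[:, :2] @ nrm)
        near = dist_plane <= max(2.0 * h, 1.0)
        if not near.any():
            continue
        z = np.sort(p[near, 2])
        runs = np.split(z, np.where(np.diff(z) > merge_tol)[0] + 1)
        best = max((r[-1] - r[0]) for r in runs)
        out[(la, lb)] = float(best)
    return out
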