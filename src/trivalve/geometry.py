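"""Tri-tube valve parameterization and constructed-surface meshing.

A tri-leaflet valve of target diameter 24 mm is assembled from three
identical tissue tubes of diameter ``D`` and height 50 mm.  A section of arc
length ``c = pi D - 24 pi / 3`` and vertical extent ``L`` is removed from
each tube so that the three retained arcs close the 24 mm ring, and the
leaflet height follows ``H = 50 - 21 - L`` from the fixed suture-line
geometry (suture ends 21 mm, suture center 19 mm above the tube end).  The
flattened front face of each tube (width pi D / 2) becomes one leaflet of
nominal area ``LA = pi D H / 2``.

``build_constructed_valve`` emulates the two-step flatten/roll-up
construction geometrically: each flattened tube is mapped onto a 120-degree
sector of the 12 mm-radius ring, and the leaflet sheet is inset radially
inward by a profile whose free-edge shape (smooth bow for width deficit,
D < 16 mm; wrinkle ripple for width excess, D > 16 mm) is solved so the
free-edge arc length equals the material width pi D / 2.  The resulting
fully-open surface is taken as the stress-free reference for the closure
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ValveDesign",
    "ValveSurface",
    "DesignValidationError",
    "derive_design",
    "validate_design",
    "suture_curve",
    "build_constructed_valve",
    "REGION_NAMES",
    "REGION_CODES",
    "leaflet_region_area",
]

# fixed tube/valve constants [mm]
TUBE_HEIGHT = 50.0
CONDUIT_SEGMENT = 10.0
SUTURE_END_OFFSET = 21.0
SUTURE_CENTER_OFFSET = 19.0
TARGET_VALVE_DIAMETER = 24.0
VALVE_RADIUS = TARGET_VALVE_DIAMETER / 2.0

D_RANGE = (15.0, 16.875)
H_RANGE = (7.0, 13.25)

REGION_NAMES = {0: "root", 1: "conduit", 2: "leaflet_1", 3: "leaflet_2", 4: "leaflet_3"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}
LEAFLET_CODES = (2, 3, 4)


class DesignValidationError(ValueError):
    """Raised when (D, H) violates the admissible design space."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class ValveDesign:
    """A tri-tube valve design point with derived geometric quantities."""

    D: float  # tube diameter [mm]
    H: float  # leaflet height [mm]

    @property
    def L(self) -> float:
        """Vertical tube length removed above the leaflet [mm]."""
        return TUBE_HEIGHT - SUTURE_END_OFFSET - self.H

    @property
    def c(self) -> float:
        """Arc length removed per tube so three arcs close the 24 mm ring [mm]."""
        return np.pi * self.D - TARGET_VALVE_DIAMETER * np.pi / 3.0

    @property
    def leaflet_area(self) -> float:
        """Nominal leaflet area pi D H / 2 [mm^2] (flattened width x height)."""
        return np.pi * self.D * self.H / 2.0

    @property
    def leaflet_area_rounded(self) -> int:
        return int(round(self.leaflet_area))

    @property
    def leaflet_width(self) -> float:
        """Flattened front-face width pi D / 2 [mm]."""
        return np.pi * self.D / 2.0

    @property
    def free_edge_height(self) -> float:
        """Height of the leaflet free edge above the valve base [mm]."""
        return SUTURE_END_OFFSET + self.H


def validate_design(D: float, H: float) -> list[str]:
    """Return the list of design-space violations (empty iff admissible)."""
    violations = []
    if D < D_RANGE[0]:
        violations.append(f"D = {D} mm below lower bound {D_RANGE[0]} mm")
    if D > D_RANGE[1]:
        violations.append(f"D = {D} mm above upper bound {D_RANGE[1]} mm")
    if H < H_RANGE[0]:
        violations.append(f"H = {H} mm below lower bound {H_RANGE[0]} mm")
    if H > H_RANGE[1]:
        violations.append(f"H = {H} mm above upper bound {H_RANGE[1]} mm")
    return violations


def derive_design(D: float, H: float) -> ValveDesign:
    """Validated design point with derived fields (L, c, leaflet area)."""
    violations = validate_design(D, H)
    if violations:
        raise DesignValidationError(violations)
    return ValveDesign(D=float(D), H=float(H))


def suture_curve(design: ValveDesign, x: np.ndarray | None = None,
                 shape: str = "parabola") -> tuple[np.ndarray, np.ndarray]:
    """Suture-line height profile in the flattened-tube frame.

    Returns (x, height) with x spanning [0, w], w = pi D / 2, height 21 mm at
    both ends and 19 mm at the center above the tube end.  The default is the
    parabola h(x) = 21 - 2 (1 - (2x/w - 1)^2); a circular arc through the same
    three control points is available with ``shape='arc'``.
    """
    w = design.leaflet_width
    if x is None:
        x = np.linspace(0.0, w, 101)
    x = np.asarray(x, dtype=float)
    u = 2.0 * x / w - 1.0  # in [-1, 1]
    if shape == "parabola":
        h = SUTURE_END_OFFSET - 2.0 * (1.0 - u**2)
    elif shape == "arc":
        # circle through (0, 21), (w/2, 19), (w, 21) in physical coordinates:
        # center (w/2, k), k = ((w/2)^2 + 80) / 4, radius k - 19
        k = ((w / 2.0) ** 2 + 80.0) / 4.0
        r = k - SUTURE_CENTER_OFFSET
        h = k - np.sqrt(r**2 - (x - w / 2.0) ** 2)
    else:
        raise ValueError(f"unknown suture shape {shape!r}")
    return x, h


@dataclass
class ValveSurface:
    """Triangulated valve state with region labels and fiber directions.

    vertices    : (N, 3) [mm], Z along the valve axis, base at Z = 0
    faces       : (M, 3) vertex indices
    region      : (M,) small-int codes (see REGION_NAMES)
    fiber_circ  : (M, 3) unit reference fiber direction, circumferential family
    fiber_axial : (M, 3) unit reference fiber direction, axial family
    thickness   : wall thickness [mm]
    free_edges  : one ordered vertex path per leaflet (commissure to
                  commissure along the free edge)
    fixed_vertices : indices pinned in the closure simulation (valve ends)
    """

    vertices: np.ndarray
    faces: np.ndarray
    region: np.ndarray
    fiber_circ: np.ndarray
    fiber_axial: np.ndarray
    thickness: float = 0.6
    free_edges: list[np.ndarray] = field(default_factory=list)
    fixed_vertices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    design: ValveDesign | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.region = np.asarray(self.region, dtype=int)
        if len(self.region) != len(self.faces):
            raise ValueError("one region code per face required")

    # -- geometry helpers ---------------------------------------------------

    def triangles(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return v[self.faces]

    def face_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        tri = self.triangles(vertices)
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def face_normals(self, vertices: np.ndarray | None = None) -> np.ndarray:
        tri = self.triangles(vertices)
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-30)

    def face_centroids(self, vertices: np.ndarray | None = None) -> np.ndarray:
        return self.triangles(vertices).mean(axis=1)

    def leaflet_faces(self, k: int | None = None) -> np.ndarray:
        """Boolean face mask for leaflet k (1..3) or all leaflets."""
        if k is None:
            return np.isin(self.region, LEAFLET_CODES)
        return self.region == REGION_CODES[f"leaflet_{k}"]

    def with_vertices(self, vertices: np.ndarray) -> "ValveSurface":
        return ValveSurface(
            vertices=np.asarray(vertices, dtype=float), faces=self.faces,
            region=self.region, fiber_circ=self.fiber_circ,
            fiber_axial=self.fiber_axial, thickness=self.thickness,
            free_edges=self.free_edges, fixed_vertices=self.fixed_vertices,
            design=self.design,
        )

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    def identify_free_edges(self, z_tol: float = 1e-6) -> list[np.ndarray]:
        """Free edges = boundary edges not on the fixed end rings, grouped and
        ordered into one path per leaflet."""
        if self.free_edges:
            return self.free_edges
        from collections import defaultdict

        count: dict[tuple[int, int], int] = defaultdict(int)
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                count[(min(a, b), max(a, b))] += 1
        zmin = self.vertices[:, 2].min()
        zmax = self.vertices[:, 2].max()
        fixed = set(self.fixed_vertices.tolist())
        boundary = []
        for (a, b), c in count.items():
            if c != 1:
                continue
            za, zb = self.vertices[a, 2], self.vertices[b, 2]
            on_ring = (abs(za - zmin) < z_tol and abs(zb - zmin) < z_tol) or (
                abs(za - zmax) < z_tol and abs(zb - zmax) < z_tol
            )
            if on_ring or (a in fixed and b in fixed):
                continue
            boundary.append((a, b))
        # chain into paths
        adj: dict[int, list[int]] = defaultdict(list)
        for a, b in boundary:
            adj[a].append(b)
            adj[b].append(a)
        paths: list[np.ndarray] = []
        unused = set(boundary)
        while unused:
            a, b = next(iter(unused))
            path = [a, b]
            unused.discard((a, b))
            for _ in range(2):  # extend forward then backward
                extended = True
                while extended:
                    extended = False
                    tail = path[-1]
                    for nb in adj[tail]:
                        e = (min(tail, nb), max(tail, nb))
                        if e in unused:
                            path.append(nb)
                            unused.discard(e)
                            extended = True
                            break
                path.reverse()
            paths.append(np.array(path, dtype=int))
        self.free_edges = paths
        return paths


def leaflet_region_area(surface: ValveSurface, k: int,
                        above_commissure: bool = True) -> float:
    """Mesh area of leaflet k [mm^2].

    With ``above_commissure`` only faces whose centroid lies above the
    commissure level (21 mm) are counted, matching the nominal rectangle
    pi D / 2 x H; the strip between the dipping suture curve and the
    commissure level is excluded.
    """
    mask = surface.leaflet_faces(k)
    if above_commissure:
        mask = mask & (surface.face_centroids()[:, 2] >= SUTURE_END_OFFSET)
    return float(surface.face_areas()[mask].sum())


_RIPPLE_WAVES = 6  # wrinkle half-waves across one leaflet


def _bulge_profile(x: np.ndarray) -> np.ndarray:
    return np.sin(np.pi * x)


def _ripple_profile(x: np.ndarray) -> np.ndarray:
    # inward-only wrinkle pattern, clean at the commissures
    return np.sin(np.pi * x) ** 2 * 0.5 * (1.0 - np.cos(_RIPPLE_WAVES * np.pi * x))


def _radial_inset(x: np.ndarray, offset: float, amp: float, slack: bool) -> np.ndarray:
    """Radial inset of the free edge from the 12 mm ring at parameter x."""
    inset = offset * _bulge_profile(x)
    inset += amp * (_ripple_profile(x) if slack else _bulge_profile(x))
    return inset


def _free_edge_length(offset: float, amp: float, slack: bool, n: int = 601) -> float:
    x = np.linspace(0.0, 1.0, n)
    phi = x * (2.0 * np.pi / 3.0)
    r = VALVE_RADIUS - _radial_inset(x, offset, amp, slack)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _solve_free_edge_shape(w: float, offset: float, n: int = 601) -> tuple[float, bool]:
    """(amplitude, slack?) so the free-edge arc length equals the width w.

    Width deficit (w below the sector arc at the seeded offset, D < 16 mm):
    the free edge bows smoothly inward toward the commissure chord, which
    shortens it.  Width excess (D > 16 mm): a smooth inward excursion cannot
    lengthen a curve inside the ring, so the slack is absorbed by an inward
    wrinkle ripple - the geometric signature of a sheet with excess material.
    """
    arc = _free_edge_length(offset, 0.0, False, n)
    if w <= arc:
        f = lambda a: _free_edge_length(offset, a, False, n) - w
        hi = 0.25
        while f(hi) > 0 and hi < 8.0:
            hi += 0.25
        return (float(brentq(f, 0.0, hi, xtol=1e-10)) if f(hi) <= 0 else hi, False)
    # ripple branch: length first dips slightly, then grows with amplitude
    g = lambda a: _free_edge_length(offset, a, True, n) - w
    amps = np.linspace(0.0, 6.0, 121)
    vals = np.array([g(a) for a in amps])
    i_min = int(np.argmin(vals))
    j = i_min + int(np.argmax(vals[i_min:] >= 0))
    if vals[j] < 0:  # unreachable; keep the closest shape
        return float(amps[int(np.argmin(np.abs(vals)))]), True
    return float(brentq(g, amps[max(j - 1, i_min)], amps[j] + 1e-9, xtol=1e-10)), True


def build_constructed_valve(
    design: ValveDesign,
    n_circ: int = 24,
    n_leaflet_rows: int = 12,
    n_below_rows: int = 10,
    inward_offset: float = 0.24,
    bulge_power: float = 0.4,
    suture_shape: str = "parabola",
    thickness: float = 0.6,
    twist_seed_deg: float = 8.0,
) -> ValveSurface:
    """Closed-ring valve surface in its fully-open post-construction state.

    Each tube sector (120 degrees) carries a wall grid (root + conduit) on the
    12 mm cylinder and a leaflet grid attached to the wall along the suture
    curve and the two commissure meridians.  The leaflet is inset radially
    inward by a profile growing as ``s^bulge_power`` (s = normalized height
    above the suture) whose free-edge shape is solved so the free-edge arc
    length equals the flattened width pi D / 2; ``inward_offset`` scales the
    seeded inset separating leaflets from the root in the open state.

    ``twist_seed_deg`` applies a small same-handed azimuthal bias to every
    leaflet interior (zero at the suture and commissures), emulating the
    construction/suturing asymmetry of a real assembly.  A perfectly
    symmetric open valve is a degenerate unstable configuration whose central
    orifice cannot close without tangential sliding of the free edges; the
    seed deterministically selects that physical (pinwheeling) branch.
    """
    if n_circ < 8:
        raise ValueError(
            f"n_circ = {n_circ} too coarse to resolve the suture curve; need >= 8"
        )
    if inward_offset < 0:
        raise ValueError("inward offset must be non-negative")
    w = design.leaflet_width
    z_fe = design.free_edge_height
    amp, slack = _solve_free_edge_shape(w, inward_offset, n_circ + 1)

    n_cols = n_circ + 1
    xhat = np.linspace(0.0, 1.0, n_cols)
    _, s_height = suture_curve(design, xhat * w, shape=suture_shape)

    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    region: list[int] = []
    fiber_circ: list[np.ndarray] = []
    fiber_axial: list[np.ndarray] = []
    free_edges: list[np.ndarray] = []

    def add_vertex(p: np.ndarray) -> int:
        vertices.append(p)
        return len(vertices) - 1

    n_wall_rows = n_below_rows + n_leaflet_rows  # row count per wall column
    wall_ids = np.full((3, n_cols, n_wall_rows + 1), -1, dtype=int)
    sector_phi0 = [k * 2.0 * np.pi / 3.0 for k in range(3)]

    # --- wall grids (shared commissure columns between adjacent sectors) ----
    for k in range(3):
        phi0 = sector_phi0[k]
        for i in range(n_cols):
            if i == 0 and k > 0:
                wall_ids[k, 0] = wall_ids[k - 1, n_cols - 1]
                continue
            if i == n_cols - 1 and k == 2:
                wall_ids[2, n_cols - 1] = wall_ids[0, 0]
                continue
            phi = phi0 + xhat[i] * 2.0 * np.pi / 3.0
            si = s_height[i]
            z_below = np.linspace(0.0, si, n_below_rows + 1)
            z_above = si + (z_fe - si) * np.arange(1, n_leaflet_rows + 1) / n_leaflet_rows
            z_col = np.concatenate([z_below, z_above])
            for j, z in enumerate(z_col):
                p = np.array([VALVE_RADIUS * np.cos(phi), VALVE_RADIUS * np.sin(phi), z])
                wall_ids[k, i, j] = add_vertex(p)

    def quad(a: int, b: int, c: int, d: int, code: int,
             e_circ: np.ndarray, e_ax: np.ndarray) -> None:
        """Two triangles for quad a-b-c-d (a-b bottom row, d-c top row)."""
        for tri in ((a, b, c), (a, c, d)):
            faces.append(tri)
            region.append(code)
            fiber_circ.append(e_circ)
            fiber_axial.append(e_ax)

    verts_arr = None  # filled later

    def unit(v: np.ndarray) -> np.ndarray:
        return v / max(np.linalg.norm(v), 1e-30)

    for k in range(3):
        for i in range(n_circ):
            for j in range(n_wall_rows):
                a = wall_ids[k, i, j]
                b = wall_ids[k, i + 1, j]
                c = wall_ids[k, i + 1, j + 1]
                d = wall_ids[k, i, j + 1]
                zc = (vertices[a][2] + vertices[c][2]) / 2.0
                code = REGION_CODES["conduit"] if zc < CONDUIT_SEGMENT else REGION_CODES["root"]
                # tube circumferential direction wraps the ring horizontally
                mid = 0.5 * (vertices[a] + vertices[b])
                phi_mid = np.arctan2(mid[1], mid[0])
                e_circ = np.array([-np.sin(phi_mid), np.cos(phi_mid), 0.0])
                e_ax = np.array([0.0, 0.0, 1.0])
                quad(a, b, c, d, code, e_circ, e_ax)

    # --- leaflet grids ------------------------------------------------------
    for k in range(3):
        phi0 = sector_phi0[k]
        code = REGION_CODES[f"leaflet_{k + 1}"]
        ids = np.full((n_cols, n_leaflet_rows + 1), -1, dtype=int)
        # suture row and commissure columns are welded to the wall
        ids[:, 0] = wall_ids[k, :, n_below_rows]
        ids[0, 1:] = wall_ids[k, 0, n_below_rows + 1:]
        ids[n_cols - 1, 1:] = wall_ids[k, n_cols - 1, n_below_rows + 1:]
        for i in range(1, n_cols - 1):
            phi = phi0 + xhat[i] * 2.0 * np.pi / 3.0
            si = s_height[i]
            for j in range(1, n_leaflet_rows + 1):
                s_norm = j / n_leaflet_rows
                z = si + (z_fe - si) * s_norm
                inset = _radial_inset(np.array([xhat[i]]), inward_offset, amp,
                                      slack)[0] * s_norm**bulge_power
                r = VALVE_RADIUS - inset
                dphi = (np.radians(twist_seed_deg) * s_norm**bulge_power
                        * np.sin(np.pi * xhat[i]))
                p = np.array([r * np.cos(phi + dphi), r * np.sin(phi + dphi), z])
                ids[i, j] = add_vertex(p)
        for i in range(n_circ):
            for j in range(n_leaflet_rows):
                a, b = ids[i, j], ids[i + 1, j]
                c, d = ids[i + 1, j + 1], ids[i, j + 1]
                e_circ = unit(vertices[b] - vertices[a])
                e_ax = unit(vertices[d] - vertices[a])
                quad(a, b, c, d, code, e_circ, e_ax)
        free_edges.append(ids[:, n_leaflet_rows].copy())

    verts_arr = np.array(vertices)
    faces_arr = np.array(faces, dtype=int)
    z = verts_arr[:, 2]
    fixed = np.where((np.abs(z) < 1e-9) | (np.abs(z - z_fe) < 1e-9))[0]
    # the free-edge interior is not fixed even though it sits at z_fe
    free_set = set(np.concatenate(free_edges).tolist())
    wall_top = set(wall_ids[:, :, -1].ravel().tolist())
    fixed = np.array(sorted((set(fixed.tolist()) - free_set) | wall_top), dtype=int)

    return ValveSurface(
        vertices=verts_arr,
        faces=faces_arr,
        region=np.array(region, dtype=int),
        fiber_circ=np.array(fiber_circ),
        fiber_axial=np.array(fiber_axial),
        thickness=thickness,
        free_edges=free_edges,
        fixed_vertices=fixed,
        design=design,
    )
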