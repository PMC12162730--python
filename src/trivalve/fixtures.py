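"""Deterministic synthetic inputs with known ground truths.

Two families of fixtures make every pipeline stage testable without any
external data:

* ``make_curves`` generates stress-strain test curves from a constitutive
  model (optionally with seeded Gaussian noise), the inverse of material
  calibration;
* ``make_valve_state`` builds analytic tri-leaflet valve states whose closure
  metrics are known in closed form (ideal closure, fully open, pinwheeled,
  prolapsed, coaptation bands), triangulated at configurable resolution.
  Ground truths are computed from the generating curves and shapes, never by
  the metric engine under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constitutive import (AhyperParams, HyperfoamParams, StressStrainCurve,
                           mode_response)
from .geometry import ValveSurface, VALVE_RADIUS, REGION_CODES

__all__ = ["FixtureSpec", "make_curves", "make_valve_state"]

_LEAFLET = [REGION_CODES[f"leaflet_{k}"] for k in (1, 2, 3)]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request (CLI surface)."""

    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# synthetic stress-strain curves
# ---------------------------------------------------------------------------


def make_curves(
    params: AhyperParams | HyperfoamParams,
    model: str = "ahyper",
    strain_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    modes: Sequence[tuple[str, str]] | None = None,
    compressibility: str = "incompressible",
) -> list[StressStrainCurve]:
    """Stress-strain curves from a constitutive model plus Gaussian noise.

    ``noise_sd`` is expressed as a fraction of each curve's peak |stress|.
    Default modes mirror the physical testing: equibiaxial tension read out
    in both directions for the anisotropic model; equibiaxial tension and
    unconfined compression for the foam model.
    """
    if modes is None:
        if model == "ahyper":
            modes = [("equibiaxial_tension", "circumferential"),
                     ("equibiaxial_tension", "axial")]
        else:
            modes = [("equibiaxial_tension", "circumferential"),
                     ("unconfined_compression", "through_thickness")]
    rng = np.random.default_rng(seed)
    curves = []
    for mode, direction in modes:
        if strain_grid is None:
            grid = (np.linspace(0.0, -0.3, 16) if mode == "unconfined_compression"
                    else np.linspace(0.0, 0.25, 16))
        else:
            grid = np.asarray(strain_grid, dtype=float)
        curve = mode_response(params, mode, grid, direction=direction,
                              compressibility=compressibility)
        if noise_sd > 0:
            peak = np.max(np.abs(curve.stress))
            curve.stress = curve.stress + rng.normal(
                0.0, noise_sd * peak, size=curve.stress.shape)
        curves.append(curve)
    return curves


# ---------------------------------------------------------------------------
# analytic valve states
# ---------------------------------------------------------------------------


def _mesh_grid_patch(corner_fn, n_u: int, n_v: int):
    """Triangulated structured patch from a parametric map (u, v) -> R^3."""
    verts = []
    ids = np.empty((n_u + 1, n_v + 1), dtype=int)
    for i in range(n_u + 1):
        for j in range(n_v + 1):
            ids[i, j] = len(verts)
            verts.append(corner_fn(i / n_u, j / n_v))
    faces = []
    for i in range(n_u):
        for j in range(n_v):
            a, b, c, d = ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]
            faces.append((a, b, c))
            faces.append((a, c, d))
    return np.array(verts, dtype=float), np.array(faces, dtype=int), ids


class _Builder:
    def __init__(self, thickness: float = 0.6):
        self.verts: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []
        self.region: list[int] = []
        self.free_edges: list[np.ndarray] = []
        self.thickness = thickness

    def add_patch(self, corner_fn, n_u, n_v, code):
        v, f, ids = _mesh_grid_patch(corner_fn, n_u, n_v)
        off = len(self.verts)
        self.verts.extend(v)
        self.faces.extend((f + off).tolist())
        self.region.extend([code] * len(f))
        return ids + off

    def build(self, design=None) -> ValveSurface:
        verts = np.array(self.verts)
        faces = np.array(self.faces, dtype=int)
        nf = len(faces)
        ez = np.tile([0.0, 0.0, 1.0], (nf, 1))
        tri = verts[faces]
        e_circ = tri[:, 1] - tri[:, 0]
        e_circ /= np.maximum(np.linalg.norm(e_circ, axis=1, keepdims=True), 1e-12)
        return ValveSurface(
            vertices=verts, faces=faces, region=np.array(self.region, dtype=int),
            fiber_circ=e_circ, fiber_axial=ez, thickness=self.thickness,
            free_edges=self.free_edges, design=design,
        )


def _ideal_closed(radius: float, skirt_height: float, z0: float,
                  n: int) -> tuple[ValveSurface, dict]:
    """Three flat 120-degree sectors + coincident vertical coaptation skirts.

    Free edges run commissure - center - commissure along the exact radial
    coaptation lines, so their projected length is 2R per leaflet (PI = 0).
    """
    b = _Builder()
    az = [k * 2 * np.pi / 3 for k in range(4)]
    for k in range(3):
        code = _LEAFLET[k]
        a0, a1 = az[k], az[k + 1]

        def sector(u, v, a0=a0, a1=a1):
            phi = a0 + u * (a1 - a0)
            r = v * radius
            return np.array([r * np.cos(phi), r * np.sin(phi), z0])

        b.add_patch(sector, n, n, code)

        skirt_ids = []
        for a_edge in (a0, a1):
            def skirt(u, v, a=a_edge):
                r = u * radius
                return np.array([r * np.cos(a), r * np.sin(a),
                                 z0 + v * skirt_height])

            ids = b.add_patch(skirt, n, max(2, n // 3), code)
            skirt_ids.append(ids)
        # free edge: top of left skirt reversed (commissure->center) then top
        # of right skirt (center->commissure)
        left_top = skirt_ids[0][:, -1][::-1]
        right_top = skirt_ids[1][:, -1]
        b.free_edges.append(np.concatenate([left_top, right_top]))
    surf = b.build()
    truth = {
        "CA": 3.0 * radius * skirt_height,  # three coincident-sheet pairs, one side
        "RA": 0.0,
        "PI": 0.0,
        "PA": 0.0,
        "l_actual": 6.0 * radius,
    }
    return surf, truth


def _open_valve(radius: float, height: float, z0: float, n: int,
                margin: float = 0.02) -> tuple[ValveSurface, dict]:
    """Leaflets flat against the wall: vertical shells of zero projected area.

    A small angular margin separates adjacent shells so no commissure line
    contact registers (the fully open reference state has no coaptation).
    """
    b = _Builder()
    for k in range(3):
        a0 = k * 2 * np.pi / 3 + margin
        a1 = (k + 1) * 2 * np.pi / 3 - margin

        def shell(u, v, a0=a0, a1=a1):
            phi = a0 + u * (a1 - a0)
            return np.array([radius * np.cos(phi), radius * np.sin(phi),
                             z0 + v * height])

        ids = b.add_patch(shell, n, max(2, n // 2), _LEAFLET[k])
        b.free_edges.append(ids[:, -1])
    surf = b.build()
    arc = (2 * np.pi - 6 * margin) * radius  # free edges at the wall
    truth = {"CA": 0.0, "RA": np.pi * radius**2, "PI": (arc - 6 * radius) / (6 * radius),
             "PA": 0.0, "l_actual": arc}
    return surf, truth


def _spiral_length(radius: float, twist: float, n_quad: int = 20001) -> float:
    """Projected arc length of r(t) = R(1-t), phi(t) = a + twist * t."""
    t = np.linspace(0.0, 1.0, n_quad)
    r = radius * (1 - t)
    x = r * np.cos(twist * t)
    y = r * np.sin(twist * t)
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def _pinwheeled(radius: float, twist: float, z0: float,
                n: int) -> tuple[ValveSurface, dict]:
    """Sector sheets twisted about the axis; free edges are spirals whose
    length (hence PI) follows from the analytic curve."""
    b = _Builder()
    az = [k * 2 * np.pi / 3 for k in range(4)]
    for k in range(3):
        a0, a1 = az[k], az[k + 1]

        def sheet(u, v, a0=a0, a1=a1):
            phi = a0 + u * (a1 - a0) + twist * (1 - v)
            r = v * radius
            return np.array([r * np.cos(phi), r * np.sin(phi), z0])

        ids = b.add_patch(sheet, n, 3 * n, _LEAFLET[k])
        # free edges are the two twisted radial boundaries
        b.free_edges.append(np.concatenate([ids[0, :][::-1], ids[-1, :]]))
    surf = b.build()
    half = _spiral_length(radius, twist)
    l_actual = 6.0 * half
    li = 6.0 * radius
    truth = {"PI": (l_actual - li) / li, "l_actual": l_actual}
    return surf, truth


def _prolapsed(overlap: float, size: float, z0: float,
               n: int) -> tuple[ValveSurface, dict]:
    """Two flat square sheets overlapping in an ``overlap x overlap`` square."""
    b = _Builder()

    def sheet(x0, y0, code):
        def fn(u, v, x0=x0, y0=y0):
            return np.array([x0 + u * size, y0 + v * overlap, z0])
        return b.add_patch(fn, n, n, code)

    # overlap region: x in [0, overlap], y in [0, overlap]
    ids1 = sheet(overlap - size, 0.0, _LEAFLET[0])
    ids2 = sheet(0.0, 0.0, _LEAFLET[1])
    far = sheet(10 * size, 0.0, _LEAFLET[2])
    for ids in (ids1, ids2, far):
        b.free_edges.append(ids[:, -1])
    surf = b.build()
    truth = {"PA": overlap * overlap, "CA": 0.0}
    return surf, truth


def _contact_band(bands: Sequence[tuple[float, float]], width: float,
                  separation: float, n: int) -> tuple[ValveSurface, dict]:
    """Two parallel sheets coincident over given z-bands (for coaptation
    length): sheet A is continuous; sheet B consists of the band strips."""
    b = _Builder()
    z_lo = min(b0 for b0, _ in bands)
    z_hi = max(b1 for _, b1 in bands)

    def sheet_a(u, v):
        return np.array([u * width, 0.0, z_lo + v * (z_hi - z_lo)])

    ids = b.add_patch(sheet_a, n, 3 * n, _LEAFLET[0])
    b.free_edges.append(ids[:, -1])
    for (bz0, bz1) in bands:
        def strip(u, v, bz0=bz0, bz1=bz1):
            return np.array([u * width, separation, bz0 + v * (bz1 - bz0)])

        ids = b.add_patch(strip, n, max(2, n), _LEAFLET[1])
    b.free_edges.append(ids[:, -1])
    surf = b.build()
    truth = {"coaptation_length": max(b1 - b0 for b0, b1 in bands),
             "bands": list(bands)}
    return surf, truth


def make_valve_state(kind: str, n: int = 24, radius: float = VALVE_RADIUS,
                     z0: float = 25.0, **kwargs) -> tuple[ValveSurface, dict]:
    """Analytic tri-leaflet state and its ground-truth metrics.

    kinds: ``ideal_closed`` (skirt_height), ``open_valve`` (height),
    ``pinwheeled`` (twist [rad]), ``prolapsed`` (overlap, size),
    ``contact_band`` (bands, width, separation).  Returns
    ``(surface, truth_dict)``; the truths come from the generating shapes.
    """
    if kind == "ideal_closed":
        return _ideal_closed(radius, kwargs.get("skirt_height", 4.0), z0, n)
    if kind == "open_valve":
        return _open_valve(radius, kwargs.get("height", 11.0), z0, n)
    if kind == "pinwheeled":
        return _pinwheeled(radius, kwargs.get("twist", 0.5), z0, n)
    if kind == "prolapsed":
        return _prolapsed(kwargs.get("overlap", 2.0), kwargs.get("size", 8.0),
                          z0, n)
    if kind == "contact_band":
        return _contact_band(kwargs.get("bands", [(20.0, 25.0)]),
                             kwargs.get("width", 8.0),
                             kwargs.get("separation", 0.0), n)
    raise ValueError(f"unknown fixture kind {kind!r}")
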