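"""Diastolic closure-performance metrics.

Four metrics quantify how well a tri-leaflet valve closes under back
pressure:

* coaptation area (CA, mm^2) - leaflet surface currently in contact with a
  neighboring leaflet, summed over the contact-side faces (each contacting
  pair counted once);
* regurgitation area (RA, mm^2) - open gap between the closed leaflets seen
  in the short-axis (XY) projection, i.e. the lumen disk minus the union of
  the projected leaflets;
* pinwheel index (PI, -) - normalized excess of the projected free-edge
  length over the ideal straight-coaptation length 6R (each ideal free edge
  runs commissure - center - commissure, 2R per leaflet); PI < 0 flags free
  edges too short to coapt;
* prolapse area (PA, mm^2) - superposed leaflet material in the projection:
  the union of the pairwise intersections of the three projected leaflets.

All projections use exact polygon booleans (shapely) on the projected
triangulation.  Metrics are time-averaged over at least 20 equi-spaced
points inside the diastolic hold window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, Point
from shapely.ops import unary_union

from .geometry import ValveSurface, VALVE_RADIUS
from .closure import ClosureResult

__all__ = [
    "MetricSample",
    "DesignEvaluation",
    "coaptation_area",
    "regurgitation_area",
    "pinwheel_index",
    "prolapse_area",
    "evaluate_state",
    "metric_samples",
    "time_average",
    "projected_leaflet_polygons",
]

IDEAL_FREE_EDGE = 6.0 * VALVE_RADIUS  # straight coaptation lines, 2R per leaflet


@dataclass
class MetricSample:
    """Closure metrics of one snapshot."""

    t: float
    CA: float
    RA: float
    PI: float
    PA: float
    l_actual: float
    l_ideal: float
    pi_negative: bool = False

    def __post_init__(self) -> None:
        if min(self.CA, self.RA, self.PA) < 0:
            raise ValueError("areas must be non-negative")


@dataclass
class DesignEvaluation:
    """Time-averaged metrics of a design over the diastolic hold window."""

    design: object
    window: tuple[float, float]
    n_samples: int
    CA: float
    RA: float
    PI: float
    PA: float
    samples: list[MetricSample] = field(default_factory=list)
    provenance: str = ""

    def as_dict(self) -> dict:
        return {
            "D": getattr(self.design, "D", None),
            "H": getattr(self.design, "H", None),
            "CA": self.CA, "RA": self.RA, "PI": self.PI, "PA": self.PA,
            "n_samples": self.n_samples, "window": list(self.window),
        }


def _leaflet_ids(surface: ValveSurface) -> list[int]:
    return [1, 2, 3]


def vertex_areas(surface: ValveSurface) -> np.ndarray:
    """Reference area attributed to each vertex (one third per incident face)."""
    areas = surface.face_areas()
    va = np.zeros(len(surface.vertices))
    for c in range(3):
        np.add.at(va, surface.faces[:, c], areas / 3.0)
    return va


def coaptation_area(surface: ValveSurface, contacts: np.ndarray) -> float:
    """Reference area [mm^2] of leaflet surface in contact, one side per pair.

    ``contacts`` is one of

    * an (n, 4) array of solver contact records (vertex, face_a, face_b, gap):
      the contact side of each pair is the lower-region-labeled one; its
      contacting vertices contribute their reference vertex areas, which
      converges with mesh refinement;
    * an (n, >=2) array of face pairs: reference areas of the contact-side
      (lower-labeled) faces, each counted once;
    * a boolean face mask: all flagged leaflet faces, halved (both sides of
      every pair are flagged but cannot be told apart).
    """
    areas = surface.face_areas()
    leaf = surface.leaflet_faces()
    contacts = np.asarray(contacts)
    region = surface.region
    if contacts.ndim == 2 and contacts.shape[1] == 4 and len(contacts):
        v = contacts[:, 0].astype(int)
        fa = contacts[:, 1].astype(int)
        fb = contacts[:, 2].astype(int)
        side = region[fa] < region[fb]
        verts = np.unique(v[side])
        return float(vertex_areas(surface)[verts].sum())
    if contacts.ndim == 2 and contacts.shape[1] >= 2 and len(contacts):
        fa = contacts[:, 0].astype(int)
        fb = contacts[:, 1].astype(int)
        side = np.where(region[fa] <= region[fb], fa, fb)
        side = np.unique(side)
        side = side[leaf[side]]
        return float(areas[side].sum())
    if contacts.ndim == 1 and contacts.dtype == bool:
        mask = contacts & leaf
        return float(0.5 * areas[mask].sum())
    return 0.0


def projected_leaflet_polygons(surface: ValveSurface,
                               vertices: np.ndarray | None = None,
                               min_area: float = 1e-10) -> list[Polygon]:
    """Short-axis (XY) projection of each leaflet as a shapely polygon."""
    V = surface.vertices if vertices is None else vertices
    polys = []
    for k in _leaflet_ids(surface):
        mask = surface.leaflet_faces(k)
        tris = V[surface.faces[mask]][:, :, :2]
        parts = shapely.polygons(tris)
        parts = shapely.make_valid(parts)
        keep = [p for p in parts if p.area > min_area]
        union = unary_union(keep)
        if not union.is_valid:
            union = shapely.make_valid(union)
        polys.append(union)
    return polys


def _lumen_disk(radius: float = VALVE_RADIUS) -> Polygon:
    return Point(0.0, 0.0).buffer(radius, quad_segs=256)


def regurgitation_area(surface: ValveSurface,
                       vertices: np.ndarray | None = None,
                       lumen_radius: float = VALVE_RADIUS,
                       include_root: bool = True) -> float:
    """Projected open-gap area [mm^2]: lumen disk minus the projected valve.

    The covering set contains the three leaflets and, by default, the root
    wall: an undeformed root is a vertical cylinder of zero projected area,
    but a root pulled inward by leaflet tension blocks part of the lumen and
    must not be double-counted as leak.
    """
    V = surface.vertices if vertices is None else vertices
    lumen = _lumen_disk(lumen_radius)
    parts = projected_leaflet_polygons(surface, vertices)
    if include_root:
        mask = ~surface.leaflet_faces()
        tris = V[surface.faces[mask]][:, :, :2]
        polys = shapely.make_valid(shapely.polygons(tris))
        keep = [p for p in polys if p.area > 1e-10]
        if keep:
            parts = parts + [unary_union(keep)]
    cover = unary_union(parts)
    return float(lumen.difference(cover).area)


def pinwheel_index(surface: ValveSurface,
                   vertices: np.ndarray | None = None,
                   l_ideal: float = IDEAL_FREE_EDGE) -> tuple[float, float, float]:
    """(PI, l_actual, l_ideal): projected free-edge excess over the ideal."""
    V = surface.vertices if vertices is None else vertices
    paths = surface.identify_free_edges()
    if not paths:
        raise ValueError("no free edges identified on this surface")
    l_actual = 0.0
    for path in paths:
        pts = V[path][:, :2]
        l_actual += float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    pi = (l_actual - l_ideal) / l_ideal
    return pi, l_actual, l_ideal


def prolapse_area(surface: ValveSurface,
                  vertices: np.ndarray | None = None,
                  convention: str = "union") -> float:
    """Projected leaflet-overlap area [mm^2].

    ``union`` counts the triple overlap once (union of pairwise
    intersections); ``pairwise_sum`` adds the three pairwise intersection
    areas, counting triple overlap three times.
    """
    polys = projected_leaflet_polygons(surface, vertices)
    inters = []
    for i in range(3):
        for j in range(i + 1, 3):
            inter = polys[i].intersection(polys[j])
            if not inter.is_empty:
                inters.append(inter)
    if not inters:
        return 0.0
    if convention == "pairwise_sum":
        return float(sum(p.area for p in inters))
    if convention == "union":
        return float(unary_union(inters).area)
    raise ValueError(f"unknown prolapse convention {convention!r}")


def evaluate_state(surface: ValveSurface, contact_faces: np.ndarray,
                   t: float = 0.0,
                   vertices: np.ndarray | None = None) -> MetricSample:
    """All four metrics for one snapshot."""
    state = surface if vertices is None else surface.with_vertices(vertices)
    ca = coaptation_area(surface, contact_faces)
    ra = regurgitation_area(state)
    pi, la, li = pinwheel_index(state)
    pa = prolapse_area(state)
    return MetricSample(t=t, CA=ca, RA=ra, PI=pi, PA=pa, l_actual=la,
                        l_ideal=li, pi_negative=pi < 0)


def metric_samples(result: ClosureResult,
                   indices: Sequence[int] | None = None) -> list[MetricSample]:
    """Metric time series over a closure result (default: hold window)."""
    if indices is None:
        indices = result.hold_indices
    out = []
    for i in indices:
        out.append(
            evaluate_state(result.surface, result.contact_pairs[i],
                           t=float(result.times[i]),
                           vertices=result.snapshots[i])
        )
    return out


def time_average(samples: Sequence[MetricSample],
                 window: tuple[float, float] | None = None,
                 n: int = 20,
                 design: object = None,
                 provenance: str = "") -> DesignEvaluation:
    """Arithmetic mean of each metric at n >= 20 equi-spaced times.

    Metric values between snapshots are linearly interpolated.
    """
    if n < 20:
        raise ValueError(f"at least 20 equi-spaced timepoints required, got {n}")
    if len(samples) < 2:
        raise ValueError("need at least two samples to average")
    ts = np.array([s.t for s in samples])
    order = np.argsort(ts)
    ts = ts[order]
    if window is None:
        window = (float(ts[0]), float(ts[-1]))
    lo, hi = window
    if lo < ts[0] - 1e-9 or hi > ts[-1] + 1e-9:
        raise ValueError(f"window {window} not covered by samples "
                         f"[{ts[0]}, {ts[-1]}]")
    grid = np.linspace(lo, hi, n)
    means = {}
    for name in ("CA", "RA", "PI", "PA"):
        vals = np.array([getattr(samples[i], name) for i in order])
        means[name] = float(np.mean(np.interp(grid, ts, vals)))
    return DesignEvaluation(
        design=design, window=(lo, hi), n_samples=n,
        CA=means["CA"], RA=means["RA"], PI=means["PI"], PA=means["PA"],
        samples=list(samples), provenance=provenance,
    )
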