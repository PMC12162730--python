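"""Closure-performance metrics: CA, RA, PI, PA and time averaging."""

import numpy as np
import pytest

from trivalve.fixtures import make_valve_state
from trivalve.geometry import VALVE_RADIUS
from trivalve.metrics import (
    MetricSample,
    coaptation_area,
    pinwheel_index,
    prolapse_area,
    regurgitation_area,
    time_average,
    projected_leaflet_polygons,
    vertex_areas,
    IDEAL_FREE_EDGE,
)

LUMEN_AREA = np.pi * VALVE_RADIUS**2


def _contact_rows(surface, gap_tol):
    """Solver-style (vertex, face_a, face_b, gap) rows from a static state."""
    from trivalve.closure import _Contact

    c = _Contact(surface, penalty=1.0, detect=gap_tol)
    c.update_pairs(surface.vertices)
    out = np.zeros_like(surface.vertices)
    return c.forces(surface.vertices, out)


class TestCoaptationArea:
    def test_open_valve_has_no_contact(self):
        surf, _ = make_valve_state("open_valve")
        assert coaptation_area(surf, _contact_rows(surf, 0.3)) == 0.0

    def test_two_coincident_patches_count_once(self):
        # 8 x 2 mm sheets fully coincident: CA equals one patch area
        surf, truth = make_valve_state("contact_band", bands=[(20.0, 22.0)],
                                       width=8.0, separation=0.0, n=16)
        rows = _contact_rows(surf, 0.3)
        ca = coaptation_area(surf, rows)
        assert ca == pytest.approx(8.0 * 2.0, rel=0.01)

    def test_additive_over_leaflet_pairs(self):
        surf, gt = make_valve_state("ideal_closed", skirt_height=4.0, n=24)
        ca = coaptation_area(surf, _contact_rows(surf, 0.2))
        # three coincident skirt pairs of R x h each, plus an O(h_mesh) strip
        # where the coplanar sector bellies meet along the coaptation lines
        assert ca >= gt["CA"] * 0.99
        assert ca == pytest.approx(gt["CA"], rel=0.12)

    def test_empty_contacts(self):
        surf, _ = make_valve_state("open_valve")
        assert coaptation_area(surf, np.zeros((0, 4))) == 0.0


class TestRegurgitationArea:
    def test_ideal_closed_valve_has_no_gap(self):
        surf, _ = make_valve_state("ideal_closed", n=48)
        ra = regurgitation_area(surf, include_root=False)
        assert ra < 0.005 * LUMEN_AREA  # polygonal-rim discretization only

    def test_fully_open_valve_leaks_the_whole_lumen(self):
        surf, gt = make_valve_state("open_valve")
        ra = regurgitation_area(surf, include_root=False)
        assert ra == pytest.approx(LUMEN_AREA, rel=1e-3)

    def test_central_triangular_gap_measured_exactly(self):
        # shrink each sector radially so an equilateral triangle opens at the
        # center; the triangle's area is known in closed form
        from trivalve.fixtures import _Builder, _LEAFLET

        d = 1.0  # apothem of the central triangular hole
        b = _Builder()
        for k in range(3):
            a0, a1 = k * 2 * np.pi / 3, (k + 1) * 2 * np.pi / 3
            mid = (a0 + a1) / 2

            def sheet(u, v, a0=a0, a1=a1, mid=mid):
                # sector whose inner edge is the chord at distance d from center
                phi = a0 + u * (a1 - a0)
                r_lo = d / np.cos(phi - mid)
                r = r_lo + v * (VALVE_RADIUS - r_lo)
                return np.array([r * np.cos(phi), r * np.sin(phi), 25.0])

            b.add_patch(sheet, 60, 8, _LEAFLET[k])
            b.free_edges.append(np.arange(2))
        surf = b.build()
        tri_area = 3 * np.sqrt(3) * d**2  # equilateral triangle, apothem d
        ra = regurgitation_area(surf, include_root=False)
        assert ra == pytest.approx(tri_area, rel=0.02)

    def test_root_projection_not_counted_as_leak(self, closure_opt):
        last = len(closure_opt.snapshots) - 1
        state = closure_opt.surface_at(last)
        with_root = regurgitation_area(state)
        without = regurgitation_area(state, include_root=False)
        assert with_root <= without


class TestPinwheelIndex:
    def test_ideal_fixture_is_exactly_zero(self):
        surf, _ = make_valve_state("ideal_closed")
        pi, la, li = pinwheel_index(surf)
        assert pi == 0.0
        assert la == pytest.approx(6 * VALVE_RADIUS)
        assert li == IDEAL_FREE_EDGE == 72.0

    def test_formula_values(self):
        # direct formula checks: l_actual of 78 and 69 mm
        assert (78 - 72) / 72 == pytest.approx(0.0833, abs=1e-4)
        assert (69 - 72) / 72 == pytest.approx(-0.0417, abs=1e-4)

    def test_negative_index_flagged(self):
        sample = MetricSample(t=0, CA=0, RA=0, PI=-0.04, PA=0, l_actual=69,
                              l_ideal=72, pi_negative=True)
        assert sample.pi_negative

    def test_scale_invariance(self):
        surf, _ = make_valve_state("pinwheeled", twist=0.4)
        pi1, _, li = pinwheel_index(surf)
        scaled = surf.with_vertices(surf.vertices * 2.0)
        scaled.free_edges = surf.free_edges
        pi2, _, _ = pinwheel_index(scaled, l_ideal=2 * li)
        assert pi2 == pytest.approx(pi1, rel=1e-12)


class TestProlapseArea:
    def test_disjoint_projections_give_zero(self):
        surf, _ = make_valve_state("ideal_closed")
        assert prolapse_area(surf) == pytest.approx(0.0, abs=1e-9)

    def test_square_overlap_measured_exactly(self):
        surf, gt = make_valve_state("prolapsed", overlap=2.0)
        assert prolapse_area(surf) == pytest.approx(4.0, rel=1e-6)

    def test_scales_quadratically(self):
        surf, _ = make_valve_state("prolapsed", overlap=2.0)
        scaled = surf.with_vertices(surf.vertices * 3.0)
        assert prolapse_area(scaled) == pytest.approx(9 * prolapse_area(surf),
                                                      rel=1e-9)

    def test_pairwise_sum_convention_counts_triple_overlap_thrice(self):
        from trivalve.fixtures import _Builder, _LEAFLET

        b = _Builder()
        for k in range(3):
            def sheet(u, v, k=k):  # three coincident unit squares
                return np.array([u, v, 25.0 + 0.0 * k])
            b.add_patch(sheet, 4, 4, _LEAFLET[k])
            b.free_edges.append(np.arange(2))
        surf = b.build()
        assert prolapse_area(surf, convention="union") == pytest.approx(1.0, rel=1e-6)
        assert prolapse_area(surf, convention="pairwise_sum") == pytest.approx(
            3.0, rel=1e-6)


class TestTimeAverage:
    def _samples(self, ts, ca):
        return [MetricSample(t=t, CA=c, RA=1.0, PI=0.1, PA=0.0,
                             l_actual=72, l_ideal=72) for t, c in zip(ts, ca)]

    def test_constant_series_returns_the_constants(self):
        s = self._samples(np.linspace(1.0, 1.5, 6), np.full(6, 4.0))
        ev = time_average(s, n=20)
        assert ev.CA == pytest.approx(4.0)
        assert ev.RA == pytest.approx(1.0)

    def test_linear_series_averages_to_midpoint(self):
        ts = np.linspace(1.0, 1.5, 11)
        s = self._samples(ts, 2.0 * (ts - 1.0))
        ev = time_average(s, n=21)
        assert ev.CA == pytest.approx(0.5, rel=1e-9)

    def test_fewer_than_twenty_points_rejected(self):
        s = self._samples(np.linspace(1.0, 1.5, 6), np.zeros(6))
        with pytest.raises(ValueError, match="20"):
            time_average(s, n=10)

    def test_window_outside_samples_rejected(self):
        s = self._samples(np.linspace(1.0, 1.5, 6), np.zeros(6))
        with pytest.raises(ValueError, match="window"):
            time_average(s, window=(0.5, 1.5), n=20)


class TestRasterizationOracle:
    """RA and PA against a pixel-counting oracle at 25 um resolution."""

    @staticmethod
    def _rasterize(tri_xy: np.ndarray, cell: float, extent: float):
        n = int(round(2 * extent / cell))
        xs = -extent + (np.arange(n) + 0.5) * cell
        occ = np.zeros((n, n), dtype=bool)
        for (a, b, c) in tri_xy:
            lo = np.floor((np.minimum(np.minimum(a, b), c) + extent) / cell).astype(int)
            hi = np.ceil((np.maximum(np.maximum(a, b), c) + extent) / cell).astype(int)
            lo = np.clip(lo, 0, n)
            hi = np.clip(hi, 0, n)
            if (hi <= lo).any():
                continue
            gx, gy = np.meshgrid(xs[lo[0]:hi[0]], xs[lo[1]:hi[1]], indexing="ij")
            p = np.stack([gx.ravel(), gy.ravel()], axis=1)
            def cross_z(u, w):
                return u[0] * w[..., 1] - u[1] * w[..., 0]

            d = (cross_z(b - a, p - a), cross_z(c - b, p - b),
                 cross_z(a - c, p - c))
            inside = ((d[0] >= 0) & (d[1] >= 0) & (d[2] >= 0)) | (
                (d[0] <= 0) & (d[1] <= 0) & (d[2] <= 0))
            sub = occ[lo[0]:hi[0], lo[1]:hi[1]]
            occ[lo[0]:hi[0], lo[1]:hi[1]] = sub | inside.reshape(sub.shape)
        return occ

    def test_ra_and_pa_match_pixel_counting_on_random_states(self, rng):
        from trivalve.fixtures import _Builder, _LEAFLET

        cell = 0.025
        extent = VALVE_RADIUS
        n_grid = int(round(2 * extent / cell))
        xs = -extent + (np.arange(n_grid) + 0.5) * cell
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        lumen_mask = gx**2 + gy**2 <= VALVE_RADIUS**2
        for trial in range(20):
            b = _Builder()
            occs = []
            for k in range(3):
                # random blob: polar star polygon around a random center
                c = rng.uniform(-3, 3, 2)
                n_pts = 9
                ang = np.sort(rng.uniform(0, 2 * np.pi, n_pts))
                rad = rng.uniform(2.0, 8.0, n_pts)

                def sheet(u, v, c=c, ang=ang, rad=rad):
                    # triangulated fan over the star polygon
                    a = np.interp(u * 2 * np.pi, np.concatenate([ang, [ang[0] + 2 * np.pi]]),
                                  np.concatenate([rad, [rad[0]]]), period=2 * np.pi)
                    r = v * a
                    phi = u * 2 * np.pi
                    return np.array([c[0] + r * np.cos(phi),
                                     c[1] + r * np.sin(phi), 25.0])

                b.add_patch(sheet, 36, 4, _LEAFLET[k])
                b.free_edges.append(np.arange(2))
            surf = b.build()
            tris = surf.vertices[surf.faces][:, :, :2]
            occ_per_leaf = []
            for k in (2, 3, 4):
                occ_per_leaf.append(self._rasterize(tris[surf.region == k],
                                                    cell, extent))
            any_cover = occ_per_leaf[0] | occ_per_leaf[1] | occ_per_leaf[2]
            multi = ((occ_per_leaf[0] & occ_per_leaf[1])
                     | (occ_per_leaf[0] & occ_per_leaf[2])
                     | (occ_per_leaf[1] & occ_per_leaf[2]))
            ra_pix = np.sum(lumen_mask & ~any_cover) * cell**2
            pa_pix = np.sum(multi) * cell**2
            ra = regurgitation_area(surf, include_root=False)
            pa = prolapse_area(surf)
            assert ra == pytest.approx(ra_pix, rel=0.01, abs=0.01 * LUMEN_AREA / 10)
            assert pa == pytest.approx(pa_pix, rel=0.01, abs=0.05)

    def test_vertex_areas_sum_to_surface_area(self):
        surf, _ = make_valve_state("ideal_closed")
        assert vertex_areas(surf).sum() == pytest.approx(surf.face_areas().sum())
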