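"""Cycloid grid geometry and intersection/point counting."""

import math

import numpy as np
import pytest
import shapely
from scipy.spatial import cKDTree

from nervestereo.errors import (
    DegenerateGeometryError,
    InvalidParameterError,
    NoPoreError,
)
from nervestereo.grid import (
    CycloidGrid,
    SectionPlane,
    build_grid,
    count,
    lamina_orientation,
    mask_to_polygon,
    restriction_line,
)

from conftest import disc_section


def grid_points_mod_tile(grid, frame_grid):
    """All sampled arc points of ``grid`` folded into ``frame_grid``'s tile."""
    u_dir, v_dir = frame_grid.local_frame()
    phase_vec = frame_grid.phase[0] * u_dir + frame_grid.phase[1] * v_dir
    pts = np.concatenate(grid.arcs) - phase_vec
    uv = np.column_stack([pts @ u_dir, pts @ v_dir])
    uv[:, 0] %= frame_grid.tile[0]
    uv[:, 1] %= frame_grid.tile[1]
    return uv


class TestBuildGrid:
    def test_arc_length_is_lp(self):
        """One full cycloid arc has length 8 r_c = l/p (within 0.1%)."""
        g = build_grid(1.0, math.pi / 2, (0.0, 0.0), (0, 0, 2, 2))
        lengths = [
            np.sum(np.hypot(*np.diff(arc, axis=0).T)) for arc in g.arcs
        ]
        assert np.allclose(lengths, 8 * g.arc_scale, rtol=1e-3)
        assert g.lp == pytest.approx(8 * g.arc_scale)

    def test_line_length_density(self):
        """Total arc length / area = lp / (area per point) on a many-tile extent."""
        lp = 0.8
        g = build_grid(lp, math.pi / 2, (0.0, 0.0), (0, 0, 10, 10))
        # total arc length clipped to a central window, related to its area
        x0, x1 = 1.0, 9.0
        total = 0.0
        for arc in g.arcs:
            seg_len = np.hypot(*np.diff(arc, axis=0).T)
            mid = 0.5 * (arc[1:] + arc[:-1])
            inside = (
                (mid[:, 0] >= x0)
                & (mid[:, 0] <= x1)
                & (mid[:, 1] >= x0)
                & (mid[:, 1] <= x1)
            )
            total += float(seg_len[inside].sum())
        expected = (x1 - x0) ** 2 * lp / g.area_per_point
        assert total == pytest.approx(expected, rel=0.005)

    def test_phase_shift_by_one_tile_is_identity(self):
        g0 = build_grid(1.0, 0.3, (0.05, 0.11), (0, 0, 3, 3))
        g1 = build_grid(
            1.0, 0.3, (0.05 + g0.tile[0], 0.11 + g0.tile[1]), (0, 0, 3, 3)
        )
        a = np.sort(np.round(np.concatenate(g0.arcs), 9), axis=0)
        b = np.sort(np.round(np.concatenate(g1.arcs), 9), axis=0)
        # identical arc sets modulo indexing: nearest-neighbour distance zero
        tree = cKDTree(np.concatenate(g0.arcs))
        d, _ = tree.query(np.concatenate(g1.arcs))
        assert d.max() < 1e-9

    def test_pi_rotation_reproduces_geometry(self):
        """The two-arc tile packs with 2-fold symmetry: rotating the grid by π
        yields the same arc set modulo a lattice translation."""
        phi = 0.4
        g0 = build_grid(1.0, phi, (0.0, 0.0), (0, 0, 3, 3))
        g1 = build_grid(1.0, phi + math.pi, (0.0, 0.0), (0, 0, 3, 3))
        uv0 = grid_points_mod_tile(g0, g0)
        uv1 = grid_points_mod_tile(g1, g0)
        # the symmetry maps the set onto itself shifted by half a tile in u
        uv1[:, 0] = (uv1[:, 0] + g0.tile[0] / 2.0) % g0.tile[0]
        tree = cKDTree(np.vstack([uv0, uv0 + [g0.tile[0], 0], uv0 + [0, g0.tile[1]]]))
        d, _ = tree.query(uv1)
        assert d.max() < 1e-8

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            build_grid(0.0, 0.0, (0, 0), (0, 0, 1, 1))
        with pytest.raises(InvalidParameterError):
            build_grid(1.0, 0.0, (0, 0), (1, 1, 1, 1))

    def test_minor_axis_parallel_to_orientation(self):
        """Arc extents: 2 r_c along the orientation (minor) axis, 2π r_c across."""
        phi = 1.1
        g = build_grid(1.0, phi, (0.0, 0.0), (0, 0, 3, 3))
        u_dir, v_dir = g.local_frame()
        arc = g.arcs[len(g.arcs) // 2]
        spans_v = (arc @ v_dir).max() - (arc @ v_dir).min()
        spans_u = (arc @ u_dir).max() - (arc @ u_dir).min()
        # polyline sampling misses the exact apex by O((Δt)²)
        assert spans_v == pytest.approx(2 * g.arc_scale, rel=1e-4)
        assert spans_u == pytest.approx(2 * math.pi * g.arc_scale, rel=1e-6)


class TestLaminaOrientation:
    def test_horizontal_trace(self):
        sp = SectionPlane(
            image=np.zeros((4, 4), np.uint16),
            spacing=(0.01, 0.01),
            lamina_trace=np.array([[0.0, 0.5], [1.0, 0.5], [2.0, 0.5]]),
        )
        assert lamina_orientation(sp) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phi", [0.2, 0.9, 1.7, 2.8])
    def test_rotation_equivariance(self, phi):
        t = np.linspace(0, 1, 30)
        base = np.column_stack([t, np.zeros_like(t)])
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        sp = SectionPlane(
            image=np.zeros((4, 4), np.uint16),
            spacing=(0.01, 0.01),
            lamina_trace=base @ rot.T,
        )
        assert lamina_orientation(sp) == pytest.approx(phi % math.pi, abs=1e-6)

    def test_noisy_trace_recovers_slope(self, rng):
        """TLS through a 1 px-noise trace recovers a 30° slope within 2°."""
        phi = math.radians(30.0)
        t = np.linspace(0, 3.0, 300)
        pts = np.column_stack([t * math.cos(phi), t * math.sin(phi)])
        pts += rng.normal(0, 0.01, pts.shape)  # σ = 1 px at 10 nm pixels
        sp = SectionPlane(
            image=np.zeros((4, 4), np.uint16), spacing=(0.01, 0.01), lamina_trace=pts
        )
        assert abs(math.degrees(lamina_orientation(sp)) - 30.0) < 2.0

    def test_degenerate_trace_raises(self):
        sp = SectionPlane(
            image=np.zeros((4, 4), np.uint16),
            spacing=(0.01, 0.01),
            lamina_trace=np.array([[0.5, 0.5]] * 5),
        )
        with pytest.raises(DegenerateGeometryError):
            lamina_orientation(sp)


class TestRestrictionLine:
    def make_section(self, centroid_y):
        return SectionPlane(
            image=np.zeros((4, 4), np.uint16),
            spacing=(0.01, 0.01),
            lamina_trace=np.array([[0.0, 0.0], [4.0, 0.0]]),
            pore_endpoints=(np.array([0.0, 0.0]), np.array([4.0, 0.0])),
            epithelium_centroid=np.array([2.0, centroid_y]),
        )

    def test_stromal_side_opposes_epithelium(self):
        rl = restriction_line(self.make_section(centroid_y=-1.0))
        assert rl.stromal_side(np.array([[2.0, 1.0]]))[0]  # y > 0 is stromal
        assert not rl.stromal_side(np.array([[2.0, -1.0]]))[0]

    def test_missing_pore_raises(self):
        sp = SectionPlane(image=np.zeros((4, 4), np.uint16), spacing=(0.01, 0.01))
        with pytest.raises(NoPoreError):
            restriction_line(sp)


class TestCount:
    def test_disc_crossed_by_straight_segment(self):
        """A straight test line through a disc crosses its boundary twice."""
        sp = disc_section(0.3)
        segment = np.column_stack([np.linspace(0, 1.2, 400), np.full(400, 0.6)])
        grid = CycloidGrid(
            lp=1.2,
            arc_scale=0.15,
            orientation=0.0,
            phase=(0.0, 0.0),
            tile=(1.0, 1.0),
            arcs=(segment,),
            points=np.empty((0, 2)),
        )
        tally = count(grid, 1, sp)
        assert tally.I == 2

    def test_empty_mask_counts_zero(self):
        sp = disc_section(0.3)
        sp.image = np.zeros_like(sp.image)
        g = build_grid(1.0, math.pi / 2, (0.0, 0.0), sp.extent)
        with pytest.warns(UserWarning, match="absent"):
            tally = count(g, 1, sp)
        assert (tally.I, tally.P) == (0, 0)

    def test_closed_boundary_gives_even_crossings(self, rng):
        """Arcs entering and leaving a compact region cross an even number of
        times in total; with every arc starting/ending outside, per-arc I is even."""
        for _ in range(20):
            sp = disc_section(rng.uniform(0.1, 0.25), center=(0.6, 0.6))
            g = build_grid(
                rng.uniform(0.3, 0.6),
                rng.uniform(0, math.pi),
                (rng.uniform(0, 0.2), rng.uniform(0, 0.2)),
                sp.extent,
            )
            tally = count(g, 1, sp)
            # disc is far from the extent edge; arcs are short vs the margin
            assert tally.I % 2 == 0

    def test_crossings_match_dense_sampling_oracle(self, rng):
        """128+-vertex counting equals a 10⁴-samples-per-arc brute force."""
        for _ in range(100):
            dx = 0.01
            sp = disc_section(rng.uniform(0.15, 0.45), center=tuple(rng.uniform(0.4, 0.8, 2)), dx=dx)
            lp = rng.uniform(0.4, 1.2)
            phase = (rng.uniform(0, 2 * math.pi * lp / 8), rng.uniform(0, lp / 2))
            ang = rng.uniform(0, math.pi)
            g = build_grid(lp, ang, phase, sp.extent)
            tally = count(g, 1, sp)
            geom = mask_to_polygon(np.asarray(sp.image) == 1, sp.spacing)
            shapely.prepare(geom)
            dense = build_grid(lp, ang, phase, sp.extent, vertices_per_arc=10_000)
            i_oracle = 0
            for arc in dense.arcs:
                ins = shapely.contains_xy(geom, arc[:, 0], arc[:, 1])
                i_oracle += int(np.count_nonzero(ins[1:] != ins[:-1]))
            assert tally.I == i_oracle

    def test_point_counting_estimates_area(self, rng):
        """Mean P × (area per point) over many phases converges to the mask area
        (point counting is unbiased for area)."""
        sp = disc_section(0.35, center=(0.6, 0.6))
        geom = mask_to_polygon(np.asarray(sp.image) == 1, sp.spacing)
        lp = 0.5
        total_p = 0
        n_phase = 500
        for _ in range(n_phase):
            phase = (rng.uniform(0, 2 * math.pi * lp / 8), rng.uniform(0, lp / 2))
            g = build_grid(lp, rng.uniform(0, math.pi), phase, sp.extent)
            total_p += count(g, 1, sp).P
        g0 = build_grid(lp, 0.0, (0, 0), sp.extent)
        est_area = total_p / n_phase * g0.area_per_point
        assert est_area == pytest.approx(geom.area, rel=0.02)

    def test_restriction_partitions_counts(self, rng):
        """Stromal-side + epithelial-side counts equal the unrestricted count."""
        for _ in range(10):
            sp = disc_section(0.3, center=(0.6, 0.6))
            sp.lamina_trace = np.array([[0.0, 0.6], [1.2, 0.6]])
            sp.pore_endpoints = (np.array([0.0, 0.6]), np.array([1.2, 0.6]))
            sp.epithelium_centroid = np.array([0.6, 0.1])  # epithelium above
            lp = 0.6
            phase = (rng.uniform(0, 2 * math.pi * lp / 8), rng.uniform(0, lp / 2))
            g = build_grid(lp, rng.uniform(0, math.pi), phase, sp.extent)
            full = count(g, 1, sp, restricted=False)
            stromal = count(g, 1, sp, restricted=True)
            sp.epithelium_centroid = np.array([0.6, 1.1])  # flip sides
            epithelial = count(g, 1, sp, restricted=True)
            assert stromal.I + epithelial.I == full.I
            assert stromal.P + epithelial.P == full.P
            assert stromal.I <= full.I and stromal.P <= full.P

    def test_mask_on_epithelial_side_restricted_to_zero(self):
        sp = disc_section(0.2, center=(0.6, 0.3))  # disc above the line
        sp.lamina_trace = np.array([[0.0, 0.7], [1.2, 0.7]])
        sp.pore_endpoints = (np.array([0.0, 0.7]), np.array([1.2, 0.7]))
        sp.epithelium_centroid = np.array([0.6, 0.2])  # epithelium also above
        g = build_grid(0.6, math.pi / 2, (0.03, 0.02), sp.extent)
        tally = count(g, 1, sp, restricted=True)
        assert (tally.I, tally.P) == (0, 0)
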