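"""Geometry: splines, chains, orthogonal segments, frames, medial axis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spam import (
    PolygonalChain,
    build_frame,
    coverage_fraction,
    fit_boundary_spline,
    medial_centrality,
    nearest_neighbor_segments,
    sample_chain,
)
from spam.geometry import chains_to_mask, segments_cross


def brute_force_crossings(segments):
    """Independent pairwise interior-crossing count using shapely."""
    from shapely.geometry import LineString

    lines = [LineString([s.endpoint_a, s.endpoint_b]) for s in segments]
    count = 0
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            if lines[i].crosses(lines[j]):
                count += 1
    return count


class TestBoundarySpline:
    def test_two_points_is_straight_segment(self):
        curve = fit_boundary_spline([(0, 0), (10, 0)])
        t0, t1 = curve.parameter_range
        mid = curve(0.5 * (t0 + t1))
        assert mid[1] == pytest.approx(0.0, abs=1e-12)
        assert mid[0] == pytest.approx(5.0, abs=1e-9)

    def test_circle_reconstruction_subpixel(self):
        theta = np.linspace(0, 2 * np.pi, 21)[:-1]
        pts = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        curve = fit_boundary_spline(pts)
        # natural endpoint conditions distort only near the open ends; assess
        # the interior span of the (non-closed) control polygon
        t0, t1 = curve.parameter_range
        dense = curve(np.linspace(t0 + (t1 - t0) * 0.05, t1 - (t1 - t0) * 0.05, 2000))
        radii = np.linalg.norm(dense, axis=1)
        assert np.abs(radii - 50.0).max() < 0.1

    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=12,
            unique=True,
        )
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_interpolates_control_points(self, pts):
        pts = np.asarray(pts, dtype=float)
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            return
        curve = fit_boundary_spline(pts)
        evaluated = curve(curve.knots)
        assert np.allclose(evaluated, pts, atol=1e-9)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_boundary_spline([(0, 0)])
        with pytest.raises(ValueError):
            fit_boundary_spline([(0, 0), (0, 0), (1, 1)])


class TestSampleChain:
    def test_straight_curve_quarter_steps(self):
        curve = fit_boundary_spline([(0, 0), (10, 0)])
        t0, t1 = curve.parameter_range
        chain = sample_chain(curve, (t1 - t0) / 4)
        assert len(chain) == 5
        assert np.allclose(chain.points[:, 1], 0.0, atol=1e-9)

    def test_point_count_matches_enumeration(self):
        curve = fit_boundary_spline([(0, 0), (5, 7), (11, 2), (20, 9)])
        t0, t1 = curve.parameter_range
        step = 0.1
        # direct enumeration of the parameter ladder
        expected = int(np.floor((t1 - t0) / step + 1e-12)) + 1
        hits_end = abs((t1 - t0) / step - round((t1 - t0) / step)) < 1e-9
        if not hits_end:
            expected += 1
        assert len(sample_chain(curve, step)) == expected

    def test_cumulative_length_non_decreasing(self):
        curve = fit_boundary_spline([(0, 0), (5, 7), (11, 2), (20, 9)])
        chain = sample_chain(curve, 0.1)
        assert np.all(np.diff(chain.cumulative_length) >= 0)

    def test_rejects_nonpositive_step(self):
        curve = fit_boundary_spline([(0, 0), (10, 0)])
        with pytest.raises(ValueError):
            sample_chain(curve, 0.0)


class TestNearestNeighborSegments:
    def test_parallel_chains_all_vertical_and_mutual(self):
        xs = np.arange(10.0)
        a = PolygonalChain(np.column_stack([xs, np.zeros(10)]))
        b = PolygonalChain(np.column_stack([xs, np.full(10, 10.0)]))
        segs = nearest_neighbor_segments(a, b)
        assert len(segs) == 10
        for s in segs:
            assert s.length == pytest.approx(10.0)
            assert s.endpoint_a[0] == pytest.approx(s.endpoint_b[0])
            assert s.mutual

    def test_concentric_arcs_segments_radial(self):
        theta_a = np.linspace(0, np.pi / 2, 40)
        theta_b = np.linspace(0, np.pi / 2, 120)
        a = PolygonalChain(5.0 * np.column_stack([np.cos(theta_a), np.sin(theta_a)]))
        b = PolygonalChain(15.0 * np.column_stack([np.cos(theta_b), np.sin(theta_b)]))
        segs = nearest_neighbor_segments(a, b)
        # brute-force oracle over all point pairs
        for s in segs:
            d = np.linalg.norm(b.points - s.endpoint_a, axis=1)
            assert np.linalg.norm(s.endpoint_b - s.endpoint_a) == pytest.approx(d.min())
            # radial alignment: angles of the two endpoints agree within sampling
            ang_a = np.arctan2(s.endpoint_a[1], s.endpoint_a[0])
            ang_b = np.arctan2(s.endpoint_b[1], s.endpoint_b[0])
            assert abs(ang_a - ang_b) < (np.pi / 2) / 119 + 1e-9

    def test_single_point_chains(self):
        a = PolygonalChain([[0.0, 0.0]])
        b = PolygonalChain([[3.0, 4.0]])
        segs = nearest_neighbor_segments(a, b)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(5.0)

    def test_mutual_pairs_symmetric_under_chain_swap(self, arch_chains):
        ca, cb = arch_chains
        fwd = {(s.index_a, s.index_b) for s in nearest_neighbor_segments(ca, cb) if s.mutual}
        rev = {(s.index_b, s.index_a) for s in nearest_neighbor_segments(cb, ca) if s.mutual}
        assert fwd == rev

    def test_rejects_empty_chain(self):
        with pytest.raises(ValueError):
            PolygonalChain(np.empty((0, 2)))


class TestBuildFrame:
    def test_parallel_chains_identity(self):
        xs = np.arange(20.0)
        a = PolygonalChain(np.column_stack([xs, np.zeros(20)]))
        b = PolygonalChain(np.column_stack([xs, np.full(20, 8.0)]))
        frame = build_frame(a, b)
        assert brute_force_crossings(frame.segments) == 0
        assert len(frame) == 20
        assert np.allclose(frame.medial_axis.points[:, 1], 4.0)

    def test_annulus_bend_keeps_outer_segments(self):
        # outer arc (A) is longer; all non-mutual kept segments must come from it
        theta_a = np.linspace(0, np.pi, 300)
        theta_b = np.linspace(0, np.pi, 180)
        a = PolygonalChain(50.0 * np.column_stack([np.cos(theta_a), np.sin(theta_a)]))
        b = PolygonalChain(30.0 * np.column_stack([np.cos(theta_b), np.sin(theta_b)]))
        frame = build_frame(a, b)
        non_mutual = [s for s in frame.segments if not s.mutual]
        assert non_mutual and all(s.origin == "A" for s in non_mutual)
        assert brute_force_crossings(frame.segments) == 0

    def test_s_curve_switches_origin_once_near_inflection(self):
        # centerline y = 20 sin(x/20) on x in [pi/2*20, 3pi/2*20]: single
        # inflection at x = 20*pi where curvature changes sign
        def offset_marks(side, spacing=20.0):
            # sparse marked points on the offset wall of the S centerline
            t = np.linspace(np.pi / 2, 3 * np.pi / 2, 4000)
            c = np.column_stack([20.0 * t, 20.0 * np.sin(t)])
            d = np.gradient(c, axis=0)
            n = np.column_stack([-d[:, 1], d[:, 0]])
            n /= np.linalg.norm(n, axis=1)[:, None]
            off = c + side * 6.0 * n
            cum = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(off, axis=0), axis=1))]
            )
            s = np.append(np.arange(0, cum[-1], spacing), cum[-1])
            return np.column_stack(
                [np.interp(s, cum, off[:, 0]), np.interp(s, cum, off[:, 1])]
            )

        a = sample_chain(fit_boundary_spline(offset_marks(+1.0)))
        b = sample_chain(fit_boundary_spline(offset_marks(-1.0)))
        frame = build_frame(a, b)
        origins = [s.origin for s in frame.segments if s.origin != "mutual"]
        switches = sum(1 for u, v in zip(origins, origins[1:]) if u != v)
        assert switches == 1
        # locate the switch and compare against the analytic inflection x
        idx = next(i for i, (u, v) in enumerate(zip(origins, origins[1:])) if u != v)
        non_mutual = [s for s in frame.segments if s.origin != "mutual"]
        switch_x = non_mutual[idx].midpoint[0]
        assert abs(switch_x - 20.0 * np.pi) < 10.0

    def test_synthetic_vessel_frame_non_crossing(self, arch_frame):
        assert brute_force_crossings(arch_frame.segments) == 0
        assert len(arch_frame.medial_axis.points) == len(arch_frame.segments)

    def test_rejects_opposed_orientation(self):
        xs = np.arange(20.0)
        a = PolygonalChain(np.column_stack([xs, np.zeros(20)]))
        b = PolygonalChain(np.column_stack([xs[::-1], np.full(20, 8.0)]))
        with pytest.raises(ValueError):
            build_frame(a, b)


class TestMedialCentrality:
    def test_parallel_chains_exact_midline(self):
        xs = np.arange(20.0)
        a = PolygonalChain(np.column_stack([xs, np.zeros(20)]))
        b = PolygonalChain(np.column_stack([xs, np.full(20, 8.0)]))
        mean, sd = medial_centrality(build_frame(a, b))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_vessel_subpixel(self, arch_frame):
        mean, sd = medial_centrality(arch_frame)
        assert mean < 1.0
        assert sd < 1.0

    def test_single_segment_sd_zero(self):
        a = PolygonalChain([[0.0, 0.0], [1.0, 0.0]])
        b = PolygonalChain([[0.0, 4.0], [1.0, 4.0]])
        frame = build_frame(a, b)
        sub = frame.segments[:1]
        from spam.geometry import OrthogonalFrame

        single = OrthogonalFrame(
            sub, PolygonalChain([sub[0].midpoint]), frame.chain_a, frame.chain_b
        )
        _, sd = medial_centrality(single)
        assert sd == 0.0


class TestCoverage:
    def test_complete_at_default_step(self, arch_frame, arch_chains, arch_vessel):
        mask = chains_to_mask(*arch_chains, arch_vessel.image.shape)
        assert coverage_fraction(arch_frame, mask) == 1.0

    def test_decreases_with_larger_step(self, arch_vessel, arch_chains):
        ca, cb = arch_chains
        mask = chains_to_mask(ca, cb, arch_vessel.image.shape)
        curve_a = fit_boundary_spline(arch_vessel.boundary_a)
        curve_b = fit_boundary_spline(arch_vessel.boundary_b)
        cov = [
            coverage_fraction(
                build_frame(sample_chain(curve_a, s), sample_chain(curve_b, s)), mask
            )
            for s in (0.1, 1.0, 2.0)
        ]
        assert cov[0] == 1.0
        assert cov[1] < cov[0]
        assert cov[2] < cov[1]

    def test_rejects_empty_mask(self, arch_frame):
        with pytest.raises(ValueError):
            coverage_fraction(arch_frame, np.zeros((10, 10), dtype=bool))


def test_strict_crossing_predicate():
    assert segments_cross([0, 0], [2, 2], [0, 2], [2, 0])
    # shared endpoint is not a crossing
    assert not segments_cross([0, 0], [2, 2], [2, 2], [3, 0])
    assert not segments_cross([0, 0], [1, 0], [0, 1], [1, 1])
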