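"""Aggregate metrics against analytic cases and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay

import rootphene.metrics as M

from conftest import make_root, make_system, random_system, vertical_rod, \
    toy_three_root


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mec_bruteforce(pts):
    """Minimum enclosing circle radius by O(n^3) search over all 2- and
    3-point support sets."""
    pts = np.asarray(pts, dtype=float)

    def covers(c, r):
        return np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9)

    best = np.inf
    n = len(pts)
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - c)
        if r < best and covers(c, r):
            best = r
    for i, j, k in itertools.combinations(range(n), 3):
        c = circumcenter(pts[i], pts[j], pts[k])
        if c is None:
            continue
        r = np.linalg.norm(pts[i] - c)
        if r < best and covers(c, r):
            best = r
    return best


def circumcenter(a, b, c):
    d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) +
             c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        return None
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) +
          (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) +
          (c @ c) * (b[0] - a[0])) / d
    return np.array([ux, uy])


def hull_volume_by_delaunay(pts):
    """Sum of Delaunay tetrahedra volumes = convex hull volume."""
    tri = Delaunay(pts)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = pts[simplex]
        vol += abs(np.linalg.det(np.array([b - a, c - a, d - a]))) / 6.0
    return vol


def depth_counts_bruteforce(system, depths):
    """Half-open straddle test [lo, hi); the deepest point still counts."""
    starts, ends, _ = system.segment_arrays()
    deepest = max(max(s[1], e[1]) for s, e in zip(starts, ends))
    out = []
    for d in depths:
        k = 0
        for s, e in zip(starts, ends):
            lo, hi = min(s[1], e[1]), max(s[1], e[1])
            if (lo <= d < hi) or (hi == d == deepest):
                k += 1
        out.append(k)
    return np.array(out)


def volume_ratio_analytic(system):
    """Independent exact volume split at one-third depth."""
    starts, ends, radii = system.segment_arrays()
    plane = max(p[1] for p in system.endpoints()) / 3.0
    above = below = 0.0
    for s, e, r in zip(starts, ends, radii):
        L = np.linalg.norm(e - s)
        v = math.pi * r * r * L
        lo, hi = min(s[1], e[1]), max(s[1], e[1])
        if hi <= plane:
            above += v
        elif lo >= plane:
            below += v
        else:
            f = (plane - lo) / (hi - lo)
            above += v * f
            below += v * (1 - f)
    return above / below


# ---------------------------------------------------------------------------
# size / extent
# ---------------------------------------------------------------------------

class TestTotals:
    def test_single_cylinder(self, vertical_rod):
        L, A, V = M.totals(vertical_rod)
        assert L == pytest.approx(10.0)
        assert A == pytest.approx(2 * math.pi * 0.05 * 10)
        assert V == pytest.approx(math.pi * 0.05 ** 2 * 10)

    def test_matches_per_segment_sum(self, toy_three_root):
        L, A, V = M.totals(toy_three_root)
        eL = eA = eV = 0.0
        for r in toy_three_root.roots:
            for a, b in zip(r.points[:-1], r.points[1:]):
                l = math.dist(a, b)
                eL += l
                eA += 2 * math.pi * r.radius * l
                eV += math.pi * r.radius ** 2 * l
        assert (L, A, V) == pytest.approx((eL, eA, eV))


class TestMaxDepthWidth:
    def test_vertical_rod(self, vertical_rod):
        assert M.max_depth(vertical_rod) == pytest.approx(10.0)
        assert M.max_width(vertical_rod) == 0.0

    def test_45_degree_depth(self):
        c = math.cos(math.pi / 4)
        pts = [(i * c, i * c, 0) for i in np.arange(0, 10.5, 0.5)]
        s = make_system([make_root(pts)])
        assert M.max_depth(s) == pytest.approx(10 * c)

    def test_equilateral_triangle_width(self):
        h = math.sqrt(3) / 2
        roots = [make_root([(0, 0, 0), (x, 1, z)], root_id=i)
                 for i, (x, z) in enumerate([(0, 0), (1, 0), (0.5, h)])]
        s = make_system(roots)
        assert M.max_width(s) == pytest.approx(2 / math.sqrt(3), rel=1e-9)

    def test_minimum_circle_against_bruteforce(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            pts = rng.uniform(-5, 5, size=(30, 2))
            roots = [make_root([(0, 0, 0), (x, 1.0, z)], root_id=i)
                     for i, (x, z) in enumerate(pts)]
            s = make_system(roots)
            got = M.max_width(s)
            pts_all = s.endpoints()[:, [0, 2]]
            expect = 2 * mec_bruteforce(np.unique(pts_all, axis=0))
            assert got == pytest.approx(expect, rel=1e-9)


class TestDepthProfile:
    def test_single_vertical_root_all_ones(self, vertical_rod):
        prof = M.depth_profile(vertical_rod)
        assert np.all(prof.counts == 1)

    def test_four_parallel_roots(self):
        roots = [make_root([(i, 0, 0), (i, 10, 0)], root_id=i)
                 for i in range(4)]
        prof = M.depth_profile(make_system(roots))
        assert np.all(prof.counts == 4)

    def test_against_interval_straddle_oracle(self, toy_three_root):
        prof = M.depth_profile(toy_three_root, n_slices=37)
        expect = depth_counts_bruteforce(toy_three_root, prof.depths)
        assert np.array_equal(prof.counts, expect)

    def test_random_systems_against_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            s = random_system(rng)
            prof = M.depth_profile(s)
            expect = depth_counts_bruteforce(s, prof.depths)
            assert np.array_equal(prof.counts, expect)


class TestCountStats:
    def test_constant_counts(self):
        prof = M.DepthProfile(np.arange(5.0), np.full(5, 2))
        assert M.count_stats(prof) == (2, 2, 1.0)

    def test_rank_rules_on_1_to_100(self):
        prof = M.DepthProfile(np.arange(100.0), np.arange(1, 101))
        med, p84, bush = M.count_stats(prof)
        assert med == 50.5            # midpoint rule, even n
        assert p84 == 84              # nearest rank: ceil(0.84*100) = 84
        assert bush == pytest.approx(84 / 50.5)

    def test_bushiness_at_least_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = rng.integers(1, 30, size=rng.integers(3, 60))
            _, _, bush = M.count_stats(
                M.DepthProfile(np.arange(len(counts), dtype=float), counts))
            assert bush >= 1.0

    def test_zero_median_flagged(self):
        prof = M.DepthProfile(np.arange(3.0), np.array([0, 0, 5]))
        med, p84, bush = M.count_stats(prof)
        assert math.isnan(bush)


class TestVolumeDistribution:
    def test_uniform_rod_is_half(self):
        pts = [(0, i * 0.5, 0) for i in range(7)]  # depth 3
        s = make_system([make_root(pts)])
        assert M.volume_distribution(s) == pytest.approx(0.5)

    def test_all_mass_above_plane_is_inf(self):
        # wide shallow pancake + one hair-thin deep root
        roots = [make_root([(i, 0, 0), (i, 1, 0)], radius=0.5, root_id=i)
                 for i in range(4)]
        deep = make_root([(0, 0, 0), (0, 30, 0)], radius=1e-12, root_id=99)
        val = M.volume_distribution(make_system(roots + [deep]))
        assert val > 1e10

    def test_against_analytic_split_oracle(self, toy_three_root):
        got = M.volume_distribution(toy_three_root)
        assert got == pytest.approx(volume_ratio_analytic(toy_three_root),
                                    rel=1e-9)

    def test_against_sampling_oracle(self, toy_three_root):
        # Monte-Carlo-free fine subdivision of each segment
        starts, ends, radii = toy_three_root.segment_arrays()
        plane = M.max_depth(toy_three_root) / 3.0
        above = below = 0.0
        for s, e, r in zip(starts, ends, radii):
            for t in np.linspace(0, 1, 10000, endpoint=False) + 5e-5:
                p = s + t * (e - s)
                v = math.pi * r * r * np.linalg.norm(e - s) / 10000
                if p[1] <= plane:
                    above += v
                else:
                    below += v
        assert M.volume_distribution(toy_three_root) == pytest.approx(
            above / below, rel=1e-3)


class TestConvexHull:
    def test_unit_cube(self):
        corners = list(itertools.product([0, 1], repeat=3))
        roots = [make_root([(0, 0, 0), c], root_id=i)
                 for i, c in enumerate(corners) if c != (0, 0, 0)]
        vol, area, degen = M.convex_hull_3d(make_system(roots))
        assert not degen
        assert vol == pytest.approx(1.0)
        assert area == pytest.approx(6.0)

    def test_unit_tetrahedron(self):
        verts = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        roots = [make_root([(0, 0, 0), v], root_id=i)
                 for i, v in enumerate(verts)]
        vol, _, degen = M.convex_hull_3d(make_system(roots))
        assert vol == pytest.approx(1 / 6)

    def test_against_delaunay_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            s = random_system(rng, n_roots=5, n_pts=7)
            vol, _, degen = M.convex_hull_3d(s)
            assert not degen
            assert vol == pytest.approx(
                hull_volume_by_delaunay(s.endpoints()), rel=1e-9)

    def test_coplanar_flagged_degenerate(self):
        roots = [make_root([(0, 0, 0), (x, y, 0)], root_id=i)
                 for i, (x, y) in enumerate([(1, 0), (0, 1), (1, 1)])]
        vol, area, degen = M.convex_hull_3d(make_system(roots))
        assert degen
        assert vol == 0.0
        assert area == pytest.approx(1.0)  # planar hull area


class TestSolidity:
    def test_scale_invariance(self, toy_three_root):
        s0 = M.solidity(toy_three_root)
        scaled = []
        for r in toy_three_root.roots:
            nr = make_root([(2 * x, 2 * y, 2 * z) for x, y, z in r.points],
                           radius=2 * r.radius, class_id=r.class_id,
                           root_id=r.root_id)
            scaled.append(nr)
        assert M.solidity(make_system(scaled)) == pytest.approx(s0,
                                                                rel=1e-9)

    def test_distant_thin_root_decreases_solidity(self, toy_three_root):
        s0 = M.solidity(toy_three_root)
        far = make_root([(0, 0, 0), (30, 1, 30)], radius=1e-4, root_id=77)
        s1 = M.solidity(make_system(toy_three_root.roots + [far]))
        assert s1 < s0


class TestEnclosingEllipse:
    def test_circle_gives_equal_axes(self):
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([3 * np.cos(th), 3 * np.sin(th)])
        maj, mino, asp = M.min_enclosing_ellipse_2d(pts)
        assert maj == pytest.approx(6.0, rel=1e-4)
        assert mino == pytest.approx(6.0, rel=1e-4)
        assert asp == pytest.approx(1.0, abs=1e-4)

    def test_rectangle_corners_analytic(self):
        a, b = 3.0, 1.0
        pts = np.array([[a, b], [a, -b], [-a, b], [-a, -b]])
        maj, mino, asp = M.min_enclosing_ellipse_2d(pts)
        assert maj == pytest.approx(2 * a * math.sqrt(2), rel=1e-4)
        assert mino == pytest.approx(2 * b * math.sqrt(2), rel=1e-4)
        assert asp == pytest.approx(a / b, rel=1e-4)

    def test_containment_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pts = rng.normal(size=(rng.integers(5, 60), 2)) * [3, 1]
            maj, mino, asp, c, A = M.min_enclosing_ellipse_2d(
                pts, return_form=True)
            assert maj >= mino > 0
            # defining property: every point satisfies the ellipse form
            q = np.einsum("ni,ij,nj->n", pts - c, A, pts - c)
            assert np.all(q <= 1.0 + 1e-4)

    def test_collinear_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        maj, mino, asp = M.min_enclosing_ellipse_2d(pts)
        assert mino == 0.0
        assert math.isinf(asp)


class TestFractalBoxCount:
    def test_single_point(self):
        fd, fa, ok = M.fractal_box_count(np.array([[1.0, 2.0, 3.0]]), dim=3)
        assert fd == 0.0 and fa == 0.0

    def test_straight_segment_dimension_one(self):
        pts = np.column_stack([np.zeros(201), np.linspace(0, 10, 201),
                               np.zeros(201)])
        fd, fa, ok = M.fractal_box_count(pts, dim=3)
        assert ok
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_filled_square_dimension_two(self):
        g = np.linspace(0, 10, 101)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        fd, fa, ok = M.fractal_box_count(pts, dim=2)
        assert fd == pytest.approx(2.0, abs=0.1)

    def test_filled_cube_dimension_three(self):
        g = np.linspace(0, 4, 41)
        pts = np.array(list(itertools.product(g, g, g)))
        fd, fa, ok = M.fractal_box_count(pts, dim=3)
        assert 2.8 <= fd <= 3.0

    def test_fa_shifts_by_dim_log_c_under_scaling(self):
        g = np.linspace(0, 4, 41)
        pts = np.array(list(itertools.product(g, g, g)))
        fd0, fa0, _ = M.fractal_box_count(pts, dim=3)
        c = 2.0
        fd1, fa1, _ = M.fractal_box_count(pts * c, dim=3)
        assert fd1 == pytest.approx(fd0, abs=0.05)
        assert fa1 - fa0 == pytest.approx(fd0 * math.log10(c), abs=0.15)


class TestComputeAll:
    def test_composition_matches_parts(self, toy_three_root):
        m = M.compute_all(toy_three_root)
        assert m.total_length == pytest.approx(M.totals(toy_three_root)[0])
        assert m.max_depth == pytest.approx(M.max_depth(toy_three_root))
        assert m.max_width == pytest.approx(M.max_width(toy_three_root))
        vol, area, _ = M.convex_hull_3d(toy_three_root)
        assert m.convex_hull_volume == pytest.approx(vol)
        assert m.solidity == pytest.approx(m.total_volume / vol)
        assert math.isnan(m.ellipse_major)  # 2D-only, filled by projection

    def test_empty_system_rejected(self):
        with pytest.raises(ValueError):
            M.compute_all(make_system([]))

    def test_rotation_invariance_of_3d_metrics(self):
        rng = np.random.default_rng(17)
        s = random_system(rng, n_roots=5, n_pts=10)
        m0 = M.compute_all(s)
        for az in (47.0, 213.9):
            m1 = M.compute_all(s.rotated(az))
            for name in ("total_length", "total_area", "total_volume",
                         "max_depth", "max_width", "median_root_count",
                         "max_root_count", "bushiness",
                         "volume_distribution", "convex_hull_volume",
                         "convex_hull_area", "solidity"):
                assert getattr(m1, name) == pytest.approx(
                    getattr(m0, name), rel=1e-9), name
            assert m1.fd == pytest.approx(m0.fd, abs=0.02)

    def test_monotone_metrics_on_growing_fixture(self):
        from rootphene.simulate import simulate
        from conftest import recovery_spec
        ser = simulate(recovery_spec(cv=0.0), end_day=40, dt=0.5)
        prev = None
        for d in ser.days:
            m = M.compute_all(ser[d])
            if prev is not None:
                for name in ("total_length", "total_area", "total_volume",
                             "max_depth", "convex_hull_volume",
                             "convex_hull_area", "fa"):
                    assert getattr(m, name) >= getattr(prev, name) - 1e-9, \
                        name
            prev = m
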