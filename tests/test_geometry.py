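"""Geometry: AGA computation, triangle rasterization, minimum enclosing
triangle and vertex labeling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfpose.geometry import (
    DegenerateGeometryError,
    Keypoint,
    KeypointTriplet,
    compute_aga,
    label_triangle_vertices,
    min_enclosing_triangle,
    shoelace_area,
    triangle_mask,
    triplet_from_mask,
)


def tri(lv, rv, a):
    return KeypointTriplet(
        LV=Keypoint(*lv), RV=Keypoint(*rv), A=Keypoint(*a)
    )


def law_of_cosines_angle(lv, rv, a):
    u = np.asarray(lv, float) - np.asarray(a, float)
    v = np.asarray(rv, float) - np.asarray(a, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


class TestComputeAga:
    @pytest.mark.parametrize(
        "lv,rv,a,expected",
        [
            ((1, 0), (0, 1), (0, 0), 90.0),
            ((3, 0), (6, 0), (0, 0), 0.0),
            ((0, 5), (0, -5), (0, 0), 180.0),
        ],
    )
    def test_known_angles(self, lv, rv, a, expected):
        assert compute_aga(tri(lv, rv, a)) == pytest.approx(expected, abs=1e-12)

    def test_matches_law_of_cosines_oracle(self):
        assert compute_aga(tri((90, 40), (134, 40), (112, 200))) == pytest.approx(
            law_of_cosines_angle((90, 40), (134, 40), (112, 200)), abs=1e-9
        )

    def test_random_triplets_match_oracle(self, rng):
        for _ in range(2000):
            pts = rng.uniform(-100, 100, size=(3, 2))
            if (
                np.linalg.norm(pts[0] - pts[2]) < 1e-3
                or np.linalg.norm(pts[1] - pts[2]) < 1e-3
            ):
                continue
            got = compute_aga(tri(pts[0], pts[1], pts[2]))
            assert got == pytest.approx(
                law_of_cosines_angle(pts[0], pts[1], pts[2]), abs=1e-9
            )

    @given(
        st.floats(-500, 500),
        st.floats(-500, 500),
        st.floats(0.01, 50),
        st.floats(0, 2 * math.pi),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_similarity_invariance(self, dx, dy, scale, theta):
        """AGA is unchanged by translation, uniform scaling and rotation."""
        base = np.array([[30.0, 10.0], [60.0, 15.0], [45.0, 80.0]])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = (base @ rot.T) * scale + [dx, dy]
        a0 = compute_aga(tri(base[0], base[1], base[2]))
        a1 = compute_aga(tri(moved[0], moved[1], moved[2]))
        assert a1 == pytest.approx(a0, abs=1e-7)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            compute_aga(tri((5, 5), (1, 0), (5, 5)))


class TestTriangleMask:
    def test_covering_triangle_is_all_ones(self):
        t = tri((-100, -100), (100, -100), (0, 300))
        assert triangle_mask(t, 32, 32).all()

    def test_area_within_perimeter_band_of_shoelace(self):
        pts = np.array([[10.0, 10.0], [50.0, 10.0], [30.0, 40.0]])
        t = tri(pts[0], pts[1], pts[2])
        mask = triangle_mask(t, 64, 64)
        area = shoelace_area(pts)
        perim = sum(np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3))
        assert abs(int(mask.sum()) - area) <= perim

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            triangle_mask(tri((0, 0), (5, 5), (10, 10)), 32, 32)

    def test_values_binary(self):
        mask = triangle_mask(tri((3, 4), (20, 6), (12, 25)), 32, 32)
        assert set(np.unique(mask)) <= {0, 1}


# --- independent brute-force enclosing-triangle oracle -----------------


def _oracle_min_triangle_area(hull):
    """Naive flush-side search: every triple of hull edge lines."""
    h = len(hull)
    best = math.inf
    for i in range(h):
        for j in range(h):
            for k in range(h):
                if len({i, j, k}) < 3:
                    continue
                lines = []
                for e in (i, j, k):
                    p = hull[e]
                    d = hull[(e + 1) % h] - hull[e]
                    lines.append((p, d))
                verts = []
                ok = True
                for a in range(3):
                    (p1, d1), (p2, d2) = lines[a], lines[(a + 1) % 3]
                    den = d1[0] * d2[1] - d1[1] * d2[0]
                    if abs(den) < 1e-12:
                        ok = False
                        break
                    t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / den
                    verts.append(p1 + t * d1)
                if not ok:
                    continue
                verts = np.array(verts)
                area = shoelace_area(verts)
                if area < 1e-9:
                    continue
                # containment of all hull points
                d1, d2 = verts[1] - verts[0], verts[2] - verts[0]
                sign = np.sign(d1[0] * d2[1] - d1[1] * d2[0])
                contains = True
                for a in range(3):
                    p, q = verts[a], verts[(a + 1) % 3]
                    s = (q[0] - p[0]) * (hull[:, 1] - p[1]) - (q[1] - p[1]) * (
                        hull[:, 0] - p[0]
                    )
                    if np.any(sign * s < -1e-7):
                        contains = False
                        break
                if contains:
                    best = min(best, area)
    return best


def _random_mask_from_points(rng, n_pts=12, size=48):
    mask = np.zeros((size, size), dtype=np.uint8)
    pts = rng.integers(5, size - 5, size=(n_pts, 2))
    mask[pts[:, 1], pts[:, 0]] = 1
    return mask


class TestMinEnclosingTriangle:
    def test_roundtrip_recovers_elongated_triangle(self):
        """Rasterize a glottal-like triangle, decode it back through the
        minimum enclosing triangle, and label the vertices."""
        # apex A at top, ~17 deg opening; LV (anatomical left) on image right
        t = tri((120, 165), (80, 160), (100, 30))
        mask = triangle_mask(t, 200, 200)
        rec = triplet_from_mask(mask)
        for name in ("LV", "RV", "A"):
            got, want = getattr(rec, name), getattr(t, name)
            assert math.hypot(got.x - want.x, got.y - want.y) <= 2.0

    def test_contains_all_foreground(self, rng):
        from vfpose.geometry import _contains_all

        for _ in range(10):
            mask = _random_mask_from_points(rng)
            verts = min_enclosing_triangle(mask)
            ys, xs = np.nonzero(mask)
            pts = np.column_stack([xs, ys]).astype(float)
            assert _contains_all(verts, pts, tol=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        from vfpose.geometry import _convex_hull

        for _ in range(8):
            mask = _random_mask_from_points(rng, n_pts=12)
            ys, xs = np.nonzero(mask)
            hull = _convex_hull(np.column_stack([xs, ys]))
            if len(hull) > 12:
                continue
            got = shoelace_area(min_enclosing_triangle(mask))
            want = _oracle_min_triangle_area(hull)
            assert got <= want * 1.005
            assert got >= want * 0.995

    @pytest.mark.parametrize(
        "mask",
        [
            np.zeros((10, 10), dtype=np.uint8),  # empty
            np.eye(10, dtype=np.uint8),  # collinear
            np.pad(np.ones((1, 2), dtype=np.uint8), 4),  # two pixels
        ],
    )
    def test_undecodable_masks_raise(self, mask):
        with pytest.raises(DegenerateGeometryError):
            min_enclosing_triangle(mask)


class TestLabelTriangleVertices:
    def test_apex_is_smallest_angle(self):
        # isoceles with ~20 deg apex at (50, 5)
        verts = [(20, 100), (80, 100), (50, 5)]
        out = label_triangle_vertices(verts)
        assert (out.A.x, out.A.y) == (50, 5)

    def test_mirror_flip_swaps_lv_rv(self):
        verts = np.array([(20.0, 100.0), (80.0, 100.0), (50.0, 5.0)])
        out = label_triangle_vertices(verts)
        mirrored = verts.copy()
        mirrored[:, 0] = 100 - mirrored[:, 0]
        out_m = label_triangle_vertices(mirrored)
        assert (out_m.A.x, out_m.A.y) == (100 - out.A.x, out.A.y)
        assert (out_m.LV.x, out_m.LV.y) == (100 - out.RV.x, out.RV.y)
        assert (out_m.RV.x, out_m.RV.y) == (100 - out.LV.x, out.LV.y)

    def test_orientation_convention(self):
        """Cross product (LV-A) x (RV-A) is positive in image coords."""
        out = label_triangle_vertices([(10, 80), (90, 85), (48, 10)])
        u = out.LV.xy - out.A.xy
        v = out.RV.xy - out.A.xy
        assert u[0] * v[1] - u[1] * v[0] > 0

    def test_equilateral_tiebreak_stable_under_vertex_order(self):
        s = 60.0
        verts = np.array([(0.0, 0.0), (s, 0.0), (s / 2, s * math.sqrt(3) / 2)])
        outs = set()
        import itertools

        for perm in itertools.permutations(range(3)):
            out = label_triangle_vertices(verts[list(perm)])
            outs.add(
                tuple(
                    round(c, 9)
                    for kp in (out.LV, out.RV, out.A)
                    for c in (kp.x, kp.y)
                )
            )
        assert len(outs) == 1
        # tie-break: apex has the lowest y (then lowest x)
        out = label_triangle_vertices(verts)
        assert out.A.y == 0.0 and out.A.x == 0.0

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            label_triangle_vertices([(0, 0), (1, 1), (2, 2)])
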