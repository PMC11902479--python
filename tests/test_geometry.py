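import math

import numpy as np
import pytest

from mwmaze import (
    PoolGeometry,
    distance_to_zone,
    m_to_px,
    make_annuli,
    make_quadrants,
    px_to_m,
    zone_of_point,
)
from mwmaze.geometry import border_distances, zone_indices

from oracles import annulus_index, quadrant_index


class TestCalibration:
    def test_pool_center_maps_to_origin(self, geom):
        assert np.allclose(px_to_m(geom, geom.pool_center_px), [0.0, 0.0])

    def test_wall_pixel_maps_to_pool_radius(self, geom):
        p = (geom.pool_center_px[0] + geom.pool_radius_px, geom.pool_center_px[1])
        assert np.hypot(*px_to_m(geom, p)) == pytest.approx(0.90)

    def test_round_trip_identity(self, geom):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 444, (100, 2))
        back = m_to_px(geom, px_to_m(geom, px))
        assert np.abs(back - px).max() < 1e-9 / geom.scale_m_per_px

    def test_y_axis_flip(self, geom):
        up = px_to_m(geom, (geom.pool_center_px[0], geom.pool_center_px[1] - 10))
        assert up[1] > 0


class TestGeometryValidation:
    def test_platform_outside_pool_rejected(self):
        with pytest.raises(ValueError):
            PoolGeometry(platform_center_m=(0.88, 0.0))

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            PoolGeometry(pool_radius_px=0)

    def test_from_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "geom.yaml"
        cfg.write_text(
            "geometry:\n"
            "  pool_diameter_m: 1.8\n"
            "  platform_center_m: [0.45, 0.45]\n"
            "  platform_diameter_m: 0.14\n"
            "  frame_rate_hz: 25\n"
        )
        g = PoolGeometry.from_config(str(cfg))
        assert g.platform_center_m == (0.45, 0.45)


class TestQuadrants:
    def test_zone1_contains_platform_and_clockwise_order(self):
        g = PoolGeometry(platform_center_m=(0.45, 0.45))
        q = make_quadrants(g)
        # zone 1 upper-right, zone 2 lower-right (clockwise)
        assert q.zones[0].angle_start_deg == 0.0
        assert q.zones[1].angle_start_deg == 270.0
        assert zone_of_point(q, g.platform_center_m) == 1

    def test_platform_center_is_zone_one_both_partitions(self, geom, quadrants, annuli):
        assert zone_of_point(quadrants, geom.platform_center_m) == 1
        assert zone_of_point(annuli, geom.platform_center_m) == 1

    def test_boundary_platform_tie_break_clockwise(self):
        # platform exactly on the +y boundary ray between UL and UR:
        # assigned to the clockwise-first adjacent quadrant (UR)
        g = PoolGeometry(platform_center_m=(0.0, 0.45))
        q = make_quadrants(g)
        assert q.zones[0].angle_start_deg == 0.0

    def test_tiling_monte_carlo(self, quadrants, uniform_disc_points):
        idx = zone_indices(quadrants, uniform_disc_points)
        assert set(np.unique(idx)) <= {1, 2, 3, 4}
        counts = np.bincount(idx, minlength=5)[1:]
        sigma = math.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 2500) < 4 * sigma)

    def test_platform_quadrant_move_permutes_labels(self):
        pt = (0.3, 0.3)
        base = zone_of_point(make_quadrants(PoolGeometry(platform_center_m=(0.45, 0.45))), pt)
        # platform one quadrant clockwise: the point is now three clockwise
        # steps from the platform quadrant
        moved = zone_of_point(make_quadrants(PoolGeometry(platform_center_m=(0.45, -0.45))), pt)
        assert base == 1 and moved == 4


class TestAnnuli:
    def test_ring_count_formula(self):
        g = PoolGeometry(platform_center_m=(0.45, 0.0))
        part = make_annuli(g, 1.0)
        assert part.n_zones == 10  # ceil(1.35 / 0.14)
        # dense grid: every ring index actually occurs inside the pool
        xs = np.linspace(-0.9, 0.9, 301)
        gx, gy = np.meshgrid(xs, xs)
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 0.9]
        assert set(zone_indices(part, pts)) == set(range(1, 11))

    def test_single_ring_when_width_covers_pool(self):
        g = PoolGeometry(platform_center_m=(0.0, 0.0))
        with pytest.warns(UserWarning):
            part = make_annuli(g, 0.90 / 0.14)
        assert part.n_zones == 1

    def test_innermost_and_outermost_by_construction(self, geom, annuli):
        assert zone_of_point(annuli, geom.platform_center_m) == 1
        c = np.asarray(geom.platform_center_m)
        far = -c / np.hypot(*c) * geom.pool_radius_m
        assert zone_of_point(annuli, far) == annuli.n_zones

    def test_half_open_interval_membership(self, geom, annuli):
        c = np.asarray(geom.platform_center_m)
        u = np.array([1.0, 0.0])
        assert zone_of_point(annuli, c + 0.20 * u) == 2  # 0.14 <= 0.20 < 0.28
        assert zone_of_point(annuli, c + 0.28 * u) == 3  # inner edge belongs to 3

    def test_index_monotone_in_platform_distance(self, geom, annuli):
        rng = np.random.default_rng(3)
        c = np.asarray(geom.platform_center_m)
        th = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(th), np.sin(th)])
        rr = np.sort(rng.uniform(0, 0.45, 50))
        idx = zone_indices(annuli, c + rr[:, None] * u)
        assert np.all(np.diff(idx) >= 0)

    def test_outside_pool_flagged_invalid(self, annuli):
        assert zone_of_point(annuli, (1.2, 1.2)) == -1


class TestMembershipOracle:
    def test_agreement_with_bruteforce(self, geom, quadrants, annuli, uniform_disc_points):
        pts = uniform_disc_points[:1000]
        qi = zone_indices(quadrants, pts)
        ai = zone_indices(annuli, pts)
        for k, p in enumerate(pts):
            assert qi[k] == quadrant_index(p, geom.platform_center_m)
            assert ai[k] == annulus_index(
                p, geom.platform_center_m, annuli.annulus_width_m, annuli.n_zones
            )


def _discretized_border(partition, zone_index, n=10_000):
    """Boundary point cloud of one zone, for the curve-distance oracle."""
    geom = partition.geom
    R = geom.pool_radius_m
    z = partition.zones[zone_index - 1]
    pts = []
    if partition.kind == "quadrant":
        a0 = math.radians(z.angle_start_deg)
        a1 = math.radians(z.angle_end_deg)
        t = np.linspace(0, 1, n)
        for a in (a0, a1):
            pts.append(np.stack([t * R * math.cos(a), t * R * math.sin(a)], axis=1))
        th = np.linspace(a0, a1, n)
        pts.append(np.stack([R * np.cos(th), R * np.sin(th)], axis=1))
    else:
        c = np.asarray(z.center_m)
        th = np.linspace(0, 2 * np.pi, 4 * n)
        for rad in (z.inner_radius_m, z.outer_radius_m):
            if rad <= 0:
                continue
            ring = c + rad * np.stack([np.cos(th), np.sin(th)], axis=1)
            pts.append(ring[np.hypot(ring[:, 0], ring[:, 1]) <= R])
        wall = R * np.stack([np.cos(th), np.sin(th)], axis=1)
        d = np.hypot(wall[:, 0] - c[0], wall[:, 1] - c[1])
        pts.append(wall[(d >= z.inner_radius_m) & (d <= z.outer_radius_m)])
    return np.vstack([p for p in pts if len(p)])


class TestDistances:
    def test_annulus_inner_zone_border(self, geom, annuli):
        c = np.asarray(geom.platform_center_m)
        p = c + np.array([0.05, 0.0])
        d_center, d_border = distance_to_zone(annuli, 1, p)
        assert d_border == pytest.approx(0.09)
        assert d_center == pytest.approx(0.05)

    def test_platform_center_distance_zero(self, geom, annuli):
        d_center, _ = distance_to_zone(annuli, 1, geom.platform_center_m)
        assert d_center == 0.0

    def test_against_curve_discretization_oracle(self, geom, quadrants, annuli):
        rng = np.random.default_rng(11)
        for part in (quadrants, annuli):
            boundaries = {
                z: _discretized_border(part, z) for z in range(1, part.n_zones + 1)
            }
            for _ in range(250):
                z = int(rng.integers(1, part.n_zones + 1))
                r = geom.pool_radius_m * math.sqrt(rng.random())
                th = rng.uniform(0, 2 * math.pi)
                p = np.array([r * math.cos(th), r * math.sin(th)])
                d = border_distances(part, z, p[None, :])[0]
                b = boundaries[z]
                d_oracle = np.min(np.hypot(b[:, 0] - p[0], b[:, 1] - p[1]))
                assert d == pytest.approx(d_oracle, abs=1e-3)

    def test_invalid_zone_index_rejected(self, annuli):
        with pytest.raises(ValueError):
            distance_to_zone(annuli, 0, (0.0, 0.0))
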