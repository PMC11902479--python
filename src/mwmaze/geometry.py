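"""Metric geometry of the water-maze arena.

The pool is modelled as a disc of configurable diameter (default 1.80 m)
holding a circular escape platform (default 0.14 m diameter).  Everything
downstream works in a metric frame with its origin at the pool centre,
+x right and +y up; pixel coordinates from the video are mapped into this
frame by an affine calibration derived from the detected pool circle.

Two alternative partitions of the pool disc into *zones* are provided:

* four quadrants, bounded by the two diameters aligned with the wall
  markers, numbered clockwise starting from the quadrant that contains
  the platform;
* concentric annuli centred on the platform, of width equal to a multiple
  of the platform diameter, numbered from the innermost ring outwards.

Both partitions tile the disc exactly (half-open boundary conventions),
and both expose membership and distance-to-centre / distance-to-border
queries used by the feature engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PoolGeometry",
    "Zone",
    "ZonePartition",
    "make_quadrants",
    "make_annuli",
    "zone_of_point",
    "zone_indices",
    "distance_to_zone",
    "px_to_m",
    "m_to_px",
]


# ---------------------------------------------------------------------------
# Pool geometry and calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolGeometry:
    """Metric model of the pool, platform and pixel calibration.

    Parameters
    ----------
    pool_center_px
        Pool centre in image coordinates (x, y), pixels.
    pool_radius_px
        Pool radius in pixels; fixes the metre-per-pixel scale.
    pool_diameter_m
        Physical pool diameter, metres.
    platform_center_m
        Platform centre in the pool-centred metric frame (+y up), metres.
    platform_diameter_m
        Physical platform diameter, metres.
    frame_rate_hz
        Video frame rate; one trajectory sample per frame.
    """

    pool_center_px: tuple[float, float] = (222.0, 222.0)
    pool_radius_px: float = 200.0
    pool_diameter_m: float = 1.80
    platform_center_m: tuple[float, float] = (0.39, -0.39)
    platform_diameter_m: float = 0.14
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        if self.pool_radius_px <= 0:
            raise ValueError("pool_radius_px must be positive")
        if self.pool_diameter_m <= 0:
            raise ValueError("pool_diameter_m must be positive")
        if not 0 < self.platform_diameter_m < self.pool_diameter_m:
            raise ValueError("platform must be smaller than the pool")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        r = math.hypot(*self.platform_center_m) + self.platform_diameter_m / 2
        if r > self.pool_diameter_m / 2 + 1e-12:
            raise ValueError("platform does not lie fully inside the pool")

    @property
    def pool_radius_m(self) -> float:
        return self.pool_diameter_m / 2.0

    @property
    def platform_radius_m(self) -> float:
        return self.platform_diameter_m / 2.0

    @property
    def scale_m_per_px(self) -> float:
        return self.pool_diameter_m / (2.0 * self.pool_radius_px)

    @classmethod
    def from_config(cls, source) -> "PoolGeometry":
        """Build a geometry from a YAML/JSON mapping, path or stream.

        Recognised keys mirror the constructor arguments; unknown keys are
        ignored so the block can live inside a larger pipeline config.
        """
        if isinstance(source, dict):
            cfg = source
        else:
            if isinstance(source, (str, bytes)) and "\n" not in str(source):
                with open(source) as fh:
                    cfg = yaml.safe_load(fh)
            else:
                cfg = yaml.safe_load(source)
        cfg = cfg.get("geometry", cfg)
        kwargs = {}
        for key in (
            "pool_center_px",
            "pool_radius_px",
            "pool_diameter_m",
            "platform_center_m",
            "platform_diameter_m",
            "frame_rate_hz",
        ):
            if key in cfg:
                val = cfg[key]
                if isinstance(val, (list, tuple)):
                    val = tuple(float(v) for v in val)
                kwargs[key] = val
        return cls(**kwargs)


def px_to_m(geom: PoolGeometry, p_px) -> np.ndarray:
    """Map image pixels to the pool-centred metric frame (+y up)."""
    p = np.asarray(p_px, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = (p[..., 0] - geom.pool_center_px[0]) * geom.scale_m_per_px
    out[..., 1] = -(p[..., 1] - geom.pool_center_px[1]) * geom.scale_m_per_px
    return out


def m_to_px(geom: PoolGeometry, p_m) -> np.ndarray:
    """Inverse of :func:`px_to_m`."""
    p = np.asarray(p_m, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] / geom.scale_m_per_px + geom.pool_center_px[0]
    out[..., 1] = -p[..., 1] / geom.scale_m_per_px + geom.pool_center_px[1]
    return out


# ---------------------------------------------------------------------------
# Zones and partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Zone:
    """One zone of a partition.

    ``kind == "quadrant"``: an angular sector [angle_start, angle_end)
    measured counterclockwise from +x in degrees, with the half-open edge
    on the counterclockwise end (a boundary ray belongs to the sector that
    lies clockwise of it).

    ``kind == "annulus"``: the ring inner_radius_m <= r < outer_radius_m
    around the platform centre, clipped to the pool disc; the outermost
    ring is closed at its outer edge.
    """

    index: int
    kind: str
    angle_start_deg: float = 0.0
    angle_end_deg: float = 0.0
    inner_radius_m: float = 0.0
    outer_radius_m: float = 0.0
    center_m: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ZonePartition:
    """Ordered list of zones tiling the pool disc."""

    kind: str
    zones: tuple[Zone, ...]
    geom: PoolGeometry
    annulus_width_m: float = 0.0

    @property
    def n_zones(self) -> int:
        return len(self.zones)


def _platform_quadrant(px: float, py: float) -> int:
    """Standard quadrant (0=UR, 1=UL, 2=LL, 3=LR counted CCW) containing
    the point, with boundary rays assigned to the clockwise-adjacent
    sector (a point on +y belongs to the upper-right quadrant)."""
    theta = math.degrees(math.atan2(py, px)) % 360.0
    if theta == 0.0:
        theta = 360.0
    return int(math.ceil(theta / 90.0)) - 1


def make_quadrants(geom: PoolGeometry) -> ZonePartition:
    """Partition the pool into four quadrants along the marker axes.

    Zone 1 is the quadrant containing the platform centre; zones 2-4
    proceed clockwise.  A platform centre exactly on a boundary diameter
    is assigned to the clockwise-first adjacent quadrant, matching the
    half-open sector convention.
    """
    pq = _platform_quadrant(*geom.platform_center_m)
    zones = []
    half_r = geom.pool_radius_m / 2.0
    for i in range(4):
        q = (pq - i) % 4  # clockwise from the platform quadrant
        a0, a1 = 90.0 * q, 90.0 * q + 90.0
        mid = math.radians((a0 + a1) / 2.0)
        zones.append(
            Zone(
                index=i + 1,
                kind="quadrant",
                angle_start_deg=a0,
                angle_end_deg=a1,
                center_m=(half_r * math.cos(mid), half_r * math.sin(mid)),
            )
        )
    return ZonePartition(kind="quadrant", zones=tuple(zones), geom=geom)


def make_annuli(geom: PoolGeometry, width_multiple: float = 1.0) -> ZonePartition:
    """Concentric rings around the platform, width a multiple of the
    platform diameter, numbered innermost to outermost.

    The ring count is ``K = ceil((d + R) / w)`` where ``d`` is the
    platform-centre offset from the pool centre, ``R`` the pool radius and
    ``w`` the ring width: the outermost zone is the last ring whose area
    intersects the pool disc.  Zone 1 is the full disc of radius ``w``
    about the platform centre.
    """
    if width_multiple <= 0:
        raise ValueError("width_multiple must be positive")
    w = width_multiple * geom.platform_diameter_m
    d = math.hypot(*geom.platform_center_m)
    K = math.ceil((d + geom.pool_radius_m) / w - 1e-12)
    if K == 1:
        warnings.warn("annulus width covers the whole pool; single zone")
    zones = tuple(
        Zone(
            index=i + 1,
            kind="annulus",
            inner_radius_m=i * w,
            outer_radius_m=(i + 1) * w,
            center_m=geom.platform_center_m,
        )
        for i in range(K)
    )
    return ZonePartition(
        kind="annulus", zones=zones, geom=geom, annulus_width_m=w
    )


# ---------------------------------------------------------------------------
# Membership
# ---------------------------------------------------------------------------

def zone_indices(
    partition: ZonePartition, points, tolerance: float = 0.05
) -> np.ndarray:
    """Vectorised zone membership; −1 flags points outside the pool disc
    beyond ``tolerance`` (a fraction of the pool radius)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    geom = partition.geom
    r_pool = np.hypot(p[:, 0], p[:, 1])
    invalid = r_pool > geom.pool_radius_m * (1.0 + tolerance)

    if partition.kind == "quadrant":
        pq = _platform_quadrant(*geom.platform_center_m)
        theta = np.degrees(np.arctan2(p[:, 1], p[:, 0])) % 360.0
        theta = np.where(theta == 0.0, 360.0, theta)
        std_q = np.ceil(theta / 90.0).astype(int) - 1
        idx = (pq - std_q) % 4 + 1
    else:
        c = np.asarray(geom.platform_center_m)
        d = np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])
        idx = np.floor(d / partition.annulus_width_m).astype(int) + 1
        idx = np.clip(idx, 1, partition.n_zones)

    idx = np.where(invalid, -1, idx)
    return idx


def zone_of_point(partition: ZonePartition, p, tolerance: float = 0.05) -> int:
    """Zone index (1-based) of a single point; −1 if outside the pool."""
    return int(zone_indices(partition, [p], tolerance=tolerance)[0])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _circle_circle_intersections(c1, r1, c2, r2):
    """Intersection points of two circles (possibly none)."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    d = float(np.hypot(*(c2 - c1)))
    if d < 1e-15 or d > r1 + r2 or d < abs(r1 - r2):
        return []
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h2 = r1**2 - a**2
    h = math.sqrt(max(h2, 0.0))
    mid = c1 + a * (c2 - c1) / d
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    if h == 0.0:
        return [mid]
    return [mid + h * perp, mid - h * perp]


def _dist_to_clipped_circle(p, center, radius, pool_radius_m, endpoints):
    """Distance from points ``p`` (N×2) to the part of circle
    (center, radius) lying inside the pool disc; inf where the arc is
    empty for the fallback direction."""
    p = np.atleast_2d(p)
    c = np.asarray(center, float)
    v = p - c
    dc = np.hypot(v[:, 0], v[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dc[:, None] > 1e-15, v / np.maximum(dc, 1e-15)[:, None], 0.0)
    nearest = c + radius * unit
    # degenerate p at the circle centre: any direction; pick +x
    deg = dc <= 1e-15
    if np.any(deg):
        nearest[deg] = c + np.array([radius, 0.0])
    inside_pool = np.hypot(nearest[:, 0], nearest[:, 1]) <= pool_radius_m + 1e-12
    d_radial = np.abs(dc - radius)
    if endpoints:
        ep = np.asarray(endpoints, float)
        d_ep = np.min(
            np.hypot(p[:, 0][:, None] - ep[:, 0], p[:, 1][:, None] - ep[:, 1]),
            axis=1,
        )
    else:
        d_ep = np.full(len(p), np.inf)
    return np.where(inside_pool, d_radial, d_ep)


def _dist_to_wall_arc(p, pool_radius_m, predicate, endpoints):
    """Distance to the portion of the pool wall satisfying ``predicate``
    (a boolean function of the nearest wall points)."""
    p = np.atleast_2d(p)
    r = np.hypot(p[:, 0], p[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 1e-15, p / np.maximum(r, 1e-15)[:, None], 0.0)
    nearest = pool_radius_m * unit
    deg = r <= 1e-15
    if np.any(deg):
        nearest[deg] = np.array([pool_radius_m, 0.0])
    ok = predicate(nearest)
    d_radial = np.abs(r - pool_radius_m)
    if endpoints:
        ep = np.asarray(endpoints, float)
        d_ep = np.min(
            np.hypot(p[:, 0][:, None] - ep[:, 0], p[:, 1][:, None] - ep[:, 1]),
            axis=1,
        )
    else:
        d_ep = np.full(len(p), np.inf)
    return np.where(ok, d_radial, d_ep)


def _dist_to_segment(p, a, b):
    p = np.atleast_2d(p)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(p[:, 0] - proj[:, 0], p[:, 1] - proj[:, 1])


def border_distances(
    partition: ZonePartition, zone_index: int, points
) -> np.ndarray:
    """Unsigned minimum distance from each point to the boundary of the
    zone (radial segments and wall arc for quadrants; clipped circles and
    wall arc for annuli)."""
    p = np.atleast_2d(np.asarray(points, float))
    geom = partition.geom
    R = geom.pool_radius_m
    zone = partition.zones[zone_index - 1]
    cands = []
    if partition.kind == "quadrant":
        a0 = math.radians(zone.angle_start_deg)
        a1 = math.radians(zone.angle_end_deg)
        e0 = np.array([math.cos(a0), math.sin(a0)]) * R
        e1 = np.array([math.cos(a1), math.sin(a1)]) * R
        cands.append(_dist_to_segment(p, (0.0, 0.0), e0))
        cands.append(_dist_to_segment(p, (0.0, 0.0), e1))

        def in_sector(q):
            th = np.degrees(np.arctan2(q[:, 1], q[:, 0])) % 360.0
            lo = zone.angle_start_deg % 360.0
            return (th - lo) % 360.0 <= 90.0

        cands.append(_dist_to_wall_arc(p, R, in_sector, [e0, e1]))
    else:
        c = np.asarray(zone.center_m)
        for radius in (zone.inner_radius_m, zone.outer_radius_m):
            if radius <= 0:
                continue
            eps = _circle_circle_intersections(c, radius, (0.0, 0.0), R)
            # skip circles entirely outside the pool (no boundary there)
            d_oc = float(np.hypot(*c))
            if d_oc - radius > R:  # pragma: no cover - platform inside pool
                continue
            if d_oc + R < radius:
                continue
            cands.append(_dist_to_clipped_circle(p, c, radius, R, eps))

        def in_ring(q):
            d = np.hypot(q[:, 0] - c[0], q[:, 1] - c[1])
            return (d >= zone.inner_radius_m - 1e-12) & (
                d <= zone.outer_radius_m + 1e-12
            )

        eps_in = _circle_circle_intersections(c, zone.inner_radius_m, (0, 0), R)
        eps_out = _circle_circle_intersections(c, zone.outer_radius_m, (0, 0), R)
        wall = _dist_to_wall_arc(p, R, in_ring, eps_in + eps_out)
        if not np.all(np.isinf(wall)):
            cands.append(wall)
    return np.min(np.vstack(cands), axis=0)


def center_distances(
    partition: ZonePartition, zone_index: int, points
) -> np.ndarray:
    """Euclidean distance to the zone's reference centre (annulus: the
    platform centre; quadrant: the sector bisector at half pool radius)."""
    p = np.atleast_2d(np.asarray(points, float))
    c = np.asarray(partition.zones[zone_index - 1].center_m)
    return np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])


def distance_to_zone(
    partition: ZonePartition, zone_index: int, p
) -> tuple[float, float]:
    """(distance to zone centre, distance to zone border) for one point."""
    if not 1 <= zone_index <= partition.n_zones:
        raise ValueError(f"zone index {zone_index} out of range")
    pt = np.asarray(p, float).reshape(1, 2)
    return (
        float(center_distances(partition, zone_index, pt)[0]),
        float(border_distances(partition, zone_index, pt)[0]),
    )
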