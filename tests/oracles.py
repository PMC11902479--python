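"""Independent brute-force oracles used by the test suite.

Everything here is written as plain scalar per-sample loops, sharing no
code with the package, so that agreement between the two routes checks
the vectorized implementations rather than restating them.
"""

from __future__ import annotations

import math


def wrap_deg(a: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    r = a % 360.0
    if r > 180.0:
        r -= 360.0
    if r <= -180.0:
        r += 360.0
    return r


# ---------------------------------------------------------------------------
# Zone membership and distances (scalar re-derivations)
# ---------------------------------------------------------------------------

def quadrant_index(p, platform_center) -> int:
    def std_q(x, y):
        th = math.degrees(math.atan2(y, x)) % 360.0
        if th == 0.0:
            th = 360.0
        return math.ceil(th / 90.0) - 1

    pq = std_q(*platform_center)
    return (pq - std_q(*p)) % 4 + 1


def annulus_index(p, platform_center, width, n_zones) -> int:
    d = math.hypot(p[0] - platform_center[0], p[1] - platform_center[1])
    return min(int(d // width) + 1, n_zones)


def circle_intersections(c1, r1, c2, r2):
    dx, dy = c2[0] - c1[0], c2[1] - c1[1]
    d = math.hypot(dx, dy)
    if d < 1e-15 or d > r1 + r2 or d < abs(r1 - r2):
        return []
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h2 = r1 * r1 - a * a
    h = math.sqrt(max(h2, 0.0))
    mx, my = c1[0] + a * dx / d, c1[1] + a * dy / d
    px, py = -dy / d, dx / d
    if h == 0.0:
        return [(mx, my)]
    return [(mx + h * px, my + h * py), (mx - h * px, my - h * py)]


def seg_dist(p, a, b):
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    t = ((p[0] - ax) * vx + (p[1] - ay) * vy) / (vx * vx + vy * vy)
    t = min(max(t, 0.0), 1.0)
    return math.hypot(p[0] - (ax + t * vx), p[1] - (ay + t * vy))


def quadrant_border_distance(p, angle_start_deg, pool_radius) -> float:
    a0 = math.radians(angle_start_deg)
    a1 = math.radians(angle_start_deg + 90.0)
    R = pool_radius
    e0 = (R * math.cos(a0), R * math.sin(a0))
    e1 = (R * math.cos(a1), R * math.sin(a1))
    cands = [seg_dist(p, (0.0, 0.0), e0), seg_dist(p, (0.0, 0.0), e1)]
    r = math.hypot(*p)
    if r > 1e-15:
        th = math.degrees(math.atan2(p[1], p[0])) % 360.0
        lo = angle_start_deg % 360.0
        on_arc = (th - lo) % 360.0 <= 90.0
    else:
        on_arc = False  # nearest wall point convention: +x; check angle 0
        on_arc = (0.0 - angle_start_deg % 360.0) % 360.0 <= 90.0
    if on_arc:
        cands.append(abs(r - R))
    else:
        cands.append(min(math.hypot(p[0] - e0[0], p[1] - e0[1]),
                         math.hypot(p[0] - e1[0], p[1] - e1[1])))
    return min(cands)


def annulus_border_distance(p, center, r_in, r_out, pool_radius) -> float:
    R = pool_radius
    d_oc = math.hypot(*center)
    cands = []
    eps_all = {}
    for rad in (r_in, r_out):
        if rad <= 0:
            eps_all[rad] = []
            continue
        eps_all[rad] = circle_intersections(center, rad, (0.0, 0.0), R)
        if d_oc - rad > R or d_oc + R < rad:
            continue  # circle has no part inside the pool
        dc = math.hypot(p[0] - center[0], p[1] - center[1])
        if dc > 1e-15:
            q = (center[0] + rad * (p[0] - center[0]) / dc,
                 center[1] + rad * (p[1] - center[1]) / dc)
        else:
            q = (center[0] + rad, center[1])
        if math.hypot(*q) <= R + 1e-12:
            cands.append(abs(dc - rad))
        elif eps_all[rad]:
            cands.append(min(math.hypot(p[0] - e[0], p[1] - e[1])
                             for e in eps_all[rad]))
    r = math.hypot(*p)
    q = (R * p[0] / r, R * p[1] / r) if r > 1e-15 else (R, 0.0)
    dq = math.hypot(q[0] - center[0], q[1] - center[1])
    if r_in - 1e-12 <= dq <= r_out + 1e-12:
        cands.append(abs(r - R))
    else:
        eps = eps_all.get(r_in, []) + eps_all.get(r_out, [])
        if eps:
            cands.append(min(math.hypot(p[0] - e[0], p[1] - e[1]) for e in eps))
    return min(cands)


# ---------------------------------------------------------------------------
# Brute-force 32-measure computation
# ---------------------------------------------------------------------------

def zone_description(partition, zone_index):
    """Extract plain numbers describing one zone of a package partition
    (the oracle only reads dataclass fields, no package logic)."""
    z = partition.zones[zone_index - 1]
    return {
        "kind": partition.kind,
        "index": z.index,
        "angle_start": z.angle_start_deg,
        "r_in": z.inner_radius_m,
        "r_out": z.outer_radius_m,
        "center": tuple(z.center_m),
        "width": partition.annulus_width_m,
        "n_zones": len(partition.zones),
    }


def oracle_zone_features(
    traj, geom, partition, zone_index,
    eps_m=1e-4, orientation_threshold_deg=20.0,
):
    """All 32 measures by direct per-frame loops."""
    zd = zone_description(partition, zone_index)
    plat = tuple(geom.platform_center_m)
    R = geom.pool_radius_m
    fr = traj.frame_rate_hz
    pts = [tuple(p) for p in traj.points_m]
    times = list(traj.times_s)
    n = len(pts)
    duration = times[-1] - times[0]

    def member(p):
        if zd["kind"] == "quadrant":
            return quadrant_index(p, plat) == zone_index
        return annulus_index(p, plat, zd["width"], zd["n_zones"]) == zone_index

    def border_dist(p):
        if zd["kind"] == "quadrant":
            return quadrant_border_distance(p, zd["angle_start"], R)
        return annulus_border_distance(p, zd["center"], zd["r_in"], zd["r_out"], R)

    def center_dist(p):
        return math.hypot(p[0] - zd["center"][0], p[1] - zd["center"][1])

    inz = [member(p) for p in pts]
    d_center = [center_dist(p) for p in pts]
    d_border = [border_dist(p) for p in pts]

    step_len, headings, hvalid = [], [], []
    for i in range(n - 1):
        dx = pts[i + 1][0] - pts[i][0]
        dy = pts[i + 1][1] - pts[i][1]
        L = math.hypot(dx, dy)
        step_len.append(L)
        if L >= eps_m:
            headings.append(math.degrees(math.atan2(dy, dx)) % 360.0)
            hvalid.append(True)
        else:
            headings.append(None)
            hvalid.append(False)

    # visits
    visits = []  # (start, stop_exclusive, entry_t, exit_t, censored)
    i = 0
    while i < n:
        if inz[i]:
            j = i
            while j + 1 < n and inz[j + 1]:
                j += 1
            censored = j == n - 1
            visits.append(
                (i, j + 1, times[i], times[j] if censored else times[j + 1], censored)
            )
            i = j + 1
        else:
            i += 1

    f = {}

    # turn angle: wrapped diff of consecutive valid headings, attributed
    # to the zone of the later step's starting sample
    valid_idx = [i for i in range(n - 1) if hvalid[i]]
    turn = 0.0
    for a, b in zip(valid_idx[:-1], valid_idx[1:]):
        if inz[b]:
            turn += abs(wrap_deg(headings[b] - headings[a]))
    f["absolute_turn_angle"] = turn

    ref = plat if zone_index == 1 else zd["center"]

    he_plat, he_zone, sel_idx = [], [], []
    for i in range(n - 1):
        if not hvalid[i]:
            continue
        bp = math.degrees(math.atan2(plat[1] - pts[i][1], plat[0] - pts[i][0])) % 360.0
        bz = math.degrees(math.atan2(ref[1] - pts[i][1], ref[0] - pts[i][0])) % 360.0
        if inz[i]:
            he_plat.append(abs(wrap_deg(headings[i] - bp)))
            he_zone.append(abs(wrap_deg(headings[i] - bz)))
            sel_idx.append(i)
    f["avg_heading_error_platform"] = sum(he_plat) / len(he_plat) if he_plat else 0.0
    f["avg_heading_error_zone"] = sum(he_zone) / len(he_zone) if he_zone else 0.0

    db = [d_border[i] for i in range(n) if inz[i]] or d_border
    dc = [d_center[i] for i in range(n) if inz[i]] or d_center
    f["avg_distance_to_border"] = sum(db) / len(db)
    f["max_distance_to_border"] = max(db)
    f["min_distance_to_border"] = min(db)
    f["avg_distance_to_center"] = sum(dc) / len(dc)
    f["max_distance_to_center"] = max(dc)
    f["min_distance_to_center"] = min(dc)

    durs = [v[3] - v[2] for v in visits]
    f["avg_visit_duration"] = sum(durs) / len(durs) if durs else 0.0
    f["longest_visit"] = max(durs) if durs else 0.0
    f["shortest_visit"] = min(durs) if durs else 0.0

    speeds = [step_len[i] * fr for i in range(n - 1) if inz[i]]
    f["avg_speed"] = sum(speeds) / len(speeds) if speeds else 0.0
    f["max_speed"] = max(speeds) if speeds else 0.0

    f["cumulative_distance_from_zone"] = sum(
        d_border[i] for i in range(n) if not inz[i]
    )
    f["distance_in_zone"] = sum(step_len[i] for i in range(n - 1) if inz[i])
    if inz[0]:
        f["distance_until_first_entry"] = 0.0
    elif visits:
        f["distance_until_first_entry"] = sum(step_len[: visits[0][0]])
    else:
        f["distance_until_first_entry"] = sum(step_len)
    f["initial_distance_to_zone"] = d_center[0]

    first_h = next((headings[i] for i in range(n - 1) if hvalid[i]), None)
    if first_h is not None:
        b0 = math.degrees(math.atan2(ref[1] - pts[0][1], ref[0] - pts[0][0])) % 360.0
        delta = wrap_deg(first_h - b0)
        f["initial_heading_error"] = abs(delta)
        f["signed_initial_heading_error"] = -delta
    else:
        f["initial_heading_error"] = 0.0
        f["signed_initial_heading_error"] = 0.0

    t0 = times[0]
    if visits:
        f["latency_first_entry"] = visits[0][2] - t0
        exits = [v[3] for v in visits if not v[4]]
        f["latency_first_exit"] = exits[0] - t0 if exits else duration
        f["latency_last_entry"] = visits[-1][2] - t0
    else:
        f["latency_first_entry"] = duration
        f["latency_first_exit"] = duration
        f["latency_last_entry"] = duration

    q = [quadrant_index(p, plat) for p in pts]
    f["line_crossings"] = float(sum(1 for i in range(n - 1) if q[i] != q[i + 1]))

    f["n_entries"] = float(len(visits))
    f["n_exits"] = float(sum(1 for v in visits if not v[4]))

    if zd["kind"] == "quadrant":
        f["starting_zone"] = float(quadrant_index(pts[0], plat))
    else:
        f["starting_zone"] = float(
            annulus_index(pts[0], plat, zd["width"], zd["n_zones"])
        )

    towards = away = 0
    for i in range(n - 1):
        if inz[i]:
            continue
        dd = d_center[i + 1] - d_center[i]
        if dd < 0:
            towards += 1
        elif dd > 0:
            away += 1
    f["time_moving_towards"] = towards / fr
    f["time_moving_away"] = away / fr

    ori_p = ori_z = 0
    for k, i in enumerate(sel_idx):
        if he_plat[k] < orientation_threshold_deg:
            ori_p += 1
        if he_zone[k] < orientation_threshold_deg:
            ori_z += 1
    f["time_oriented_platform"] = ori_p / fr
    f["time_oriented_zone"] = ori_z / fr

    f["total_time_in_zone"] = sum(inz) / fr
    return f
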