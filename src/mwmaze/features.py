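"""Zone-wise behavioural measures and the trial feature table.

For every zone of a partition (quadrants or platform-centred annuli) 32
measures are computed from the cleaned trajectory: occupancy times and
visit statistics, path length and speed, distances to the zone centre and
border, heading errors towards the platform and the zone centre, turn
angle, approach/retreat times and quadrant line crossings.  Measure units
are degrees, metres, metres per second, seconds or counts.

Operationalization conventions (the published measure list gives names
and units only; the precise definitions here are this package's own and
are documented in the methods note):

* a displacement step is attributed to the zone of its *starting* sample;
* step speed = step length × frame rate;
* headings come from displacement vectors; steps shorter than ``eps_m``
  carry no heading; turn angle is the wrapped difference of consecutive
  valid headings, attributed to the zone of the starting sample of the
  later step;
* "moving towards (away from)" a zone counts out-of-zone steps whose
  distance to the zone centre strictly decreases (increases);
* a trial starting inside a zone counts an entry at t=0; an exit is only
  counted when the animal leaves before trial end;
* never-entered zones: visit/latency measures are censored (latencies to
  trial duration, distance-until-first-entry to total path length, visit
  durations and in-zone sums to 0) and min/max/average distance measures
  fall back to statistics over *all* samples, keeping every cell numeric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    PoolGeometry,
    ZonePartition,
    border_distances,
    center_distances,
    make_annuli,
    make_quadrants,
    zone_indices,
)
from .trajectory import Trajectory

__all__ = [
    "MEASURES",
    "MEASURE_UNITS",
    "Visit",
    "segment_visits",
    "heading_series",
    "compute_zone_features",
    "build_feature_table",
    "write_feature_table",
    "EXPERIMENT_MEASURES",
]

# Table of the 32 measures, in the order they are reported.
MEASURE_UNITS: dict[str, str] = {
    "absolute_turn_angle": "deg",
    "avg_heading_error_platform": "deg",
    "avg_heading_error_zone": "deg",
    "avg_distance_to_border": "m",
    "avg_distance_to_center": "m",
    "avg_visit_duration": "s",
    "avg_speed": "m/s",
    "cumulative_distance_from_zone": "m",
    "distance_in_zone": "m",
    "distance_until_first_entry": "m",
    "initial_distance_to_zone": "m",
    "initial_heading_error": "deg",
    "latency_first_entry": "s",
    "latency_first_exit": "s",
    "latency_last_entry": "s",
    "line_crossings": "count",
    "longest_visit": "s",
    "max_distance_to_border": "m",
    "max_distance_to_center": "m",
    "max_speed": "m/s",
    "min_distance_to_border": "m",
    "min_distance_to_center": "m",
    "n_entries": "count",
    "n_exits": "count",
    "shortest_visit": "s",
    "signed_initial_heading_error": "deg",
    "starting_zone": "index",
    "time_moving_away": "s",
    "time_moving_towards": "s",
    "time_oriented_platform": "s",
    "time_oriented_zone": "s",
    "total_time_in_zone": "s",
}
MEASURES: tuple[str, ...] = tuple(MEASURE_UNITS)

# measure subsets used by the classification experiments
EXPERIMENT_MEASURES = {
    "occupancy": ("n_entries", "total_time_in_zone"),
    "all": MEASURES,
}


@dataclass(frozen=True)
class Visit:
    """One maximal contiguous stay in a zone (sample index range is
    half-open)."""

    zone_index: int
    entry_time_s: float
    exit_time_s: float
    start: int
    stop: int
    censored: bool  # trial ended while still inside


def segment_visits(
    traj: Trajectory, partition: ZonePartition, zone_index: int
) -> list[Visit]:
    """Maximal runs of consecutive samples inside the zone."""
    inz = zone_indices(partition, traj.points_m) == zone_index
    return _visits_from_mask(inz, traj.times_s, zone_index)


def _visits_from_mask(inz: np.ndarray, times: np.ndarray, zone_index: int):
    visits = []
    n = len(inz)
    i = 0
    while i < n:
        if inz[i]:
            j = i
            while j + 1 < n and inz[j + 1]:
                j += 1
            censored = j == n - 1
            visits.append(
                Visit(
                    zone_index=zone_index,
                    entry_time_s=float(times[i]),
                    exit_time_s=float(times[j] if censored else times[j + 1]),
                    start=i,
                    stop=j + 1,
                    censored=censored,
                )
            )
            i = j + 1
        else:
            i += 1
    return visits


def _wrap_deg(a):
    """Wrap angles into (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def heading_series(traj: Trajectory, eps_m: float = 1e-4):
    """Per-step heading (degrees in [0, 360), east = 0, north = 90) and a
    validity mask; steps shorter than ``eps_m`` carry no heading."""
    steps = np.diff(traj.points_m, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    valid = lengths >= eps_m
    headings = np.degrees(np.arctan2(steps[:, 1], steps[:, 0])) % 360.0
    headings[~valid] = np.nan
    return headings, valid


def _bearings_to(points: np.ndarray, target) -> np.ndarray:
    t = np.asarray(target, float)
    return np.degrees(
        np.arctan2(t[1] - points[:, 1], t[0] - points[:, 0])
    ) % 360.0


def _heading_reference(partition, zone, geom):
    """Reference point for heading-error measures: the platform centre for
    the platform-containing zone, the zone centre otherwise (for annuli the
    two coincide)."""
    if zone.index == 1:
        return np.asarray(geom.platform_center_m, float)
    return np.asarray(zone.center_m, float)


def compute_zone_features(
    traj: Trajectory,
    geom: PoolGeometry,
    partition: ZonePartition,
    zone_index: int,
    quadrant_partition: ZonePartition | None = None,
    eps_m: float = 1e-4,
    orientation_threshold_deg: float = 20.0,
) -> dict[str, float]:
    """All 32 measures for one (trial, zone); never returns missing values.

    ``quadrant_partition`` backs the line-crossings measure (quadrant
    boundary transitions over the whole path, identical for every zone of
    a partition); it defaults to quadrants derived from ``geom``.
    """
    zone = partition.zones[zone_index - 1]
    pts = traj.points_m
    times = traj.times_s
    fr = traj.frame_rate_hz
    n = len(pts)
    duration = float(times[-1] - times[0])

    zidx = zone_indices(partition, pts)
    inz = zidx == zone_index
    visits = _visits_from_mask(inz, times, zone_index)

    steps = np.diff(pts, axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    step_in = inz[:-1]  # step belongs to the zone of its starting sample

    headings, hvalid = heading_series(traj, eps_m)
    d_center = center_distances(partition, zone_index, pts)
    d_border = border_distances(partition, zone_index, pts)

    f: dict[str, float] = {}

    # --- turn angle (1) ---
    hv = np.nonzero(hvalid)[0]
    turn_abs = 0.0
    if len(hv) >= 2:
        dh = np.abs(_wrap_deg(headings[hv[1:]] - headings[hv[:-1]]))
        # a turn belongs to the zone of the later step's starting sample
        turn_abs = float(np.sum(dh[step_in[hv[1:]]]))
    f["absolute_turn_angle"] = turn_abs

    # --- heading errors (2, 3) ---
    ref = _heading_reference(partition, zone, geom)
    plat = np.asarray(geom.platform_center_m, float)
    bear_plat = _bearings_to(pts[:-1], plat)
    bear_zone = _bearings_to(pts[:-1], ref)
    he_plat = np.abs(_wrap_deg(headings - bear_plat))
    he_zone = np.abs(_wrap_deg(headings - bear_zone))
    sel = step_in & hvalid
    f["avg_heading_error_platform"] = float(np.mean(he_plat[sel])) if sel.any() else 0.0
    f["avg_heading_error_zone"] = float(np.mean(he_zone[sel])) if sel.any() else 0.0

    # --- distance statistics (4, 5, 18, 19, 21, 22) ---
    def _stats(d, mask):
        # empty in-zone sample set falls back to all samples (censoring)
        dd = d[mask] if mask.any() else d
        return float(np.mean(dd)), float(np.max(dd)), float(np.min(dd))

    f["avg_distance_to_border"], f["max_distance_to_border"], f["min_distance_to_border"] = _stats(d_border, inz)
    f["avg_distance_to_center"], f["max_distance_to_center"], f["min_distance_to_center"] = _stats(d_center, inz)

    # --- visit statistics (6, 17, 25) ---
    durs = np.array([v.exit_time_s - v.entry_time_s for v in visits])
    f["avg_visit_duration"] = float(durs.mean()) if len(durs) else 0.0
    f["longest_visit"] = float(durs.max()) if len(durs) else 0.0
    f["shortest_visit"] = float(durs.min()) if len(durs) else 0.0

    # --- speed (7, 20) ---
    sp = step_len * fr
    f["avg_speed"] = float(np.mean(sp[step_in])) if step_in.any() else 0.0
    f["max_speed"] = float(np.max(sp[step_in])) if step_in.any() else 0.0

    # --- distances travelled (8, 9, 10, 11) ---
    f["cumulative_distance_from_zone"] = float(np.sum(d_border[~inz]))
    f["distance_in_zone"] = float(np.sum(step_len[step_in]))
    if inz[0]:
        f["distance_until_first_entry"] = 0.0
    elif visits:
        f["distance_until_first_entry"] = float(np.sum(step_len[: visits[0].start]))
    else:  # never entered: censor to the total path length
        f["distance_until_first_entry"] = float(np.sum(step_len))
    f["initial_distance_to_zone"] = float(d_center[0])

    # --- initial heading error (12, 26); + = clockwise offset ---
    if len(hv):
        h0 = headings[hv[0]]
        bear0 = _bearings_to(pts[:1], ref)[0]
        delta = float(_wrap_deg(h0 - bear0))
        f["initial_heading_error"] = abs(delta)
        f["signed_initial_heading_error"] = -delta
    else:
        f["initial_heading_error"] = 0.0
        f["signed_initial_heading_error"] = 0.0

    # --- latencies (13, 14, 15), relative to trial start ---
    t0 = float(times[0])
    if visits:
        f["latency_first_entry"] = visits[0].entry_time_s - t0
        first_exits = [v.exit_time_s for v in visits if not v.censored]
        f["latency_first_exit"] = (
            first_exits[0] - t0 if first_exits else duration
        )
        f["latency_last_entry"] = visits[-1].entry_time_s - t0
    else:
        f["latency_first_entry"] = duration
        f["latency_first_exit"] = duration
        f["latency_last_entry"] = duration

    # --- line crossings (16): quadrant boundary transitions, whole path ---
    qpart = quadrant_partition or make_quadrants(geom)
    q = zone_indices(qpart, pts)
    f["line_crossings"] = float(np.sum(q[1:] != q[:-1]))

    # --- entries / exits (23, 24) ---
    f["n_entries"] = float(len(visits))
    f["n_exits"] = float(sum(not v.censored for v in visits))

    # --- starting zone (27) ---
    f["starting_zone"] = float(zidx[0])

    # --- approach / retreat (28, 29) ---
    ddc = np.diff(d_center)
    out_step = ~inz[:-1]
    f["time_moving_towards"] = float(np.sum(out_step & (ddc < 0)) / fr)
    f["time_moving_away"] = float(np.sum(out_step & (ddc > 0)) / fr)

    # --- orientation times (30, 31) ---
    ori = sel & (he_plat < orientation_threshold_deg)
    f["time_oriented_platform"] = float(np.sum(ori) / fr)
    ori_z = sel & (he_zone < orientation_threshold_deg)
    f["time_oriented_zone"] = float(np.sum(ori_z) / fr)

    # --- total time (32) ---
    f["total_time_in_zone"] = float(np.sum(inz) / fr)

    return f


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

class ConfigMismatch(RuntimeError):
    """Trials were produced under inconsistent geometry."""


def build_feature_table(
    trials,
    geom: PoolGeometry,
    partitions: dict[str, ZonePartition] | None = None,
    measure_subset=MEASURES,
    annulus_width_multiple: float = 1.0,
) -> pd.DataFrame:
    """Trials × (partition, zone, measure) matrix with label/id columns.

    ``trials`` is an iterable of objects (or dicts) carrying ``trajectory``
    plus ``label``, ``animal_id``, ``day``, ``trial`` metadata.  Column
    names are ``{kind}_z{index}_{measure}`` in deterministic order:
    quadrants before annuli, zones in index order, measures in the
    :data:`MEASURES` order.
    """
    measure_subset = tuple(measure_subset)
    if not measure_subset:
        raise ValueError("measure subset must not be empty")
    unknown = set(measure_subset) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if partitions is None:
        partitions = {
            "quadrant": make_quadrants(geom),
            "annulus": make_annuli(geom, annulus_width_multiple),
        }
    qpart = partitions.get("quadrant") or make_quadrants(geom)

    rows = []
    meta = []
    for trial in trials:
        get = trial.get if isinstance(trial, dict) else lambda k, d=None: getattr(trial, k, d)
        traj = get("trajectory")
        if abs(traj.frame_rate_hz - geom.frame_rate_hz) > 1e-9:
            raise ConfigMismatch("trial frame rate differs from geometry")
        row = {}
        for kind in ("quadrant", "annulus"):
            part = partitions.get(kind)
            if part is None:
                continue
            for z in range(1, part.n_zones + 1):
                feats = compute_zone_features(
                    traj, geom, part, z, quadrant_partition=qpart
                )
                for m in measure_subset:
                    row[f"{kind}_z{z}_{m}"] = feats[m]
        rows.append(row)
        meta.append(
            {
                "label": get("label"),
                "animal_id": get("animal_id"),
                "day": get("day"),
                "trial": get("trial"),
            }
        )
    table = pd.concat([pd.DataFrame(meta), pd.DataFrame(rows)], axis=1)
    return table


FEATURE_META_COLUMNS = ("label", "animal_id", "day", "trial")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in FEATURE_META_COLUMNS]


def write_feature_table(table: pd.DataFrame, csv_path, sidecar_path=None) -> None:
    """CSV plus a JSON sidecar describing each feature column."""
    table.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".meta.json"
    meta = {}
    for col in feature_columns(table):
        kind, zone, measure = col.split("_", 2)
        meta[col] = {
            "partition": kind,
            "zone": int(zone[1:]),
            "measure": measure,
            "unit": MEASURE_UNITS[measure],
        }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)
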