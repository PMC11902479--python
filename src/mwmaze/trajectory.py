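"""Trajectory assembly and rule-based cleaning.

Detections are turned into a metric path sampled once per frame and then
cleaned in three fixed steps, in order:

1. *entropy filter* — sliding-window positional-occupancy entropy flags
   static stretches (tracker locked onto a stain, animal parked on the
   platform edge before the trial is cut) whose windows all fall below a
   normalized-entropy threshold;
2. *percentile filter* — a single pass removing samples whose incoming
   step length exceeds the 95th percentile of all step lengths (tracker
   teleports);
3. *linear interpolation* — interior gaps (missed detections plus samples
   removed above) are filled linearly so the path is continuous at the
   frame rate.

The entropy quantity is **positional**: a window's samples are binned on
a G×G grid over the window's bounding square and the Shannon entropy of
the occupancy distribution, normalized by log(G²), is compared with the
threshold.  The grid side has a floor (``min_extent_m``) and is anchored
at the window minimum, so sub-centimetre jitter around a fixed point
lands in a single bin and scores zero entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import DetectionSeries
from .geometry import PoolGeometry, px_to_m

__all__ = [
    "Trajectory",
    "CleaningParams",
    "EmptyTrack",
    "assemble",
    "entropy_filter",
    "percentile_filter",
    "interpolate",
    "postprocess",
]

DETECTED = "detected"
INTERPOLATED = "interpolated"


class EmptyTrack(RuntimeError):
    """No (or not enough) valid samples to build a path."""


@dataclass
class Trajectory:
    """Timestamped 2-D path in the pool-centred metric frame.

    ``valid`` marks usable samples; ``provenance`` distinguishes directly
    detected samples from interpolated ones.  After :func:`postprocess`
    every sample is valid and the time step is uniform at one frame.
    """

    times_s: np.ndarray
    points_m: np.ndarray
    valid: np.ndarray
    provenance: np.ndarray
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.points_m = np.asarray(self.points_m, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = len(self.times_s)
        if not (len(self.points_m) == len(self.valid) == len(self.provenance) == n):
            raise ValueError("field lengths disagree")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self) else 0.0

    def path_length_m(self) -> float:
        p = self.points_m[self.valid]
        return float(np.sum(np.hypot(*np.diff(p, axis=0).T))) if len(p) > 1 else 0.0

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.times_s.copy(),
            self.points_m.copy(),
            self.valid.copy(),
            self.provenance.copy(),
            self.frame_rate_hz,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times_s,
                "x_m": self.points_m[:, 0],
                "y_m": self.points_m[:, 1],
                "valid": self.valid.astype(int),
                "provenance": self.provenance,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path, frame_rate_hz: float = 25.0, column_map: dict | None = None
    ) -> "Trajectory":
        """Read a trajectory CSV; ``column_map`` renames external tracker
        columns onto time_s/x_m/y_m (valid/provenance default when absent)."""
        df = pd.read_csv(path, float_precision="round_trip")
        if column_map:
            df = df.rename(columns=column_map)
        n = len(df)
        valid = (
            df["valid"].to_numpy().astype(bool)
            if "valid" in df
            else np.ones(n, bool)
        )
        prov = (
            df["provenance"].to_numpy()
            if "provenance" in df
            else np.array([DETECTED] * n, object)
        )
        return cls(
            df["time_s"].to_numpy(float),
            df[["x_m", "y_m"]].to_numpy(float),
            valid,
            prov,
            frame_rate_hz,
        )


@dataclass(frozen=True)
class CleaningParams:
    """Parameters of the three-step cleaning pipeline."""

    entropy_window_n: int = 25          # ~1 s at 25 fps
    entropy_threshold: float = 0.1
    entropy_bins: int = 8
    entropy_min_extent_m: float = 0.05
    displacement_percentile: float = 95.0


def assemble(series: DetectionSeries, geom: PoolGeometry) -> Trajectory:
    """Map detection box centres into the metric frame, one sample per
    frame; frames without a detection are invalid placeholders."""
    if not series.boxes:
        raise EmptyTrack("detection series contains no boxes")
    n = max(series.n_frames, max(series.boxes) + 1)
    fr = series.frame_rate_hz
    times = np.arange(n, dtype=float) / fr
    points = np.zeros((n, 2))
    valid = np.zeros(n, bool)
    prov = np.array([DETECTED] * n, object)
    for i, box in series.boxes.items():
        points[i] = px_to_m(geom, np.asarray(box.center_px, float))
        valid[i] = True
    return Trajectory(times, points, valid, prov, frame_rate_hz=fr)


def _window_entropy(points: np.ndarray, bins: int, min_extent: float) -> float:
    """Normalized occupancy entropy of one window (see module docstring)."""
    mins = points.min(axis=0)
    ext = float(max(np.max(points.max(axis=0) - mins), min_extent))
    edges = np.linspace(0.0, ext, bins + 1)
    h, _, _ = np.histogram2d(
        points[:, 0] - mins[0], points[:, 1] - mins[1], bins=[edges, edges]
    )
    p = h.ravel()
    p = p[p > 0] / p.sum()
    ent = float(-(p * np.log(p)).sum())
    return ent / np.log(bins * bins)


def entropy_filter(
    traj: Trajectory,
    window_n: int = 25,
    threshold: float = 0.1,
    bins: int = 8,
    min_extent_m: float = 0.05,
) -> Trajectory:
    """Invalidate samples every one of whose covering windows is
    low-entropy (static); samples sharing any window with real movement
    are kept, which preserves moving/static boundaries."""
    if window_n < 4:
        raise ValueError("window_n must be at least 4")
    out = traj.copy()
    n = len(traj)
    if n < window_n:
        warnings.warn("trajectory shorter than entropy window; returned unchanged")
        return out
    idx = np.nonzero(traj.valid)[0]
    if len(idx) < window_n:
        return out
    pts = traj.points_m[idx]
    m = len(idx)
    # windows slide over the valid samples
    keep = np.zeros(m, bool)  # rescued by at least one high-entropy window
    covered = np.zeros(m, bool)
    for s in range(m - window_n + 1):
        ent = _window_entropy(pts[s : s + window_n], bins, min_extent_m)
        covered[s : s + window_n] = True
        if ent >= threshold:
            keep[s : s + window_n] = True
    drop = covered & ~keep
    out.valid[idx[drop]] = False
    return out


def percentile_filter(traj: Trajectory, pct: float = 95.0) -> Trajectory:
    """Single-pass displacement filter: the arrival sample of any step
    strictly longer than the ``pct``-th percentile of all steps between
    consecutive valid samples is invalidated; ties are kept."""
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    out = traj.copy()
    idx = np.nonzero(traj.valid)[0]
    if len(idx) < 2:
        return out
    steps = np.diff(traj.points_m[idx], axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])
    thresh = np.percentile(d, pct)
    bad = d > thresh
    out.valid[idx[1:][bad]] = False
    return out


def interpolate(traj: Trajectory) -> Trajectory:
    """Trim leading/trailing invalid runs and linearly fill interior gaps
    in time; filled samples are marked ``interpolated``."""
    idx = np.nonzero(traj.valid)[0]
    if len(idx) < 2:
        raise EmptyTrack("fewer than 2 valid samples")
    lo, hi = idx[0], idx[-1]
    t = traj.times_s[lo : hi + 1]
    p = traj.points_m[lo : hi + 1].copy()
    v = traj.valid[lo : hi + 1]
    prov = traj.provenance[lo : hi + 1].copy()
    tv = t[v]
    for axis in range(2):
        p[~v, axis] = np.interp(t[~v], tv, p[v, axis])
    prov[~v] = INTERPOLATED
    return Trajectory(
        t, p, np.ones(len(t), bool), prov, frame_rate_hz=traj.frame_rate_hz
    )


def postprocess(
    traj: Trajectory, params: CleaningParams | None = None
) -> Trajectory:
    """Entropy filter → percentile filter → interpolation, in that order."""
    params = params or CleaningParams()
    t = entropy_filter(
        traj,
        window_n=params.entropy_window_n,
        threshold=params.entropy_threshold,
        bins=params.entropy_bins,
        min_extent_m=params.entropy_min_extent_m,
    )
    t = percentile_filter(t, pct=params.displacement_percentile)
    return interpolate(t)
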