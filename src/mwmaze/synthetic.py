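"""Synthetic trial generator: swim paths, cohorts and rendered videos.

Swim paths are correlated random walks in the pool disc with four
strategy archetypes commonly described for the water maze — direct swim
(strong attraction toward the platform), thigmotaxis (wall hugging in the
outer radial band), circling (constant angular drift) and random search.
A trial ends on platform contact or at the duration cap.  Cohorts pair a
"young" and an "old" group whose parameter mixtures produce the contrasts
reported for aged animals: the old group swims slower, escapes later and
spends more time far from the platform (thigmotaxis-heavy mixture), which
also makes the group difference partly a *proximity* effect that
platform-centred annuli resolve better than quadrants.

``render_video`` draws each trajectory as a dark blob moving over a
bright pool disc with a brighter rim and four distinct wall markers,
optionally degraded with shimmer noise and single-pixel line artifacts
(camera signal errors), and returns ground-truth boxes for closure tests.

All randomness flows from a single seed through spawned NumPy generators,
so every layer is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import PoolGeometry, m_to_px
from .preprocess import FrameSequence, render_markers
from .trajectory import DETECTED, Trajectory

__all__ = [
    "StrategyParams",
    "CohortSpec",
    "Cohort",
    "CohortTrial",
    "ArtifactParams",
    "simulate_trajectory",
    "simulate_cohort",
    "render_video",
    "default_cohort_spec",
]

STRATEGIES = ("direct_swim", "thigmotaxis", "circling", "random_search")


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of one correlated-random-walk strategy.

    ``platform_attraction`` in [0, 1] blends the heading toward the
    platform bearing each step; ``heading_noise_sd_deg`` is per-step
    angular diffusion; ``turn_bias_deg`` adds constant drift (circling).
    """

    strategy: str = "random_search"
    speed_mean: float = 0.18          # m/s
    speed_sd: float = 0.03
    heading_noise_sd_deg: float = 25.0
    platform_attraction: float = 0.05
    turn_bias_deg: float = 0.0
    max_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.speed_mean <= 0 or self.max_duration_s <= 0:
            raise ValueError("speeds and durations must be positive")


def simulate_trajectory(
    params: StrategyParams, geom: PoolGeometry, seed
) -> tuple[Trajectory, float | None]:
    """One swim path; returns (trajectory, escape time or None).

    The walk starts at a random point near the wall (the release point),
    takes one step per frame with speed ~ N(speed_mean, speed_sd) and a
    heading updated by Gaussian noise, a constant turn bias and partial
    alignment with the platform bearing; the pool wall reflects.  The
    trial ends when the animal touches the platform disc or at
    ``max_duration_s``.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / geom.frame_rate_hz
    R = geom.pool_radius_m
    plat = np.asarray(geom.platform_center_m)
    p_r = geom.platform_radius_m
    n_max = int(round(params.max_duration_s * geom.frame_rate_hz)) + 1

    start_angle = rng.uniform(0, 2 * math.pi)
    pos = 0.92 * R * np.array([math.cos(start_angle), math.sin(start_angle)])
    heading = math.atan2(*(plat - pos)[::-1]) + rng.normal(0, 1.0)

    wall_band = (0.85 * R, 0.97 * R)
    pts = [pos.copy()]
    escape = None
    for i in range(1, n_max):
        speed = max(rng.normal(params.speed_mean, params.speed_sd), 1e-3)
        bearing = math.atan2(plat[1] - pos[1], plat[0] - pos[0])
        # wrap the bearing difference before blending
        diff = (bearing - heading + math.pi) % (2 * math.pi) - math.pi
        heading += params.platform_attraction * diff
        heading += math.radians(params.turn_bias_deg)
        heading += rng.normal(0.0, math.radians(params.heading_noise_sd_deg))
        if params.strategy == "thigmotaxis":
            # steer back into the outer band
            r = np.hypot(*pos)
            tangent = math.atan2(pos[0], -pos[1])  # clockwise tangent
            if r < wall_band[0]:
                outward = math.atan2(pos[1], pos[0])
                heading += 0.5 * ((outward - heading + math.pi) % (2 * math.pi) - math.pi)
            else:
                heading += 0.3 * ((tangent - heading + math.pi) % (2 * math.pi) - math.pi)
        step = speed * dt * np.array([math.cos(heading), math.sin(heading)])
        nxt = pos + step
        r = np.hypot(*nxt)
        if r > 0.98 * R:  # reflect off the wall
            normal = nxt / r
            v = step - 2 * np.dot(step, normal) * normal
            nxt = pos + v
            heading = math.atan2(v[1], v[0])
            r2 = np.hypot(*nxt)
            if r2 > 0.98 * R:
                nxt *= 0.98 * R / r2
        pos = nxt
        pts.append(pos.copy())
        if np.hypot(*(pos - plat)) <= p_r:
            escape = i * dt
            break
    pts = np.asarray(pts)
    n = len(pts)
    times = np.arange(n) * dt
    traj = Trajectory(
        times,
        pts,
        np.ones(n, bool),
        np.array([DETECTED] * n, object),
        frame_rate_hz=geom.frame_rate_hz,
    )
    return traj, escape


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortTrial:
    trajectory: Trajectory
    label: str
    animal_id: str
    day: int
    trial: int
    escape_time_s: float | None = None
    strategy: str = ""


@dataclass
class Cohort:
    trials: list[CohortTrial]
    geom: PoolGeometry
    seed: int

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [t.animal_id for t in self.trials],
                "day": [t.day for t in self.trials],
                "trial": [t.trial for t in self.trials],
                "label": [t.label for t in self.trials],
                "escape_time_s": [t.escape_time_s for t in self.trials],
                "strategy": [t.strategy for t in self.trials],
            }
        )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort design: per-group strategy mixtures with the
    young-faster / young-shorter-latency contrast built in.

    Each animal contributes ``trials_per_day × n_days`` trials.  Mixture
    weights are per-trial strategy probabilities.
    """

    n_young: int = 10
    n_old: int = 10
    n_days: int = 3
    trials_per_day: int = 3
    young_mixture: tuple[tuple[StrategyParams, float], ...] = ()
    old_mixture: tuple[tuple[StrategyParams, float], ...] = ()


def default_cohort_spec(n_young: int = 10, n_old: int = 10) -> CohortSpec:
    """The default study conditions for synthetic cohorts.

    Young animals mostly swim directly toward the platform at higher
    speed; old animals are slower and mix random search with thigmotaxis,
    so they escape later and distribute their time toward the outer
    annuli (a proximity contrast as well as a speed/latency contrast).
    """
    young = (
        (StrategyParams("direct_swim", speed_mean=0.22, speed_sd=0.04,
                        heading_noise_sd_deg=20.0, platform_attraction=0.35), 0.7),
        (StrategyParams("random_search", speed_mean=0.22, speed_sd=0.04,
                        heading_noise_sd_deg=30.0, platform_attraction=0.12), 0.3),
    )
    old = (
        (StrategyParams("random_search", speed_mean=0.15, speed_sd=0.04,
                        heading_noise_sd_deg=35.0, platform_attraction=0.06), 0.5),
        (StrategyParams("thigmotaxis", speed_mean=0.15, speed_sd=0.04,
                        heading_noise_sd_deg=25.0, platform_attraction=0.02), 0.35),
        (StrategyParams("circling", speed_mean=0.15, speed_sd=0.04,
                        heading_noise_sd_deg=20.0, platform_attraction=0.04,
                        turn_bias_deg=6.0), 0.15),
    )
    return CohortSpec(
        n_young=n_young, n_old=n_old, young_mixture=young, old_mixture=old
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
    geom: PoolGeometry | None = None,
    seed: int = 0,
) -> Cohort:
    """Labelled trials for two groups, ``trials_per_day × n_days`` per
    animal, all randomness derived from ``seed``."""
    spec = spec or default_cohort_spec()
    geom = geom or PoolGeometry()
    root = np.random.SeedSequence(seed)
    trials: list[CohortTrial] = []
    groups = [
        ("young", spec.n_young, spec.young_mixture),
        ("old", spec.n_old, spec.old_mixture),
    ]
    animal_seeds = root.spawn(spec.n_young + spec.n_old)
    a = 0
    for label, n_animals, mixture in groups:
        if not mixture:
            raise ValueError(f"empty strategy mixture for group {label!r}")
        params_list = [m[0] for m in mixture]
        weights = np.array([m[1] for m in mixture], float)
        weights /= weights.sum()
        for _ in range(n_animals):
            aseq = animal_seeds[a]
            animal_id = f"{label}_{a:03d}"
            a += 1
            rng = np.random.default_rng(aseq)
            trial_seeds = aseq.spawn(spec.n_days * spec.trials_per_day)
            k = 0
            for day in range(1, spec.n_days + 1):
                for tr in range(1, spec.trials_per_day + 1):
                    params = params_list[rng.choice(len(params_list), p=weights)]
                    traj, escape = simulate_trajectory(
                        params, geom, trial_seeds[k]
                    )
                    k += 1
                    trials.append(
                        CohortTrial(
                            trajectory=traj,
                            label=label,
                            animal_id=animal_id,
                            day=day,
                            trial=tr,
                            escape_time_s=escape,
                            strategy=params.strategy,
                        )
                    )
    return Cohort(trials=trials, geom=geom, seed=seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactParams:
    """Degradations applied to rendered frames (intensity levels 0-255)."""

    shimmer_sd: float = 0.0        # additive Gaussian noise on the water
    n_lines_per_frame: int = 0     # random 1-px dark/bright line segments
    line_amplitude: float = 100.0


@dataclass(frozen=True)
class RenderParams:
    frame_size: int = 444
    surround_level: float = 30.0
    water_level: float = 150.0
    rim_level: float = 210.0
    marker_level: float = 60.0
    blob_level: float = 55.0
    blob_axes_px: tuple[float, float] = (9.0, 6.0)
    rotation_deg: float = 0.0


def render_video(
    traj: Trajectory,
    geom: PoolGeometry,
    artifact_params: ArtifactParams | None = None,
    seed: int = 0,
    render_params: RenderParams | None = None,
    include_blob: bool = True,
) -> tuple[FrameSequence, list]:
    """Render a trajectory as a grayscale frame stack.

    Returns ``(FrameSequence, ground_truth_boxes)`` where each ground
    truth entry is ``(frame_index, cx_px, cy_px, w_px, h_px)``.  The scene
    is a bright water disc with a brighter rim and four distinct dark wall
    markers (rotated by ``rotation_deg`` from canonical), over a dark
    surround; the animal is a dark ellipse oriented along its heading.
    """
    ap = artifact_params or ArtifactParams()
    rp = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    size = rp.frame_size
    cx, cy = geom.pool_center_px
    R = geom.pool_radius_px

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rho = np.hypot(xx - cx, yy - cy)
    base = np.full((size, size), rp.surround_level)
    base[rho <= R] = rp.water_level
    rim = (rho <= R) & (rho >= 0.975 * R)
    base[rim] = rp.rim_level
    render_markers(
        base, (cx, cy), R, angle_deg=rp.rotation_deg, intensity=rp.marker_level
    )

    pts_px = m_to_px(geom, traj.points_m)
    headings = np.zeros(len(pts_px))
    if len(pts_px) > 1:
        d = np.diff(pts_px, axis=0)
        headings[1:] = np.arctan2(d[:, 1], d[:, 0])
        headings[0] = headings[1]

    frames = np.empty((len(pts_px), size, size), dtype=float)
    truth = []
    a, b = rp.blob_axes_px
    pad = int(math.ceil(max(a, b))) + 2
    for i, (px, py) in enumerate(pts_px):
        f = base.copy()
        if include_blob:
            x0, x1 = int(px) - pad, int(px) + pad + 1
            y0, y1 = int(py) - pad, int(py) + pad + 1
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, size), min(y1, size)
            sy, sx = np.mgrid[y0c:y1c, x0c:x1c].astype(float)
            ct, st = math.cos(headings[i]), math.sin(headings[i])
            u = (sx - px) * ct + (sy - py) * st
            v = -(sx - px) * st + (sy - py) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            sub = f[y0c:y1c, x0c:x1c]
            sub[mask] = rp.blob_level
            if mask.any():
                ys2, xs2 = np.nonzero(mask)
                w = float(xs2.max() - xs2.min() + 1)
                h = float(ys2.max() - ys2.min() + 1)
                truth.append(
                    (
                        i,
                        x0c + (xs2.min() + xs2.max()) / 2.0,
                        y0c + (ys2.min() + ys2.max()) / 2.0,
                        w,
                        h,
                    )
                )
        if ap.shimmer_sd > 0:
            noise = rng.normal(0.0, ap.shimmer_sd, f.shape)
            f[rho <= R] += noise[rho <= R]
        for _ in range(ap.n_lines_per_frame):
            amp = ap.line_amplitude * (1 if rng.random() < 0.5 else -1)
            if rng.random() < 0.5:
                r0 = rng.integers(0, size)
                c0, c1 = sorted(rng.integers(0, size, 2))
                f[r0, c0:c1 + 1] = np.clip(f[r0, c0:c1 + 1] + amp, 0, 255)
            else:
                c0 = rng.integers(0, size)
                r0, r1 = sorted(rng.integers(0, size, 2))
                f[r0:r1 + 1, c0] = np.clip(f[r0:r1 + 1, c0] + amp, 0, 255)
        frames[i] = np.clip(f, 0, 255)
    return FrameSequence(frames, frame_rate_hz=geom.frame_rate_hz), truth
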