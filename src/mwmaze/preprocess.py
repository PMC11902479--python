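"""Frame normalization: locate the pool, undo its rotation, mask and blur.

Raw overhead videos show the bright circular pool surrounded by the room,
with four marker shapes on the inside wall whose angular placement varies
between recordings.  Localization matches a zero-mean ring kernel against
the frame by normalized cross-correlation (so global lighting changes do
not move the peak); the in-plane rotation is recovered by correlating the
angular intensity profile of the wall-marker band against the canonical
template profile.  ``normalize_frame`` then rotates the frame back,
centres and crops it to the pool bounding box and zeroes everything
outside the disc, which is the representation the detector consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "FrameSequence",
    "PoolTemplate",
    "PoolNotFound",
    "RotationAmbiguous",
    "make_pool_template",
    "locate_pool",
    "estimate_rotation",
    "normalize_frame",
    "blur",
]

# canonical angular positions (degrees CCW from +x, image y-down frame)
# of the four distinct wall markers
MARKER_ANGLES_DEG = (45.0, 135.0, 225.0, 315.0)
MARKER_BAND = (0.82, 0.96)  # radial band of the markers, fraction of pool radius


class PoolNotFound(RuntimeError):
    """No sufficiently strong ring-correlation peak in the frame."""


class RotationAmbiguous(RuntimeError):
    """The angular correlation profile is too flat to fix a rotation."""


@dataclass
class FrameSequence:
    """Ordered grayscale frames plus timing metadata."""

    frames: np.ndarray  # (n, h, w) float or uint8, 0-255
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (n, h, w) stack")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PoolTemplate:
    """Zero-mean matching kernels: the pool border ring (with its band
    mask, for masked correlation) and the four wall markers at their
    canonical angles."""

    ring_kernel: np.ndarray
    ring_mask: np.ndarray
    marker_kernel: np.ndarray
    radius_px: float


def _marker_stamp(shape_id: int, size: int) -> np.ndarray:
    """Four visually distinct marker shapes (disc, square, triangle, bar)
    so that 90-degree rotations are distinguishable."""
    s = size
    yy, xx = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2
    if shape_id == 0:  # disc
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= (s / 2) ** 2
    elif shape_id == 1:  # square
        m = np.ones((s, s), bool)
    elif shape_id == 2:  # triangle
        m = (yy >= s - 1 - 2 * np.abs(xx - cx)) & (yy < s)
    else:  # horizontal bar
        m = np.abs(yy - cy) <= s / 6
    return m.astype(float)


def render_markers(
    canvas: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    angle_deg: float = 0.0,
    intensity: float = 1.0,
    size_frac: float = 0.07,
) -> None:
    """Stamp the four marker shapes onto ``canvas`` (in place) at the
    marker band, rotated by ``angle_deg`` (CCW in image coordinates)."""
    h, w = canvas.shape
    band_r = radius_px * (MARKER_BAND[0] + MARKER_BAND[1]) / 2.0
    size = max(5, int(round(2 * radius_px * size_frac)))
    for k, base in enumerate(MARKER_ANGLES_DEG):
        th = np.deg2rad(base + angle_deg)
        mx = center[0] + band_r * np.cos(th)
        my = center[1] - band_r * np.sin(th)  # image y is down
        stamp = _marker_stamp(k, size)
        y0 = int(round(my - size / 2))
        x0 = int(round(mx - size / 2))
        ys = slice(max(y0, 0), min(y0 + size, h))
        xs = slice(max(x0, 0), min(x0 + size, w))
        sy = slice(ys.start - y0, ys.stop - y0)
        sx = slice(xs.start - x0, xs.stop - x0)
        sub = stamp[sy, sx]
        canvas[ys, xs] = canvas[ys, xs] * (1 - sub) + intensity * sub


def make_pool_template(
    radius_px: float, ring_width_px: float = 6.0
) -> PoolTemplate:
    """Build zero-mean ring and marker kernels for a pool of the given
    pixel radius.

    The ring kernel models the pool border as seen from above: a bright
    band just inside the wall falling to dark just outside it.  It is
    zero-mean over its annular support so the correlation score is
    invariant to global lighting."""
    r = float(radius_px)
    half = int(np.ceil(r + ring_width_px)) + 2
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size]
    rho = np.hypot(xx - half, yy - half)
    mask = np.abs(rho - r) <= ring_width_px
    ring = np.where(rho < r, 1.0, -1.0) * mask
    ring -= ring[mask].mean()
    ring *= mask

    # markers appear dark against the water, so the kernel is negative
    # where a marker sits
    markers = np.zeros((size, size))
    render_markers(markers, (half, half), r, angle_deg=0.0, intensity=1.0)
    marker = -markers
    marker -= marker.mean()
    return PoolTemplate(
        ring_kernel=ring,
        ring_mask=mask.astype(float),
        marker_kernel=marker,
        radius_px=r,
    )


def _masked_ncc(frame: np.ndarray, kernel: np.ndarray, mask: np.ndarray):
    """Normalized cross-correlation of ``frame`` with ``kernel`` evaluated
    only over the kernel's support ``mask`` (zero pixels of the kernel
    outside the mask do not dilute the normalization)."""
    kf = kernel[::-1, ::-1]
    mf = mask[::-1, ::-1]
    n = mask.sum()
    num = fftconvolve(frame, kf, mode="same")
    s1 = fftconvolve(frame, mf, mode="same")
    s2 = fftconvolve(frame * frame, mf, mode="same")
    var_i = np.maximum(s2 - s1 * s1 / n, 1e-9)
    var_t = float((kernel * kernel).sum())
    return num / np.sqrt(var_t * var_i)


def locate_pool(
    frame: np.ndarray,
    template: PoolTemplate,
    radius_scan: float = 0.10,
    radius_step_px: float = 2.0,
    score_threshold: float = 0.3,
) -> tuple[tuple[float, float], float, float]:
    """Find the pool circle by masked normalized cross-correlation with
    ring kernels over a small radius scan.

    Returns ``((cx, cy), radius_px, score)`` with the centre in image
    (x, y) pixels.  Raises :class:`PoolNotFound` when the best score falls
    below ``score_threshold``.
    """
    frame = np.asarray(frame, dtype=float)
    r0 = template.radius_px
    radii = np.arange(
        r0 * (1 - radius_scan), r0 * (1 + radius_scan) + 1e-9, radius_step_px
    )
    best = (-np.inf, None, None)
    for r in radii:
        tmpl = make_pool_template(r)
        if tmpl.ring_kernel.shape[0] > min(frame.shape):
            continue
        resp = _masked_ncc(frame, tmpl.ring_kernel, tmpl.ring_mask)
        ij = np.unravel_index(np.argmax(resp), resp.shape)
        score = float(resp[ij])
        if score > best[0]:
            best = (score, (float(ij[1]), float(ij[0])), float(r))
    score, center, radius = best
    if center is None or score < score_threshold:
        raise PoolNotFound(f"best ring correlation {score:.3f} below threshold")
    return center, radius, score


def _angular_profile(
    frame: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    n_angles: int,
    n_radii: int = 7,
) -> np.ndarray:
    """Mean intensity over the marker radial band as a function of angle
    (CCW in image coordinates, i.e. screen-clockwise)."""
    angles = np.deg2rad(np.arange(n_angles) * 360.0 / n_angles)
    radii = np.linspace(
        MARKER_BAND[0] * radius_px, MARKER_BAND[1] * radius_px, n_radii
    )
    xs = center[0] + radii[:, None] * np.cos(angles)[None, :]
    ys = center[1] - radii[:, None] * np.sin(angles)[None, :]
    vals = ndimage.map_coordinates(
        np.asarray(frame, float), [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(n_radii, n_angles)
    return vals.mean(axis=0)


def estimate_rotation(
    frame: np.ndarray,
    template: PoolTemplate,
    center_px: tuple[float, float],
    radius_px: float | None = None,
    step_deg: float = 1.0,
    flatness_threshold: float = 0.05,
) -> float:
    """Rotation of the wall markers relative to their canonical placement.

    The marker band of the frame and of the template are resampled into
    angular intensity profiles; their circular normalized cross-correlation
    over a ``step_deg`` grid, refined by a parabolic fit around the peak,
    yields the angle (degrees, in [0, 360)).  Rotating the frame by the
    negative of this angle (image convention of :func:`normalize_frame`)
    restores the canonical marker placement.
    """
    r = template.radius_px if radius_px is None else radius_px
    n = int(round(360.0 / step_deg))
    prof = _angular_profile(frame, center_px, r, n)
    tsize = template.marker_kernel.shape[0]
    tcent = ((tsize - 1) / 2.0, (tsize - 1) / 2.0)
    tprof = _angular_profile(template.marker_kernel, tcent, r, n)

    a = prof - prof.mean()
    b = tprof - tprof.mean()
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise RotationAmbiguous("no angular structure in marker band")
    corr = np.real(np.fft.ifft(np.fft.fft(a) * np.conj(np.fft.fft(b))))
    corr /= len(a) * a.std() * b.std()
    if corr.max() - np.median(corr) < flatness_threshold:
        raise RotationAmbiguous("flat angular correlation profile")
    k = int(np.argmax(corr))
    # parabolic refinement on the wrapped 3-point neighbourhood
    y0, y1, y2 = corr[(k - 1) % n], corr[k], corr[(k + 1) % n]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if abs(denom) < 1e-15 else 0.5 * (y0 - y2) / denom
    return float((k + delta) * step_deg % 360.0)


def normalize_frame(
    frame: np.ndarray,
    center_px: tuple[float, float],
    radius_px: float,
    angle_deg: float = 0.0,
) -> np.ndarray:
    """Rotate by ``-angle_deg`` about the pool centre, crop to the pool
    bounding box (zero-padding as needed) and zero everything outside the
    disc.  Output is a square of side ``2*round(radius)+1`` with the pool
    centre at the middle pixel."""
    frame = np.asarray(frame, dtype=float)
    if abs(angle_deg % 360.0) > 1e-9:
        frame = _sk_rotate(
            frame,
            angle_deg,
            center=center_px,
            preserve_range=True,
            mode="constant",
            cval=0.0,
        )
    r = int(round(radius_px))
    size = 2 * r + 1
    out = np.zeros((size, size), dtype=float)
    cx, cy = int(round(center_px[0])), int(round(center_px[1]))
    ys = slice(max(cy - r, 0), min(cy + r + 1, frame.shape[0]))
    xs = slice(max(cx - r, 0), min(cx + r + 1, frame.shape[1]))
    oy = slice(ys.start - (cy - r), ys.stop - (cy - r))
    ox = slice(xs.start - (cx - r), xs.stop - (cx - r))
    out[oy, ox] = frame[ys, xs]
    yy, xx = np.mgrid[0:size, 0:size]
    out[np.hypot(xx - r, yy - r) > radius_px] = 0.0
    return out


def blur(frame: np.ndarray, sigma_px: float = 1.5) -> np.ndarray:
    """Gaussian blur; ``sigma_px == 0`` returns an unchanged copy."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    frame = np.asarray(frame, dtype=float)
    if sigma_px == 0:
        return frame.copy()
    return ndimage.gaussian_filter(frame, sigma_px, mode="nearest")
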