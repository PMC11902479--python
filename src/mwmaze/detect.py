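"""Background-subtraction animal detection.

A background image — the pool with no animal — is estimated as a
(optionally exponentially) weighted average of all frames; the animal in
each frame is the largest sufficiently large connected region of absolute
difference from that background, returned as a tight bounding box.  Any
callable mapping a :class:`~mwmaze.preprocess.FrameSequence` to a
:class:`DetectionSeries` satisfies the detector contract, so a learned
detector can be slotted in place of this stage without touching the rest
of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import FrameSequence, blur

__all__ = [
    "BoundingBox",
    "DetectionSeries",
    "DetectorParams",
    "InsufficientFrames",
    "build_background",
    "detect_frame",
    "detect_sequence",
]


class InsufficientFrames(RuntimeError):
    """Too few frames to estimate a background."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box around the detected animal in one frame."""

    center_px: tuple[float, float]
    width_px: float
    height_px: float
    confidence: float
    frame_index: int

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("box dimensions must be positive")


@dataclass
class DetectionSeries:
    """Per-frame optional detections for one video."""

    boxes: dict[int, BoundingBox] = field(default_factory=dict)
    n_frames: int = 0
    frame_rate_hz: float = 25.0
    source: str = "background_subtraction"

    def detection_rate(self) -> float:
        return len(self.boxes) / self.n_frames if self.n_frames else 0.0

    def to_csv(self, path) -> None:
        rows = [
            {
                "frame": i,
                "x_px": b.center_px[0],
                "y_px": b.center_px[1],
                "w_px": b.width_px,
                "h_px": b.height_px,
                "confidence": b.confidence,
            }
            for i, b in sorted(self.boxes.items())
        ]
        pd.DataFrame(
            rows, columns=["frame", "x_px", "y_px", "w_px", "h_px", "confidence"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_frames: int | None = None,
                 frame_rate_hz: float = 25.0) -> "DetectionSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        boxes = {
            int(r.frame): BoundingBox(
                center_px=(float(r.x_px), float(r.y_px)),
                width_px=float(r.w_px),
                height_px=float(r.h_px),
                confidence=float(r.confidence),
                frame_index=int(r.frame),
            )
            for r in df.itertuples()
        }
        if n_frames is None:
            n_frames = (max(boxes) + 1) if boxes else 0
        return cls(
            boxes=boxes,
            n_frames=n_frames,
            frame_rate_hz=frame_rate_hz,
            source="external",
        )


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the background-subtraction detector.

    ``diff_threshold`` is in intensity levels on the 0-255 scale;
    ``min_area_px`` rejects specks; ``background_decay`` is the
    exponential weighting rate (0 = plain mean); ``blur_sigma_px`` is the
    Gaussian blur applied before background modelling.
    """

    diff_threshold: float = 25.0
    min_area_px: int = 30
    background_decay: float = 0.0
    blur_sigma_px: float = 1.5


def build_background(frames, decay: float = 0.0) -> np.ndarray:
    """Pixelwise exponentially weighted average of the frames.

    Weights are proportional to ``exp(-decay * age)`` where the last
    frame has age 0; ``decay=0`` reduces to the arithmetic mean.  With the
    animal occupying a small, moving fraction of the pool, the average
    approximates the empty-pool image.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or len(stack) < 10:
        raise InsufficientFrames("need at least 10 frames for a background")
    n = len(stack)
    w = np.exp(-decay * np.arange(n - 1, -1, -1, dtype=float))
    w /= w.sum()
    return np.tensordot(w, stack, axes=1)


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float = 25.0,
    min_area_px: int = 30,
    frame_index: int = 0,
) -> BoundingBox | None:
    """Largest above-threshold difference component as a bounding box.

    The absolute difference from the background is binarized at
    ``threshold``, cleaned by a 3×3 morphological opening, and the largest
    connected component with area >= ``min_area_px`` yields a tight box.
    Confidence is the component's fill fraction of its box.  Returns
    ``None`` when nothing qualifies.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    mask = np.abs(frame - background) >= threshold
    mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), bool))
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area_px:
        return None
    ys, xs = np.nonzero(labels == best)
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    w = float(x1 - x0 + 1)
    h = float(y1 - y0 + 1)
    return BoundingBox(
        center_px=((x0 + x1) / 2.0, (y0 + y1) / 2.0),
        width_px=w,
        height_px=h,
        confidence=float(areas[best - 1] / (w * h)),
        frame_index=frame_index,
    )


def detect_sequence(
    seq: FrameSequence, params: DetectorParams | None = None
) -> DetectionSeries:
    """Blur, model the background, then detect the animal frame by frame."""
    params = params or DetectorParams()
    frames = np.asarray(seq.frames, dtype=float)
    if params.blur_sigma_px > 0:
        frames = np.stack([blur(f, params.blur_sigma_px) for f in frames])
    bg = build_background(frames, decay=params.background_decay)
    series = DetectionSeries(
        n_frames=len(frames), frame_rate_hz=seq.frame_rate_hz
    )
    for i, f in enumerate(frames):
        box = detect_frame(
            f, bg, params.diff_threshold, params.min_area_px, frame_index=i
        )
        if box is not None:
            series.boxes[i] = box
    return series
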