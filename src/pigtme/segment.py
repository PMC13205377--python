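"""Adaptive hue-threshold segmentation and biometric feature extraction.

Works on pseudo-color depth frames in which hue encodes camera-to-object
distance (near objects have low hue).  The segmenter binarizes the hue
channel at an adaptive threshold that starts 15 degrees below the frame's
mean hue and escalates one degree at a time, up to 5 degrees above the
mean, until the largest foreground component's bounding box clears the
image border by more than ``border_px`` pixels; lower thresholds are
preferred because they capture more of the animal.  The animal's head and
tail are then trimmed along the long axis of its minimum-area rectangle,
and four biometric features are measured: dorsal length and abdominal
width (the rectangle's sides, pixels), mean height above the floor
(``camera_height`` minus the mean masked distance, meters) and volume (the
per-pixel sum of the same height, meter*pixel^2).  Per-video medians of the
four features give one estimate per animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage import color as _skcolor

from .simdata import DepthFrame, DepthVideo

__all__ = [
    "BinaryMask",
    "ContourBox",
    "BiometricFeatures",
    "SegmentError",
    "NoPigError",
    "SegmentationFailedError",
    "OverTrimError",
    "NoDepthSignalError",
    "min_area_rect",
    "adaptive_hue_threshold",
    "trim_head_tail",
    "extract_features",
    "aggregate_video",
    "process_video",
]


class SegmentError(RuntimeError):
    """Base class for segmentation failures."""


class NoPigError(SegmentError):
    """No foreground found at any threshold in the adaptive range."""


class SegmentationFailedError(SegmentError):
    """Foreground box still touches the border at the maximum threshold."""


class OverTrimError(SegmentError):
    """Head/tail trimming removed every pixel."""


class NoDepthSignalError(SegmentError):
    """Every masked distance is zero (total sensor dropout)."""


@dataclass
class BinaryMask:
    """Foreground mask plus the hue threshold (degrees) that produced it."""

    mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ContourBox:
    """Minimum-area rotated rectangle of a contour.

    ``corners`` are four (row, col) points in order around the rectangle;
    ``length``/``width`` are the long and short side lengths in pixels and
    ``axis`` is the unit vector of the long side.
    """

    corners: np.ndarray
    length: float
    width: float
    angle_deg: float
    axis: np.ndarray


@dataclass
class BiometricFeatures:
    """Dorsal length, abdominal width (px), mean height (m), volume (m*px^2)."""

    dorsal_length: float
    abdominal_width: float
    height: float
    volume: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dorsal_length": self.dorsal_length,
            "abdominal_width": self.abdominal_width,
            "height": self.height,
            "volume": self.volume,
        }


def min_area_rect(points: np.ndarray) -> ContourBox:
    """Minimum-area enclosing rectangle by rotating calipers on the convex hull.

    The optimal rectangle has one side collinear with a hull edge, so it
    suffices to test each edge direction.  ``points`` are (row, col)
    coordinates; sub-pixel corners are allowed.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        raise ValueError("degenerate (collinear) point set has no area")
    best = None
    k = len(hp)
    for i in range(k):
        e = hp[(i + 1) % k] - hp[i]
        nrm = np.hypot(e[0], e[1])
        if nrm == 0.0:
            continue
        u = e / nrm
        v = np.array([-u[1], u[0]])
        pu = hp @ u
        pv = hp @ v
        w = pu.max() - pu.min()
        h = pv.max() - pv.min()
        if best is None or w * h < best[0]:
            best = (w * h, u, v, pu.min(), pu.max(), pv.min(), pv.max())
    _, u, v, u0, u1, v0, v1 = best
    corners = np.array(
        [
            u0 * u + v0 * v,
            u1 * u + v0 * v,
            u1 * u + v1 * v,
            u0 * u + v1 * v,
        ]
    )
    su, sv = u1 - u0, v1 - v0
    if su >= sv:
        length, width, axis = su, sv, u
    else:
        length, width, axis = sv, su, v
    angle = float(np.degrees(np.arctan2(axis[0], axis[1])))  # vs column axis
    return ContourBox(
        corners=corners, length=float(length), width=float(width), angle_deg=angle, axis=axis
    )


def _boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points of boundary pixels, so box sides span full pixel extents."""
    rr, cc = np.nonzero(mask)
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    br, bc = np.nonzero(mask & ~interior)
    if br.size == 0:
        br, bc = rr, cc
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    base = np.column_stack([br, bc]).astype(np.float64)
    return (base[:, None, :] + offs[None, :, :]).reshape(-1, 2)


def frame_hue_degrees(frame: DepthFrame) -> np.ndarray:
    """Hue channel of the pseudo-color image, degrees in [0, 360)."""
    rgb = np.asarray(frame.color_image, dtype=np.float64) / 255.0
    return _skcolor.rgb2hsv(rgb)[..., 0] * 360.0


def adaptive_hue_threshold(
    frame: DepthFrame,
    border_px: int = 5,
    range_below: float = 15.0,
    range_above: float = 5.0,
    crop: tuple[slice, slice] | None = None,
) -> tuple[BinaryMask, ContourBox]:
    """Segment the animal by escalating hue thresholding.

    Foreground is hue strictly below the threshold (the near-object-is-low-
    hue convention).  Starting at (mean hue - ``range_below``), the threshold
    is raised by one degree at a time until the axis-aligned bounding box of
    the largest 8-connected foreground component keeps all four corners more
    than ``border_px`` pixels from the image edge, up to (mean hue +
    ``range_above``).  A threshold at which essentially the whole frame is
    foreground provides no figure/ground separation and is treated as empty.

    Raises :class:`NoPigError` if no threshold yields foreground and
    :class:`SegmentationFailedError` if the box still touches the border at
    the maximum threshold (such frames are dropped upstream).
    """
    hue = frame_hue_degrees(frame)
    if crop is not None:
        hue = hue[crop]
    rows, cols = hue.shape
    mean_hue = float(hue.mean())
    saw_foreground = False
    thr = mean_hue - range_below
    while thr <= mean_hue + range_above + 1e-9:
        fg = hue < thr
        n_fg = int(fg.sum())
        if 0 < n_fg < 0.95 * fg.size:
            saw_foreground = True
            lab = measure.label(fg, connectivity=2)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            comp = lab == sizes.argmax()
            rr, cc = np.nonzero(comp)
            clear = (
                rr.min() > border_px
                and cc.min() > border_px
                and rr.max() < rows - 1 - border_px
                and cc.max() < cols - 1 - border_px
            )
            if clear:
                box = min_area_rect(_boundary_corner_points(comp))
                return BinaryMask(mask=comp, threshold_used=float(thr)), box
        thr += 1.0
    if saw_foreground:
        raise SegmentationFailedError(
            f"foreground box within {border_px} px of the border at max threshold "
            f"{mean_hue + range_above:.1f} deg"
        )
    raise NoPigError("no pig detected: no foreground at any threshold in range")


def trim_head_tail(mask: BinaryMask, box: ContourBox, trim_ratio: float = 1.0) -> BinaryMask:
    """Remove head and tail: cut both ends of the long axis.

    The cut fraction at each end is ``trim_ratio * width / length`` of the
    long-axis extent, capped at 0.25 so at least half the body survives.
    ``trim_ratio = 0`` is the identity.
    """
    if trim_ratio < 0:
        raise ValueError("trim_ratio must be non-negative")
    if trim_ratio == 0.0:
        return mask
    f = min(trim_ratio * box.width / box.length, 0.25)
    rr, cc = np.nonzero(mask.mask)
    proj = rr * box.axis[0] + cc * box.axis[1]
    lo, hi = proj.min(), proj.max()
    ext = hi - lo
    keep = (proj >= lo + f * ext) & (proj <= hi - f * ext)
    if not keep.any():
        raise OverTrimError(f"trimming at ratio {trim_ratio} emptied the mask")
    out = np.zeros_like(mask.mask)
    out[rr[keep], cc[keep]] = True
    return BinaryMask(mask=out, threshold_used=mask.threshold_used)


def extract_features(
    mask: BinaryMask, distance_map: np.ndarray, camera_height: float = 1.40
) -> BiometricFeatures:
    """Measure the four biometric features on a (trimmed) mask.

    Zero distances inside the mask are sensor dropouts and are replaced by
    the mean of the non-zero masked distances before any statistic is
    computed.  Height is ``camera_height`` minus the mean masked distance;
    volume is the sum of per-pixel heights over the mask.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    if distance_map.shape != m.shape:
        raise ValueError("distance map shape does not match mask")
    d = np.asarray(distance_map, dtype=np.float64)[m]
    nz = d > 0
    if not nz.any():
        raise NoDepthSignalError("all masked distances are zero")
    d = np.where(nz, d, d[nz].mean())
    box = min_area_rect(_boundary_corner_points(m))
    height = camera_height - float(d.mean())
    volume = float(np.sum(camera_height - d))
    return BiometricFeatures(
        dorsal_length=box.length,
        abdominal_width=box.width,
        height=height,
        volume=volume,
    )


def aggregate_video(features: list[BiometricFeatures]) -> BiometricFeatures:
    """Component-wise median over the per-frame features of one video."""
    if not features:
        raise ValueError("no frame features to aggregate")
    arr = np.array(
        [[f.dorsal_length, f.abdominal_width, f.height, f.volume] for f in features]
    )
    med = np.median(arr, axis=0)
    return BiometricFeatures(*med)


def process_video(
    video: DepthVideo,
    camera_height: float = 1.40,
    trim_ratio: float = 1.0,
    border_px: int = 5,
) -> tuple[BiometricFeatures, pd.DataFrame]:
    """Run the full per-frame pipeline on a video and aggregate by medians.

    Returns the median features plus a per-frame table with columns
    ``frame, status, threshold, dorsal_length, abdominal_width, height,
    volume`` where failed frames carry their drop reason in ``status``.
    """
    rows = []
    feats = []
    for frame in video.frames:
        rec: dict = {"frame": frame.frame_index}
        try:
            mask, box = adaptive_hue_threshold(frame, border_px=border_px)
            trimmed = trim_head_tail(mask, box, trim_ratio=trim_ratio)
            f = extract_features(trimmed, frame.distance_map, camera_height)
            rec.update(status="ok", threshold=mask.threshold_used, **f.as_dict())
            feats.append(f)
        except SegmentError as exc:
            rec.update(status=type(exc).__name__, threshold=np.nan)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if not feats:
        raise SegmentationFailedError("every frame of the video was dropped")
    return aggregate_video(feats), table
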