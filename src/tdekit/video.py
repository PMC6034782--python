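"""Extraction of per-pixel ablation onset maps and ROI count series from TDE videos.

During MRI-guided laser interstitial thermal therapy (LITT) the vendor
workstation overlays a thermal damage estimate (TDE) on the imaging plane:
pixels predicted to be irreversibly ablated are painted yellow, and the
overlay grows frame by frame.  This module turns an ordered stack of such
frames into

* a :class:`PixelOnsetMap` — for every pixel, the time at which it first
  classified as ablated (or "never"), together with its position relative to
  the laser fiber, and
* :class:`AblationSeries` — cumulative ablated-pixel counts over time inside
  regions of interest flanking the laser (mesial/lateral in the axial plane,
  superior/inferior in the sagittal plane).

Once a pixel classifies as ablated it stays ablated (cumulative OR across
frames): the overlay encodes *irreversible* damage, so transient flicker in
the source video is resolved to the first onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "YellowRule",
    "TDEVideo",
    "PixelOnsetMap",
    "AblationSeries",
    "read_video",
    "classify_ablated",
    "onset_map",
    "partition_rois",
    "count_series",
    "laser_frame",
    "NEVER",
]

#: Sentinel onset value for pixels that never classify as ablated.
NEVER = np.inf


@dataclass(frozen=True)
class YellowRule:
    """Color threshold defining the "pixel turned yellow" classification.

    The vendor overlay's exact palette is unpublished, so the thresholds are
    configurable.  A pixel is ablated when ``R >= r_min AND G >= g_min AND
    B <= b_max`` on the 0-255 scale.
    """

    r_min: int = 200
    g_min: int = 200
    b_max: int = 100


@dataclass
class TDEVideo:
    """Ordered color frame stack with timing, scale and laser geometry.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols, 3)
        8-bit RGB frames in temporal order.  Frame ``j`` is taken at time
        ``j * frame_interval`` seconds after ablation onset.
    frame_interval : float
        Seconds between frames (vendor default ~6.7 s).
    pixel_spacing : float
        Millimetres per pixel (from the workstation ruler calibration).
    laser : ((r0, c0), (r1, c1))
        Pixel coordinates (row, col; pixel centers) of the two laser-fiber
        endpoints in the imaging plane.
    plane_label : {"axial", "sagittal"}
    side_label : {"left", "right"} or None
        Operated hemisphere; required to assign mesial/lateral ROIs in the
        axial plane.
    first_ablation : bool
        Whether this video covers the first ablative dose.  Downstream
        analyses only accept first ablations by default.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_spacing: float
    laser: tuple[tuple[float, float], tuple[float, float]]
    plane_label: str = "axial"
    side_label: str | None = None
    first_ablation: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[0] < 2:
            raise ValueError("need >= 2 frames of identical shape (n, rows, cols, 3)")
        if self.frames.shape[-1] != 3:
            raise ValueError("frames must be RGB")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        p0, p1 = self.laser
        if np.allclose(p0, p1):
            raise ValueError("laser endpoints must be distinct")
        if self.plane_label not in ("axial", "sagittal"):
            raise ValueError(f"unknown plane_label {self.plane_label!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds: 0, dt, 2·dt, ..."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PixelOnsetMap:
    """Per-pixel first-ablation time plus laser-relative coordinates.

    ``onset`` holds seconds (multiples of the frame interval); pixels that
    never ablate hold ``inf``.  ``axial_coord`` is the normalized projection
    onto the laser segment (0 at the first endpoint, 1 at the second);
    ``perp_dist`` is the signed perpendicular distance to the laser line in
    millimetres, the sign distinguishing the two sides.
    """

    onset: np.ndarray
    axial_coord: np.ndarray
    perp_dist: np.ndarray
    frame_interval: float
    pixel_spacing: float
    laser: tuple[tuple[float, float], tuple[float, float]]
    plane_label: str = "axial"
    side_label: str | None = None

    @property
    def ever_ablated(self) -> np.ndarray:
        return np.isfinite(self.onset)


@dataclass
class AblationSeries:
    """Cumulative ablated-pixel counts over time for one region of interest."""

    times: np.ndarray
    counts: np.ndarray
    roi_label: str = "total"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if self.times.size == 0:
            raise ValueError("empty time vector")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("counts must be non-decreasing")
        if self.counts[0] < 0:
            raise ValueError("counts must be non-negative")


def laser_frame(
    shape: tuple[int, int],
    laser: tuple[tuple[float, float], tuple[float, float]],
    pixel_spacing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Laser-relative coordinates for every pixel of a grid.

    Returns
    -------
    axial : ndarray
        Normalized projection onto the laser segment (0 at endpoint 0,
        1 at endpoint 1; values outside [0, 1] fall beyond the endpoints).
    perp_mm : ndarray
        Signed perpendicular distance to the (infinite) laser line, in mm.
        The sign is positive on the side of the normal obtained by rotating
        the laser direction by -90 degrees in (row, col) coordinates.
    seg_dist_mm : ndarray
        Unsigned Euclidean distance to the laser *segment*, in mm.
    """
    p0 = np.asarray(laser[0], dtype=float)
    p1 = np.asarray(laser[1], dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("degenerate laser segment")
    dhat = d / length
    nhat = np.array([dhat[1], -dhat[0]])  # rotate -90deg in (row, col)

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    off_r = rr - p0[0]
    off_c = cc - p0[1]
    axial = (off_r * dhat[0] + off_c * dhat[1]) / length
    perp = off_r * nhat[0] + off_c * nhat[1]

    t = np.clip(axial, 0.0, 1.0)
    close_r = p0[0] + t * d[0]
    close_c = p0[1] + t * d[1]
    seg_dist = np.hypot(rr - close_r, cc - close_c)
    return axial, perp * pixel_spacing, seg_dist * pixel_spacing


def read_video(
    frame_paths: Sequence[str | Path],
    frame_interval: float,
    pixel_spacing: float,
    laser: tuple[tuple[float, float], tuple[float, float]],
    plane_label: str = "axial",
    side_label: str | None = None,
    first_ablation: bool = True,
) -> TDEVideo:
    """Load a TDE video from numbered image files (PNG/TIFF).

    Frames are ordered by filename sort, so zero-padded numeric names load
    in temporal order.
    """
    paths = sorted(Path(p) for p in frame_paths)
    if len(paths) < 2:
        raise ValueError("need at least 2 frames")
    frames = []
    for p in paths:
        img = iio.imread(p)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    return TDEVideo(
        frames=np.stack(frames),
        frame_interval=frame_interval,
        pixel_spacing=pixel_spacing,
        laser=laser,
        plane_label=plane_label,
        side_label=side_label,
        first_ablation=first_ablation,
    )


def classify_ablated(frame: np.ndarray, rule: YellowRule | None = None) -> np.ndarray:
    """Binary mask of pixels whose color satisfies the yellow-overlay rule."""
    rule = rule or YellowRule()
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("classify_ablated requires an RGB frame; "
                         "grayscale input needs an explicit single-channel rule")
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    return (r >= rule.r_min) & (g >= rule.g_min) & (b <= rule.b_max)


def onset_map(video: TDEVideo, rule: YellowRule | None = None) -> PixelOnsetMap:
    """First-ablation time for every pixel of a TDE video.

    A pixel's onset is ``frame_interval`` times the index of the first frame
    in which it classifies as ablated; the classification is made monotone by
    a cumulative OR across frames (irreversible-damage semantics), so a pixel
    ablated at frame 3 that flickers off at frames 4-5 keeps onset 3·dt.
    """
    rule = rule or YellowRule()
    masks = np.stack([classify_ablated(f, rule) for f in video.frames])
    cum = np.maximum.accumulate(masks, axis=0)
    ever = cum[-1]
    first_idx = np.argmax(cum, axis=0)  # first True along time (0 if never)
    onset = np.where(ever, first_idx * video.frame_interval, NEVER)

    axial, perp_mm, _ = laser_frame(video.shape, video.laser, video.pixel_spacing)
    return PixelOnsetMap(
        onset=onset,
        axial_coord=axial,
        perp_dist=perp_mm,
        frame_interval=video.frame_interval,
        pixel_spacing=video.pixel_spacing,
        laser=video.laser,
        plane_label=video.plane_label,
        side_label=video.side_label,
    )


def _side_labels(plane_label: str, side_label: str | None,
                 orientation: str) -> tuple[str, str, np.ndarray]:
    """Names of the (positive-perp, negative-perp) ... resolved via a
    reference direction vector in (row, col) coordinates.

    Returns (label_toward_ref, label_opposite, ref_vector).  For axial planes
    the reference points mesially; under the radiological convention the
    patient's left appears on the image right (columns increase toward the
    patient's left), so for a left-sided laser the midline lies toward
    decreasing columns.  For sagittal planes the reference points superiorly
    (decreasing rows).
    """
    if plane_label == "axial":
        if side_label not in ("left", "right"):
            raise ValueError("axial planes need side_label 'left' or 'right'")
        sign = -1.0 if side_label == "left" else 1.0
        if orientation == "neurological":
            sign = -sign
        return "mesial", "lateral", np.array([0.0, sign])
    if plane_label == "sagittal":
        return "superior", "inferior", np.array([-1.0, 0.0])
    raise ValueError(f"unknown plane_label {plane_label!r}")


def partition_rois(
    om: PixelOnsetMap,
    roi_halfwidth: float = np.inf,
    orientation: str = "radiological",
) -> dict[str, np.ndarray]:
    """Split the grid into the two rectangular bands flanking the laser.

    Each band spans ``axial_coord`` in [0, 1] and extends ``roi_halfwidth``
    millimetres perpendicular to the laser on its side.  Pixels exactly on
    the laser line (zero perpendicular distance) belong to neither band; they
    count only toward "total".  Axial planes yield ``mesial``/``lateral``
    bands (resolved from the operated side and image orientation), sagittal
    planes ``superior``/``inferior``.
    """
    lab_ref, lab_opp, ref = _side_labels(om.plane_label, om.side_label, orientation)

    p0 = np.asarray(om.laser[0], dtype=float)
    p1 = np.asarray(om.laser[1], dtype=float)
    d = p1 - p0
    dhat = d / np.hypot(*d)
    nhat = np.array([dhat[1], -dhat[0]])
    align = float(nhat @ ref)
    if align == 0:
        raise ValueError("laser is parallel to the side axis; cannot assign sides")

    in_band = (om.axial_coord >= 0) & (om.axial_coord <= 1) & \
        (np.abs(om.perp_dist) <= roi_halfwidth)
    signed_toward_ref = om.perp_dist * np.sign(align)
    return {
        lab_ref: in_band & (signed_toward_ref > 0),
        lab_opp: in_band & (signed_toward_ref < 0),
    }


def count_series(
    om: PixelOnsetMap,
    roi: np.ndarray | None,
    times: np.ndarray | None = None,
    roi_label: str = "total",
) -> AblationSeries:
    """Cumulative count of ROI pixels ablated by each time point.

    ``counts[j]`` is the number of ROI pixels with onset <= ``times[j]``;
    the series is non-decreasing by construction and ends at the number of
    ever-ablated ROI pixels once times cover the video.
    """
    if times is None:
        raise ValueError("empty time vector")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time vector")
    onset = om.onset if roi is None else om.onset[np.asarray(roi, dtype=bool)]
    finite = onset[np.isfinite(onset)]
    counts = np.searchsorted(np.sort(finite), times, side="right")
    return AblationSeries(times=times, counts=counts, roi_label=roi_label)
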