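"""Overlap, extent and laser-aligned boundary-profile geometry.

Quantifies how well intraoperative TDE maps predict the immediate and
delayed (involuted) ablation zones:

* Dice similarity coefficient, DSC(A, B) = 2|A∩B| / (|A| + |B|), between
  binary region masks aligned in the same imaging cut;
* physical areas/volumes of masks;
* per-subject boundary profiles — perpendicular laser-to-boundary distances
  measured at equidistant stations along the laser fiber — and their
  cohort composite (per-station mean ± SE with paired-bootstrap
  significance flags when two boundary families are overlaid);
* the laser position/angle measures used as covariates (normalized
  mesial-lateral and superior-inferior positions, axial and sagittal
  angles) and CSF compartment volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionMask",
    "OverlapResult",
    "CompositeProfile",
    "LaserGeometry",
    "dice",
    "measure_extent",
    "slice_mask",
    "boundary_profile",
    "composite_average",
    "laser_position_measures",
    "csf_compartment_volumes",
    "plot_composite",
]


@dataclass
class RegionMask:
    """Binary 2D/3D region with per-axis spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, ...]
    frame: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if len(self.spacing) != self.voxels.ndim:
            raise ValueError("one spacing per axis required")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")

    @property
    def voxel_measure(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class OverlapResult:
    dsc: float
    area_a: float
    area_b: float
    labels: tuple[str, str] = ("A", "B")


@dataclass
class CompositeProfile:
    """Cohort-averaged laser-to-boundary distances at stations along the laser."""

    stations: np.ndarray
    mean_side1: np.ndarray
    se_side1: np.ndarray
    mean_side2: np.ndarray
    se_side2: np.ndarray
    sig_side1: np.ndarray | None = None
    sig_side2: np.ndarray | None = None
    p_side1: np.ndarray | None = None
    p_side2: np.ndarray | None = None


@dataclass
class LaserGeometry:
    """Normalized laser position and trajectory angles."""

    ml_position: float
    si_position: float
    axial_angle: float
    sagittal_angle: float


def dice(a: RegionMask, b: RegionMask) -> OverlapResult:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) with physical extents."""
    if a.voxels.shape != b.voxels.shape:
        raise ValueError("shape mismatch")
    if a.spacing != b.spacing:
        raise ValueError("spacing mismatch")
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int((a.voxels & b.voxels).sum())
    return OverlapResult(
        dsc=2.0 * inter / (na + nb),
        area_a=na * a.voxel_measure,
        area_b=nb * b.voxel_measure,
        labels=(a.frame or "A", b.frame or "B"),
    )


def measure_extent(mask: RegionMask) -> float:
    """Physical size: true-voxel count times voxel area (2D) or volume (3D)."""
    return float(mask.voxels.sum()) * mask.voxel_measure


def slice_mask(volume: RegionMask, axis: int, index: int) -> RegionMask:
    """Axis-aligned 2D section of a 3D mask, in-plane spacings preserved."""
    if volume.voxels.ndim != 3:
        raise ValueError("slice_mask needs a 3D mask")
    if not 0 <= index < volume.voxels.shape[axis]:
        raise IndexError(f"index {index} out of bounds on axis {axis}")
    section = np.take(volume.voxels, index, axis=axis)
    spacing = tuple(s for i, s in enumerate(volume.spacing) if i != axis)
    return RegionMask(voxels=section, spacing=spacing, frame=volume.frame)


def _stations(n: int) -> np.ndarray:
    """Midpoints of n equal subdivisions of [0, 1] (endpoints excluded)."""
    return (np.arange(n) + 0.5) / n


def boundary_profile(
    mask: RegionMask,
    laser: tuple[tuple[float, float], tuple[float, float]],
    n_stations: int = 20,
    step_px: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perpendicular laser-to-boundary distances at stations along the laser.

    At each of ``n_stations`` equidistant points (midpoints of equal
    subdivisions of the laser segment, so lesion tips never coincide with a
    station), rays are cast perpendicular to the laser on both sides and the
    distance to the last mask-true pixel along the ray is recorded in mm
    (robust to small interior holes); 0 where the ray never meets the mask.

    Returns ``(stations, dist_side_pos, dist_side_neg)`` where the sides use
    the same sign convention as :func:`tdekit.video.laser_frame`.
    """
    if mask.voxels.ndim != 2:
        raise ValueError("boundary_profile needs a 2D mask")
    if abs(mask.spacing[0] - mask.spacing[1]) > 1e-9:
        raise ValueError("anisotropic in-plane spacing is not supported")
    spacing = mask.spacing[0]
    p0 = np.asarray(laser[0], dtype=float)
    p1 = np.asarray(laser[1], dtype=float)
    d = p1 - p0
    if np.allclose(d, 0):
        raise ValueError("degenerate laser segment")
    dhat = d / np.hypot(*d)
    nhat = np.array([dhat[1], -dhat[0]])

    n_comp = ndimage.label(mask.voxels, structure=np.ones((3, 3)))[1]
    if n_comp > 1:
        warnings.warn("mask is not connected; profiles follow the outermost pixels",
                      stacklevel=2)

    rows, cols = mask.voxels.shape
    max_len = float(np.hypot(rows, cols))
    s = np.arange(0.0, max_len, step_px)  # ray arc length in pixels

    stations = _stations(n_stations)
    dist_pos = np.zeros(n_stations)
    dist_neg = np.zeros(n_stations)
    fmask = mask.voxels.astype(float)
    for i, t in enumerate(stations):
        P = p0 + t * d
        for sign, out in ((+1.0, dist_pos), (-1.0, dist_neg)):
            rr = P[0] + sign * s * nhat[0]
            cc = P[1] + sign * s * nhat[1]
            # bilinear membership between pixel centers (subpixel boundary)
            vals = ndimage.map_coordinates(fmask, np.stack([rr, cc]),
                                           order=1, mode="constant", cval=0.0)
            hits = np.nonzero(vals >= 0.5)[0]
            out[i] = hits[-1] * step_px * spacing if hits.size else 0.0
    return stations, dist_pos, dist_neg


def composite_average(
    profiles: list[tuple[np.ndarray, np.ndarray]],
    group_b: list[tuple[np.ndarray, np.ndarray]] | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> CompositeProfile:
    """Cohort composite of per-subject boundary profiles.

    ``profiles`` holds per-subject ``(dist_side1, dist_side2)`` vectors on a
    shared station grid ("lined up end to end" along the normalized laser
    axis, distances staying in mm).  Returns per-station across-subject mean
    and standard error per side.  When ``group_b`` is given (a second
    boundary family from the same subjects, e.g. ablation-zone vs TDE
    boundaries), a per-station paired bootstrap compares the families on
    each side and flags stations with p <= alpha.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 subjects")
    s1 = np.stack([p[0] for p in profiles])
    s2 = np.stack([p[1] for p in profiles])
    n_sta = s1.shape[1]
    n_subj = s1.shape[0]
    stations = _stations(n_sta)

    def _se(x):
        return x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])

    out = CompositeProfile(
        stations=stations,
        mean_side1=s1.mean(axis=0), se_side1=_se(s1),
        mean_side2=s2.mean(axis=0), se_side2=_se(s2),
    )
    if group_b is not None:
        if len(group_b) != n_subj:
            raise ValueError("group_b must pair with profiles subject-by-subject")
        b1 = np.stack([p[0] for p in group_b])
        b2 = np.stack([p[1] for p in group_b])
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
        for diffs, side in (((s1 - b1), "1"), ((s2 - b2), "2")):
            boot = diffs[idx].mean(axis=1)  # (n_boot, n_stations)
            p_lo = (boot <= 0).mean(axis=0)
            p_hi = (boot >= 0).mean(axis=0)
            p = np.clip(2 * np.minimum(p_lo, p_hi), 1.0 / n_boot, 1.0)
            setattr(out, f"p_side{side}", p)
            setattr(out, f"sig_side{side}", p <= alpha)
    return out


def laser_position_measures(
    laser_point: tuple[float, float],
    laser_direction_axial: tuple[float, float],
    laser_direction_sagittal: tuple[float, float],
    landmarks: dict,
) -> LaserGeometry:
    """Normalized laser position and unsigned trajectory angles.

    ``landmarks`` supplies, in a shared coronal reference cut (the most
    posterior cut containing the vertical digitation of the hippocampus):
    ``mesial_wall_x``/``lateral_wall_x`` and ``cranial_y``/``caudal_y``
    coordinates, plus the ``ap_midline`` direction (axial plane) and the
    ``ac``/``pc`` commissure points (sagittal plane).

    ml_position is 0 at the mesial wall and 1 at the lateral wall;
    si_position is 0 at the cranial and 1 at the caudal extent.  Values
    outside [0, 1] mean the laser lies beyond the reference span (allowed;
    a warning is emitted).  Angles are unsigned, in [0°, 90°].
    """
    x_m, x_l = landmarks["mesial_wall_x"], landmarks["lateral_wall_x"]
    y_c, y_d = landmarks["cranial_y"], landmarks["caudal_y"]
    if x_m == x_l or y_c == y_d:
        raise ValueError("coincident wall landmarks")
    ml = (laser_point[0] - x_m) / (x_l - x_m)
    si = (laser_point[1] - y_c) / (y_d - y_c)
    if not (0 <= ml <= 1) or not (0 <= si <= 1):
        warnings.warn("laser lies outside the reference span", stacklevel=2)

    def _angle(u, v) -> float:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("degenerate direction vector")
        c = abs(float(u @ v)) / (nu * nv)
        return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))

    axial_angle = _angle(laser_direction_axial, landmarks["ap_midline"])
    acpc = np.asarray(landmarks["pc"], dtype=float) - np.asarray(landmarks["ac"], dtype=float)
    sagittal_angle = _angle(laser_direction_sagittal, acpc)
    return LaserGeometry(ml_position=float(ml), si_position=float(si),
                         axial_angle=axial_angle, sagittal_angle=sagittal_angle)


def csf_compartment_volumes(csf_above: RegionMask,
                            csf_lateral: RegionMask) -> tuple[float, float]:
    """Physical volumes (mm³) of the two CSF heat-sink compartments."""
    if csf_above.voxels.shape == csf_lateral.voxels.shape and \
            np.any(csf_above.voxels & csf_lateral.voxels):
        warnings.warn("CSF compartments overlap", stacklevel=2)
    return measure_extent(csf_above), measure_extent(csf_lateral)


def plot_composite(profile: CompositeProfile, other: CompositeProfile | None = None,
                   labels: tuple[str, str] = ("TDE", "ablation"), ax=None):
    """Mean ± SE ribbon plot of one or two composite profiles.

    Side 1 is drawn above the laser axis and side 2 below; stations flagged
    significant are marked with vertical lines.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    series = [(profile, "goldenrod", labels[0])]
    if other is not None:
        series.append((other, "steelblue", labels[1]))
    for prof, color, label in series:
        for sign, m, se in ((1, prof.mean_side1, prof.se_side1),
                            (-1, prof.mean_side2, prof.se_side2)):
            ax.plot(prof.stations, sign * m, color=color, lw=2,
                    label=label if sign == 1 else None)
            ax.fill_between(prof.stations, sign * (m - se), sign * (m + se),
                            color=color, alpha=0.3)
    for sig in (profile.sig_side1, profile.sig_side2):
        if sig is not None:
            for x in profile.stations[sig]:
                ax.axvline(x, color="k", lw=0.8)
    ax.axhline(0, color="gray", lw=1)
    ax.set_xlabel("normalized position along laser")
    ax.set_ylabel("distance from laser (mm)")
    ax.legend(loc="best")
    return ax
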