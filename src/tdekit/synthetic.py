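"""Synthetic LITT cohort generator with exact ground truth.

Real thermal-damage-estimate (TDE) videos and traced ablation masks are
clinical data; this module fabricates subjects whose every downstream
quantity is known exactly, so the extraction, fitting, overlap and
statistics stages all have recovery oracles.

A synthetic subject consists of

* a TDE video whose cumulative ablated-pixel count follows the saturating
  exponential ``N(t) = C·(1 − exp(−(t − t_shift)/τ))`` exactly (to rank
  quantization, ±1 pixel) — onset times are obtained by inverting the count
  law at midpoint ranks, ``t_k = t_shift − τ·ln(1 − (k−0.5)/C)``, and pixels
  receive onsets in order of an anisotropic distance from the laser fiber
  (the mesial side compressed by the configured asymmetry ratio, emulating
  the observed lateral-dominant spread);
* a "CSF" heat-sink mask near the mesial edge of the lesion inside which no
  pixel ever ablates;
* an immediate ablation mask dilated from the final TDE footprint to a
  configured area ratio, and a delayed (involuted) mask eroded to a smaller
  ratio with a smooth seeded boundary perturbation;
* a 16-covariate record; covariates named in ``covariate_effects`` are
  constructed so that the inverse time constant satisfies
  ``τ⁻¹ = 1/tau_mean + Σ βᵢ·(xᵢ − μᵢ) + ε`` identically.

Identical configurations (including the seed) produce byte-identical
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .video import TDEVideo, laser_frame

__all__ = [
    "SimulationConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "COVARIATE_NAMES",
    "generate_subject",
    "generate_masks",
    "generate_covariates",
    "generate_cohort",
    "write_cohort",
    "read_manifest",
    "synthetic_supplementary_tables",
]

#: The 16 per-subject independent variables examined by the cohort screens.
COVARIATE_NAMES = (
    "age", "sex", "mts", "csf_above", "csf_lateral", "ahc_volume",
    "t1_signal", "t1_gad_signal", "t2_signal", "total_joules",
    "ablation_time", "mean_power", "ml_position", "si_position",
    "axial_angle", "sagittal_angle",
)

# Plausible marginal (mean, sd) for each continuous covariate; sex and MTS
# are Bernoulli(0.5) and Bernoulli(0.7).  Units: years, mm^3, arbitrary
# intensity, J, s, W, normalized position, degrees.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (43.5, 11.3),
    "csf_above": (400.0, 150.0),
    "csf_lateral": (900.0, 300.0),
    "ahc_volume": (3600.0, 700.0),
    "t1_signal": (300.0, 50.0),
    "t1_gad_signal": (320.0, 60.0),
    "t2_signal": (140.0, 30.0),
    "total_joules": (7000.0, 2000.0),
    "ablation_time": (150.0, 40.0),
    "mean_power": (11.0, 2.0),
    "ml_position": (0.5, 0.15),
    "si_position": (0.5, 0.15),
    "axial_angle": (10.0, 5.0),
    "sagittal_angle": (35.0, 8.0),
}

# Subject-level parameter draws are truncated to physically sensible ranges
# that also guarantee every onset fits inside the default video duration.
TAU_BOUNDS = (12.0, 180.0)
C_BOUNDS = (60.0, 600.0)
TSHIFT_BOUNDS = (-10.0, 15.0)

_BACKGROUND_RGB = (120, 120, 120)
_CSF_RGB = (40, 40, 90)
_ABLATED_RGB = (255, 255, 0)


class SimulationError(ValueError):
    """Raised when a configuration cannot produce a valid subject."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Dynamics defaults follow the axial study conditions: τ = 92 ± 61 s,
    C = 284 ± 75 pixels, t_shift = 0.7 ± 5.7 s, 6.7 s frames.  The mask area
    ratios default to the reported immediate/TDE (565/493) and delayed/TDE
    (386/495) axial cross-sectional area ratios.
    """

    n_subjects: int = 28
    grid_shape: tuple[int, int] = (64, 64)
    pixel_spacing: float = 1.3
    frame_interval: float = 6.7
    n_frames: int = 220
    tau_mean: float = 92.0
    tau_sd: float = 61.0
    C_mean: float = 284.0
    C_sd: float = 75.0
    tshift_mean: float = 0.7
    tshift_sd: float = 5.7
    asymmetry_ratio: float = 1.4
    csf_fraction: float = 0.06
    immediate_area_ratio: float = 565.0 / 493.0
    delayed_area_ratio: float = 386.0 / 495.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.002
    mask_noise_sd: float = 0.4
    plane_label: str = "axial"
    side_label: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise SimulationError("n_subjects must be positive")
        if self.tau_mean <= 0:
            raise SimulationError("tau_mean must be positive")
        if self.n_frames * self.frame_interval <= 5 * self.tau_mean:
            raise SimulationError(
                "video too short: n_frames*frame_interval must exceed 5*tau_mean")
        n_pix = int(np.prod(self.grid_shape))
        if self.C_mean > n_pix * (1 - self.csf_fraction):
            raise SimulationError("C_mean exceeds available non-CSF pixels")
        for name in ("immediate_area_ratio", "delayed_area_ratio",
                     "asymmetry_ratio", "pixel_spacing", "frame_interval"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not 0 <= self.csf_fraction < 1:
            raise SimulationError("csf_fraction must be in [0, 1)")
        unknown = set(self.covariate_effects) - set(COVARIATE_NAMES)
        if unknown:
            raise SimulationError(f"unknown covariates in effects map: {sorted(unknown)}")

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class SyntheticSubject:
    """One synthetic subject with its exact ground truth."""

    subject_id: str
    truth: dict
    video: TDEVideo
    onset_exact: np.ndarray       # exact model onsets, inf = never
    onset_quantized: np.ndarray   # onsets as seen at the frame grid
    footprint: np.ndarray         # final TDE footprint (bool)
    immediate_mask: np.ndarray
    delayed_mask: np.ndarray
    csf_mask: np.ndarray
    laser: tuple[tuple[float, float], tuple[float, float]]
    covariates: dict | None = None


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    subjects: list[SyntheticSubject]
    covariates: pd.DataFrame


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (cheap at these widths)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _csf_ellipse(config: SimulationConfig, laser_col: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Elliptical heat-sink region mesial to and above the laser track."""
    rows, cols = config.grid_shape
    mask = np.zeros(config.grid_shape, dtype=bool)
    if config.csf_fraction <= 0:
        return mask
    k = int(np.round(config.csf_fraction * rows * cols))
    if k == 0:
        return mask
    # elliptical metric (1.6:1 aspect), exact pixel count by rank selection
    area = config.csf_fraction * rows * cols
    b = np.sqrt(area / (np.pi * 1.6))
    a = 1.6 * b
    mesial = -1.0 if config.side_label == "left" else 1.0
    cr = rows * 0.30 + rng.uniform(-1, 1)
    cc = laser_col + mesial * (0.22 * cols) + rng.uniform(-1, 1)
    rr, cc_grid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    metric = ((rr - cr) / a) ** 2 + ((cc_grid - cc) / b) ** 2
    sel = np.argsort(metric.ravel(), kind="stable")[:k]
    mask.ravel()[sel] = True
    return mask


def generate_subject(
    config: SimulationConfig,
    subject_index: int,
    *,
    tau: float | None = None,
    C: float | None = None,
    t_shift: float | None = None,
) -> SyntheticSubject:
    """Generate one synthetic subject (video, masks, exact truth).

    Pixels outside the CSF mask are rank-ordered by an anisotropic distance
    to the laser segment (mesial distances inflated by sqrt(asymmetry_ratio),
    lateral deflated, so the realized lateral:mesial allocation of ablated
    pixels approximates the configured ratio); the k-th ranked pixel receives
    onset ``t_shift − τ·ln(1 − (k − 0.5)/C)``.  Frames mark pixels whose
    onset has passed.
    """
    config.validate()
    if subject_index >= config.n_subjects:
        raise SimulationError("subject_index out of range")
    rng = np.random.default_rng([config.seed, subject_index])

    tau = tau if tau is not None else _truncnorm(rng, config.tau_mean, config.tau_sd, *TAU_BOUNDS)
    C = C if C is not None else _truncnorm(rng, config.C_mean, config.C_sd, *C_BOUNDS)
    t_shift = t_shift if t_shift is not None else _truncnorm(
        rng, config.tshift_mean, config.tshift_sd, *TSHIFT_BOUNDS)
    if tau <= 0:
        raise SimulationError("tau must be positive")

    rows, cols = config.grid_shape
    # laser along the row axis, slight seeded jitter
    col0 = cols * 0.5 + rng.uniform(-1.5, 1.5)
    r0 = rows * 0.25 + rng.uniform(-1.5, 1.5)
    r1 = rows * 0.70 + rng.uniform(-1.5, 1.5)
    laser = ((float(r0), float(col0)), (float(r1), float(col0)))

    csf = _csf_ellipse(config, col0, rng)

    axial, perp_mm, seg_dist_mm = laser_frame(config.grid_shape, laser,
                                              config.pixel_spacing)
    # same side convention as video.partition_rois (radiological orientation)
    d_vec = np.asarray(laser[1]) - np.asarray(laser[0])
    dhat = d_vec / np.hypot(*d_vec)
    nhat = np.array([dhat[1], -dhat[0]])
    mesial_dir = np.array([0.0, -1.0 if config.side_label == "left" else 1.0])
    align = float(nhat @ mesial_dir)
    on_mesial = (perp_mm * np.sign(align)) > 0
    scale = np.where(on_mesial, np.sqrt(config.asymmetry_ratio),
                     1.0 / np.sqrt(config.asymmetry_ratio))
    score = seg_dist_mm * scale
    score[csf] = np.inf

    K = int(np.round(C))
    n_avail = int(np.isfinite(score).sum())
    if K > n_avail:
        raise SimulationError(f"C={C:.0f} exceeds {n_avail} available non-CSF pixels")

    flat_score = score.ravel()
    jitter = rng.random(flat_score.size)          # seeded tie-breaking
    order = np.lexsort((jitter, flat_score))[:K]

    q = (np.arange(1, K + 1) - 0.5) / C
    # cap the top quantile: when frac(C) is just above 0.5 the last midpoint
    # rank approaches 1 arbitrarily closely and its onset would be unbounded
    q = np.clip(q, None, 1.0 - 0.25 / C)
    onsets_sorted = t_shift - tau * np.log1p(-q)

    onset_exact = np.full(rows * cols, np.inf)
    onset_exact[order] = onsets_sorted
    onset_exact = onset_exact.reshape(rows, cols)

    if onsets_sorted[-1] > config.duration:
        raise SimulationError(
            f"last onset {onsets_sorted[-1]:.0f}s exceeds video duration "
            f"{config.duration:.0f}s; lengthen the video or reduce tau/C")

    dt = config.frame_interval
    finite = np.isfinite(onset_exact)
    onset_q = np.full_like(onset_exact, np.inf)
    onset_q[finite] = np.maximum(0.0, np.ceil(onset_exact[finite] / dt)) * dt

    times = np.arange(config.n_frames) * dt
    frames = np.empty((config.n_frames, rows, cols, 3), dtype=np.uint8)
    frames[...] = np.array(_BACKGROUND_RGB, dtype=np.uint8)
    frames[:, csf] = np.array(_CSF_RGB, dtype=np.uint8)
    ablated = onset_exact[None, :, :] <= times[:, None, None]
    frames[ablated] = np.array(_ABLATED_RGB, dtype=np.uint8)

    footprint = finite
    video = TDEVideo(
        frames=frames, frame_interval=dt, pixel_spacing=config.pixel_spacing,
        laser=laser, plane_label=config.plane_label,
        side_label=config.side_label, first_ablation=True,
    )
    truth = {"tau": tau, "C": C, "t_shift": t_shift,
             "inv_tau": 1.0 / tau, "asymmetry_ratio": config.asymmetry_ratio}
    subject = SyntheticSubject(
        subject_id=f"subject_{subject_index:03d}", truth=truth, video=video,
        onset_exact=onset_exact, onset_quantized=onset_q, footprint=footprint,
        immediate_mask=np.zeros_like(footprint), delayed_mask=np.zeros_like(footprint),
        csf_mask=csf, laser=laser,
    )
    imm, dl = generate_masks(subject, config,
                             np.random.default_rng([config.seed, subject_index, 1]))
    subject.immediate_mask, subject.delayed_mask = imm, dl
    return subject


def generate_masks(
    subject: SyntheticSubject,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Immediate (dilated) and delayed (eroded, noisy-boundary) masks.

    The immediate mask adds background pixels in order of Euclidean distance
    to the TDE footprint until its area hits ``round(immediate_area_ratio ·
    area)`` — within 2% of the ratio by construction.  The delayed mask keeps
    the deepest footprint pixels by inner distance plus a smooth seeded
    perturbation; if the perturbed selection disconnects, the noise-free
    erosion is used instead.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fp = subject.footprint
    area = int(fp.sum())
    if area == 0:
        raise SimulationError("empty footprint")

    k_imm = int(np.round(config.immediate_area_ratio * area))
    d_out = ndimage.distance_transform_edt(~fp)
    order = np.argsort(d_out.ravel(), kind="stable")
    if k_imm > order.size:
        raise SimulationError("immediate_area_ratio unreachable on this grid")
    immediate = np.zeros(fp.size, dtype=bool)
    immediate[order[:k_imm]] = True
    immediate = immediate.reshape(fp.shape)

    k_del = int(np.round(config.delayed_area_ratio * area))
    d_in = ndimage.distance_transform_edt(fp)
    noise = ndimage.gaussian_filter(rng.standard_normal(fp.shape), sigma=3.0)
    sd = noise.std()
    if sd > 0 and config.mask_noise_sd > 0:
        noise = noise / sd * config.mask_noise_sd
    else:
        noise = np.zeros_like(d_in)
    score = np.where(fp, d_in + noise, -np.inf)
    sel = np.argsort(-score.ravel(), kind="stable")[:k_del]
    delayed = np.zeros(fp.size, dtype=bool)
    delayed[sel] = True
    delayed = delayed.reshape(fp.shape)
    n_comp = ndimage.label(delayed, structure=np.ones((3, 3)))[1]  # 8-connectivity
    if n_comp > 1:  # fall back to pure erosion to keep the mask connected
        sel = np.argsort(-np.where(fp, d_in, -np.inf).ravel(), kind="stable")[:k_del]
        delayed = np.zeros(fp.size, dtype=bool)
        delayed[sel] = True
        delayed = delayed.reshape(fp.shape)
    return immediate, delayed


def generate_covariates(
    config: SimulationConfig,
    truths: list[dict],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """The 16-covariate table, with planted linear effects on τ⁻¹.

    For each covariate named in ``config.covariate_effects`` the values are
    constructed by exact inversion so that ``τ⁻¹ = 1/tau_mean +
    Σ βᵢ·(xᵢ − μᵢ) + ε`` with ``ε ~ N(0, noise_sd)`` holds identically
    across subjects (the residual is split evenly across the named
    covariates).  Remaining covariates are independent draws from their
    marginals; sex ~ Bernoulli(0.5) and MTS ~ Bernoulli(0.7).
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng([config.seed if seed is None else seed, 2])
    n = len(truths)
    tau_inv = np.array([t["inv_tau"] for t in truths])

    effects = config.covariate_effects
    for name, beta in effects.items():
        if beta == 0:
            raise SimulationError(f"zero coefficient for {name}")

    table: dict[str, np.ndarray] = {}
    eps = rng.normal(0.0, config.noise_sd, size=n)
    resid = tau_inv - 1.0 / config.tau_mean - eps
    m = len(effects)
    for name in COVARIATE_NAMES:
        if name in effects:
            mu = DEFAULT_MARGINALS.get(name, (0.0, 1.0))[0]
            table[name] = mu + resid / (m * effects[name])
        elif name == "sex":
            table[name] = rng.binomial(1, 0.5, size=n).astype(float)
        elif name == "mts":
            table[name] = rng.binomial(1, 0.7, size=n).astype(float)
        else:
            mu, sd = DEFAULT_MARGINALS[name]
            table[name] = rng.normal(mu, sd, size=n)
    df = pd.DataFrame(table, columns=list(COVARIATE_NAMES))
    df.insert(0, "subject", [f"subject_{i:03d}" for i in range(n)])
    return df


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: subjects, masks and the covariate table."""
    subjects = [generate_subject(config, i) for i in range(config.n_subjects)]
    covariates = generate_covariates(config, [s.truth for s in subjects])
    for subj, (_, row) in zip(subjects, covariates.iterrows()):
        subj.covariates = row.to_dict()
    return SyntheticCohort(config=config, subjects=subjects, covariates=covariates)


def _write_nifti(path: Path, arr: np.ndarray, spacing: float) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.diag([spacing, spacing, 1.0, 1.0]))
    nib.save(img, str(path))


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort to disk; returns (and saves) the JSON manifest.

    Frames become zero-padded 8-bit RGB PNGs, masks and exact-onset truth
    NIfTI-1 images carrying the pixel spacing, covariates and dynamics truth
    CSV tables, and the manifest lists every path plus the seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = cohort.config
    manifest: dict = {
        "seed": config.seed,
        "frame_interval": config.frame_interval,
        "pixel_spacing": config.pixel_spacing,
        "n_subjects": config.n_subjects,
        "subjects": [],
    }
    truth_rows = []
    for subj in cohort.subjects:
        sdir = directory / subj.subject_id
        (sdir / "frames").mkdir(parents=True, exist_ok=True)
        frame_paths = []
        for j, frame in enumerate(subj.video.frames):
            p = sdir / "frames" / f"frame_{j:04d}.png"
            iio.imwrite(p, frame)
            frame_paths.append(str(p.relative_to(directory)))
        masks = {}
        for name, arr in (("immediate", subj.immediate_mask),
                          ("delayed", subj.delayed_mask),
                          ("csf", subj.csf_mask)):
            p = sdir / f"{name}_mask.nii"
            _write_nifti(p, arr.astype(np.uint8), config.pixel_spacing)
            masks[name] = str(p.relative_to(directory))
        onset_path = sdir / "truth_onset.nii"
        onset_out = np.where(np.isfinite(subj.onset_exact), subj.onset_exact, -1.0)
        _write_nifti(onset_path, onset_out, config.pixel_spacing)
        manifest["subjects"].append({
            "id": subj.subject_id,
            "frames": frame_paths,
            "masks": masks,
            "truth_onset": str(onset_path.relative_to(directory)),
            "laser": [list(subj.laser[0]), list(subj.laser[1])],
            "plane_label": subj.video.plane_label,
            "side_label": subj.video.side_label,
            "first_ablation": subj.video.first_ablation,
        })
        truth_rows.append({"subject": subj.subject_id, **subj.truth})
    pd.DataFrame(truth_rows).to_csv(directory / "truth.csv", index=False)
    cohort.covariates.to_csv(directory / "covariates.csv", index=False)
    manifest["truth"] = "truth.csv"
    manifest["covariates"] = "covariates.csv"
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest(path: str | Path) -> dict:
    """Load a cohort manifest; paths stay relative to the manifest directory."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    manifest["_root"] = str(path.parent)
    return manifest


def synthetic_supplementary_tables(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SYNTHETIC stand-ins for the per-patient supplementary tables.

    The real per-patient tables accompany the published study and are not
    redistributable here.  These stand-ins are random draws whose *sample*
    moments are standardized to equal the published cohort aggregates — per
    plane the DSC(Immediate, TDE) and DSC(Delayed, TDE) means/SDs and the
    (τ, C, t_shift) means/SDs — and, for the axial table, whose
    DSC(Delayed, TDE) has a planted negative dependence on CSF_Above with a
    sample R² of exactly 0.13.  They exercise the reproduction runner's
    arithmetic; they carry no information beyond the printed aggregates.

    Returns the axial (n = 29) and sagittal (n = 17) tables.
    """

    def _standardize(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
        z = (z - z.mean()) / z.std(ddof=1)
        return mean + sd * z

    def _build(rng: np.random.Generator, n: int, dsc_imm: tuple[float, float],
               dsc_del: tuple[float, float], tau: tuple[float, float],
               C: tuple[float, float], tshift: tuple[float, float],
               plant_r2: float | None) -> pd.DataFrame:
        cols = {}
        cols["tau"] = _standardize(rng.standard_normal(n), *tau)
        cols["C"] = _standardize(rng.standard_normal(n), *C)
        cols["t_shift"] = _standardize(rng.standard_normal(n), *tshift)
        cols["dsc_immediate_tde"] = _standardize(rng.standard_normal(n), *dsc_imm)
        cov = {}
        for name in COVARIATE_NAMES:
            if name == "sex":
                cov[name] = rng.binomial(1, 0.5, n).astype(float)
            elif name == "mts":
                cov[name] = rng.binomial(1, 0.7, n).astype(float)
            else:
                mu, sd = DEFAULT_MARGINALS[name]
                cov[name] = rng.normal(mu, sd, n)
        if plant_r2 is None:
            cols["dsc_delayed_tde"] = _standardize(rng.standard_normal(n), *dsc_del)
        else:
            # exact-R² construction: unit-variance predictor component plus an
            # orthogonalized residual, mixed so the sample R² equals plant_r2
            x = cov["csf_above"]
            xz = (x - x.mean()) / x.std(ddof=1)
            e = rng.standard_normal(n)
            e = e - e.mean() - xz * np.dot(e - e.mean(), xz) / np.dot(xz, xz)
            e = e / e.std(ddof=1)
            y = -np.sqrt(plant_r2) * xz + np.sqrt(1 - plant_r2) * e
            cols["dsc_delayed_tde"] = _standardize(y, *dsc_del)
        cols.update(cov)
        df = pd.DataFrame(cols)
        df.insert(0, "subject", [f"P{i + 1:02d}" for i in range(n)])
        return df

    rng = np.random.default_rng([seed, 99])
    axial = _build(rng, 29, (0.92, 0.06), (0.74, 0.11), (92.0, 61.0),
                   (284.0, 75.0), (0.7, 5.7), plant_r2=0.13)
    sagittal = _build(rng, 17, (0.94, 0.04), (0.82, 0.09), (108.0, 118.0),
                      (120.0, 33.0), (2.6, 3.4), plant_r2=None)
    return axial, sagittal
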