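"""End-to-end orchestration: raw cohort (or synthetic manifest) -> results bundle.

Per subject: pixel-onset map extraction, ROI partition, count series,
exponential and asymmetry fits, DSC overlaps of the final TDE footprint
against the immediate and delayed masks, and boundary profiles.  Cohort
level: composite boundary profiles with bootstrap flags, the pointwise
side comparison, paired bootstrap mean comparisons of extents, and the
regression screens of τ⁻¹ against the 16 covariates.

Subjects that fail any stage (unreadable frames, missing masks, no signal)
are skipped with a logged reason so one corrupted video does not abort a
cohort run; the run fails only if no usable subject remains.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import dynamics, geometry, stats, video as vid
from .synthetic import SyntheticCohort, read_manifest
from .video import TDEVideo, YellowRule

__all__ = ["PipelineConfig", "load_config", "analyze_cohort", "load_subject_videos"]

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "yellow_r_min": 200, "yellow_g_min": 200, "yellow_b_max": 100,
    "frame_interval": 6.7, "roi_halfwidth": float("inf"), "n_stations": 20,
    "split": 60.0, "n_boot": 1000, "seed": 0, "orientation": "radiological",
    "allow_multi_ablation": False, "alpha": 0.05,
}


@dataclass
class PipelineConfig:
    """Analysis settings; all defaults mirror the study's stated settings."""

    yellow_r_min: int = 200
    yellow_g_min: int = 200
    yellow_b_max: int = 100
    frame_interval: float = 6.7
    roi_halfwidth: float = float("inf")
    n_stations: int = 20
    split: float = 60.0
    n_boot: int = 1000
    seed: int = 0
    orientation: str = "radiological"
    allow_multi_ablation: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("frame_interval", "roi_halfwidth", "n_stations",
                     "split", "n_boot", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def yellow_rule(self) -> YellowRule:
        return YellowRule(self.yellow_r_min, self.yellow_g_min, self.yellow_b_max)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys."""
    if path is None:
        return PipelineConfig()
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"known keys: {sorted(_CONFIG_FIELDS)}")
    return PipelineConfig(**data)


def _load_mask(root: Path, rel: str, spacing: float) -> geometry.RegionMask:
    img = nib.load(str(root / rel))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return geometry.RegionMask(voxels=arr > 0.5, spacing=(spacing, spacing))


def load_subject_videos(manifest: dict, config: PipelineConfig):
    """Yield (entry, TDEVideo, masks dict) for each usable manifest subject."""
    root = Path(manifest["_root"])
    for entry in manifest["subjects"]:
        sid = entry["id"]
        try:
            if not entry.get("first_ablation", True) and not config.allow_multi_ablation:
                raise ValueError("not a first ablation "
                                 "(pass allow_multi_ablation to override)")
            laser = tuple(tuple(p) for p in entry["laser"])
            video = vid.read_video(
                [root / p for p in entry["frames"]],
                frame_interval=manifest["frame_interval"],
                pixel_spacing=manifest["pixel_spacing"],
                laser=laser,
                plane_label=entry["plane_label"],
                side_label=entry.get("side_label"),
                first_ablation=entry.get("first_ablation", True),
            )
            masks = {name: _load_mask(root, rel, manifest["pixel_spacing"])
                     for name, rel in entry["masks"].items()}
        except Exception as exc:  # noqa: BLE001 - per-subject fault isolation
            logger.warning("skipping %s: %s", sid, exc)
            continue
        yield entry, video, masks


def _analyze_subject(sid: str, video: TDEVideo,
                     masks: dict, config: PipelineConfig) -> dict:
    om = vid.onset_map(video, config.yellow_rule)
    rois = vid.partition_rois(om, config.roi_halfwidth, config.orientation)
    (lab1, roi1), (lab2, roi2) = rois.items()
    times = video.times
    total = vid.count_series(om, None, times, "total")
    s1 = vid.count_series(om, roi1, times, lab1)
    s2 = vid.count_series(om, roi2, times, lab2)

    fit = dynamics.fit_exponential(total)
    d = dynamics.difference_series(s1, s2)
    axis = "ML" if video.plane_label == "axial" else "SI"
    try:
        asym = dynamics.fit_piecewise_linear(d, split=config.split, axis=axis)
    except ValueError:
        asym = None

    spacing = (video.pixel_spacing, video.pixel_spacing)
    tde_mask = geometry.RegionMask(om.ever_ablated, spacing, frame="tde")
    overlaps = {}
    profiles = {"tde": geometry.boundary_profile(tde_mask, video.laser,
                                                 config.n_stations)}
    for name in ("immediate", "delayed"):
        if name in masks:
            mask = masks[name]
            mask.frame = name
            overlaps[name] = geometry.dice(mask, tde_mask)
            profiles[name] = geometry.boundary_profile(mask, video.laser,
                                                       config.n_stations)
    return {
        "id": sid, "onset_map": om, "series": {"total": total, lab1: s1, lab2: s2},
        "side_labels": (lab1, lab2), "fit": fit, "diff": d, "asymmetry": asym,
        "overlaps": overlaps, "profiles": profiles,
        "tde_area": geometry.measure_extent(tde_mask),
    }


def analyze_cohort(
    source: SyntheticCohort | dict | str | Path,
    config: PipelineConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis over a cohort.

    ``source`` is a :class:`SyntheticCohort`, a loaded manifest dict, or a
    path to ``manifest.json``.  Returns a results dict with per-subject
    records, cohort tables (fits, overlaps), composite profiles, the side
    comparison, bootstrap comparisons, the regression screens, and a JSON-
    serializable ``summary``.
    """
    config = config or PipelineConfig()

    subjects: list[dict] = []
    skipped: dict[str, str] = {}
    if isinstance(source, SyntheticCohort):
        covariates = covariates if covariates is not None else source.covariates
        for subj in source.subjects:
            masks = {
                "immediate": geometry.RegionMask(
                    subj.immediate_mask,
                    (subj.video.pixel_spacing,) * 2, frame="immediate"),
                "delayed": geometry.RegionMask(
                    subj.delayed_mask,
                    (subj.video.pixel_spacing,) * 2, frame="delayed"),
            }
            try:
                subjects.append(_analyze_subject(subj.subject_id, subj.video,
                                                 masks, config))
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping %s: %s", subj.subject_id, exc)
                skipped[subj.subject_id] = str(exc)
    else:
        manifest = read_manifest(source) if not isinstance(source, dict) else source
        root = Path(manifest["_root"])
        if covariates is None and manifest.get("covariates"):
            covariates = pd.read_csv(root / manifest["covariates"])
        listed = {e["id"] for e in manifest["subjects"]}
        for entry, video, masks in load_subject_videos(manifest, config):
            try:
                subjects.append(_analyze_subject(entry["id"], video, masks, config))
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping %s: %s", entry["id"], exc)
                skipped[entry["id"]] = str(exc)
        for sid in listed - {s["id"] for s in subjects} - set(skipped):
            skipped[sid] = "failed to load"

    if not subjects:
        raise RuntimeError("no usable subject in cohort")

    fits = pd.DataFrame([
        {"subject": s["id"], "tau": s["fit"].tau, "C": s["fit"].C,
         "t_shift": s["fit"].t_shift, "inv_tau": s["fit"].inv_tau,
         "r_squared": s["fit"].r_squared, "converged": s["fit"].converged,
         **({"m_early": s["asymmetry"].m_early, "b_early": s["asymmetry"].b_early,
             "m_late": s["asymmetry"].m_late, "b_late": s["asymmetry"].b_late}
            if s["asymmetry"] else {}),
         "tde_area": s["tde_area"],
         **{f"dsc_{k}_tde": v.dsc for k, v in s["overlaps"].items()},
         **{f"area_{k}": v.area_a for k, v in s["overlaps"].items()},
         } for s in subjects])
    converged = fits[fits["converged"]]
    if len(converged) < len(fits):
        logger.info("excluding %d non-converged fits from regressions",
                    len(fits) - len(converged))

    results: dict = {"subjects": subjects, "skipped": skipped, "fits": fits,
                     "config": config}

    # cohort-level side comparison and composites
    pairs = [(s["series"][s["side_labels"][0]], s["series"][s["side_labels"][1]])
             for s in subjects]
    if len(pairs) >= 5:
        results["side_comparison"] = dynamics.pointwise_side_comparison(
            pairs, n_boot=config.n_boot, seed=config.seed, alpha=config.alpha)

    tde_profiles = [(s["profiles"]["tde"][1], s["profiles"]["tde"][2])
                    for s in subjects]
    composites = {}
    if len(subjects) >= 3:
        for name in ("immediate", "delayed"):
            have = [s for s in subjects if name in s["profiles"]]
            if len(have) >= 3:
                composites[name] = geometry.composite_average(
                    [(s["profiles"][name][1], s["profiles"][name][2]) for s in have],
                    group_b=[(s["profiles"]["tde"][1], s["profiles"]["tde"][2])
                             for s in have],
                    n_boot=config.n_boot, seed=config.seed, alpha=config.alpha)
        composites["tde"] = geometry.composite_average(
            tde_profiles, n_boot=config.n_boot, seed=config.seed)
    results["composites"] = composites

    # bootstrap extent comparisons (paired within subject)
    boots = {}
    for name in ("immediate", "delayed"):
        col = f"area_{name}"
        if col in fits.columns and fits[col].notna().all() and len(fits) >= 3:
            boots[f"{name}_vs_tde_area"] = stats.bootstrap_mean_diff(
                fits[col], fits["tde_area"], paired=True,
                n_boot=config.n_boot, seed=config.seed)
    results["bootstrap_comparisons"] = boots

    # covariate screens on τ⁻¹ (converged fits only)
    screens = None
    multi = None
    if covariates is not None:
        table = converged.merge(covariates, on="subject", how="inner")
        if len(table) >= 5:
            screens = stats.univariate_screen(table, "inv_tau")
            try:
                multi = stats.multivariate_fit(table, "inv_tau")
            except ValueError as exc:
                logger.info("multivariate fit unavailable: %s", exc)
        results["screen_table"] = table
    results["univariate_screens"] = screens
    results["multivariate_fit"] = multi

    summary = {
        "n_subjects": len(subjects),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "subject_ids": [s["id"] for s in subjects],
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tau_mean": float(converged["tau"].mean()),
        "tau_sd": float(converged["tau"].std(ddof=1)) if len(converged) > 1 else 0.0,
        "C_mean": float(converged["C"].mean()),
        "t_shift_mean": float(converged["t_shift"].mean()),
        "r_squared_median": float(converged["r_squared"].median()),
        "tde_area_mean": float(fits["tde_area"].mean()),
    }
    for name in ("immediate", "delayed"):
        col = f"dsc_{name}_tde"
        if col in fits.columns:
            summary[f"dsc_{name}_tde_mean"] = float(fits[col].mean())
            summary[f"area_{name}_mean"] = float(fits[f"area_{name}"].mean())
    for key, b in boots.items():
        summary[f"bootstrap_{key}"] = {"estimate": b.estimate, "ci": list(b.ci),
                                       "p": b.p_two_sided}
    if screens:
        summary["univariate_inv_tau"] = {
            r.predictors[0]: {"coef": r.coefficients[r.predictors[0]],
                              "r_squared": r.r_squared, "p": r.p_overall}
            for r in screens}
    results["summary"] = summary
    return results


def write_results(results: dict, out_dir: str | Path) -> None:
    """Write the results bundle: CSV tables, series, profiles and summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["fits"].to_csv(out / "fits.csv", index=False)

    series_rows = []
    for s in results["subjects"]:
        for label, ser in s["series"].items():
            for t, c in zip(ser.times, ser.counts):
                series_rows.append({"subject": s["id"], "roi_label": label,
                                    "time": t, "count": int(c)})
    pd.DataFrame(series_rows).to_csv(out / "series.csv", index=False)

    prof_rows = []
    for s in results["subjects"]:
        for name, (stations, d1, d2) in s["profiles"].items():
            for st, a, b in zip(stations, d1, d2):
                prof_rows.append({"subject": s["id"], "boundary": name,
                                  "station": st, "dist_side1": a, "dist_side2": b})
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    if results.get("univariate_screens"):
        pd.DataFrame([
            {"response": r.response, "predictor": r.predictors[0],
             "coef": r.coefficients[r.predictors[0]], "f_stat": r.f_stat,
             "r_squared": r.r_squared, "p": r.p_overall, "n": r.n}
            for r in results["univariate_screens"]
        ]).to_csv(out / "univariate_screens.csv", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump({"schema_version": 1, **results["summary"]}, fh, indent=2,
                  default=float)
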