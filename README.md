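# tdekit

Quantification of MRI-guided laser interstitial thermal therapy (LITT)
ablation dynamics from intraoperative **thermal damage estimate (TDE)
videos**, with overlap analysis of TDE maps against immediate and delayed
(follow-up) ablation masks.

During a LITT procedure the workstation overlays a per-pixel prediction of
irreversible tissue damage on the imaging plane; ablated pixels turn yellow
and the overlay grows frame by frame (one frame every ~6.7 s). `tdekit` is
aimed at researchers analyzing such recordings — e.g. from mesial temporal
lobe epilepsy ablations — and provides:

* **Onset extraction** — per-pixel first-ablation times from the frame
  stack (cumulative-OR, first-onset semantics), with laser-relative
  coordinates and mesial/lateral (axial) or superior/inferior (sagittal)
  regions of interest flanking the laser fiber.
* **Dynamics fitting** — the cumulative ablated-pixel count N(t) is fit by
  the saturating exponential

  ```
  N(t) = C · (1 − exp(−(t − t_shift)/τ))
  ```

  with time constant τ (s), plateau count C (pixels) and onset delay
  t_shift (s); the ablation rate τ⁻¹ is used in covariate regressions.
  Side asymmetry (mesial − lateral counts) is summarized by independent
  OLS lines on the early (< 60 s) and late (≥ 60 s) phases, and by a paired
  bootstrap comparison of the side series at each time point.
* **Overlap geometry** — Dice similarity coefficient
  DSC(A, B) = 2|A∩B|/(|A|+|B|), physical extents, laser-aligned boundary
  profiles (perpendicular laser-to-boundary distances at 20 stations along
  the fiber) and their cohort composites with bootstrap significance flags,
  laser position/angle measures, and CSF compartment volumes.
* **Cohort statistics** — percentile bootstrap mean comparisons (1000
  resamples), univariate/multivariate OLS screens against 16 per-subject
  covariates, and a reproduction runner that recomputes published cohort
  aggregates from supplementary-style per-patient tables.
* **A synthetic cohort generator** — subjects whose videos follow the count
  law exactly (onsets from inverse-count-law rank quantiles), with
  configurable mesial/lateral asymmetry, CSF no-ablation zones, immediate
  (dilated) and delayed (eroded) masks at configured area ratios, and
  covariates with planted linear effects on τ⁻¹. Every downstream stage is
  verified against this exact ground truth.

The curve fits are scikit-learn-style estimators
(`SaturatingExponential`, `PiecewiseLinearPhases`) and compose with
sklearn tooling; module-level functions wrap them.

## Worked example

```python
import numpy as np
from tdekit import (SimulationConfig, generate_subject, onset_map,
                    partition_rois, count_series, fit_exponential,
                    dice, RegionMask)

config = SimulationConfig(n_subjects=1, seed=42)   # axial study conditions
subject = generate_subject(config, 0)
print(f"truth: tau={subject.truth['tau']:.1f} s, ...")

om = onset_map(subject.video)                      # per-pixel onset times
rois = partition_rois(om)                          # mesial / lateral bands
total = count_series(om, None, subject.video.times, "total")
fit = fit_exponential(total)

spacing = (subject.video.pixel_spacing,) * 2
tde = RegionMask(om.ever_ablated, spacing, frame="tde")
imm = RegionMask(subject.immediate_mask, spacing, frame="immediate")
res = dice(imm, tde)
```

This prints:

```
truth: tau=110.6 s, C=206 px, t_shift=4.98 s
fit:   tau=110.5 s, C=206 px, t_shift=5.08 s, R^2=1.0000
DSC(immediate, TDE) = 0.932  (areas 399 vs 348 mm^2)
final counts: mesial=64, lateral=118
```

The fitted (τ, C, t_shift) recover the generator's truth to a fraction of
a percent — the count series is exact up to rank quantization — the
immediate mask overlaps the TDE footprint at DSC 0.93 while being ~15%
larger, and the lateral band accumulates roughly 1.5× the mesial count,
reflecting the configured lateral-dominant spread.

A command line mirrors the library
(`tdekit simulate | extract | fit | overlap | composite | stats | analyze |
reproduce`):

```sh
tdekit simulate --seed 1 --out cohort --n-subjects 12
tdekit analyze cohort/manifest.json --out results
tdekit reproduce s1_table.csv s2_table.csv
```

`analyze` writes per-subject onset maps, count series, fits, DSCs and
boundary profiles plus cohort-level composites, bootstrap comparisons and
regression screens into CSV tables and a versioned `summary.json`.
Subjects with unreadable inputs are skipped with a logged reason.

## Layout

```
src/tdekit/
  synthetic.py   # synthetic cohort generator with exact ground truth
  video.py       # onset maps, ROI partition, count series
  dynamics.py    # exponential + piecewise-linear estimators, side tests
  geometry.py    # DSC, extents, boundary profiles, composites, laser measures
  stats.py       # bootstrap tests, regression screens, reproduction runner
  pipeline.py    # end-to-end orchestration and results bundle
  cli.py         # click command line
docs/methods.md  # model, assumptions, parameter choices, limitations
```
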