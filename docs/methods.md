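# Methods

## The model

Cumulative counts of irreversibly-ablated pixels in a thermal damage
estimate (TDE) video rise sharply after laser activation and plateau within
a few minutes. First-order heat-transfer arguments motivate the saturating
exponential

    N(t) = C · (1 − exp(−(t − t_shift)/τ)),   t ≥ t_shift,

with three parameters per subject and imaging plane:

| parameter | units | meaning | default generator marginal |
|---|---|---|---|
| τ | s | thermal time constant | 92 ± 61 (axial conditions) |
| C | pixels | plateau (final ablated count) | 284 ± 75 |
| t_shift | s | onset delay | 0.7 ± 5.7 |

The ablation *rate* τ⁻¹ is the response used in covariate regressions
because it correlates more linearly with procedural covariates than τ.
Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region with bounds τ, C > 0, t_shift free), initialized from the
series shape: C₀ = max count, t_shift₀ = last zero-count time, τ₀ = time to
reach (1 − 1/e)·C₀ minus t_shift₀. The model is clamped to 0 for
t < t_shift, matching the data (counts cannot be negative) and keeping the
fit sensible for series with a late onset. R² is 1 − SS_res/SS_tot about
the series mean, over all frames (the conventional definition). Solver
failure is reported via `converged = False` with a diagnostic message, not
raised, so cohort loops complete; non-converged subjects are excluded from
downstream regressions and logged. Fitting with τ⁻¹ as the free parameter
instead of τ gives the same curve (tested to 1e−6).

Side asymmetry uses the difference of the two side-band count series
(mesial − lateral in the axial plane, superior − inferior sagittally), fit
by **independent** OLS lines on the early and late phases split at 60 s.
The boundary point t = 60 s is assigned to the late phase; the split value
and its boundary assignment are configurable, and the assignment is this
package's stated convention.

## Onset extraction

A pixel classifies as ablated when its color satisfies the yellow-overlay
rule R ≥ 200 ∧ G ≥ 200 ∧ B ≤ 100 (0–255). The thresholds are configurable
because the vendor palette is unpublished. Classification is made monotone
by a cumulative OR over frames, and the onset is the time of the *first*
ablated frame: the overlay encodes irreversible damage, so transient
flicker is resolved to first onset. Whether the vendor overlay ever
un-marks pixels is unknown; first-onset is this package's convention.

Frame j is taken at time j·Δ (Δ = frame interval, default 6.7 s), so
onsets are multiples of Δ and a pixel ablated before the first frame has
onset 0. Coordinates are 0-based row-major pixel centers. ROI bands flank
the laser segment, span its normalized extent [0, 1], and extend a
configurable half-width on each side; pixels exactly on the line belong to
neither band and count only toward the total (additivity
total = side1 + side2 + on-line is asserted). Mesial direction is resolved
from the operated side under the radiological display convention (patient
left on image right); a `neurological` orientation flag flips it. Only
first-ablation videos are analyzed unless explicitly overridden.

## Overlap and boundary geometry

DSC(A, B) = 2|A∩B|/(|A|+|B|) on identically-sampled masks; two empty masks
are an error (undefined), and areas are reported in physical units.

Boundary profiles cast rays perpendicular to the laser at 20 stations —
the midpoints of 20 equal subdivisions of the segment, so lesion tips
never coincide with a station and boundary rays never degenerate to zero
length. Along each ray (step 0.25 px) mask membership is sampled by
bilinear interpolation thresholded at 0.5, giving a subpixel boundary; the
recorded distance is to the *last* mask-true sample, which tolerates small
interior holes — a deliberate choice for non-convex boundaries, where
"distance to the boundary" is otherwise ambiguous; disconnected masks
trigger a warning.
On analytic disc/ellipse fixtures the profiles match chord geometry to
well under one pixel, and the midpoint-rule integral of the two side
widths over the laser span reproduces convex mask areas to a few percent.

Cohort composites normalize each subject's laser span to [0, 1] while
distances stay in millimetres, then report the per-station across-subject
mean ± SE (whether the published per-station SE is across- or
within-subject is not stated; across-subject is implemented). When two
boundary families from the same subjects are overlaid, a per-station
paired bootstrap flags differences at p ≤ 0.05. No multiple-testing
correction is applied across stations by default (matching the published
screens); a Benjamini–Hochberg option exists in the regression screen API.

## Bootstrap inference

All mean comparisons are percentile bootstrap tests with 1000 resamples:
the two-sided p-value is 2·min(P(diff* ≤ 0), P(diff* ≥ 0)), floored at
1/n_boot so zero is never reported, with a 95% percentile CI. Within-
subject comparisons (immediate vs delayed extents, side vs side counts)
resample subject pairs; unpaired comparisons resample each group
independently. Identical seeds give identical p-values. Empirically the
unpaired test's type-I error at n = 30/group is ≈ 0.054 and its power at a
1 SD shift ≈ 0.96–0.98; the per-station paired composite test runs
slightly liberal at small cohorts (≈ 0.08 at n = 15, ≈ 0.065 at n = 30), a
known small-sample property of percentile bootstrap tests.

## The synthetic generator

The generator emulates the *measured structure* of intraoperative TDE
data, not its physics — no Pennes/bioheat or Arrhenius simulation. Design:

* **Onsets by exact inversion.** Candidate pixels (outside the CSF mask)
  are ranked by an anisotropic distance to the laser segment; the k-th
  pixel receives onset t_k = t_shift − τ·ln(1 − (k − 0.5)/C). Midpoint
  ranks make the frame-sampled cumulative count equal round(N(t)) exactly
  (±1 pixel from rank quantization at ties) and avoid the singularity a
  k/C quantile would hit at k = round(C). Ties in the distance score are
  broken by a seeded random jitter, so growth order is deterministic given
  the seed and identical configurations produce byte-identical cohorts.
* **Asymmetry as one knob.** Mesial distances are inflated by
  √(asymmetry_ratio) and lateral deflated by the same factor, so the
  lateral:mesial width of the grown region equals the configured ratio.
  The realized *pixel-count* ratio runs somewhat above it (end caps of the
  stadium-shaped region and the mesial CSF exclusion both add lateral
  pixels; ≈ 1.5–1.6 for the default ratio 1.4), which is the quantity the
  side-series tests compare.
* **CSF heat sink.** An elliptical no-ablation region (default 6% of the
  grid, exact by rank selection) sits mesial/above the laser track,
  emulating choroidal-fissure/temporal-horn CSF; ablated pixels never
  intersect it.
* **Masks at calibrated ratios.** The immediate mask adds background
  pixels in distance-transform order until area/footprint hits the
  configured ratio (default 565/493 ≈ 1.146); the delayed mask keeps the
  deepest footprint pixels by inner distance plus a smooth seeded
  perturbation, at ratio 386/495 ≈ 0.780 (both published area pairs are
  exposed as parameters because the two printed axial TDE means, 493 and
  495 mm², differ between paragraphs). Areas are exact to rank selection;
  if the perturbed delayed mask disconnects, the noise-free erosion is
  used. Because the synthetic delayed mask is a subset of the footprint,
  its DSC against the TDE (≈ 0.87) is *higher* than the published 0.74 —
  real delayed lesions also displace, which the generator does not model.
* **Covariates.** Sixteen per-subject variables with plausible, documented
  marginals (sex ~ Bernoulli(0.5), MTS ~ Bernoulli(0.7), age 43.5 ± 11.3 y,
  the rest configurable normals — invented scales for signals/energies).
  Covariates named in `covariate_effects` are built by exact inversion so
  τ⁻¹ = 1/τ_mean + Σβᵢ(xᵢ − μᵢ) + ε holds identically with
  ε ~ N(0, noise_sd = 0.002 s⁻¹); the regression slope of τ⁻¹ on xᵢ is then
  attenuated toward zero by the noise but never flips sign, which is what
  the sign-recovery experiments measure.
* **Truncations.** Subject draws are truncated normals (τ ∈ [12, 180] s,
  C ∈ [60, 600] px, t_shift ∈ [−10, 15] s) so that every onset fits inside
  the default 220-frame (~24 min) video; a configuration whose last onset
  would fall outside the video is rejected with a clear error.

What passing tests on this generator do **not** show: robustness to
palette drift, compression artifacts, or patient motion in real videos;
registration error between TDE planes and traced masks; delayed-lesion
displacement (above); or real covariate collinearity.

## Problem sizes and defaults

The default cohort is 28 subjects on a 64×64 grid at 1.3 mm/pixel (chosen
so the default plateau count of 284 pixels matches the published ~493 mm²
axial TDE area), 220 frames at 6.7 s. The recovery experiment uses 100
subjects at the axial mean dynamics with 5% count jitter; bootstrap
calibration uses 500 null and 200 power replicates at n = 30/group;
screen recovery uses 100 cohorts of n = 200. These sizes make the full
suite and the acceptance script run in well under the defaults' fitting
budgets on a single CPU while keeping Monte-Carlo error small relative to
the tolerances tested.

## Supplementary-table reproduction

The reproduction runner recomputes, from per-patient tables, the mean
DSC(Immediate, TDE) and DSC(Delayed, TDE), mean (τ, C, t_shift) per plane,
and the univariate R² of axial DSC(Delayed, TDE) on CSF_Above, and
compares them with the published aggregates at half-unit-in-last-digit
tolerances (scalable; 0 = exact mode). The original per-patient files are
not redistributable, so the package ships
`synthetic_supplementary_tables()`: stand-in tables whose *sample* moments
are standardized to the published aggregates, including an exact-R²
construction (predictor component plus orthogonalized residual) for the
CSF_Above relation. These verify the runner's arithmetic end to end; they
carry no information beyond the printed aggregates themselves.

## Known limitations

* 2D, single-plane analysis; no deformable registration or atlas
  segmentation — masks are assumed co-registered with the TDE plane.
* The exponential model is the only growth law offered (no logistic or
  Gompertz alternatives, no mixed-effects pooling across subjects).
* Laser endpoints are supplied metadata; there is no automatic fiber
  detection from imagery.
* The percentile bootstrap runs mildly liberal at very small cohorts (see
  above); users comparing few subjects should interpret p ≈ 0.05 flags
  accordingly.
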