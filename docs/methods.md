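# Methods

## The measurement

`eduquant` quantifies drug target efficacy in tumor xenograft sections from
two-channel fluorescence images: a red channel carrying the EdU
(5-ethynyl-2′-deoxyuridine) proliferation label and a green channel carrying
the immunofluorescence of a target protein. EdU-positive nuclei concentrate
in a contiguous *proliferating region* of the section; its complement within
the tissue is the *non-proliferating region*. Using that partition as an
internal spatial standard, the pipeline measures, per section,

1. the density of EdU⁺ cells inside the proliferating area
   (tumor-proliferation readout), and
2. the density of protein⁺ cells inside the compartment the protein is
   expressed in (target-efficacy readout),

each as the mean count over k random circles fully contained in the
compartment, divided by the circle area (cells/mm²). Group-level treatment
effect is

    percent_change = 100 × (1 − mean treated density / mean control density),

with group means taken over per-section densities so that each animal
contributes once. A treated *increase* yields a negative value; the
statistic is undefined (an explicit error, never NaN) when the control mean
is zero. No hypothesis test is attached by default; an opt-in seeded
bootstrap over sections gives a percentile 95% interval.

## Pipeline stages and the choices behind them

**Segmentation** (EdU channel → proliferating mask). Gaussian smoothing
pools individual nuclear spots into a region-scale plateau; a global
threshold (Otsu unless fixed) separates it from background; isotropic
closing (radius 15 px), hole filling and small-object removal (< 2000 px)
clean the mask. The one parameter that matters is the pooling scale. It
must sit *above* the typical positive-cell spacing — otherwise the mask
collapses onto individual cells whenever labeling is sparse (strongly
treated sections), and an isolated stray cell can pool to a brighter peak
than a genuinely sparse region, so the threshold picks up stray cells
instead of the region — yet an unnecessarily large scale blurs the boundary
of densely labeled sections and destabilizes the threshold. No fixed value
serves both ends of a 90% knockdown, so the default is adaptive:

    sigma = 0.9 / sqrt(lambda_px),   clamped to [15, 64] px,

where `lambda_px` is the detected EdU spot count per pixel². This keeps the
coefficient of variation of the pooled spot field roughly constant (~20%)
at any labeling density, which is the condition under which a global
threshold separates region from background rather than carving up the
region's own Poisson lumps. A fixed sigma remains available in the
parameters.

**Detection** (either channel → cell centroids). Large-scale Gaussian
background subtraction (σ = 50 px; computed on a 4× decimated grid and
bilinearly upsampled, within ~3% of the full filter at a tenth of the
cost), scale-normalized Laplacian-of-Gaussian response maximized over
σ ∈ {0.8, 1.1, 1.5} × PSF width, local maxima above 10% of the image's
maximum response, non-maximum suppression at 3 px (= 2 × PSF σ, the
separation below which two equal Gaussian spots no longer produce distinct
maxima), and per-axis quadratic sub-pixel refinement. Detection runs once
per section; ROI counts are then pure point-in-circle queries, so all
circles see the same detection set. Circle membership is
boundary-inclusive (distance² ≤ r²).

**Localization** (which compartment is the protein in?). The fraction f of
protein⁺ centroids whose nearest pixel lies inside the proliferating mask
is classified three ways: f ≥ 0.75 → proliferating, f ≤ 0.25 →
non-proliferating, otherwise ambiguous. The band exists because a forced
binary call on genuinely mixed expression would silently misdirect ROI
placement; an ambiguous call aborts the pipeline unless a compartment is
forced explicitly. The call is made on pooled control sections only and
reused for treated sections, whose depleted staining would make a
per-section call unstable. An area-overlap metric (protein mask ∩
proliferating mask) is available behind a config switch.

**ROI sampling.** Circle centers are drawn uniformly from the pixels whose
Euclidean distance to the nearest background pixel — with everything
outside the image frame counting as background — exceeds the radius, i.e.
the erosion of the mask by the circle's disk. Containment is therefore
guaranteed up front and an infeasible radius is reported (with the largest
feasible one) before any sampling. k = 3 circles by default, matching the
workflow's standard count; circles may overlap (a no-overlap rejection mode
exists). The default radius makes each circle 6% of the compartment area:
at realistic densities (a few hundred cells/mm² on a few-mm² compartment) a
much smaller circle holds only a handful of cells and the 3-circle mean
becomes too noisy to recover group effects, while 6% circles hold tens of
cells and remain small next to the compartment. The radius actually used is
always recorded.

**Quantification.** Counts → per-section densities → group means → percent
change, as defined above. Densities require all circles of one section to
share one radius; the circle area is π r² in calibrated mm².

## The synthetic-data generator

Because no real image set accompanies the method, validation runs on a
simulator whose structure mirrors the method's assumptions:

* **Region**: a union of 4 chained, overlapping disks (radii 130–210 px)
  smoothed at 18 px and re-thresholded — a single connected blob occupying
  5–80% of the frame (redrawn otherwise), typically around 40%.
* **Cells**: homogeneous Poisson point processes per compartment — counts
  Poisson(λ × area), positions uniform. This is the simplest spatial model
  consistent with counting cells in circles; it also makes the density
  estimator's expectation exactly λ, which the calibration study exploits.
* **Rendering**: each cell is an isotropic Gaussian spot (amplitude 2000,
  PSF σ 1.5 px) on background 200 with additive Gaussian read noise
  (σ 50); optional Poisson photon noise. Images are written as 16-bit
  TIFFs on a fixed [0, 65535] range.
* **Default study conditions**: 768 × 768 px at 4 µm/px — a 3.07 mm
  whole-section field; λ_in = 250 cells/mm² for both channels
  (nearest-neighbor spacing ≈ 8 px ≈ 5 PSF σ, so individual nuclei are
  countable and merge losses stay in single digits), λ_out = 5 (EdU) and
  12 (protein) cells/mm². At these conditions a default circle holds ~60
  cells, which keeps the percent-change standard deviation near 3 points.
  A treated scenario scales the in-region intensities of both channels by
  (1 − reduction).
* **Reproducibility**: every section gets the sub-seed
  `SeedSequence([master_seed, section_index])`; identical (scenario, seed)
  pairs reproduce identical arrays bit for bit across platforms.

What the simulator does *not* emulate: tissue autofluorescence gradients,
staining artifacts, vignetting, 3-D sectioning, cell-size variation, and
any spatial clustering of cells beyond the two-compartment structure.
Passing validation therefore demonstrates that the estimator chain is
correct and calibrated under the method's own assumptions — not that those
assumptions hold for any particular real staining.

## Numerical choices

* Coordinates are 0-based (row, col); the center of pixel (i, j) is at
  (i, j), so the frame spans [−0.5, H−0.5] × [−0.5, W−0.5].
* Detection filtering runs in float32; peak ordering ties are broken by
  response, then (row, col); detections are emitted sorted by (row, col).
* Sub-pixel refinement offsets are clipped to ±0.5 px, and minimum
  separation is re-enforced on refined coordinates (greedy, highest
  response first) so the spacing invariant holds exactly.
* Intermediate CSV artifacts that later stages re-read (detections, ROIs)
  are written at %.17g so floats round-trip exactly; report tables use
  %.10g. Rows are sorted; reruns are byte-identical.
* ROI centers are integer pixel positions; feasibility uses strict
  dt > r, with the frame border padded as background.
* The pipeline aborts with a stage-labeled error on: constant EdU channel,
  empty/infeasible compartment, ambiguous localization (unless forced),
  zero control density.

## Validation studies (the acceptance suite)

1. **Oracle equivalence** — circle counting and overlap fractions agree
   exactly with brute-force membership scans on 1000 random instances.
2. **Density calibration** — with ground-truth centroids at 200 cells/mm²
   and k = 3 default circles, the 200-seed mean density is within 3% of
   truth (the estimator is exactly unbiased; the band covers Monte-Carlo
   error).
3. **Detection quality** — F1 ≥ 0.95 (Hungarian matching at 3 px) on
   scenes with amplitude/noise 40 and spacing ≥ 4 PSF σ, 20/20 seeds.
4. **Segmentation quality** — mask-vs-true-region IoU ≥ 0.90 at default
   contrast, 20/20 seeds.
5. **Compartment calls** — targets with true inside-share ≥ 0.9 or ≤ 0.1
   called correctly, 40/40 seeds.
6. **End-to-end recovery** — full pipeline on 5 + 5 sections at true
   reductions 25/50/75/90%: both readouts within ±10 points of truth in
   ≥ 80% of 20 master seeds per level. Residual bias (−1 to −4 points,
   from density-dependent spot merging in dense controls and residual
   mask-boundary effects) and Poisson counting noise both fit inside the
   band at the default conditions.
7. **Determinism** — identical config + seed reproduces every artifact
   byte-identically; a fixed-seed run is frozen as a golden file.

Problem sizes (20 seeds per study, 200 for calibration, 5 sections per
group) were chosen as the smallest giving clear statistical separation
between pass and fail for each check.

## Known limitations

* The EdU readout is self-referential — circles are placed in a mask
  derived from the channel being counted — so any residual cell-locking of
  the mask inflates treated densities slightly; the adaptive pooling scale
  reduces this to a ~2-point effect at 90% reduction, but it does not
  vanish.
* Detection merges genuinely unresolvable neighbors (closer than 2 PSF σ),
  undercounting dense sections by a few percent; the effect partially
  cancels in the control/treated ratio.
* Percent change carries no uncertainty by default; the bootstrap interval
  reflects only between-section variability, not segmentation or detection
  systematics.
* The compartment call assumes one-sided expression, which is what the
  strategy itself presumes; mixed-expression targets stop the pipeline by
  design.
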