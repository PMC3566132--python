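# Methods

## The assay being modelled

Differentiated adipocytes in 96-well plates are fixed and labelled in four
fluorescence channels: DAPI (nuclei), a neutral-lipid stain (droplets),
and one or two antibody channels reporting phosphorylated
droplet-associated proteins (phospho-perilipin 1A site 5/6,
phospho-HSL serine 563/660). Four fields per well are acquired at 20×
(0.6848 µm/pixel after 2×2 binning) or 40× (0.344 µm/pixel). The
biological readout is the per-cell area of phospho-positive droplet rim
(`Area Pm`, µm²/cell), its integrated intensity (`Tii Pi Pm`), and the
per-cell Pearson correlation between two labels; lipolytic agonists (FSK,
isoproterenol, L-γ-MSH) raise `Area Pm` several-fold within minutes.

## Pipeline

**Nucleus detection.** The DAPI channel is thresholded at
`median + k·σ_MAD` with `σ_MAD = 1.4826·MAD` and `k = 4` by default; the
median/MAD pair is robust to the bright-but-sparse nuclei so no explicit
background model is needed. Connected components are hole-filled and
filtered at `min_nucleus_area_um2` (default 30 µm²). Touching nuclei are
optionally split by a watershed on the distance transform seeded at
distance peaks at least `split_min_distance_um` (5 µm) apart. The original
instrument's segmentation internals are unpublished; this stage is
therefore a deliberately parameter-light re-design validated against the
simulator's ground truth (≥95% of simulated nuclei recovered 1:1 at
default densities), not a re-implementation.

**Cell territories.** Every pixel within `max_radius_um` (default 40 µm)
of a nucleus boundary is assigned to the nearest nucleus — Euclidean
distance by default, geodesic within a thresholded cytoplasm mask when one
is provided. Assignment is computed as an argmin over per-label distance
transforms restricted to padded bounding boxes; labels are scanned in
increasing order and replacement requires a strictly smaller distance, so
exact ties deterministically go to the lower label. A per-pixel
brute-force oracle reproduces the partition exactly in tests. Cells whose
nucleus touches the field border are flagged and excluded from well
aggregates by default, since their territories and areas are truncated.

**Masks.** Protein and lipid masks use the same rule: pixel intensity
above the per-field `median + k·σ_MAD` (k = 4), connected components
smaller than `min_object_px = 4` removed (shot-noise singletons), then
intersection with the assigned territories. Thresholding is global per
field rather than per cell — at the densities used, the field median sits
on the background, and a global rule keeps control and treated wells on
the same footing. The threshold adapts to background, not signal, so
doubling the label brightness changes `Area Pm` by <5%. Flat-field
correction is off by default (the simulator produces flat illumination)
and available behind a flag. A known limitation: when a channel's
foreground approaches ~50% of the field (very dense lipid staining), the
median drifts upward and the mask becomes conservative.

**Per-cell readouts.** `Area Pm` is the positive-pixel count times the
pixel area; `Tii Pi Pm` sums the *raw stored* intensities over the mask —
no background subtraction, matching the printed definition of the
parameter (a subtracted variant exists behind a flag). The per-cell
Pearson coefficient defaults to the whole cell territory as its pixel
scope; `mask_union` (union of the two label masks) is available, since
rim-localized signals over a large cytoplasm can make whole-cell
correlations background-dominated. Zero-variance scopes yield NaN, are
excluded from well means and counted in QC rather than propagated.

**Well statistics.** The experimental unit is the well: per-cell values
pool to a well mean, SDs are sample SDs (n−1) across wells, and all tests
run on well means. `fold_change` is the ratio of group means of well
means; `normalize_to_control` divides each well mean by the control-group
mean. Comparisons follow one-way ANOVA with Tukey's HSD (all pairs,
`scipy.stats.tukey_hsd`, exact studentized-range distribution) or
Dunnett's test against a designated control (`scipy.stats.dunnett`), or
Student's equal-variance t for a single contrast. Tukey/ANOVA/t agree
with an R oracle to 1e-6 in tests; Dunnett is asserted at 1e-3 because
both implementations evaluate a multivariate-t integral by quasi-Monte
Carlo (measured jitter ≈1.5e-4). No correction is applied beyond the
post-hoc tests' built-in family-wise control.

## Synthetic plates

The generator emulates what the pipeline needs to be tested against, not
photorealism:

* **Cells.** Poisson-distributed count per field; nucleus centers placed
  sequentially with a hard 16 µm minimum separation (an error names the
  density parameter if placement fails). Nuclei are rotated ellipses
  (radius 6 µm ± 15%, aspect ≥0.7).
* **Droplets.** 12–40 per cell, log-normal radii (median 2.8 µm,
  σ = 0.35), centers area-uniform in a disk of 22 µm around the nucleus.
  These sizes are not taken from data — droplet morphometry is
  unreported — they are chosen so the total available rim area per cell
  (~400–500 µm²) comfortably exceeds the largest condition means
  (189–216 µm²/cell), which is required for the per-cell truth to converge
  to the condition mean rather than truncate.
* **Phospho-positive rim.** Each cell draws a target area from a gamma
  distribution (mean = the condition's `rim_positive_area_mean_um2`,
  CV = 0.35); droplet rims (annuli of thickness 1.4 µm) are marked
  positive in random order until the rasterized union reaches the target,
  the last rim taken partially, pixel by pixel in angular order. Emitted
  truth is the exact union pixel count × pixel area, so conservation holds
  to the pixel. The two protein channels draw independently, supporting
  dual-label designs.
* **Photometry and noise.** Backgrounds 100–200 counts, nuclei ≈3000,
  droplets ≈1500, rims 2500 × `protein_intensity_scale`; Poisson shot
  noise on the clean image plus Gaussian read noise (σ = 10), clipped to
  the bit depth. 16-bit TIFF by default, 8-bit BMP supported.
* **Seeding.** Per-field seeds derive from
  `SeedSequence([master_seed, well_index, field_index])`, so plates are
  reproducible and fields independently re-generable.

What the simulator does *not* model — uneven illumination, autofluorescence,
cell-to-cell background variation, well-level random effects, droplet
clustering between neighbouring cells' clusters, antibody off-target
binding — bounds what passing tests show: recovery on these images
demonstrates the pipeline's correctness and calibration, not robustness to
every real-data artifact.

## Experiment presets and problem sizes

Presets encode the published designs as ground truth: the 5-min agonist
experiment (site 5: control 27 µm²/cell, FSK 7-fold, L-γ-MSH 8-fold, 3
wells; site 6: control 7 µm²/cell, FSK 11-fold, L-γ-MSH 27-fold, 8 wells),
the siRNA titration (6 wells/level, up to 90% reduction; the intermediate
levels, unquantified in the source text, are set to 70%/80%), the
1/5/20-min time course (site 5: ~20 µm²/cell control, sustained 4-fold, 7
wells, with a slower HSL-serine-563 second channel), and the 20-min
agonist panel. All presets use 4 fields/well. Desk-scale cell densities
(60–133 cells/field at 512×512 px) are the package's default problem
sizes; they keep a full recovery run in minutes while leaving ≳3000 cells
per experiment, at which point the sampling error of a fold change is ~2%.

Recovered statistics carry a small systematic bias (−3…−8% on fold
changes): noise pixels add a constant ≈0.3 µm² to every cell's measured
area, which inflates control means relative to treated means, and
border-cell exclusion redistributes a few percent of rim pixels. Both are
documented behaviour of the default parameters, well inside the ±15%
sampling tolerance used by the recovery tests.

The full-pipeline null calibration runs at miniature scale (128×128 px,
~6 cells/field, 20 seeds, no p<0.001 flags expected), while the
type-I-error calibration of the well-level statistics runs at 1000
replicates directly on simulated well means; simulating 500+ full image
plates is deliberately out of scope for a default test run.

## Degenerate inputs and numerical choices

All-constant images yield zero nuclei (not an error); zero nuclei yield an
all-zero territory map with a warning; empty masks yield `Area Pm` =
`Tii Pi Pm` = 0; empty wells aggregate to n = 0 with NaN means and a QC
flag; a zero control mean makes fold change an error rather than an
infinity. Pearson values are clipped to [−1, 1] against floating-point
overshoot. CSV tables write floats as `%.17g` and re-read with
round-trip parsing, so write→read is exact. Pixel coordinates are 0-based,
row-major, origin top-left; filenames follow
`<plate>_<well>_f<field>_<channel>.<ext>`, bijectively parseable.

## Limitations

Equivalence with the original commercial analysis software cannot be
asserted — its algorithms are unpublished and the study's raw images are
not deposited; the published per-cell Pearson values (0.96/0.88/0.94) are
therefore not reproducible and only the effect-size recovery on synthetic
data is claimed. Segmentation is intensity-based and 2-D; machine-learned
or 3-D segmentation, per-droplet instance statistics, Manders/Costes
colocalization and dose–response fitting are out of scope.
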