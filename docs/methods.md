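# Methods

## Scope and model of the data

The package analyzes bright-field tiles from sequential chromogenic IHC:
one marker per staining round on a single section, each round imaged after
a destain/strip cycle that may translate, rotate, and uniformly dilate or
shrink the tissue. The unit of image work is an in-memory calibrated crop
(8-bit RGB plus microns-per-pixel); pyramidal whole-slide formats and
vendor metadata are out of scope. The cohort layer analyzes a paired
pre/post table of per-patient marker values (densities in cells/mm²,
PDL1 as percent of all cells).

## Registration

Corresponding reference marks are supplied per round (`round_id,index,x,y`
CSV; correspondence by equal index). The similarity fit is Umeyama's
closed-form least-squares solution: with centered point sets, the rotation
comes from the SVD of the cross-covariance with the determinant forced
positive — physical sections do not mirror, so reflections are excluded —
and scale and translation follow in closed form. The affine model (normal
equations) is available for anisotropic deformation but is not the
default: rotation + uniform scale + translation is the smallest family
consistent with how stripping deforms tissue. Degenerate configurations
(coincident points; collinear points for affine) are rejected rather than
silently regularized.

Fine alignment is deliberately simple and deterministic: coordinate
descent over (s, θ, tx, ty) minimizing the mean squared difference of the
two hematoxylin-OD images over their overlap, with a step-halving schedule
(initial steps 0.02 in scale, 0.01 rad, 2 px in translation; default
max_iter 50, tol 1e-6). Moves are accepted only if they lower the cost,
so the cost sequence is non-increasing by construction. The cost uses the
hematoxylin channel because the counterstain is the only signal common to
every round.

Warping is bilinear with white (255,255,255) background fill — white is
OD-neutral, so filled pixels contribute no stain signal downstream. Note
that bilinear interpolation bounds reconstruction error only for smooth
content; across a hard nucleus edge a warp/unwarp round trip can differ by
tens of gray levels, which is inherent to the interpolator, not a defect
of the transform.

## Stain deconvolution

Optical density is computed per channel as −log₁₀(max(I, 1)/I₀) with
I₀ = 255; the 1-level floor bounds OD at log₁₀(255) ≈ 2.407 and keeps the
map monotone. Stains mix additively in OD (Beer–Lambert), so unmixing is
the inversion of a 3×3 matrix whose rows are unit stain vectors:
hematoxylin, chromogen (AEC or DAB), and a residual completed by the
normalized cross product. Default vectors are the published
Ruifrok–Johnston values; they are configuration, not estimates — automatic
stain-vector estimation is out of scope, and the exact vectors used by any
particular staining protocol differ, which is why image-level validation
rests on round-trip and synthetic-recovery properties rather than on
matching any specific instrument's channel images. Negative
concentrations (pixels slightly outside the stain span) are preserved in
the unmixed planes so that recomposition is exact to 1e-9, and clipped to
zero only when measured.

## Cell detection and quantification

Detection runs on the smoothed (Gaussian, σ default 1.5 µm) hematoxylin
concentration, or on the OD sum when the counterstain is weak. The binary
nucleus mask is thresholded at 0.1 OD, split by a distance-transform
watershed seeded at local maxima separated by at least twice the radius of
the smallest plausible nucleus (2·√(min_area/π)), and filtered to the
10–400 µm² nucleus-area band. Cells are nuclei expanded radially by 5 µm,
bounded by neighboring cells; cytoplasm is cell minus nucleus. All
parameters are explicit configuration with these defaults — there is no
per-slide tuning, trading a little per-slide accuracy for exact
reproducibility. A cell belongs to a region iff its centroid lies in the
analysis mask (union of tumor polygons minus stroma ∪ necrosis ∪
artifact); centroid-inside is unambiguous where any-overlap is not.
Positivity is a threshold on one compartment statistic of the chromogen
concentration (e.g. nucleus mean for nuclear markers, cell/cytoplasm mean
for surface markers). Summaries report positive cells per mm² of mask
area and percent of all detected cells; with zero detected cells the
percentage is explicitly undefined, never 0.

## Co-expression across rounds

Detections are carried into the reference frame by the round's transform
and paired by mutual nearest neighbors within 6 µm (about one nucleus
diameter), with deterministic (distance, id) tie-breaking. This is a
formal surrogate for visual co-localization on pseudo-fluorescence
overlays; no published numeric criterion exists, so the radius is a
declared default, not an inferred one. Phenotypes are boolean rules over
the matched pair's labels. The GZMB:CD8 ratio follows the slide-level
convention — total GZMB⁺ count divided by total CD8⁺ count, regardless of
pairing — and the stricter per-cell co-expression fraction
P(GZMB⁺ | CD8⁺ among matched cells) is reported alongside. Ratios with a
zero denominator are explicitly undefined.

## Cohort statistics

The paired test is the two-tailed Wilcoxon signed-rank test: missing
values deleted pairwise, zero differences dropped (Wilcoxon's original
prescription, and the behavior of the desktop package this layer mirrors),
absolute differences midranked, W = min(W⁺, W⁻). For n ≤ 25 the two-sided
p is exact — 2·P(W⁺ ≤ W) under the uniform distribution over all 2ⁿ sign
assignments, computed by dynamic programming over doubled (integerized)
midranks, capped at 1. This reproduces, e.g., p = 4/512 = 0.0078125 for
nine pairs with a single discordant sign. Above n = 25 a normal
approximation with continuity and tie correction is used and labeled as
such. Spearman's ρ is the Pearson correlation of midranks with the
t-approximation p on n−2 df (|ρ| = 1 reports the exact permutation bound
2/n!). SEM is sd/√n with the n−1 denominator; the median of an even-sized
sample is the mean of the central two. No multiple-testing correction is
applied anywhere, matching the analysis convention this layer reproduces
(nominal p < 0.05).

Group stratification parses the pre-slash segment of the prior/following
treatment string: any immune-modulating token (Ipi, Biot, BioCT, IL-2,
IFN) puts the patient in `immuno_treated`; No/CT/RT (a trailing `*`
footnote marker is ignored) put them in `naive_ct_rt`; unknown tokens are
errors. Lesion response classes use the longest-diameter rule: regressing
at ≤ −30 %, progressing at ≥ +20 %, stable between.

## The packaged cohort fixture

The cohort table ships in two variants because the source table is
internally ambiguous in two places, and both ambiguities are carried
rather than silently resolved:

* Patient 6's pre-treatment PDL1 prints as "0.9748", yet the published
  immuno-group pre mean (4.920) is arithmetically consistent only with 0.
  `table1.csv` keeps the printed value; `table1_pt6pre_zero.csv` carries
  0. Every headline statistic (all three signed-rank p-values, the
  all-pairs and naive-group means) is identical under either reading.
* The table's parenthetical sampling labels disagree with the running
  text, which names patients 2, 6, and 10 as post-treatment — the only
  assignment consistent with the published CD8-ratio means (0.5147 ±
  0.2318 post-treatment, 0.8578 on-treatment immuno) and the 9.33-month
  post-treatment biopsy average. The fixture keeps both columns
  (`sampling_table1`, `sampling`); analysis uses the text assignment.

One related discrepancy is documented rather than reproduced: the source
text reports a PDL1 rise in 11 of 14 assessable pairs, but the printed
per-patient values yield 10 rises (PDL1 falls in patients 1, 2, 3, and
15 under either reading of the ambiguous cell). The package reports the
count computed from the data.

Cohort tables are semicolon-delimited because the comma is both the
decimal separator and a list separator inside treatment strings; the
decimal convention is always an explicit argument, never guessed.

## Synthetic fixtures: what they do and do not show

The slide generator renders anti-aliased disk nuclei (radius 3 ± 0.4 µm,
rejection-sampled so chromogen footprints never overlap) through the exact
Beer–Lambert forward model with the same stain vectors the deconvolution
inverts, deposits chromogen over the cell footprint of marker-positive
cells (marginal positive fractions 0.4/0.3 for the default CD8/GZMB pair,
P(GZMB⁺|CD8⁺) = 0.6), applies each round's known similarity transform,
and adds Gaussian intensity noise (sd 2 gray levels) — all driven by one
seeded generator, so outputs are byte-reproducible. Default tiles are
384×384 px at 0.5 µm/px with 120 cells, a scale at which the full
render → deconvolve → detect → classify → match loop runs in about a
second; tests sweep 10 seeds.

These fixtures make ground truth unambiguous, which is their purpose and
their limit: real tissue has textured, overlapping, out-of-focus nuclei,
uneven stain uptake, melanin and hemosiderin pigments, folds and edge
artifacts, and imperfect destaining between rounds. Passing the synthetic
recovery criteria (cell counts within 5 %, positive fractions within 5
points, ≥ 95 % of cross-round matches) demonstrates that the algorithms
are implemented correctly, not that they reach that accuracy on clinical
slides — the study's own image-level densities are not reproducible here
because the raw slides are not public, and the published statistics are
reproduced through the cohort table instead.

The cohort generator draws pre values log-normal (median 10, log-sd 0.5 —
the scale of percent-positive readings) and sets post = pre + effect +
N(0, 1), floored at 0; at this scale the floor is essentially never
active, so a zero effect yields an exactly symmetric null. Under that
null the exact test's empirical rejection rate at α = 0.05 over 2,000
cohorts of 14 sits inside [0.035, 0.065], and a 3-sd shift gives power
≈ 1 at n = 14.

## Numerical conventions

Coordinates are 0-based and pixel-centered, x rightward, y downward;
polygons share the frame. Transforms are 3×3 homogeneous matrices acting
on (x, y). Descriptives sort their input first, so results are exactly
independent of input order. Matching ties break on (distance, id).
Missing values are NaN internally and `na` on disk, never 0.
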