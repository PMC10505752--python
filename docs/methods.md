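# Methods

## Intensity model

All quantification runs on a scalar *intensity image*: an 8-bit map in
which lower values mean stronger DAB (brown) chromogen. Proprietary
whole-slide platforms emit such pixel values natively; for plain RGB
input the package derives them by color deconvolution with the standard
H-DAB stain matrix (scikit-image's `rgb2hed`), clipping the DAB channel
at a configurable maximum optical density `dab_od_max` and mapping it
linearly and invertedly onto [0, 255]. Only the monotone contract is
normative — a pixel with higher DAB optical density never receives a
higher value, and pure white maps to 255 — because absolute pixel values
are scanner- and software-specific. `dab_od_max` defaults to 0.3 (in the
stain-matrix units used by scikit-image), chosen so that the full
0–255 range survives an 8-bit RGB round trip with at most ±3 pixel-value
error; larger values push strongly stained pixels below 8-bit RGB
resolution and break invertibility. A pass-through mode accepts
single-channel images as ready intensity maps.

Intensity values are quantized to integers before classification, since
the level thresholds are defined as integer bands. The five bands —
background 176–255, weak 131–175, intermediate 101–130, strong 71–100,
very strong 0–70 — are validated as disjoint and jointly covering
[0, 255]; the value 176, which the band phrasing leaves ambiguous, is
assigned to background so that level 1's upper bound stays at 175.

## Areas, artifacts, normalization

Areas are pixel counts times the squared physical pixel edge (µm²).
Artifact detection is a deliberately simple rule set — saturated-white
glass (all channels ≥ 250), near-black debris (all ≤ 10), and a reserved
magenta used by the simulator — standing in for the AI tissue
segmentation of commercial platforms, which is out of scope. Artifact
pixels are excluded from every level area and from the mean intensity.

Normalization rescales areas to a standard 10 high-power (×400) fields,
2.37 mm²: `normalized = area × 2,370,000 µm² / tissue_area`, where
`tissue_area` is the ROI area minus excluded artifact area. Dividing by
the artifact-free area (rather than the raw ROI area) avoids diluting
positivity by non-tissue; this is a package choice where either
convention is defensible. Normalized areas are invariant under
replication of ROI contents, which the tests assert.

Mean intensity (MI) is averaged over all non-artifact ROI pixels by
default; a documented switch (`mi_positive_only`) restricts it to
positively stained pixels, since platforms differ on this point.

## Expression scoring

Percentage scores use half-open bins `[0,1)→1, [1,10]→2, (10,50]→3,
(50,100]→4`: the published bins are phrased on integers ("1% to 10%",
"11% to 50%"), so continuous inputs strictly between 10 and 11 need a
convention; they fall to score 3. The final grade is the product of the
percentage and intensity scores; the products only ever reach
{0,1,2,3,4,6,8,9,12}, so the category bins (0 / 1–3 / 4–6 / 8–12)
partition all attainable grades — the gap at 7 is unreachable and is
asserted by test rather than mapped.

The hotspot rule is operationalized on area fractions: the area-majority
intensity grade is found, and if regions at a strictly higher grade
jointly exceed one third of the tumor area (strict inequality at exactly
1/3), the assessment comes from those strong regions (area-weighted
percent positive, maximum grade); otherwise the whole-tumor summary is
used. Applied to a level map, pixel levels fold onto visual grades as
0→0, 1→1, 2→2, 3/4→3.

## T/N ratio and TASC rubric

The tumor-to-normal ratio divides a tumor's normalized positive area by
the unweighted mean of the pooled control measurements (all peritumoral
and healthy-control compartments — muscle, adipose, epidermis/dermis —
of the matching group). Flat pooling is the default because healthy
controls are collected per species rather than per entity; a
compartment-wise mean can be formed upstream if preferred. A zero mean
control area makes the ratio undefined and is reported as an error, and
tumors without peritumoral tissue are recorded as non-evaluable rather
than imputed.

The TASC rubric fixes criteria I, V, VI, VII at the FAP literature
constants (5, 2, 1, 1) and computes II–IV from group counts. The
"majority" decision for II and III defaults to ≥50% — a group at exactly
half scores the points — because the published per-entity scores award
criterion III at exactly 11/22; a strict >50% mode is provided as a
regression surface for that choice. Criterion IV percentages are rounded
half-up to integers before binning, and percentages below 10% score 0 by
continuity with the 10–49% bin. `CriterionInputs` accepts an optional
explicit overexpression percentage overriding the count-derived one;
this exists because published summary tables sometimes print a
percentage that disagrees with its printed counts, and the rubric then
has to follow the table's stated percentage to reproduce its scores. A
tumor counts as overexpressing when ≥10% of its cells show
intermediate-to-strong staining (grade ≥ 2); the boundary case at
exactly 10% is switchable.

## Synthetic data

The image generator writes the intensity channel directly: each pixel is
assigned a staining level (exact largest-remainder apportionment of the
requested fractions, then a seeded shuffle) and a value at the level's
band midpoint ± a jitter of up to 6. Midpoint placement keeps every
emitted value at least 8 values away from a band edge, so Gaussian pixel
noise with SD ≤ 5 essentially never flips a pixel across the
positive/background boundary, and a noiseless image is recovered
band-exactly by the quantifier. The RGB rendering applies the inverse
H-DAB transform (`hed2rgb`), so the default unmixing route round-trips
into the intended bands; artifacts are painted in reserved magenta.
Ground truth records the exact pre-noise per-level pixel counts.

What the simulator does *not* emulate: nuclei, cell instances, tissue
texture, hematoxylin counterstain, scanner color variation, or spatially
coherent staining patterns (levels are speckled, not clustered). Passing
recovery tests therefore demonstrates the correctness of the
measurement arithmetic and thresholding, not robustness to real-slide
color variability.

The cohort generator draws per-tumor rows per entity: histological grade
(categorical), percent positive cells (normal, clipped to [0, 100] —
clipping, not resampling, is used for simplicity and biases means at the
extremes), visual intensity grade (categorical; grade 0 forces percent
positive to 0), T/N ratio (lognormal, with a per-entity probability of
being evaluable), and a normalized stained area coupled to the visual
assessment (proportional to percent positive, scaled by intensity, with
lognormal scatter of log-SD 0.25) so downstream association analyses
have a known positive signal. The default `study_cohort_spec` encodes
the cross-species STS study design: 30+16+7 canine, 24 feline and
10+10+9+10 human tumors with their reported grade distributions,
per-species percent-positive means/SDs (51.1±36.2, 56.6±21.3,
61.1±41.7), T/N lognormal medians calibrated so the expected share of
tumors with T/N > 10 matches each entity's reported fraction (log-SD
fixed at 1.0), and intensity-grade distributions calibrated to the
reported per-species no-expression and high-expression marginals. The
human DFSP entity is reported ungraded, so its synthetic grades are
uniform. These defaults were set once from the study tables and are not
tuned to test outcomes.

## Statistics

Group comparisons use the Kruskal–Wallis omnibus test followed by Dunn's
pairwise z-tests on pooled mid-ranks with tie correction
(`z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j))`),
adjusted over the whole family of pairs with Bonferroni by default
(the adjustment variant is switchable — the convention is not fixed by
the workflow being modeled). Chi-squared tests are Pearson's without
continuity correction. Spearman correlation uses average mid-ranks for
ties; constant inputs yield NaN with a warning. Shapiro–Wilk normality
is reported per group but never gates the nonparametric pipeline. The
calibration tests run 1000 null replicates per test (groups of 20 for
Kruskal–Wallis, 2×2 tables of n=240 for chi-squared), sized to keep
Monte-Carlo error around ±0.007 on a nominal 0.05.

## Degenerate inputs and tie-breaks

An ROI that is empty or entirely artifact raises a degenerate-ROI error
(mean intensity undefined). A majority decision with a zero denominator
(no evaluable tumors) is a domain error, not a zero score. In the
hotspot rule, the area-majority grade breaks ties toward the higher
grade. Largest-remainder apportionment in the image generator breaks
remainder ties by order of descending remainder.

## Known limitations

- Absolute intensity values are not comparable to any commercial
  platform's pixel values; only band membership under the documented
  transform is meaningful.
- The artifact detector is rule-based and will miss real-slide artifacts
  (folds, blur, edge chatter) that trained segmentation would catch.
- Criteria V–VII are constants for FAP; the rubric is not wired to
  literature evidence for other targets.
- Cohort-level percentages and correlation coefficients of any real
  study depend on its raw per-sample data; the synthetic cohort
  reproduces study *structure*, not per-sample values.
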