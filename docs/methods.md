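# Methods

## The measurement

mIF (morphometric interstitial fibrosis) is the percentage of an
annotated cortical section classified Sirius-Red-positive:

    mIF = 100 · n_positive / n_evaluated   [%]

The evaluation region is the union of operator-drawn cortex polygons
minus the union of exclusion polygons (glomeruli, medium arteries);
reference patches never enter it. Exclusion always wins over inclusion,
mirroring the operator workflow of outlining the cortex and then deleting
structures from it.

### Rasterization convention

Pixels are 0-based, x rightward, y downward. A pixel belongs to a polygon
iff its center `(col + 0.5, row + 0.5)` lies inside the ring (non-zero
winding; shapely predicates after `make_valid` repair of self-touching
rings — identical for the simple rings produced by any reasonable
annotation workflow). With this convention an axis-aligned rectangle with
integer corners covers exactly width × height pixels, which the property
tests check against direct arithmetic. Rasterization is deterministic;
`extract_pixels` selects exactly the pixels the rasterizer would set, so
patch pixel counts and mask areas always agree.

### Stain model

Classification is a two-class Gaussian discriminant in a color space
derived from HSV: `(cos 2πh · s, sin 2πh · s, v)`, all channels in
[−1, 1]. The cyclic embedding keeps the red hue — which wraps around
h ≈ 0 — in one connected region, and multiplies the chromatic plane by
saturation so that desaturated pixels (where hue is numerically
meaningless) collapse toward the origin instead of scattering across hue
angles. Sirius-Red discrimination is chiefly chromatic, so this space
separates collagen red from pale counterstain while tolerating intensity
shifts between staining batches.

Each class (positive = red collagen, negative = counterstained tissue)
gets a mean and covariance estimated from the operator's reference
patches on the same slide, with a ridge of ε = 1e-3 added to the
covariance diagonal for numerical stability with small hand-drawn
patches. At least 100 pixels per class are required
(`min_calibration_pixels`); with the ridge, even a perfectly uniform
patch yields a usable (if wide) class model. After fitting, the training
pixels are reclassified; if either class fails to win a majority of its
own sample the calibration is flagged degenerate rather than rejected.

A pixel is positive iff the log-likelihood ratio (positive minus
negative) strictly exceeds `llr_offset` (default 0). Ties break negative
— deterministic and conservative toward underestimating fibrosis.
`n_positive` is non-increasing in `llr_offset`, and swapping the two
reference samples maps mIF to 100 − mIF exactly when no pixel sits on the
decision boundary.

The internal-control property this construction is designed for: a global
affine intensity transform (gain 0.8–1.2, offset ±10, clipped to [0,255])
applied to the slide *and* its reference patches moves mIF by at most 0.5
percentage points on default synthetic slides, because the calibration is
refit from the transformed patches. This is asserted by tests.

### Denominator policy

The default (`entire_section`) counts every evaluated cortical pixel,
lumens and white space included — i.e. percent of the entire cortical
surface. Whether luminal white space should instead be removed is an open
methodological point in morphometric fibrosis work, so `tissue_only` is
provided as an explicit option: pixels with HSV saturation < 0.08 and
value > 0.85 are dropped from numerator candidates and denominator alike.
The two modes are not numerically comparable (tissue_only yields larger
percentages); results record which policy produced them.

### Batch runs

A manifest CSV lists slide id, image path, annotation path, and an
adequacy flag with reason. Specimen adequacy (the "< 7 glomeruli and/or
no artery" rule) is a pathologist's call made upstream; it arrives as a
flag and is never computed from pixels. Inadequate slides and per-slide
failures (unreadable files, missing reference patches) are routed to an
exclusion list with reasons; every manifest entry appears exactly once
across results ∪ exclusions.

## Synthetic histology

The generator renders what the classifier actually has to cope with,
without claiming photorealism:

* **Cortex**: an irregular octagon inset from the canvas; outside is
  unstained background.
* **Glomeruli**: non-overlapping discs, painted as a 65/35
  counterstain/collagen blend — a distinct color from both classes, so
  excluding them genuinely matters. Exclusion polygons (24-gons at radius
  +1.5 px) cover them with a safety rim.
* **Tubules**: random ellipses (semi-axes 4–9 px) of counterstained
  epithelium around a white lumen at 0.55 scale, placed by rejection
  sampling without mutual overlap.
* **Fibrosis**: a Gaussian noise field smoothed with σ =
  `field_smoothness` (default 3 px) is evaluated over the paintable
  interstitium (cortex minus glomeruli, tubules and exclusion rims); the
  top-`n` pixels by field value are painted collagen, with `n` the exact
  order statistic matching the requested fraction of the evaluation
  region. This achieves |realized − target| ≤ 1/n_eval (far inside the
  0.002 documented tolerance) while producing connected, wispy
  interstitial bands rather than salt-and-pepper noise.
* **Calibration band**: before tubule placement, one 12×12 (or 10×10 at
  low fractions) window where the field is highest is reserved and
  painted solid collagen, counted toward the target. This guarantees a
  pure positive reference patch of ≥ 100 pixels exists even when the
  thresholded field yields only thin blobs — emulating an operator
  choosing a solid collagen band as the positive internal control. When
  the target fraction is too small to spend 2× the band area (e.g.
  fraction 0 or near 0), no band is reserved and the slide may carry no
  `ref_positive` patch; such slides can be quantified with a calibration
  from a sibling slide of the same batch.
* **Color and batch effects**: per-class RGB (collagen ≈ (190, 45, 45),
  counterstain ≈ (235, 215, 170), lumen/background ≈ (250, 250, 250) —
  generator parameters, not claims about real stains), plus Gaussian
  pixel noise (SD 4), then a global gain and hue rotation emulating
  staining-batch variation. Truth masks are recorded from geometry before
  noise. Identical config (including seed) gives bit-identical output;
  batch slides derive per-slide seeds from `SeedSequence([base_seed,
  index])`.
* **Reference patches**: the largest axis-aligned rectangle wholly inside
  the pure positive (respectively pure negative interstitium) truth
  region, found by the maximal-rectangle-in-histogram algorithm and
  capped at 40×40 px.

What this does *not* emulate: nuclei, texture within classes, partial-
volume blending at structure boundaries, scanner artifacts, JPEG
compression, or medulla/capsule tissue. Passing the recovery tests
therefore shows the calibration-classification-bookkeeping chain is
correct under known color statistics, not that any particular accuracy
holds on real slides — on real tissue the class overlap is larger and the
error floor is set by staining chemistry, not by this pipeline.

The standard validation batch is 3 fractions (0.05/0.15/0.25) × 3 gains
(0.9/1.0/1.1) at 192×192 px; tests require per-slide absolute error
≤ 1.5 percentage points and per-fraction gain spread ≤ 1.0 point.
Problem sizes throughout (192² default canvas, 96² in high-volume tests)
were chosen as the smallest canvases on which the structural confounders
(tubule rings, glomeruli, wispy bands) remain morphologically meaningful.

## Statistics

### ICC(1,1)

The agreement model treats the two pathologists' measurements as
interchangeable ratings sharing only a subject effect — the one-way
random-effects, single-rater ICC. From the one-way ANOVA mean squares MSB
(between subjects, df = n−1) and MSW (within, df = n(k−1)):

    ICC = (MSB − MSW) / (MSB + (k−1)·MSW)
    F   = MSB / MSW
    F_L = F / F_{1−α/2}(n−1, n(k−1)),   F_U = F · F_{1−α/2}(n(k−1), n−1)
    ρ_bound = (F_bound − 1) / (F_bound + k − 1)

The p-value is the F tail for H₀: ρ = 0. `icc_ci_from_estimate` inverts a
point estimate to its implied F and applies the identical pivot, so the
two paths agree exactly — this is what lets a published interval be
reconstructed from the printed estimate and n alone. The one-way variant
was chosen because its F-based interval reproduces the published
inter-operator interval [0.67, 0.81] at estimate 0.75, n=151, k=2;
two-way and average-rater variants are out of scope. Implementation is
validated against a from-first-principles ANOVA oracle (1e-10 on random
small tables) and against `pingouin.intraclass_corr`'s ICC(1,1) row.

### Correlation and regression

Pearson r carries a Fisher-z interval, `tanh(atanh r ± z_{1−α/2}/√(n−3))`,
with the t-test p-value; the from-estimate variant reconstructs published
intervals. Simple OLS (via `scipy.stats.linregress`) reports slope,
intercept, R² and the slope t-test, cross-checked against the normal
equations. Wilcoxon signed-rank uses the exact null for ≤ 25 non-zero
differences (validated against full sign-vector enumeration) and the
continuity-corrected normal approximation above; zero differences are
dropped, and all-zero difference vectors return p = 1 with a degenerate
flag. Comparisons against printed values round half-up to the printed
decimals. No multiple-testing correction is applied anywhere, matching
standard practice in the validation literature this package accompanies.

### Simulators

`simulate_paired_ratings` draws subject effects with variance ρ and
residuals with variance 1−ρ (total variance 1, population ICC exactly ρ).
`simulate_grouped` draws per-group normal samples from (n, mean, sd)
summaries; with the four per-ci-grade summaries (n = 40/82/18/11, means
8.3/10.7/17.1/20.1, SDs 2.4/3.6/6.4/8.0) the implied mIF-grade
correlation has closed form cov/(σ_x σ_g) ≈ 0.61, which the simulation
twin reproduces. Every stochastic operation takes an explicit seed; there
is no global RNG state.

## Cohort model

A patient's fibrosis trajectory is driven by a latent severity
z ~ N(0,1):

    mif_t = μ_t + σ_t (√ρ · z + √(1−ρ) · ε_t),   ε_t ~ N(0,1)

giving correlation ρ (default 0.5 — a free parameter, as no longitudinal
correlation is established for this design) between any two timepoints
while preserving each timepoint's marginal (μ_t, σ_t). Defaults: D0
8.4 ± 3.8, D15–30 10.0 ± 3.9, M3 13.6 ± 6.7, M12 15.9 ± 5.2 (%), with
biopsy availability 43/20/28/28 out of 66 patients (scaled
proportionally for other cohort sizes). Marginals are exact normals —
deliberately un-truncated, so a value slightly below 0% is possible
(≈ 2% of D0 draws); truncating would bias the means and SDs away from
the printed summaries the generator is meant to reproduce.

Banff ci is graded from mIF by fixed thresholds 9.5 / 13.5 / 19.0
(ci = number of thresholds exceeded), calibrated so per-grade mean mIF
approximates 8.3 / 10.7 / 17.1 / 20.1; grade means are monotone in ci by
construction. Real grading is noisier than a deterministic threshold —
an acknowledged simplification.

Clinical outcomes are linear in mIF at M12 with noise scaled to hit a
target R² in expectation: recovery time (22.6 ± 9.8 days, R² 0.29),
creatinine increase at M12 and last follow-up (R² 0.32 / 0.29, as
differences from a per-patient baseline ~ N(130, 25) µmol/L), and day-3
LDH generated from recovery time at R² 0.1028. Recovery time is floored
at 1 day and LDH at 100 IU/L (physiological floors affecting ~1% of
draws each).

`progression_analysis` reports per-timepoint summaries and, for each
consecutive pair, both the cross-sectional tests (Welch t, Mann-Whitney)
and — on the paired subset of patients biopsied at both timepoints — the
paired tests, because overlapping-but-unequal samples per timepoint make
neither view sufficient alone. `association_analysis` fits the five
pre-registered OLS pairs with pairwise deletion, skipping any pair with
fewer than 10 complete observations.

## Known limitations

* The Gaussian two-class model assumes unimodal class colors; real
  counterstain can be multimodal (cytoplasm vs nuclei), which would call
  for a mixture per class.
* No manual correction step after classification is modeled.
* Whole-slide vendor formats (SVS pyramids) are out of scope; one slide =
  one 8-bit RGB raster.
* The ci-from-mIF thresholds make grade deterministic given mIF; observer
  noise in grading is not modeled (threshold jitter would be the natural
  extension).
* Synthetic colors have no partial-volume blending, so classifier
  accuracy on synthetic slides is an upper bound, not an estimate, of
  real-slide accuracy.
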