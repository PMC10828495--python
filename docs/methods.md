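# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying laboratory procedures
leave the computational details open.

## Fibrosis color filtering

PSFG staining colors collagen red and muscle green; empty slide is white
and residual debris light gray.  Classification is per-pixel and two-stage:

1. **Exclusion filter** (plain RGB): a pixel is excluded when
   `min(R,G,B) ≥ 180` and `max−min ≤ 25`.  This captures both white and
   light gray; it runs *first*, so a pale pinkish near-white pixel can never
   be counted as fibrosis.
2. **Red filter** (HSL): hue in the wraparound window [330°, 25°],
   saturation ≥ 0.25, luminance in [0.12, 0.85].  Everything surviving
   exclusion but failing the red filter is green (non-fibrotic) tissue.

The HSL convention is the standard one: L = (max+min)/2,
S = (max−min)/(1−|2L−1|) with S = 0 for achromatic pixels, hue by the
max-channel sector formula, reported in degrees with hue ≡ 0 when S = 0.
The luminance window inside the red filter is configurable (set it to
[0, 1] to disable) because stain intensity varies between laboratories;
every threshold lives in `FilterConfig`.

The fraction is `n_red / (n_red + n_green)`.  Consequences that the tests
exercise: the three class counts partition the image exactly; padding an
image with white border leaves the fraction bit-identical; tiled
(streamed) evaluation equals whole-image evaluation exactly, because only
counts are accumulated.

There are no published numeric thresholds for this kind of in-house filter;
the defaults above were chosen so that plausible PSFG stain colors sit
comfortably inside the windows, and they are validated against the
synthetic generator (recovery error ≤ 0.01 absolute across target fractions
0–0.3).  Real slides differ from the synthetic ones in ways the generator
does not model — stain gradients, chromatic debris, out-of-focus blur,
JPEG artifacts — so passing tests demonstrate correctness of the counting
machinery and self-consistency of the defaults, not robustness to scanner
variation.  On real data the thresholds should be checked against a few
manually annotated fields.

## Morphometry

* **Area** = pixel count × pixel_size².
* **Perimeter**: marching-squares contours simplified by Douglas–Peucker
  (tolerance 1 px) before summing segment lengths.  The raw staircase
  contour overestimates smooth boundaries by ~10%; the simplified polygon is
  within a few percent for both disks and rectangles.  Crack-length
  counting was rejected because the two conventions differ by up to ~8% on
  small objects and the polygon is the better estimator of the underlying
  smooth cell outline.
* **Transverse diameter at the nuclear level**: the chord through the
  supplied nucleus point perpendicular to the cell's major principal axis
  (from the pixel-cloud covariance; ties broken toward the row axis for
  round cells), marched at 0.25 px steps.  When no nucleus point is given
  the centroid is used.  This is a deterministic proxy for what is a manual
  measurement at the microscope.
* Rasterization bounds accuracy: a disk of radius 10 px has a 21-px-wide
  central chord and ~1% excess pixel area; tolerances in the tests reflect
  this, and cells in the synthetic masks are large enough (radius ≳ 15 px
  at the defaults) that discretization error is ≤ 2%.

Coordinates are 0-based row-major; masks and images must share dimensions.
Cell segmentation itself is out of scope — labeled masks are an input
(produced in practice by external deep-learning tools).

## ACE kinetics

The assay's linear phase is fitted by ordinary least squares over the full
trace; r² is the squared Pearson correlation (equivalently 1 − SSres/SStot
for a simple linear fit).  The QC gate is strict: the fit is accepted only
when r² > 0.9, so r² = 0.9 exactly is rejected, and a constant trace
(undefined r²) is rejected with a degenerate flag.  Activity is never
computed from a rejected fit — `ace_activity` raises instead of returning a
number.

An optional longest-linear-window search (maximize window length subject to
r² > 0.9, minimum 10 points by default) is provided for plateaued traces,
but the default is the plain full-trace fit: a trace that plateaus enough
to fail the gate is simply rejected, which matches how such assays are
usually QC'd.  The calibration constant k (intensity change for complete
cleavage of 1 pmol substrate) is an instrument-determined input, never
estimated.

## Derived physiology

All formulas are fixed-unit (mm, µL, m/s, µM, mL, mg, cm, BPM) with the
single conversion µL→mL inside cardiac output.  Stroke volume is linear in
the two volumes, so the SV of group means equals the group mean of
per-animal SVs — group-mean SV/CO table cells are therefore exactly
reproducible from published group means, while FS, EF and E/e′ are ratios
and are not (the mean of ratios is not the ratio of means).  The tests
assert exactness only for the linear cases.

Peptide average mass uses standard average residue masses plus one water;
the C-terminal amide flag applies the −0.98 g/mol OH→NH₂ shift.  Average
(not monoisotopic) masses are used because synthesis reports quote average
molecular weight.

Comparisons against printed integers use round-half-away-from-zero at the
printed precision; the library itself always returns full precision.

## qPCR quantification

The standard curve is an OLS fit of mean Cq against log10(quantity) over a
dilution series (≥ 3 points; a non-negative slope is an error).  SQ is read
off the curve as 10^((Cq−intercept)/slope); efficiency = 10^(−1/slope) − 1
is reported but not used to re-correct SQ, since the interpolation already
embodies it.  Fold change by 2^−ΔΔCq assumes ~100% efficiency, as the
method requires.  Technical replicates are collapsed by arithmetic mean
with a QC flag (not dropped) when the spread exceeds 0.5 cycles — a common
laboratory rule; the threshold is an argument.  When two housekeeping
genes are carried they are combined by the geometric mean of their SQs.
Output is relative and unitless; no calibrator-sample scaling is applied.

## Statistics layer

* **Holm–Šidák**: step-down, adjusted₍ᵢ₎ = max over j ≤ i of
  1 − (1−p₍ⱼ₎)^(m−j+1), clipped at 1, returned in input order.  The
  implementation wraps the standard multiple-testing routine and is tested
  against a literal transcription of the definition.
* **One-way ANOVA + post hoc**: omnibus F, then pairwise t statistics on
  the pooled ANOVA error (df = N−k), Holm–Šidák-adjusted over the chosen
  family — all pairwise arms by default, matching designs that report
  sham-vs-disease, disease-vs-treated and dose-vs-dose contrasts within a
  timepoint; a vs-control family is available.  Under a 4-arm null at
  n = 8 the simulated family-wise error is slightly below the nominal 0.05
  (Holm–Šidák is conservative under the positive dependence of shared-
  control contrasts), within Monte-Carlo error at 2000 replicates.
* **Repeated-measures two-way ANOVA**: split-plot (mixed) ANOVA with arm as
  the between factor and the two follow-up timepoints within, computed via
  pingouin; within-arm time contrasts are paired t-tests Holm–Šidák-
  adjusted over the arms.  Animals missing a timepoint are excluded
  (complete-case) with a warning — this mirrors reporting n = 7 throughout
  for an arm that lost one animal mid-study — and an arm reduced below
  n = 2 is an error.
* **Fisher's exact r×c**: Freeman–Halton, two-sided by probability
  ordering — the p-value sums the probabilities of all fixed-margin tables
  no more probable than the observed one, enumerated recursively with an
  enumeration budget of 10⁷ tables.  Above the budget a Monte-Carlo
  estimate (default 10⁵ sampled tables, with its standard error) is
  available.  All-zero rows/columns are dropped first.  The 2×2 case is
  tested against the hypergeometric closed form and scipy.
* Two-sided tests and α = 0.05 throughout.  Near-threshold p-values are
  reported verbatim, never promoted.

## Synthetic generators

All generators take one explicit seed (`numpy.random.default_rng`), no
global state, and are bit-reproducible.

* **Slides**: tissue is a centered rectangle whose white frame supplies the
  requested background fraction; gray debris speckles are stamped inside it
  and removed from the tissue mask; fibrosis is laid down as disk-shaped
  blob clusters (radius ~6 px by default, giving the spatial structure that
  tiled evaluation needs) and then trimmed or extended pixelwise so the
  true fraction hits the target to within one pixel — ground truth is exact
  by construction.  Stain colors are painted from HSL centers (red
  0°/0.75/0.45, green 120°/0.5/0.4) with Gaussian RGB jitter (SD 6),
  small enough that no pixel crosses the default classifier boundary; a
  post-generation assertion enforces this.
* **Cohorts**: the default effect sizes are the reference group means and
  SEMs of the echocardiographic panel at both follow-ups (SD = SEM·√8),
  arm sizes 8/8/8/7 after the default one-animal dropout in the high-dose
  arm; within-animal values at the two timepoints are bivariate normal with
  correlation 0.6 (a typical test-retest correlation for echo parameters;
  configurable).  Parameters are sampled independently of each other, so
  cross-parameter correlations of real animals are *not* emulated.
* **Cell masks**: non-overlapping disks with areas ~N(350, 60²) µm² at
  0.5 µm/px (realistic rat cardiomyocyte cross-sections), truth analytic.
  Real cardiomyocytes are neither circular nor convex in general; the disks
  validate the measurement code, not segmentation robustness.
* **qPCR plates**: dilution series with ideal spacing −1/log10(1+E) cycles
  per decade and a treated/control Cq offset encoding the requested fold
  change; Gaussian Cq noise.

## Pipeline

One YAML config, one master seed; per-stage child seeds are spawned from a
`SeedSequence`, so runs are byte-identical given the same config and seed.
Stage failures abort with the failing stage named; artifacts written before
the failure are retained.  The manifest records the package version, seed,
config hash and artifact list.

## Problem sizes in the tests and acceptance script

Unit tests run the image code at 128–256 px, the acceptance sweep at
1024×1024 (15 images); the null-FWER simulation uses 2000 replicates, the
repeated-measures uniformity check 300 replicates, and qPCR/ACE recovery
50 replicates each.  These sizes give Monte-Carlo errors comfortably below
the tolerances asserted while keeping the default suite around half a
minute.

## Known limitations

* The color filter defaults are validated only against the synthetic stain
  model; real scanner color profiles require a one-off threshold check.
* Perimeter and transverse diameter carry a few percent of rasterization
  error on small objects.
* The mixed ANOVA assumes the standard split-plot model (with only two
  within levels, sphericity is not an issue); no mixed-effects or survival
  machinery is provided.
* Exact Fisher enumeration grows combinatorially; large tables must use the
  Monte-Carlo route.
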