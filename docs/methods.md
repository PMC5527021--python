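# Methods

`mimevolve` implements the three-stage analysis used to document
micro-evolution of a female-limited Batesian mimicry trait — the relative
size of the hind-wing white spot in mimetic *Papilio polytes* females —
around the arrival of a new model species (*Pachliopta aristolochiae*,
which settled Okinawa in 1993).  Every stage can be driven by synthetic
inputs with exact ground truth, so the whole pipeline is testable without
access to the original specimens.

## 1. Image quantification (`spotquant`)

**Procedure.** The image is rotated about landmark 1 (intersection of the
second anterior cubitus vein and the cell border) so that the axis to
landmark 2 (tip of the tail vein) points straight down; the analysis region
is the wing area at or below the horizontal line through landmark 1
(inclusive of its row; coordinates are 0-based, origin top-left,
x = column).  Relative spot size is spot pixel count divided by the
analysis-region pixel count; the region includes the spot pixels
themselves.

**Segmentation.** Two rules:

* *distinct* — a pixel is white when its grey value (standard luma,
  0.299 R + 0.587 G + 0.114 B) exceeds `white_cut` (default 128) and its
  R/G/B spread is below `achromatic_cut` (default 40); red when R exceeds
  both G and B by `red_margin` (default 50).  The red rule is a design
  choice of this package: red-dominance with a configurable margin.
* *fused* — for specimens whose white and red spots adjoin, the white
  threshold is the mean minus one sample standard deviation (n−1
  denominator) of the brightness at 30 points sampled from the clearly
  white area; pixels strictly brighter than the threshold are white.
  When explicit points are not supplied they are drawn uniformly (seeded)
  from the distinct-rule white mask eroded by two pixels — the erosion
  keeps resampling-diluted boundary pixels out of the "clearly white"
  sample.  The degenerate SD = 0 case (all samples identical) is kept
  as-is and warned about: the strict inequality then excludes pixels at
  exactly the sampled brightness.

**Numerical choices.** Alignment uses bilinear interpolation for intensity
and nearest-neighbour for masks, padding the canvas with the estimated
(median border) background colour so no wing pixel is lost; the wing
outline is recovered automatically as the connected non-background
component containing the landmark midpoint, with an externally supplied
mask able to override it.  Areas are computed after alignment.

**Known limitation.** On re-rotated rasters, bilinear blending creates a
one-pixel rim of intermediate brightness around the white spot; the two
segmentation rules split that rim differently (an effect of roughly half
the spot perimeter, a few percent of its area).  Rule-agreement checks are
therefore run on images already in the aligned orientation — both rules
applied to the same raster — which is also how the two identification
methods were compared in practice.  Measured area *fractions* are
insensitive to this (mean absolute error stays well below 0.005 at any
rotation).

## 2. Heritability (`heritability`)

Only females express the trait, so heritability comes from second-degree
relatives: the Pearson correlation r among grandmother–granddaughter pairs
is quadrupled, h² (or H²) = 4r, because autosomal grandmother–granddaughter
relatedness is 1/4.  Maternal-lineage pairs (mother's mother) estimate
broad-sense H²; paternal-lineage pairs (father's mother) narrow-sense h².
Estimates are deliberately not truncated to [0, 1].

* The point estimate uses the correlation; the P-value is the slope F-test
  of the least-squares regression of granddaughter on grandmother values
  (computed as the equivalent two-sided slope t-test).
* 95% CIs are percentile bootstrap (2.5/97.5) over 10 000 resamples of
  grandmother clusters: all pairs sharing a grandmother enter or leave a
  resample together, respecting their non-independence.  The resampling
  scheme is frozen (one `default_rng(seed)`, per replicate a uniform draw
  of cluster indices, clusters concatenated in sampled order; degenerate
  replicates dropped via `nanpercentile`) so it can be verified
  bit-for-bit against an independently coded loop.
* If the trait is W-linked (female-specific chromosome, mother-to-daughter)
  or organelle-encoded, maternal-line relatedness is 1: the maternal 4r
  estimate is inflated fourfold (often exceeding 1) and the paternal
  estimate collapses to ~0.  `apply_inheritance_correction` divides the
  estimate and CI by 4 under that assumption.
* Cross-trait genetic correlation is the arithmetic mean of the two one-way
  cross correlations (grandmother white ↔ granddaughter red and vice
  versa); the combination rule is a package choice since only a single
  summary value is conventionally reported.  Its P-value is the pair-level
  t-test of the mean correlation, matching the regression F-test used for
  the heritabilities.

The cluster bootstrap is approximate: in simulation (autosomal truth,
h² = 0.5, ~190 pairs per design) the 95% CI covers the truth in 90–99% of
replicates, not exactly 95%.

## 3. Temporal trends (`trends`)

The specimen series is split at the model's arrival: era regressions of
white spot fraction on collection year are ordinary least squares over
closed year windows (defaults: series start–1991 and 1994–series end; the
1992–1993 arrival gap belongs to neither era and is reported as
unassigned).  Variance change uses a two-sided F-test oriented
var(before)/var(after), df (n_before−1, n_after−1).  Normality is checked
with a one-sample Kolmogorov–Smirnov test against a normal with the
sample's own mean and SD; because the parameters are estimated, the
asymptotic p-value is anticonservative and the result is flagged
approximate rather than silently replaced by a corrected test.  Island
groups are compared with the pooled-variance Student's t-test.  The model
species' range is summarised as mean ± 2 SD and reported with the fraction
of mimic records falling inside it per era.

## 4. Synthetic data (`synthetic`)

**Wings.** The wing is an ellipse on a saturated uniform background; the
pipeline needs only areas, landmarks and brightness classes, so minimal
geometry with exact ground truth beats realistic venation.  All masks are
analytic (pixel-centre membership after inverse rotation), so ground-truth
fractions are exact on the returned rasters and rotation perturbs areas
only through rasterisation.  The white-spot radius is calibrated by pixel
counting to hit the requested analysis-region fraction; an unattainable
request raises an error naming the maximum attainable fraction.  Red spots
sit on a ring around the white spot — separated by ≥ 1 background pixel
(distinct) or tangent to it (fused).

The white spot is rendered as a two-tone texture (base 246, speckle 254 on
25% of pixels) rather than with additive Gaussian noise.  The mean − SD
rule presumes the white-area brightness histogram has its mass at the
lower edge with a brighter tail; under symmetric noise the rule would
exclude ~16% of white pixels no matter how small the noise, which
contradicts how well the rule reproduces visual counts on real
photographs.  The two-tone texture places mean − SD strictly below the
minimum white level whenever the sampled bright fraction is < 1/2
(probability ≳ 0.999 with 30 samples), reproducing the regime in which the
rule is used.  Gaussian brightness noise (default SD 4 grey levels) is
applied to the wing body and red spots.

**Pedigrees.** Sixteen wild-mated founder females (the default; any number
≥ 2) seed three laboratory generations.  Pairing within a generation is
random and monogamous under the rule that mates share neither parents nor
grandparents; founder females, and their unobserved wild mates, are
assumed unrelated, and wild-male genetic values are drawn from the founder
distribution in autosomal mode.  Transmission: autosomal — midparent plus
Mendelian segregation noise N(0, V_A/2), which keeps the additive variance
stationary; W-linked — exact maternal copy, males carry nothing; organelle
— exact maternal copy to all offspring, with only females expressing it.
Mutation is not modelled (three-generation timescale).  Female phenotype =
trait mean + genetic value + N(0, V_E); males never receive phenotypes.  A
second, genetically independent trait (the red spot) with the same
variance components provides a pleiotropy-free null for the cross-trait
correlation.  Brood size is a free knob (default 6; recovery simulations
use 8–10) because no brood sizes are anchored anywhere.

With only 16 founder lineages, the realised genetic variance of a single
design wanders around its expectation (relative SD ≈ √(2/15) ≈ 37%), so a
single-design maternal estimate under W-linkage is itself noisy;
parameter-recovery checks therefore use 64-founder designs (≥ 2000 pairs),
where the estimate concentrates.  This is a property of the breeding
design, not of the estimator.

**Temporal series.** Specimens are drawn year by year around a continuous
piecewise-linear mean with a breakpoint (default 1993), era-specific
residual SDs, and negative draws truncated at zero (spotless females
exist).  Default conditions emulate the five-decade island series in
fraction units: intercept 0.055 at the breakpoint, slopes −0.00005 and
+0.00045 per year (−0.005 / +0.045 percentage points per year), and
residual SDs 0.0124 / 0.0165.  The SDs are derived from the published
signal-to-noise regime: with the historical sampling design (~36 sparse
museum specimens before the breakpoint, ~331 after, dominated by recent
collections), they put the post-era slope test at t ≈ 2.2 and the variance
ratio at F ≈ 0.56.  At that regime a single realisation recovers both
slopes within ~2 standard errors but is not guaranteed a significant
post-era P — the honest sampling behaviour of a marginal-power design.
What passing tests show is that the estimators recover known truth under
these idealised conditions (normal residuals, exact breakpoint, no
measurement error); they cannot show anything about photographic artefacts,
curator selection biases, or island-level heterogeneity in real series.

## Problem sizes used

Default test and demo sizes are chosen to keep everything desk-scale: 20
wings of 256×320 px for the image stage; 64-founder × 8-offspring designs
(~2000–5000 pairs) for estimator recovery; 10 000 bootstrap replicates for
reported CIs (600–2000 inside resampling-heavy test loops); 2000
replicates for type-I-error checks.
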