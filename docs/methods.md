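# Methods

## The running-line smoother and its effective degrees of freedom

A trajectory fit at evaluation age x is a weighted least-squares straight
line over a neighborhood of observations, evaluated at x.  The neighborhood
is the fraction `span` of the sample nearest in age; weights are tricube in
distance scaled by the bandwidth.  Two implementation choices matter:

* **Fractional bandwidth.**  The bandwidth is the linearly interpolated
  distance to the (span·n)-th nearest neighbor, so the smoother operator —
  and hence its trace — varies continuously with span.  This is what makes
  fractional df targets such as 2.2 attainable: `span_for_df` bisects on
  span (trace is monotone decreasing in span) to within 0.01 df.  Spans
  above 1 are allowed and inflate the bandwidth beyond the data range; in
  that limit the tricube weights flatten and the fit tends to the global
  straight line (trace → 2).  df = 1 (constant) and df = 2 (ordinary least
  squares line) are handled parametrically, not through the kernel.
* **Degenerate neighborhoods.**  Ties in age are harmless (weights depend
  only on distance); a neighborhood whose ages are all identical falls back
  to a weighted mean, and a bandwidth that would leave fewer than two
  points with positive weight is widened to the two nearest points.

Because every fitted value is a linear functional of the data, local fits
reproduce affine functions of age exactly — a property the tests check both
directly and via an independent brute-force per-row weighted-least-squares
construction.

## Parsimony df selection

The candidate ladder is 1, 2, 2.2, 2.4, … up to df_max = 5.0 (configurable).
The walk starts at the constant fit; each rung is tested against the
immediately preceding rung with the approximate nested F test

    F = [(RSS_small − RSS_big)/(df_big − df_small)] / [RSS_big/(n − df_big)],

p from F(df_big − df_small, n − df_big), and stops at the first
non-rejection at α = .05.  Negative numerators (possible because smoothers
do not minimize RSS) clamp to F = 0 — non-rejection is the conservative
outcome — and a fit whose residual is already at machine precision
terminates the walk, so noise-free data cannot produce spurious rejections
out of floating-point dust.  Steps compare to the predecessor rather than
to every smaller rung; df_max = 5 reflects that developmental thickness
trajectories in this age range are at most cubic-like.  The 1-vs-2 step
reduces exactly to the classical OLS slope F test, which is what makes its
type-I error exactly nominal (the first acceptance quantity).

## The vertexwise trajectory-difference test

At each vertex, three parsimony selections are run: pooled sample, group 1,
group 2.  The F comparison of one shared curve versus two group curves is
then evaluated **at a common flexibility**: the pooled walk's chosen df,
raised when *both* group walks independently selected something wigglier.
This choice is deliberate and load-bearing:

* Using each fit at its own selected df (the naive reading) is badly
  anti-conservative.  When the truth is curved but weakly sloped, the
  pooled walk can stall at low df while one group's walk — by chance —
  escapes to a wiggly fit; the shared curvature the pooled model cannot
  express, or the single group's overfit, then masquerades as a group
  difference.  In simulation this inflated the null tail several-fold and
  broke FDR control.
* Raising the common df on the say-so of a *single* group re-imports the
  overfit bias.  Requiring agreement of both groups (or the pooled sample)
  keeps the far tail at its nominal level while retaining power for shape
  differences that cancel in the pooled average.  Measured on 20 000 null
  fits at study scale: P(p < .05) = 0.038, P(p < 10⁻⁴) = 1.0 × 10⁻⁴.

Per-group selected dfs are still reported per vertex; only the df at which
the F is evaluated is common.  If Δdf = df_g1 + df_g2 − df_pooled is not
positive the vertex is flagged degenerate with p = 1.  The signed companion
statistic is sign(mean fitted difference on a 50-point age grid) · √F,
oriented ADHD − control by default.

Thickness is residualized on sex, handedness and the scanner slice dummy
before fitting (disable with `residualize=False`); the four projected-out
dimensions are charged to the residual degrees of freedom.  Subjects at or
above 14 years are excluded before trajectory fitting because the running
line is unstable where the age distribution thins; the filter is strict
(`age < 14`) and errors if any group falls below `min_group_n`.

FDR is Benjamini–Hochberg, applied jointly across both hemispheres (the
conservative choice; per-hemisphere control is a flag).  The per-hemisphere
critical statistic reported is the smallest |signed statistic| among that
hemisphere's rejected vertices — the realized significance threshold — and
NaN when nothing was rejected.  An optional uncorrected threshold column
(e.g. p < 10⁻⁴) supports exploratory reporting but never drives rejection.

## Volumetric GLMs and IQ moderation

All volumetric models are ordinary least squares with treatment coding
(reference: control, male, right-handed, thinner-slice dummy 0) and
listwise deletion.  Dummies for factor levels absent from the estimation
sample are dropped, as a formula interface would only code observed levels;
genuinely collinear designs raise an error naming the aliased terms.
Adjusted group means are model predictions at the sample means of the
covariates.  Ventricle volumes are analyzed on the natural-log scale (they
are right-skewed), with exponentiated adjusted means as a companion —
back-transformed means estimate the distribution median, which the tests
verify on log-normal data.  The FA model omits the slice dummy (FA
acquisition does not vary by slice protocol).

Dimensional IQ models add an IQ main effect and an IQ × diagnosis
interaction to the base model and are run after removing upper-tail IQ
outliers by the 1.5-IQR rule (only the upper tail: very high IQ is sparsely
sampled and leverages the continuous-IQ fits; the lower tail is already
truncated by the IQ ≥ 70 inclusion rule).  The median split computes the
whole-sample median before any exclusions and assigns the median subject to
the below-median subgroup, so a subject at the median value is "below" and
the next integer up is "above".  Group correlations are zero-order Pearson
within diagnosis (what raw scatterplots show); a covariate-partialled
variant sits behind a flag.

Small derived quantities: percent reduction 100·(m_c − m_a)/m_c (scale
invariant); the cortical-GM proxy thickness(mm) × area(cm²) × 0.1 → ml; the
corrected medication exposure months_used/(age_months − 60), where 60
months is the youngest age at which stimulants are prescribed.

## The synthetic cohort

The generator emulates the joint statistical structure the analyses assume,
not images.  Design: four cells (diagnosis × IQ subgroup) of equal size;
ages uniform on [6, 15) identically across cells; sex (14 % F), handedness
(84/13/3 % R/L/A) and the slice dummy (31.5 %) share one marginal across
cells, so cells are matched on everything except IQ by construction.  IQ is
truncated normal at the inclusion floor of 70; by default both cells of a
diagnosis share the group-level distribution (control 106.0/12.9, ADHD
101.6/16.0) and IQ subgroups arise from the realized median split, exactly
as in the analysis — the realized subgroup moments then land near the
usual below/above-median cell values on their own.  Per-cell IQ
distributions remain configurable.

Volumetric measures are drawn per cell at configured means/SDs.  Three
pooled within-diagnosis correlations are pinned (controls: IQ–gray-matter
r = .31 and IQ–FA r = .38; ADHD: IQ–thickness r = −.25, IQ–GM and IQ–FA 0).
Because cell means already carry part of a pooled correlation, the
generator solves for the *within-cell* correlation that makes the pooled
value hit its target (a pooled covariance is the mean within-cell
covariance plus the covariance of cell means).  Ventricles are
moment-matched log-normal.  Unpinned measures get independent within-cell
noise.

Thickness maps: every subject's vertex profile is the cell trajectory at
their age plus spatially smoothed Gaussian noise.  Trajectory defaults —
baseline 3.36 mm, amplitude 0.25 mm, peak 7.5 y, width 2 y, post-peak
decline 0.04 mm/y, residual SD 0.1 mm — were chosen so the generated data
reproduce three documented features of developmental thickness data: a
grand mean near 3.34 mm, a statistically detectable thinning with age below
14 in both groups at these sample sizes, and a typical-development peak
early in the school-age window so that controls look stable-to-declining
while a 1.5-year delayed group peaks visibly inside the window.  The delay
is applied at a 30-vertex contiguous cluster (grown breadth-first on the
left hemisphere; the true spatial extent of such regions is a free
parameter), and the above-median-IQ ADHD cell gets a uniform −0.05 mm
offset — producing delayed-maturation and parallel-but-thinner phenotypes
respectively.  Surface smoothing is a per-vertex-normalized Gaussian kernel
in graph (hop) distance with FWHM 2 edges — on a toy mesh a physical
20-mm FWHM has no meaning, so the kernel preserves the role (spatial
correlation with a half-max radius of fwhm/2) rather than the physical
scale — and the smoothed noise is rescaled per vertex so the marginal SD
stays at the nominal value while correlations are kept.

The mesh is a pair of sphere-like convex-hull triangulations of seeded
rotated Fibonacci point sets (exact icosahedra at 12 vertices per
hemisphere): closed surfaces with mean degree near 6 and no edges between
hemispheres.  It stands in for a cortical surface topologically, not
geometrically.

What passing tests do *not* show about real data: the generator's noise is
Gaussian, stationary across vertices and independent across subjects; real
thickness maps have heavier tails, spatially varying variance, and
registration/segmentation artifacts.  Its trajectories are a single
parametric family; real development need not be.  Calibration results here
therefore demonstrate correctness of the procedures under their own
assumptions, not robustness to violations.

## Problem sizes and numerics

Calibration studies use 500 vertices (250 per hemisphere), 45 subjects per
group and 500 replicates for the FDR study, and 5000 replicates for the
ladder-step study — sizes at which the Monte-Carlo error of the reported
rates (≈ 0.003–0.01) is small relative to the quantities themselves and a
full study runs in about a minute on one CPU.  The whole-surface driver
shares each smoother operator across vertices (one matrix product per
ladder rung per subsample), which is why it computes numbers identical to
the scalar per-vertex API — a property the tests assert.  Determinism:
every stage draws from `numpy` Generators seeded from a single global seed
with fixed per-stage offsets; reruns are bit-identical, and `span_for_df`
bisection is deterministic with results cached per (age-vector, target).

## Known limitations

* The trajectory-difference p-values rest on the approximate F reference
  for linear smoothers; they are exact only when all selections land on
  df ≤ 2.  Measured miscalibration at study scale is small (see above) but
  not zero.
* Selection events (`chosen_df`) are reported but their post-selection
  distribution is not propagated into confidence statements.
* The per-hemisphere critical statistic summarizes the rejection boundary;
  it is not a standalone inferential threshold.
* `exclude_iq_outliers` trims only the upper tail by design; data with a
  pathological lower tail would pass through.
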