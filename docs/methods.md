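# Methods

## Data model

A trajectory is an ordered sequence of 2-D positions observed at a fixed
frame interval (default 30 s, the rate at which a slow benthic crawler
covers roughly one body length per frame).  Coordinates are kept in their
native unit — pixels from a digitization, or an arbitrary internal unit
for simulations — with an optional multiplicative conversion on read.
Every downstream metric is unit-covariant, and the three quantities the
group comparisons rest on (straightness index, ζ(q) scaling exponents,
directional entropy) are unit-invariant, so the choice of unit never
affects inference.  Frames must be consecutive: a missing frame is a
data-integrity error, and no interpolation or gap-filling is ever
performed, because a filled gap would silently distort step lengths,
turning angles and the displacement moments alike.

## Kinematics

Mean speed is the arithmetic mean of per-step speeds (step length over
frame interval).  The straightness index with window *w* is net
displacement divided by the summed Euclidean hops between positions *w*
steps apart, using non-overlapping windows anchored at the first
position; a trailing remainder shorter than *w* contributes its own hop.
This convention makes the numerator's endpoints and the denominator's
chain cover exactly the same span, so I_s ≤ 1 holds as an identity rather
than approximately.  Group comparisons are insensitive to the window
choice; the default is 1 step.

Heading angles use the four-quadrant arctangent.  The initial heading is
read from the vector connecting the start to the fifth subsequent
position — the animal is given five frames (over 2 min) to settle after
being placed in the arena — and trajectories shorter than six positions
report a missing initial heading rather than a fallback.  The start index
of that vector is exposed as a parameter (`initial_start`, default 0) for
users who prefer to skip the very first, handling-affected position.

Turning angles are signed differences of successive step headings wrapped
to (−π, π]; an exact reversal maps to +π so that binning is
deterministic.  Steps of zero length (the animal can sit still for a
frame) have no heading; they are skipped and the turning angle is taken
between the surviving flanking steps.  A `min_step` threshold generalises
this to near-zero steps dominated by digitization jitter; it defaults to
0 (only exactly-zero steps are skipped).

## Structure-function scaling

The q-th order moment of the displacement modulus, M(q, τ) =
⟨‖ΔX_τ‖^q⟩, is averaged over **all** ordered position pairs separated by
lag τ (the overlapping time-average), which is the standard
structure-function estimator and extracts the most information from short
paths.  Lags are the unique rounded integers of a log-spaced grid from 1
to ⌊N/4⌋ (12 candidates by default): log-spacing gives equally spaced
points in the log–log regression, and capping τ at a quarter of the step
count keeps at least 3N/4 pairs in every estimate while limiting the
autocorrelation-induced bias of the largest lags.

ζ(q) is the unweighted OLS slope of log M versus log τ for each q in the
default grid {0.5, 1, 1.5, 2, 2.5, 3}.  Moderate orders are used because
high moments are dominated by the few largest displacements of a short
path; weighting per-q regressions by pair counts was considered and not
adopted, since with the τ ≤ N/4 cap the pair counts vary by less than a
factor of 4/3 and the added complexity buys nothing.  Zero moments (an
animal that never moved during some lag) are dropped from that q's
regression with a record; a q with fewer than three surviving lags is
excluded from the summary.

The summary coefficient is the least-squares slope of ζ(q) against q
constrained through the origin, because ζ(0) = 0 is forced by the moment
definition.  Analytic anchors: a constant-velocity path has M(q, τ) =
(vτ)^q exactly, hence ζ(q) = q and slope 1; an uncorrelated Gaussian walk
has ζ(q) = q/2 and slope 0.5.  The finite-path estimator carries a small
downward bias in the Brownian case (the log of a noisy moment estimate
is concave), visible as replicate means near 0.49 rather than 0.500.

Regime classification uses bands of half-width 0.05 around the two
reference slopes: below the Brownian band is subdiffusive, between bands
superdiffusive, and at or above the ballistic band "ballistic" (which
includes marginally ballistic paths).  The bands are a reporting
convention, not part of any test.

## Directional entropy and the Rayleigh test

Turning angles are binned on a fixed grid anchored at −π with width
0.05 rad; since 2π is not a multiple of 0.05 the last of the 126 bins is
narrower.  Bins are half-open on the left, (edge, edge], matching the
angle domain (−π, π], so counts are deterministic.  Entropy is the
plug-in Shannon H = −Σ p̂ᵢ ln p̂ᵢ in nats; no small-sample bias correction
is applied because the statistic of interest is the Shannon H of the
observed bin counts itself, and the control-versus-predator comparison is
invariant to the logarithm base.  Absolute H values do depend on the bin
anchoring and base; between-group contrasts do not, to the extent that
group sample sizes of angles are comparable.

The Rayleigh statistic is z = n·R̄² with R̄ the mean resultant length; the
p-value uses the standard two-term series approximation, clamped to
[0, 1].  A Monte-Carlo p under the fully specified uniform null is
available for very small n.  At the study's control sample size (n = 29)
the series approximation's type-I error is 0.05 to within ±0.01
(checked by simulation in the test suite).

## Group-comparison models

Each animal is one replicate everywhere.  Speed and straightness are
compared by one-way linear models (the F on 1, n−2 df equals the squared
pooled-variance two-sample t).  The ζ(q) summary slope shows strongly
unequal group variances by design — the control group spans regimes while
the predator group clusters — so it is compared by a two-group Gaussian
model with a distinct residual variance per group, the analogue of an
identity-by-group variance structure.  Estimation is by maximum
likelihood, not REML, so likelihood-ratio tests across mean structures
are valid: the full model's ML solution is closed-form (group means and
mean squared deviations), the equal-means null is solved by a fixed-point
iteration of inverse-variance weighting (convergence tolerance 1e-12,
typically < 10 iterations), and the treatment effect is the LRT χ² on
1 df.  A Wald χ² is available as an option.  The LRT was verified to
agree with R's `nlme::gls(…, weights = varIdent(form = ~1|group),
method = "ML")` to 1e-8 on a frozen fixture.  AIC counts every estimated
parameter including variances, so the heteroscedastic fit (4 parameters)
and the homoscedastic comparator (3) are directly comparable; Levene's
test (absolute deviations from group means by default) is reported as the
variance diagnostic.

Entropy is modelled as entropy ~ treatment + ζ-slope +
treatment:ζ-slope.  The default report uses sequential (type-I) F tests,
matching the conventional single-ordering ANOVA table layout; marginal
(type-II/III) tests are an option.  One property of the sequential layout
deserves note: the first-position treatment F compares the *unadjusted*
group difference in entropy against the covariate-adjusted residual mean
square.  When entropy is strongly coupled to the diffusion slope — which
is the scientifically expected situation — that ratio is anticonservative
as a test of the treatment effect proper, because chance group imbalance
in the slope propagates into the numerator while the denominator has had
the slope's variance removed.  The covariate-adjusted (type-II) treatment
F does not have this property and is the calibrated choice when the
question is "does treatment affect entropy beyond its effect through the
diffusion slope"; the package's null-calibration checks use it.  No
multiple-testing correction is applied, and a 'day of trial' column, if
present, is accepted and ignored (documented, not modelled).

## Synthetic data

The generator exists so that every stage is testable against known truth;
its defaults emulate the reference experimental design, not any
particular dataset.  Internal length unit: 0.1 cm.  Step scale 36 (one
3.6-cm body length per 30-s frame); arena radius 1500 with trials ending
at the first frame within 100 units (10 cm) of the wall, the final
position clamped radially to the wall in the rare case a drawn step would
overshoot it; trial durations uniform over 16–208 steps (8–104 min).

Individual paths are correlated random walks: gamma-distributed speeds
(shape 4, mean = step scale, CV 0.5 — a plausible spread for a slow
crawler) and von Mises turning angles with per-individual concentration
κ.  The control group draws κ log-uniformly on (0.2, 50), spanning
near-Brownian to near-ballistic movement — heterogeneity between
individuals, not within a path.  The predator group draws κ log-uniformly
on (30, 120) and walks 34% faster; both choices were fixed from the
qualitative contrast they must emulate (homogeneous, fast, near-ballistic
escape) before any downstream testing, and produce group contrasts of the
correct sign though not of matched magnitude.  Pure Brownian, noiseless
ballistic, and Lévy-walk models (power-law run durations, exponent
μ ∈ (1, 3]) are available for the analytic limits and regime-ordering
checks.

What the generator does **not** emulate: digitization noise and pixel
quantisation, wall-following or thigmotaxis, within-individual behavioural
switching, day-of-trial effects, and any light-field heterogeneity of a
real arena.  Passing tests on synthetic data therefore validate the
estimators and the inference machinery under the stated generative
assumptions; they are not evidence about any particular empirical
dataset.

## Problem sizes and determinism

The validation suite uses 200 replicates for the Brownian slope check
(500-step walks), 5000 replicates for Rayleigh calibration at n = 29, 200
simulated studies for direction-of-effects recovery and 1000 for null
calibration — sizes at which the Monte-Carlo standard errors are several
times smaller than the acceptance bands.  All simulation is driven by
explicit seeds (numpy `default_rng`; study-level seeds spawn per-animal
streams), so a fixed seed yields a bit-identical dataset and a
byte-identical analysis report.

## Known limitations

Step-length distribution fitting (Lévy-exponent MLE) is deliberately
absent: paths of ≲ 200 steps cannot support it.  The inference module
handles exactly two treatment groups; the GLS is the two-group closed
form, not general mixed-model machinery.  Entropy values are
bin-anchoring-dependent in absolute terms.  The structure-function slope
estimator is biased slightly downward for short uncorrelated paths (see
above); comparisons between groups of similar path lengths are
unaffected, but absolute regime classification near a band edge should
be read with that bias in mind.
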