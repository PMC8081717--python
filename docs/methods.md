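# Methods

`zonemet` analyses zoned multi-environment trials (MET) — coordinated
variety trials of the same genotypes across locations stratified into
agro-ecological zones — and projects genotype performance, with honest
uncertainty, onto *new* locations that are characterised only by
environmental covariates (soil clay content, pH, humus).

## The two-stage, fully-efficient analysis

Stage I analyses each trial (location) separately with the linear mixed
model

    y_ikl = mu_i + r_k + b_kl + e_ikl,

genotype cell means `mu_i` fixed, complete replicates `r_k` and
incomplete blocks `b_kl` (alpha-design, blocks nested in replicates)
random, homogeneous plot error, all variances by REML.  The genotype
adjusted means (BLUEs) `mu_hat_j` of trial `j` are forwarded together
with their full variance–covariance matrix `R_j = var(mu_hat_j)` from
the inverse of the trial's mixed-model equations.  Stage II stacks the
means location-major and treats

    var(e) = R = diag(R_1, ..., R_J)

as *known*.  Forwarding the complete `R_j` (not just standard errors)
is what makes the stage-wise analysis fully efficient: on balanced data
it reproduces a single-stage analysis of the plot data, a property the
test suite asserts directly (two-stage vs. plot-level predictions agree
to 1% with small plot noise).

### Known limitation: plug-in R

`R_j` uses the trial's estimated variance components.  With very small
trials (e.g. 10 genotypes in two replicates) this plug-in
underestimates the pairwise-difference error variance by a few percent,
and the stage-II genotype-by-location variance absorbs the difference
(we measured roughly +300 to +400 (g/m²)² under such conditions).  The
effect shrinks with trial size and is a property of every two-stage
pipeline, not of this implementation; the engine-level recovery
experiment (below) therefore generates data at the adjusted-means level
with a known R, while the coverage experiment runs the full pipeline,
where the slight variance inflation is immaterial for interval
calibration at 20 locations per zone.

## Stage-II model catalog

Fourteen models are available, all special cases of `y = Xβ + Zu + e`.
The FG family treats genotype, genotype×zone (and in FGI1–FGI3 their
covariate regressions) as fixed; the RG family treats them as random,
which lets BLUP borrow strength across zones.  RC1–RC3 replace scalar
genotype terms by random coefficient triplets — intercept, linear and
quadratic response to the scaled covariate — with an **unstructured**
3×3 covariance per subject.  The free intercept–slope covariance is
essential: it makes predictions invariant under any affine rescaling of
the covariate.  A diagonal restriction (`rc_structure="diag3"`) is
provided purely to demonstrate that scale invariance survives but
translation invariance fails; both behaviours are asserted in the
tests.

Location and genotype×location effects are zone-heterogeneous
(`⊕_m σ²_m I`) in all models except FG2/RG2, which use a single
homogeneous variance.

## Covariate handling

Covariates are location-specific constants.  The conventional clay
transform `(clay − 40)/10` is the default; `standardise` freezes the
mean/sd of the *tested* locations so new locations are mapped with the
same statistics.  Covariate screening extends the fixed-genotype
baseline with linear + quadratic terms per candidate and applies
marginal Wald tests, quadratic first, with polynomial hierarchy (a kept
quadratic keeps its linear term; linear terms are tested only after
non-significant quadratics are dropped and the model refitted).
Denominator degrees of freedom use a containment-style approximation
(J minus the rank of the location-level fixed design); a large-sample
chi-square option exists.  Kenward–Roger corrections are not
implemented — screening at J around 20–30 locations is the use case,
and the test suite shows the containment F-test holds its size there,
while at very small J (≈8 per zone) boundary estimates of the location
variance make any plug-in test anticonservative.

## Estimation

REML on the transformed scale: `log σ²` for scalar components and a
log-Cholesky factor for unstructured 3×3 blocks, so every parameter
vector yields a PSD covariance.  The deviance is
`log|V| + log|X'V⁻¹X| + y'Py` with an orthonormal basis for the column
space of X (the value is therefore defined up to a constant per fixed
parameterisation; only differences on identical data are meaningful).
Optimisation runs L-BFGS-B with *analytic* gradients
(`tr(P ∂V) − y'P ∂V P y`, cheap via cached per-component Gram matrices)
followed by a damped average-information (AI) Newton refinement.  The
AI polish matters: random-coefficient likelihoods have long, curved,
nearly flat valleys where quasi-Newton steps crawl; AI steps restore
quadratic convergence and make affine-invariance hold to ~1e-8 instead
of ~1e-4.  Variances are floored at `exp(−30)` times the response
variance (an effective zero; boundary estimates are flagged), and up to
three jittered restarts are attempted on non-convergence.

The mixed-model equations are solved through V-based identities

    C11 = (X'V⁻¹X)⁻,  C12 = −C11 X'V⁻¹ZG,  C22 = G − GZ'PZG,

which never require `G⁻¹` and coincide with the inverse MME coefficient
matrix when G is nonsingular (asserted in tests).  Rank-deficient fixed
designs (the heavily over-parameterised FGI models use full indicator
coding) are handled with generalised inverses plus estimability checks;
only estimable functions are ever reported.

## Prediction for new locations

For a new location in zone m with scaled covariate x, the target is
`w = K'β + M'u + M0'u0`: K selects the zone's fixed effects (with x
and x² where the model has covariate terms), M the estimable
genotype-level random effects (triplet weights 1, x, x² for RC terms),
and u0 the two unobservable new-location effects — location main effect
and genotype×location interaction — with covariance
`G0 = diag(σ²_l,m, σ²_gl,m)`.  The BLUP of `M0'u0` is zero, so

    SEPV² = var(η̂) + σ²_l,m + σ²_gl,m,
    SEPD² = VDIFF(η̂) + 2 σ²_gl,m,

where `var(η̂)` is the prediction-error variance of `K'β̂ + M'û` from
the MME inverse (it includes the fixed–random error covariance, not the
naive variance of the point predictor).  In a pairwise difference the
location main effect cancels and two independent genotype×location
effects remain — hence the `2σ²_gl`.  Prediction intervals are normal:
`η̂ ± z_{1−α/2}·SEPV` (differences analogously with SEPD).  One reading
of the derivation would additionally put the random-coefficient
variances into the unobservable part; we do not — RC effects are
estimable from the tested locations and their uncertainty enters
through `var(η̂)`, consistent with the conditional-variance argument.

## Cross-validation

Leave-one-location-out: the held-out trial's stage-I adjusted means are
the observed values (genotype comparisons at location level are the
quantity of interest), its covariates are used for prediction, its
yields never enter training.  Accuracy is the MSEP of pairwise genotype
differences over ordered pairs, divided by `J·I·(I−1)` (denominator
adjusted to the terms actually summed when cells are missing).  Folds
whose zone would retain fewer than two training locations are skipped
with a warning; folds where any compared model fails are dropped for
*all* models so MSEPs stay comparable.  Covariate scaling is inherited
from the full-data frozen transform, not recomputed per fold.

## Reporting

Pairwise differences are z-tested (`z = DIFF/SEPD`, two-sided) with
Bonferroni adjustment by the number of pairs `I(I−1)/2` (300 for 25
genotypes).  The compact letter display uses insert-and-absorb: start
with one letter covering all genotypes, split every set containing a
significantly different pair into two sets each excluding one member,
absorb subsets.  The construction is exact — two genotypes share a
letter iff non-significant — and is verified against the full pair list
on every call; beyond 26 letters it refuses and points to the heatmap.

## Synthetic data

The generator emulates the Swedish winter-wheat testing structure:
three zones (default 6 tested locations each, 25 genotypes, two
replicates, alpha-design blocks of five) plus new locations (two North,
two South).  Default truth: intercept 800 g/m², zone effects −80/0/+60,
zone-heterogeneous location variances 25 000/30 000/16 000 and
genotype×location variances 580/1150/1050 (g/m²)² (chosen to mirror the
magnitudes reported for the 2016 Swedish series), genotype 600,
genotype×zone 65, replicate 400, block 300, plot error 2500.  Soil
covariates default to clay ~ U(10, 70) %, pH ~ N(6.5, 0.5), humus ~
lognormal(0.9, 0.35) — plausible Swedish topsoil ranges; real
covariate distributions are not published, so these are explicitly
arbitrary.  The genotype and genotype×zone terms can instead be drawn
as random-coefficient polynomials with user-supplied PSD 3×3
covariances.  Random draws come from named seed-derived substreams
(covariates, location, genotype, genotype×zone, genotype×location,
plot terms, then the new-location streams) so partial simulations are
reproducible and byte-identical across runs.  The alpha-design is a
random resolvable blocking (permute, then chunk), not an optimised
alpha-lattice — block variance structure is what downstream methods
consume; design optimality is out of scope.  Static covariates only; no
weather series.  Passing tests on these data show the machinery is
correct under the stated model, not that real MET data meet its
assumptions (no spatial trend, no year effects, normal errors).

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so the full suite
completes in minutes: recovery uses 3 zones × 20 locations × 10
genotypes over 50 seeds at the adjusted-means level; coverage uses nine
full-pipeline datasets of the same size with twelve new locations each
(1080 interval checks); the cross-validation ranking uses 25 seeds of a
15-location, 6-genotype MET; the affine-invariance check fits RC2 four
times on an 18-location MET.  Published summary tables of the 2016
Swedish series (average SEPV/SEPD per new location, MSEP ranking) are
bundled for context and internal-consistency checks; its plot-level
data are not publicly deposited, so those numbers are not re-derivable
from raw data here.
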