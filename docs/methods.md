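# Methods

This document records the statistical models, the assumptions behind
them, how the synthetic generators map onto those models, and the known
numerical limitations. Nothing here asserts empirical results; every
number the package reports is computed at run time from data it is
given or data it simulates.

## 1. Ancestral range reconstruction

### Index points

A species range polygon is summarised by 12 boundary points:

- the 4 latitude/longitude extrema. When an extremum is attained along
  an edge rather than at a vertex, the point used is the midpoint of
  the cut line (the centroid of the boundary segment attaining the
  extremum).
- 8 "outermost crossing" points: rays from the polygon's bounding-box
  centre along the 4 axis midlines and the 4 bounding-box diagonal
  directions (slopes proportional to the box half-extents). Each ray's
  outermost intersection with the boundary is kept.

Geometry is planar in degrees. This is a deliberate small-extent
approximation: all ranges handled here sit within the neotropics, far
from the poles and the antimeridian. Polygons spanning more than 180°
of longitude are rejected.

### Spherical embedding

Before reconstruction each index point is embedded on the unit sphere,
(lon, lat) → (cos lat · cos lon, cos lat · sin lon, sin lat), so that
Brownian motion operates on 3-D coordinates without longitude wrap
artefacts. Posterior draws are renormalised to the sphere and mapped
back to (lon, lat).

### Brownian-motion MCMC

Each of the 12 index points evolves independently under Brownian motion
on the phylogeny. Internal-node states are sampled by
Metropolis–Hastings:

- independent Gaussian proposals per node coordinate; a log-normal
  proposal on the rate σ² with an (improper) uniform prior on log σ²;
- step sizes adapted only during burn-in, targeting 30–36% acceptance,
  then frozen;
- defaults: 10⁶ generations, 10⁵ burn-in, thinning 10⁴ → 90 retained
  samples;
- the sum of squared displacements is maintained incrementally, so a
  generation costs O(degree of the updated node), not O(tree).

With σ² fixed, the joint BM density is Gaussian with precision
proportional to the graph Laplacian of the tree (edge weights 1/branch
length), which yields the closed-form conditional
x_I | x_T ~ N(−L_II⁻¹ L_IT x_T, σ² L_II⁻¹) used as the test oracle.
The sampler and the oracle share no code.

### Credible ranges and overlap

Per node, the point-estimate polygon connects the 12 per-point medians;
minimum/maximum-extent polygons take the 5th/95th percentiles of each
point's signed radial excursion about its median. Polygon assembly
sorts points by angle about their centroid. Percent overlap between
two polygons is 100 · area(A ∩ B) / min(area A, area B); the sympatry
call compares the median of draw-wise matched overlaps against a
threshold fraction (default 0.25) of the smaller range.

## 2. Display divergence

### Metrics and summaries

Roll-snap speed is snaps / duration (an n/T convention; an optional
(n−1)/T fencepost convention is provided), length is the snap count.
Individuals are summarised by mean speed, mean length, and the display
count as a regression weight.

### Species comparison

A random-intercept linear mixed model (REML) with species as fixed
effect and individual as grouping factor is fitted at the display
level — one row per display. Fitting one row per individual leaves the
random intercept unidentified and is anticonservative. The species
test is a Wald F with containment denominator degrees of freedom
(number of groups minus number of fixed-effect columns). Post-hoc
pairwise contrasts of estimated marginal means are Benjamini–Hochberg
adjusted and compressed into letter groups.

### Upper-bound quantile scan

Weighted quantile regression of individual mean speed on mean length is
solved exactly as a linear program (HiGHS) on the check loss. Standard
errors come from a pair bootstrap over individuals (default B = 2000)
or a Hall–Sheather iid sparsity estimate. The scan fits τ =
0.1, …, 0.9, BH-adjusts the slope p-values, and reports the constraint
extent: the smallest τ of the contiguous run of significantly negative
slopes ending at τ = 0.9 (None when τ = 0.9 itself is not
significant). Slope equivalence between two species at one τ is a
pooled interaction F(1, nₐ + n_b − 4). The threshold contrast tests a
drop in mean length above a speed cutoff with a mixed model on the
indicator.

The extent is a consistent estimator of a generative onset quantile
q_u only when the bound is nearly length-independent at the scale of
the individual-SD spacing between grid quantiles and individual means
are nearly noise-free; the recovery harness operates in that regime.
Under a strongly length-dependent cap the capped region invades all
quantiles at long lengths and the extent collapses toward the bottom
of the grid — a property of the estimand, not an implementation fault.

## 3. Twitch kinetics

### Percent relaxation

Per inter-pulse interval, percent relaxation is the force decay from
the local peak toward the unstimulated baseline, as a percentage of the
decay required to reach baseline. Trains carry 10 pulses; the first 8
enter analysis.

### Frequency response

Mean per-train percent relaxation (technical replicates averaged per
individual × frequency) is fitted with a 4-parameter logistic
R(f) = d + (a − d)/(1 + exp(b(f − c))) by multi-start nonlinear least
squares. The half-relaxation frequency f₅₀ is the inflection c, with a
delta-method SE. Species differences use an extra-sum-of-squares
F(4, n − 8) for whole-curve comparison and a Wald F on the inflection
parameters (pooled residual df) for f₅₀.

Because the response averages all analysed pulses, any within-train
decline (rapid fatigue) pulls the high-frequency mean down; the fitted
f₅₀ of a fatiguing muscle is therefore an operational index of the
averaged response, not the latent no-fatigue inflection. The synthetic
generator anchors its 4PL at pulse 1, so its generative inflection is
not directly comparable to the fitted f₅₀ at high κ.

### Rapid fatigue

Per frequency, pulse-wise means over individuals (replicates averaged
first) give 8 points; the fatigue slope is the OLS slope with
F(1, 6). Species comparison at a shared frequency uses the 2 × 8
pulse-mean interaction F(1, 12). A train whose mean relaxation is
below 10% is flagged fused. The slope-vs-frequency trend is OLS with a
pointwise 95% confidence band; f* is the smallest frequency where the
upper band reaches zero (grid scan refined by root bracketing).

f* carries a deterministic, grid-dependent offset: even noise-free, the
fitted line through a hinge-shaped slope profile crosses zero at a
point set by the frequency grid's placement around the hinge. On a
grid symmetric about the hinge the offset is negligible; on an
asymmetric grid it can be several Hz. The recovery harness uses a
symmetric grid for exactly this reason.

## 4. Synthetic generators

- Ranges: an octagonal template placed near Panama diffuses along the
  four-species phylogeny as Brownian motion of its index points
  (σ² = 10⁻⁴ deg²/unit length by default), giving known ancestral
  polygons for recovery scoring.
- Displays: individual latent mean speeds and lengths are bivariate
  with a per-species triangular upper bound: a hard cap
  min(s₀, mean + σ·Φ⁻¹(q_u) + β_u(L − L̄)) (or a soft shrinkage
  variant). Default species settings mirror study-scale sample sizes
  (34/24/25/76 individuals) and produce an observed golden-collared
  mean display speed near 58.4 Hz; the latent mean is set above the
  observed mean because the cap binds most individuals.
- Twitch: per train, R_k = 4PL(f) − max(0, κ(f − f_c))·(k − 1) + ε,
  clipped at 0, with per-individual random effects, replicates, and
  paired control trains for stability checks. A force-trace
  synthesiser produces raw traces whose per-pulse analysis recovers the
  programmed relaxation sequence within 1%.

All generators are deterministic functions of an integer seed; derived
sub-seeds stay below 2³¹.

## 5. Numerical choices and limitations

- Quantile regression is solved to LP optimality, so fitted losses
  match an exhaustive elemental-line oracle to ~10⁻⁷; coefficients may
  differ at degenerate vertices with equal loss.
- MCMC equality checks are statistical (3 Monte-Carlo SEs with an
  AR(1)-based effective sample size), not exact.
- Mixed models rely on statsmodels REML; near-singular random-effect
  variances are flagged, not silently dropped.
- Planar-degree areas distort with latitude; acceptable for the
  neotropical extents targeted here, wrong near the poles.
- The 4PL fit needs frequencies on both sides of the inflection for a
  well-conditioned c; fits flag f₅₀ extrapolation instead of failing.
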