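# Methods

`nichedyn` implements the gridded-PCA framework for comparing a species'
climatic niche between a native and an invaded range, together with a
regularized maximum-entropy distribution model for reciprocal geographic
projection, and a virtual-species simulator that provides ground truth for
every estimator. This note records the models, the numerical choices, and
what the synthetic validation does and does not demonstrate.

## The niche model

A region's *available climate* is characterised by a background sample
(default 10,000 uniform random points over the valid cells of its bounding
box). Climate variables are screened for collinearity by greedily removing
the later-ordered member of the worst pair until no pair exceeds |Pearson
r| = 0.90 over the background sample (configurable to all cells). A single
PCA is fitted to the *pooled* backgrounds of both regions after
standardizing each variable to zero mean and unit variance over the pooled
sample, so both regions' occurrences live in one climate plane; the first
two components define the niche space, and the grid frame is the pooled
background extent on those axes.

Each region's occupancy is an R × R grid (default R = 100) with

- `o`: Gaussian kernel density of the projected occurrence records,
- `e`: the same for the background points,
- `z = (o/e) / max(o/e)` on cells with `e > 0`, zero elsewhere.

Dividing by `e` corrects for how much of each climate the region offers:
`z` estimates preference, not availability. An uncorrected mode
(`z = o/max o`) is available behind a flag.

**Kernel numerics.** Densities are computed by binning points onto the grid
and convolving with a Gaussian truncated at 4 bandwidths, so cells far from
any data are exactly zero and "support" is well defined. One bandwidth per
axis — Silverman's rule `h = sigma * n^(-1/6)` evaluated on the region's
background scores — smooths *both* densities. This is deliberate: with
separate bandwidths the ratio `o/e` diverges wherever the narrower kernel's
tail decays first, piling spurious occupancy onto the envelope edge;
a shared bandwidth makes the two tails decay at the same rate so the ratio
stays bounded by local data counts. A fixed bandwidth can be supplied to
override the rule.

**Climate envelopes.** The 100% envelope of a region is every cell with
`e > 0`; the 75% envelope keeps cells whose background density exceeds the
25th percentile of its positive values — the densest three quarters of the
available climate, used to restrict comparisons to analogue conditions.

## Overlap, similarity, and the S/U/E decomposition

Schoener's D is `1 − 0.5 * Σ|p1 − p2|` over cells, with `p = z/Σz`; 0 means
disjoint niches, 1 identical ones.

The similarity test translates one region's occupancy rigidly to a uniform
random position inside that region's own 100% envelope (no wrapping),
recomputes D against the other region's observed niche, and reports
`p = (1 + #{D_null ≥ D_obs}) / (1 + n_reps)` (99 replicates by default; the
plus-one estimator precludes p = 0). Valid positions are those where the
niche's support fits entirely inside the envelope; they are enumerated
exactly by cross-correlating the support indicator with the envelope's
complement. The test is directional, matching the two directed p-values the
framework reports. When a niche saturates its envelope (for example a
heavily truncated region), few distinct translations exist and the test is
intentionally conservative.

Stability, unfilling and expansion restrict the grid to analogue climates —
cells inside the chosen envelope (default 75%) of *either* region — and
then measure, with `supp(·)` the occupied cells of a niche:

- `E` = fraction of invaded density outside `supp(native)` (expansion),
- `S = 1 − E` (stability; S and E partition the invaded niche's mass),
- `U` = fraction of native density outside `supp(invaded)` (unfilling).

**Support cutoff.** A truncated-Gaussian kernel support still overshoots
the data cloud by up to 4 bandwidths, which makes raw `z > 0` supports so
generous that genuine expansion becomes invisible (a niche center shifted
two breadths still fell entirely "inside" the native support). Supports
therefore discard the lowest 5% of each niche's density mass by default
(`support_mass_cutoff = 0.05`, settable to 0 for raw supports); the same
trimmed support defines legal translations in the similarity test, where
raw supports can leave essentially no legal position.

## The maximum-entropy SDM

The SDM estimates a Gibbs distribution `q(x) ∝ exp(λ·f(x))` over a region's
cells from presences and background. Features are linear and quadratic
transforms of each variable (pairwise products optional), each scaled to
[0, 1] over the training background; degenerate features are dropped with a
warning. Coefficients maximise

```
L(λ) = Σ_presences λ·f(x) − m · log Σ_background exp(λ·f(x)) − β Σ_j s_j |λ_j|
```

with `m` the presence count, `s_j` the feature's standard deviation over
the presences (floored at 1e-3 so every feature stays regularized), and a
single global multiplier β (default 1). The objective is concave; the L1
term is handled by splitting each coefficient into positive and negative
parts, giving a smooth bound-constrained problem solved with L-BFGS-B to a
projected-gradient tolerance of 1e-6 (the optimizer is restarted from its
own iterate if it stalls on rounding, and a stalled solve is accepted only
if it satisfies the first-order conditions). Any start point reaches the
same objective to ~1e-9.

Reported suitability is the classic logistic output with prevalence 0.5:
`q e^H / (1 + q e^H)` with `H` the entropy of the fitted Gibbs distribution
over the training background; with all coefficients zero every cell scores
exactly 0.5, and β → ∞ drives the model there.

Evaluation replicates a random 75/25 presence split (default 10 replicates
in validation runs; 100 mirrors the classic protocol), refits on the
training part, and scores AUC — the Mann-Whitney rank probability that a
presence outranks a background point, ties counting one half — for training
and held-out presences; replicate maps are averaged for the ensemble
projection. The binary range uses the nearest-rank 10th percentile of
presence suitabilities as threshold (position `ceil(0.1·n)` of the sorted
values, computed on all presences). Projection onto another region reuses
the training normalization without clamping; cells outside the training
environmental range are scored but flagged in an extrapolation mask. Range
areas use spherical-degree cell areas,
`(111.320·cosφ·Δλ)·(110.574·Δφ) km²` at the cell-center latitude, rather
than an equal-area reprojection — transparent and adequate at the scales
involved.

## Occupancy profiles

A profile integrates a projection's suitability over bins of a covariate
(100 m bins of altitude, classically; any single raster layer works) and
normalises to unit mass; its suitability-weighted mean (computed pre-
binning) summarises where on the gradient the model concentrates the
species. Two profiles on identical bins are compared with the two-sample
Kolmogorov-Smirnov statistic on their cumulative masses. Suitability mass
has no true sampling unit, so the accompanying p-value is advisory only: it
uses an effective sample size equal to the number of bins carrying mass in
either profile and is labelled as such; the statistic is the primary
result.

## The virtual-species generator

Each landscape layer is a mixture `a·G + c·S + d·N_k` of a deterministic
north-to-south linear gradient `G`, a shared smoothed latent field `S`, and
a private smoothed noise field `N_k` (Gaussian smoothing of seeded white
noise, length scale 5 cells by default), placed on per-layer means 10·k and
common spread 2.0. Because smoothing leaves few effective degrees of
freedom, the raw fields can carry chance correlations of ±0.2; the
ingredients are therefore Gram-Schmidt orthonormalized before mixing, which
makes the realised pairwise correlation equal the target exactly. The
gradient's weight is kept small and folded into the shared-structure budget
so it never biases the correlation. Negative targets are supported for
two-layer stacks only (a common negative pairwise correlation is not
attainable for more).

The virtual species has Gaussian suitability — a product of per-axis normal
response curves. The default species is centered on the layer means with
per-axis breadth 0.75 × the landscape's marginal spread, a moderate
generalist. That breadth is a designed property of the scenarios: clipping
the invaded region to the central-50% climate envelope of the native region
(the *unfilled* scenario) leaves about two thirds of the native suitability
mass outside the clipped box — computable directly from the true
suitability surface — so the scenario genuinely encodes large unfilling. A
specialist half as broad would lose only its niche tails to the clipping
and the scenario would carry almost no signal. The standard study regions
are 160 × 160 cells so the clipped invaded region (~6% of cells after the
four-layer central-envelope intersection) still offers more cells than a
1000-record deduplicated sample needs.

Occurrence records fall at cell centers, drawn with probability
proportional to suitability and, by default, without within-cell
duplication — matching the raster-resolution duplicate removal applied to
real records.

Scenarios: *conserved* uses one species on two independent landscape
realisations; *unfilled* clips the invaded stack to the native central
envelope; *expanded* shifts the invaded population's niche center (2
breadths along axis 1 by default). The reciprocal-SDM asymmetry experiment
instead keeps the invaded landscape whole but restricts the invading
population to cells below the median of one gradient layer and above 25% of
maximal suitability — a low-altitude filter on an established population —
which produces the expected signature: the native-trained projection
strictly contains the invaded-trained range, covers several times its area,
and sits higher on the gradient.

## Problem sizes and determinism

Validation runs use 160 × 160 landscapes, 1000 occurrences and 10,000
background points per region, R = 100 grids, 99 similarity replicates and
three replicate seeds for the niche scenarios; 500 presences, 10,000
background points and 10 split replicates for the SDM checks; and 400
presences with 3000 background points for the asymmetry experiment. Every
stochastic step is seeded, with named substreams derived from one root
seed, so identical configurations reproduce bit-identical results.

## What the synthetic validation does not show

The generator produces equal-correlation, equal-variance Gaussian fields
with a single linear gradient; it does not imitate the covariance structure
of real bioclim variables, topographic complexity, spatial sampling bias,
dispersal limitation, or demographic processes. Passing the recovery tests
shows the estimators faithfully measure the niche relations that were
built in; it does not certify performance on real occurrence data, where
sampling bias and non-analogue climates add errors the simulator does not
model. The similarity test's translation null preserves niche shape but
not orientation effects, and its power degrades when a niche fills its
envelope. KS p-values on profiles are advisory throughout.
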