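# Methods

`climbmet` implements an analysis of latent (non-genetic) mortality risk in
isogenic *Drosophila* cohorts: a cohort is fractionated by climbing
behaviour into five ordinal groups, the groups are contrasted
demographically and physiologically, and the metabolome is screened for
abundances and pairwise covariances that track the ordinal climbing axis.
Because the raw fly data are not bundled, a synthetic-data module generates
every input with the statistical structure the analysis assumes; the
generators and the estimators are adversarially cross-tested (planted
effects must be recovered, nulls must stay null).

## Climbing fractionation

A cohort is split at a partition in a vertical tube over up to three
rounds.  Discordant round-1/round-2 flies stop after two rounds and are
labelled *middle* ("top in 1 of 2 trials"); concordant flies receive a
third round, giving *top* (3/3), *mid-top* (2/3), *mid-bottom* (1/3) and
*bottom* (0/3).  The branching rule is the one consistent with the
two-trial definition of the middle group; length-3 sequences with a
discordant start cannot occur under it and are rejected as input errors.
With per-round top-probability p the label distribution is
((1-p)³, (1-p)²p, 2p(1-p), p²(1-p), p³) bottom→top — (1/8, 1/8, 1/2, 1/8,
1/8) at p = 1/2.  The within-cohort distribution of climbing propensity is
not identified by the design, so the simulator accepts any per-fly
propensity distribution (scalar, array, or callable); the default is a
common p = 1/2.

## Survival demography

All estimators handle **delayed entry**: a fractionated fly enters
observation alive at the fractionation age, so the risk set at age t is
{entry < t ≤ exit}.  Kaplan–Meier and the restricted-mean lifespan (area
under S(t) to a horizon, Greenwood-based SE) are computed by the
product-limit definition; the log-rank test is the Mantel–Cox statistic
over pooled event times.

**Gompertz model.** Hazard μ(x) = α e^{βx}; α is age-independent mortality,
β the demographic rate of aging.  The likelihood uses left truncation at
entry and right censoring:
ℓ = Σ e_i (ln α + β t_i) − α D_i, with D_i = (e^{β t_i} − e^{β s_i})/β (the
exposure-weighted integral of e^{βx}).  For any fixed β the α-MLE is
deaths / Σ D_i per group, so all model variants (α, β per group; shared β;
fully shared) reduce to one-dimensional profile optimizations in β (grid
plus bounded Brent, xatol 1e-10) — closed-form profiling replaces the
multistart log-α optimizer that a joint parameterization would need, and
cannot be trapped in a second mode because the 1-D profile is scanned
globally first.  β = 0 falls back to the exponential model via the series
limit of D.  Associations of α and β with climbing are likelihood-ratio
tests between nested variants (per-group α, shared β vs fully shared for
α; per-group α, β vs shared β for β), each with G − 1 degrees of freedom.

**Aalen additive hazards.** Design = intercept + one indicator per
non-reference fraction ("middle" is the reference).  At each event time the
death indicator is least-squares regressed on the at-risk design; the
increments cumulate into H_a(t) with variance from squared increments.
Simultaneous deaths are processed in one increment; singular at-risk
designs skip the increment (logged).  With no covariates the cumulative
intercept is exactly Nelson–Aalen.  The per-covariate test is the endpoint
statistic z = H_a(τ)/SE(τ) by default; a supremum variant with a sign-flip
resampling null is available (the endpoint form is the default because a
single per-fraction p-value is wanted).

**Velocity mixed model.** velocity ~ group + age + group×age [+ position +
batch] with a vial random intercept, fit by profiled ML: for a fixed
variance ratio λ = σ²_vial/σ²_resid the GLS solution is closed-form via
per-vial sufficient statistics, so the fit is a 1-D search over λ ≥ 0
(log-grid plus Brent).  One vial degenerates to OLS with a warning.

## Metabolome preprocessing

Order is enforced: log + sample-centering → batch correction → run-order
residualization → outlier removal → PCA.  Natural log is the default
(log2 via `base=2`).  Batch correction is the parametric empirical-Bayes
location/scale algorithm (standardize per metabolite; estimate per-batch
additive and multiplicative effects; shrink both toward cross-metabolite
priors, normal for location and inverse-gamma for scale, by the standard
iteration; back-adjust).  One numerical choice: per-batch variances use the
population (ddof = 0) convention so that the shrink-off correction is
exactly idempotent against the 1/n pooled variance; with the textbook
ddof = 1 convention every reapplication shrinks the scale by
√((n−B)/n).  Batches with a single sample get location-only adjustment.
Run-order drift is removed by per-metabolite simple regression with the
column means restored.  Outliers are samples whose Mahalanobis distance in
the PC1–4 score space exceeds the mean distance by more than 4 SD,
computed once.  PC significance uses the Tracy–Widom (β = 1) edge
distribution: each leading eigenvalue of the metabolite-scaled correlation
structure is standardized with the Patterson effective-size formulas and
compared, sequentially from the top, to an embedded quantile table
(levels 0.10–0.001, log-interpolated) at α = 0.01.  No special-function
dependency is needed at that α.

## Ordinal screens

Both screens use the cumulative-logit (proportional-odds) model with the
sign convention logit P(Y ≤ j) = θ_j − xβ − u, so positive coefficients
raise the odds of higher climbing fractions.  Thresholds are parameterized
as θ₁ plus cumulative exponentials (monotone by construction).

**Single-metabolite screen.**  fraction ~ age (categorical Week 4/6) +
metabolite + age×metabolite with a replicate random intercept.  The
Gaussian intercept is integrated out by Gauss–Hermite quadrature.  The
default is the *plain* rule with exact analytic gradients — that is what
makes 160-metabolite screens and permutation suites cheap — at order 20;
a mode-centred adaptive (Laplace-recentred) order-10 variant is available
via `adaptive=True` and agrees with the plain rule to <1e-3 in the
moderate-σ regime of these designs.  Plain order 10 is *not* used because
quadrature error at large σ can manufacture a spurious high-σ optimum.
The metabolite main effect and the interaction are LRT-tested against the
nested models (the age-only null is fitted once per screen), with BH FDR
across metabolites; non-converged or separated fits leave the family with
a warning.

**Pair (differential-covariance) screen.**  Fraction and age main effects
are removed per metabolite by the fraction×age cell-mean regression (the
least-squares fit of the two categorical factors plus interaction, so
residuals have exactly zero mean in every occupied cell).  For each pair,
fraction ~ resid_i + resid_k + resid_i×resid_k (fixed effects only, as the
model has no replicate term; the standardized product term stabilizes the
optimization) and the product term is LRT-tested.  The default FDR family
is the correlation-prefiltered pairs (overall Pearson BH-FDR ≤ 0.05);
`family="all"` tests all N(N−1)/2 pairs.  The fits run through a batched
Newton–Raphson with analytic gradient and Hessian, vectorized across
pairs/permutations (~0.2 ms per fit), verified against statsmodels'
ordinal model and a grid-search oracle.

**Label permutation.**  Climbing-fraction labels are permuted across
samples (within-sample covariance preserved) and the full screen —
residualization included — is re-run per permutation.  Empirical p-values
use the add-one convention p = (1 + #{null ≥ obs})/(1 + B).  Two
statistics are tracked: the FDR-significant pair *count* (the headline
quantity) and the continuous family chi-square sum.  The count is heavily
tied (usually 0 under the null), so its permutation p is conservative
(valid, super-uniform) rather than exactly uniform; the chi-square-sum p
is lattice-uniform under exchangeability and is the statistic whose
uniformity the calibration suite checks.

## Covariance networks

Edges join interaction-significant pairs whose within-fraction Pearson
correlation is nominally significant (p ≤ 0.05, unadjusted — "nominal" is
meant literally).  Week-4 and Week-6 samples of a fraction are pooled by
default (`stratify_age=True` requires nominal significance at each age).
Summaries report node/edge counts, degrees, the hub, and shared edges
between fraction networks on canonical pair keys.

## Heterogeneous-graph enrichment

The graph has node classes metabolite / reaction / enzyme / pathway /
module and undirected, unweighted edges; metabolite–metabolite edges are
forbidden (compounds relate only through the other classes).  Path length
is counted in **intermediate nodes** (hop distance − 1): adjacent-via-one-
node pairs have length 1, which makes the observed 1–5 range and the
4-df length-class binning natural.

* **PathIndex**: one BFS per mapped metabolite gives distances and
  Brandes-style shortest-path counts; node membership uses the identity
  d(s,v) + d(v,t) = d(s,t) (endpoints excluded) — paths are never
  enumerated.  Equivalence with exhaustive enumeration is property-tested
  on random graphs.
* **Path-length enrichment**: selected-pair lengths binned 1..5+ against
  the all-pair proportions, Pearson chi-square with df = classes − 1
  (empty background classes merged, df adjusted).
* **Node enrichment**: for each node on ≥1 shortest path of the covarying
  pairs, a one-sided hypergeometric upper tail for drawing a of n
  covarying pairs from N mapped pairs of which A contain the node; BH FDR
  over the path-touching nodes (untested nodes carry no evidence).  The
  background includes the covarying pairs by default; a disjoint
  (Fisher-exact) background is available by option.
* **Rewiring null**: the covarying pairs form a simple graph over the
  mapped metabolites; each permutation re-draws a simple graph with the
  identical degree sequence by double edge swaps (≥10·|E| mixing swaps
  from the observed network, degree sequence asserted every iteration)
  and counts permuted pairs whose shortest paths contain the focal node.
  This asks whether the enrichment reflects *which metabolites are paired*
  rather than which metabolites are present.
* **Diffusion enrichment**: heat 1 on a seed metabolite set, score
  s = (L + λI)⁻¹ b with λ = 1 (regularized Laplacian; the variant name is
  recorded in the output metadata), per-node empirical p against random
  equal-size seed sets; pathway/module rows are flagged for process-level
  reading.  Disconnected seeds diffuse within their components, a property
  of the linear system.

## Stress assay

Per-vial survival proportions are shrunk to the open interval by
y′ = (y(n−1) + 0.5)/n — the only reading of the transform that keeps
y′ ∈ (0,1); the alternative ((y·n − 1 + 0.5)/n) goes negative at y = 0 —
and fitted by beta regression (logit mean link, constant precision φ;
statsmodels' beta MLE under the `fit_betareg` surface).  Fraction enters
as ordinal numeric 0–4 by default, expressing the monotone trend;
categorical coding is an option.  The climbing effect is the LRT of
(fraction + treatment + fraction×treatment) against treatment-only.

## Synthetic data: what it emulates, and what it does not

* **Lifespans**: Gompertz with per-fraction (α, β), sampled conditional on
  survival to the fractionation age by the exact inverse CDF
  T = entry + (1/β) ln(1 − β ln U / (α e^{β·entry})) (β = 0 →
  exponential).  Defaults: entry 29 d; fraction probabilities from the
  branching rule at p = 1/2; β falling from 0.14 (bottom) to 0.10 (top)
  and α solved numerically so the unconditional mean lifespans are 45.6,
  47.2, 48.3, 49.4 and 50.3 days bottom→top — the bottom/top endpoint
  means reported for week-4-fractionated cohorts, with the bottom
  fraction's excess risk loaded on β as observed there.  Censoring
  emulates escapes: per 2.5-day census, probability 0.01.  ~25 flies per
  vial.
* **Metabolome**: log-scale abundance = baseline + fraction shift + age
  shift + latent pair factors + iid noise, then batch location/scale
  distortion and linear run-order drift.  Defaults: 160 metabolites, 71
  samples spread over 5 fractions × 2 ages (remainders to Week-6 cells,
  which the study sampled more densely), 11 replicate fractionations
  (4 Week-4, 7 Week-6), 3 batches (shifts 0/+0.6/−0.6, scales
  1.0/1.15/0.9), drift 0.01/injection, noise SD 1.  The study-conditions
  spec plants nine ±1-SD monotone-shift metabolites (alternating
  direction) and ten pairs whose correlation decays linearly from 0.8
  (bottom) to 0.0 (top).  Fraction-dependent covariance is induced by a
  shared latent factor with fraction-specific loadings
  λ_f = σ√(|ρ_f|/(1−|ρ_f|)) — the simplest mechanism giving the target
  per-fraction correlation without specifying a full covariance matrix.
  Caveat: a metabolite in many overlapping pairs accumulates factor
  variance, so realized pairwise correlations fall below nominal ρ for
  hub-like plantings.
* **Graph**: layered random graph, default 40 metabolites / 60 reactions /
  15 enzymes / 8 pathways / 5 modules (sized so all-pairs shortest paths
  take milliseconds; full KEGG-scale counts are supported, not default).
  Reactions attach to ≥2 metabolites, enzymes to reactions, pathways and
  modules to mixed member sets; stray components are re-attached through a
  reaction so the largest component holds every metabolite and no
  metabolite–metabolite edge can arise.
* **Bang assay**: binomial per-vial survivors; default vortexed survival
  0.69 → 0.92 bottom→top (monotone between the reported endpoints),
  20–25 flies/vial, 9 vortexed + 4 control vials per fraction, control
  survival 0.98.

What the generators do **not** emulate: raw LC–MS spectra and
chromatography, climbing videos, non-Gaussian abundance noise,
missingness, metabolite annotation, or a realistic KEGG topology beyond
the class/wiring constraints.  Passing tests therefore certify the
statistical machinery (calibration, power against planted structure,
oracle equivalence, determinism), not biological conclusions about real
flies.

## Problem sizes and numerical choices

The test suite runs the statistical studies at sizes chosen to finish in a
few minutes while keeping the Monte-Carlo error well inside the asserted
tolerances: Gompertz LRT calibration at 1,000 null replicates (200 flies
each); screen power medians over 3–5 study-sized datasets; permutation-p
uniformity over 200 replicate null datasets at 200 permutations each
(5 metabolites × 40 samples, all-pairs family); rewiring nulls at 2,000
permutations on the default graph (10,000 in the acceptance script).
All empirical p-values use the add-one convention.  Optimizer tolerances:
cumulative-logit Newton stops at gradient ∞-norm < 1e-8 with step-halving;
the CLMM L-BFGS-B at gtol 1e-7; separation is flagged at |coefficient| >
30.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no global random state anywhere.

## Known limitations

* The CLMM supports one random-effect grouping (replicate) and the logit
  link only.
* The beta regression has constant precision; no variable-dispersion
  variant.
* Diffusion enrichment implements one variant (regularized Laplacian);
  other kernels would need their own calibration.
* Degree-preserving rewiring can mix poorly on degenerate covarying-pair
  graphs (for example a single hub incident to every edge); the swap-try
  failure rate is tracked and a >50% failure rate is an error.
* With ~10 replicates the random-intercept SD is estimated with large
  sampling error (the realized replicate-effect SD itself deviates ~19%
  median from its population value); point estimates of σ at that design
  size should be read accordingly.
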