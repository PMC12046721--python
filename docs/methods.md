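# Methods

## The model

The package fits the Besag–York–Mollié (BYM) convolution model for
small-area count data. For census tract *i* with observed firearm-homicide
count *y&#7522;* and expected count *E&#7522;*,

    y_i ~ Poisson(λ_i),
    log(λ_i) = log(E_i) + x_i'β + u_i + v_i,

where *x&#7522;* collects the tract's fixed-effect covariates (lending
trajectory, area-deprivation decile, racial diversity), *u* is a spatially
structured intrinsic conditional autoregressive (ICAR) field over the
tract adjacency graph, and *v* is unstructured iid Gaussian noise. The
ICAR prior conditions each *u&#7522;* on the average of its neighbors with
precision τ_u·d&#7522; (d&#7522; = number of neighbors) and is constrained to sum to
zero; *v&#7522;* ~ N(0, 1/τ_v). Only the convolution *u + v* enters the
likelihood, so the two components are reported jointly through tract
relative risks RR&#7522; = exp(x&#7522;'β + u&#7522; + v&#7522;) and never interpreted
separately.

Expected counts use internal standardization: E&#7522; = pop&#7522; × (Σy / Σpop),
the citywide crude rate applied to each tract's population. This makes
ΣE = Σy exactly and the E-weighted mean SMR equal to 1; no age adjustment
is attempted because the standardization is population-only by design.
Tract-level evidence of elevated risk is summarized by exceedance
probabilities Pr(RR&#7522; > c) for c ∈ {1, 2, 3, 4}, estimated as the
fraction of posterior draws strictly above each threshold (strict
inequality chosen to match the "RR > c" reporting convention; ties have
probability zero for continuous draws).

## Lending-trajectory classification

Tracts are crossed on two dichotomous axes:

* **Historic redlining.** The historical redlining score (HRS; weighted
  1930s HOLC grade, A = 1 … D = 4) is dichotomized at the 25th percentile
  of its citywide distribution. The percentile uses linear interpolation
  between order statistics, and values *at or above* the cutoff count as
  "high historic redlining" — with a low cutoff the high side is the
  large side, matching the empirical skew of redlined cities. All-tied
  inputs flag every tract high (a value is ≥ its own cutoff).
* **Current lending discrimination.** A tract qualifies through either
  arm: loans originated per 1,000 residents at or below the 10th
  percentile citywide (per-capita rather than raw counts, so the flag is
  population-invariant; ties are included), or a high-cost-loan share
  ≥ 15% (high-cost = rate spread > 1.5 points over the average prime
  offer rate). Zero-loan tracts have an undefined high-cost share and can
  qualify only through the low-lending arm — which they always do, since
  0 is below any percentile of nonnegative volumes.

The cross yields four categories — high investment (low/none), growing
investment (high/none), disinvested (low/yes; the modeling reference
category), sustained disinvestment (high/yes). Tracts missing HRS cannot
be placed and are excluded with a recorded reason.

Covariates: racial diversity is Simpson's index 1 − Σ(n_k/N)² over seven
census race groups (0 = single-group tract, maximum 1 − 1/7; higher =
more diverse). It enters the model as the raw index, so its coefficient
is the risk ratio of a hypothetical 0 → 1 contrast. Deprivation deciles
are rank-based over included tracts (1 = least deprived 10%), ties
resolved by average rank then stable input order, which keeps every
decile within one tract of n/10 and makes the assignment invariant to
monotone transforms of the raw index.

## Inference

Posteriors are obtained by MCMC (the model's contract — posterior
summaries, DIC/WAIC, exceedance probabilities — is
approximation-agnostic):

* **β** — joint random-walk Metropolis, proposal covariance scaled from
  the inverse Fisher information at the Poisson-GLM mode (an in-package
  Newton/IRLS solver provides the mode and curvature and initializes the
  chain).
* **u** — chromatic single-site Metropolis: the adjacency graph is
  greedily colored, and all sites of one color (whose full conditionals
  are mutually independent) update simultaneously against the ICAR
  conditional. After each sweep *u* is re-centred to sum to zero with the
  mean transferred into the intercept, leaving the likelihood invariant.
  Islands (neighborless tracts) have u fixed at 0.
* **v** — vectorized single-site Metropolis (conditionally independent
  across tracts).
* **τ_u, τ_v** — conjugate gamma updates; the ICAR quadratic form uses
  rank n − (number of connected components).

Step sizes adapt by Robbins–Monro during burn-in only (targets 0.25 for
the joint β move, 0.40 for single-site moves) and are frozen afterwards,
so the retained chain is a valid fixed-kernel sampler. Default priors are
an improper flat prior on β and Γ(1, 5×10⁻⁴) on both precisions; the
built-in sensitivity alternative is N(0, 10) on β with Γ(0.1, 0.01) on
the precisions. A negative-binomial likelihood (dispersion r, Poisson as
r → ∞) is available for overdispersion comparison, with r updated by
Metropolis on log r under a Γ(2, 0.1) prior. Default run length is 4
chains × 25,000 iterations (5,000 burn-in, thin 5); the bundled analyses
and experiments use shorter, stated settings because the lattice studies
are small and β is initialized at the GLM mode.

Linear predictors are clipped at |η| = 30 before exponentiation — far
outside any plausible fit — purely to keep proposals finite.

## Model comparison and calibration

* **DIC** = D̄ + p_D with p_D = D̄ − D(θ̄); the plug-in θ̄ is the posterior
  mean of the per-tract linear predictor (standard for hierarchical
  Poisson models). Negative p_D triggers a warning.
* **WAIC** on the deviance scale: −2(lppd − p_WAIC), with p_WAIC the sum
  of per-observation posterior variances of the log density (sample
  variance, n−1 denominator).
* **PIT** for discrete counts is randomized: uniform on
  [F(y&#7522;−1), F(y&#7522;)] under the posterior-predictive CDF (mixture over
  draws), seeded; the non-randomized mode returns the interval midpoint.
* **Posterior-predictive MAE/RMSE** compare observations with the
  posterior mean of λ&#7522;.
* **Overdispersion** is the raw-count variance-to-mean ratio with the
  n−1 variance convention (stated because the ratio depends on it).
* **ESS** uses Geyer's initial-positive-sequence truncation of the
  autocorrelation sum, per chain (summed across chains); constant chains
  report their length with a degeneracy warning. ESS below 200 warns but
  never errors.

The five-model ladder (unstructured only; + CAR; + trajectory;
+ deprivation; full) is orchestrated by the pipeline and reported as a
DIC/WAIC/effective-parameters comparison table.

## The synthetic-data generator

The generator emulates a city on an n_rows × n_cols lattice (rook or
queen contiguity) and draws the outcome from exactly the BYM generative
model above with known coefficients, so every downstream stage has a
ground truth. Defaults are scaled to the Chicago study population: mean
tract population 3,495 (Poisson, floored at 50 to avoid degenerate
expected counts); baseline homicide rate 1.8×10⁻⁴ per person-year
(≈ 0.63 expected deaths per average tract, matching a citywide mean
count of ~0.64); HRS drawn from two clusters — 2.30 (sd 0.38) below and
3.41 (sd 0.47) above the historic cutoff, the observed group means;
deprivation index N(104, 20²) correlated 0.5 with HRS; race counts
multinomial with a dominant-group share that is larger (more segregated)
in historically redlined tracts; loan volumes lognormal and lower, and
high-cost shares Beta-distributed and higher, in discriminated tracts.
True precisions default to τ_u = 500 (the order implied by a fitted
structured variance of ~0.002) and τ_v = 100; the default signal is a
doubled risk under sustained disinvestment (β_sustained = log 2, all
other effects 0). Loan counts are integer Poisson and high-cost loans
Binomial, so zero-loan tracts arise naturally with undefined cost
shares.

Because the classifier dichotomizes HRS at the 25th percentile, the
realized share of high-historic-redlining tracts is pinned at 75% by
construction. The default four-category mix therefore keeps the observed
*conditional* discrimination rates (0.52 given high redlining, 0.52
given low) but fixes the historic margin at 25/75, making the classifier
self-consistent with the generator: approximately (13% disinvested, 36%
growing, 12% high investment, 39% sustained disinvestment).

What the generator does **not** emulate: real HRS distributions are
clumped and tied (so real cities can have more than 75% of tracts above
the 25th-percentile cutoff — the generator's continuous clusters
cannot); covariates are conditionally independent given the latent
trajectory rather than jointly calibrated to any real city; tract
polygons are unit squares; no person-level loan or victim records exist.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative model, not fidelity of any
particular real-data estimate.

A consequence worth knowing: fitting the model on *classified* labels
(the realistic pipeline) attenuates coefficients relative to truth,
because tracts misassigned across the percentile cutoffs contaminate the
small reference category. Validation experiments that target parameter
recovery therefore fit on the generator's latent labels (the correctly
specified model); the pipeline run on classified labels is exercised
separately for structure and diagnostics.

## Validation experiments and their sizes

* **Worked fold ratios** — pure arithmetic on published headline
  numbers: odds of 1-in-915 citywide vs 1-in-79 in the hardest-hit
  neighborhood (11.6-fold), and the fold decrease implied by a relative
  risk of 0.146 (1/0.146 ≈ 6.85).
* **GLM oracle** — 50 tracts, random effects off, flat prior; every
  posterior coefficient mean is compared to the independent IRLS MLE in
  Monte-Carlo standard-error units. Expected counts are forced to 250
  per tract so the posterior is effectively Gaussian: at realistic sparse
  counts the posterior *mean* genuinely sits above the mode by the
  analytic skew of the flat-prior cell-rate posterior (≈ +1/(2S) per
  cell), which is a property of the posterior, not of the sampler.
* **ICAR covariance** — 10,000 exact-eigendecomposition draws on the 3×3
  rook lattice against the pseudo-inverse covariance, entrywise, in MC
  standard-error units (the max over 45 correlated entries is compared
  to 4).
* **Parameter recovery** — 200 replicates of the default 20×20 study;
  reports 95%-CrI coverage of the true RR 2 and the replicate average of
  the posterior mean of exp(β_sustained). Per-replicate posterior means
  are combined *geometrically*: the per-replicate estimator is a
  positive, heavy-tailed ratio whose arithmetic average is inflated by
  convexity (≈ +10% at these event counts); the geometric average is the
  natural location summary for ratios and is reported as primary, with
  the arithmetic average alongside.
* **Calibration** — randomized-PIT uniformity under the model's own
  posterior predictive (a fresh posterior draw per tract per replicate,
  making PIT values iid uniform under calibration), 40 replicate
  datasets, KS test at α = 0.01.
* **Model ranking** — five replicates with a tripled sustained-
  disinvestment risk; DIC and WAIC must both prefer the trajectory model
  to intercept-only.

Chain lengths in these experiments (e.g. 5,000 iterations per recovery
replicate) are Monte-Carlo-precision choices sized to the small lattices
used.

## Numerical conventions and edge cases

* Percentiles: linear interpolation between order statistics throughout.
* Boundary points in point-to-tract assignment go to the first
  containing polygon in file order, boundary counted as inside;
  unassigned points are counted and excluded.
* Zero-population tracts get E = 0 and are excluded from fitting with a
  logged reason (log E undefined); a death in a zero-population tract is
  a data error.
* A trajectory or decile category absent from the data is refused
  (an all-zero dummy column would be unidentifiable).
* Disconnected adjacency is an error for the ICAR simulator (the
  constrained distribution is defined per component); at fit time,
  islands are handled by fixing their structured effect at zero and
  adjusting the ICAR rank.

## Known limitations

* The sampler is O(colors + constants) vectorized per sweep but still
  Python: comfortable to ~1,000 tracts at desk scale, not for national
  lattices.
* BYM is used in its classical parameterization; the BYM2 rescaling,
  Leroux model, and spatially varying coefficients are out of scope, as
  are causal-mediation decompositions of deprivation and diversity.
* Exponentiated-effect tables average exp(β) over draws (stated because
  the alternative — exponentiating the averaged β — differs by Jensen's
  inequality).
* The diversity covariate is Simpson's index, on which higher = more
  diverse; analyses that call this construct "segregation" are reading
  the same column with the opposite sign convention.
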