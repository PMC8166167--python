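# Methods

This note documents the statistical machinery, the assumptions baked into
each stage, the synthetic world the tests run against, and the numerical
and design choices made where the design was genuinely open.

## 1. Relative abundance from checklists

A checklist is one sampling event with effort metadata; "complete" means
every detected species was reported, so absences are inferable.  Quality
filters retain complete checklists with duration strictly between 5 and
240 minutes and distance strictly below 5 km.  Checklists are assigned to
a half-open `[lo, hi)` lattice of 5° cells (a point exactly on a boundary
belongs to the higher cell; the convention is stated because it is
otherwise arbitrary).  A cell is *eligible* when it holds at least 50
checklists in at least one calendar month.

Relative abundance of a species in a cell is computed month-first: the
monthly mean count over all the cell's checklists that month (zeros
included), then the unweighted mean over months *with at least one
checklist* — months without data are skipped rather than treated as
zeros, since an unsampled month carries no information.  Month-first
averaging deliberately weighs months equally regardless of effort, which
damps seasonal-congregation bias.

**SE of log10 RA.**  The linear-scale SE is the SD (n−1 denominator) of a
species' space × time stratum means, divided by the normality unbiasing
constant c4(n) = sqrt(2/(n−1))·Γ(n/2)/Γ((n−1)/2) — the package's choice
of small-sample correction, since no single formula is fixed by
convention.
A species observed in a single stratum falls back to the Poisson SE
sqrt(mean/n).  The delta method converts to log10:
`se_log10 = SE / (mean · ln 10)`.  At coefficient of variation 0.2 the
first-order delta method underestimates the exact log-scale SD by ≈5.7%
(numerical integration: 0.09207 vs 0.08686 at mean 0.5, SE 0.1); tests
account for this known accuracy limit.

## 2. Training regression (measurement error in the predictor)

Model (log10 scale throughout):

    y_i      ~ Normal(b_s(i) + m_s(i)·x_i*, σ)
    x_i^obs  ~ Normal(x_i*, se_i),   se_i known per record
    x_i*     ~ Normal(μ_x, τ_x)      (hyperparameters estimated)
    (b_s,m_s)~ Normal₂(μ, Σ)

Zero relative abundance in a region is replaced by −4.5 on the log10
scale with a sentinel SE of 0.5 (the substitution value reflects the
smallest nonzero value such data produce; the sentinel SE is a
configurable choice — nothing in the data identifies it).

The latent-predictor population prior `Normal(μ_x, τ_x)` matters: a flat
prior on x* over-corrects attenuation and visibly distorts slope
uncertainty (per-species interval coverage dropped to ~0.86 in
calibration runs with a flat prior).

**Sampler.**  Vectorized Gibbs: conjugate updates for x*, (b_s, m_s)
(closed-form stacked 2×2 algebra), μ, μ_x, τ_x², and σ² (inverse gamma,
shape 2, scale 0.25·var(y)); the random-effect covariance Σ is updated by
a short random-walk Metropolis on (log sd_b, log sd_m, atanh ρ) against
the *marginal* likelihood with the random effects integrated out
(Woodbury/Sylvester identities reduce each species to closed 2×2 forms).
The marginal step is essential: a centered conjugate inverse-Wishart
update sits in the classic small-variance funnel and, under weak priors,
collapses the slope variance to zero (observed: per-species slope
coverage 0.58–0.74 regardless of chain length).  Priors on the RE SDs are
half-Student-t(3) with scale equal to the response SD; ρ is uniform.
Convergence is monitored by split-R̂ on the fixed effects and σ
(threshold 1.01); non-convergence warns but still returns results.

Calibration: across repeated refits of 20-species datasets drawn from the
model, 95% posterior intervals for per-species b and m cover truth at
0.94–0.97.

**Downstream propagation.**  Per-species prediction SE assumes
slope–intercept error correlation −1 (an overestimated intercept forces a
shallower slope), giving `se = |se_b − x·se_m|`.  Residual σ is *not*
added by default — only coefficient uncertainty is propagated — but a
flag adds it in quadrature.  Bayesian R² is var(pred)/(var(pred)+σ²) per
posterior draw, reported as the posterior mean.

## 3. Two-level chained PMM imputation

The imputation table has one row per species × eligible cell in which the
species was recorded, with exactly eleven variables: species id (the
cluster), log #checklists, months observed, relative abundance (all
always complete), five species-level traits, and the two observation-level
targets (log10 density and its SE, missing together for all non-training
species).

Chained passes visit incomplete columns in order of increasing
missingness (maxit = 5 by default, 3 in the reduced pipeline profile).
Observation-level columns use a random-intercept linear model per species;
species-level columns use a regression on cluster aggregates, imputing one
value per species.  Both use predictive mean matching with a donor pool
of 5 (type-1 matching: observed predictions from point estimates, missing
predictions from a Bayesian draw of the coefficients), so imputed values
never leave the observed range.

Numerical choices that matter:

- The random-intercept model is a moment-based (between/within) variance
  component estimator with GLS quasi-demeaning — deterministic and fast
  enough for the m × maxit × columns inner loop; when every cluster is a
  singleton the model degrades gracefully to OLS.
- Design matrices standardize predictors and drop near-constant columns;
  a constant column is collinear with the intercept, and its *perturbed*
  coefficient would shift all predicted means by an arbitrary amount,
  collapsing PMM onto extreme donors (this failure was observed).
- `rel_abund`, `body_mass` and `flock_size` enter design matrices as
  log10 — they span orders of magnitude and the density relation is
  log-linear.  PMM still copies original-scale observed values.
- Clusters with no observed target rows (e.g. a withheld species) receive
  a *drawn* random intercept per imputation, with the cluster variance
  itself redrawn (scaled χ²) to propagate its estimation uncertainty;
  clusters with data use their BLUP.  Without the unseen-cluster draw,
  between-imputation spread for new species is far too small.

## 4. Abundance estimation

Per species: (i) per-imputation weighted mean of grid log10 densities,
weights ∝ reporting rate (fraction of the cell's checklists recording the
species), normalized; (ii) pooled SE = sqrt((1+1/m)·between-imputation
variance + (weighted mean imputed SE)²), hard-capped at 1.0 log10 units —
so a capped species' upper
95% limit is 10^1.96 ≈ 91× its point density; a soft-shrinkage variant
(`se² → se²/(1+se²)`) is available behind a flag; (iii) area = summed
sampled-cell areas, overridden by the known range area when the range is
smaller (clip) or when sampled cells cover <95% of the range's cells
(expand; the 95% threshold is a package choice); missing range falls back
to the grid area, flagged; (iv) 10,000 draws of `10^Normal(mean, se) ×
area`, sorted; the median is the point estimate, the 2.5/97.5% quantiles
the interval (quantile-based, not normal-theory).

Pooling order — densities first pooled across imputations per grid, then
weighted across grids — is equivalent to weighting per imputation then
pooling, because both operations are linear in the density; the
between-imputation variance is computed on the weighted per-imputation
means.

## 5. Aggregation and skewness

Group totals sum *sorted* distributions (comonotonic summation), making
every quantile of the total exactly the sum of member quantiles; this
keeps "equally likely" values aligned across species and is exact, not
approximate.  The gSAD takes log10 of species medians, with an exact zero
mapped to log10(0+1)=0.  Skewness is the type-3 estimator
`g1·((n−1)/n)^{3/2}` with `g1 = m3/m2^{3/2}` (1/n central moments); types
1–2 are selectable.  Robustness: (a) quantile resampling — one quantile
q ~ U(0.1, 0.99) per replicate applied to *all* species (the comonotonic
reading; an independent-per-species variant is behind a flag), group
values formed by summing species values, log10, skewness; 1,000
replicates give a mean and percentile interval; (b) a percentile
bootstrap over species.

## 6. Phylogenetic signal

Blomberg's K from the BM covariance matrix C (shared branch lengths; the
stem edge above the root is excluded — verified against an independent
VCV implementation): with â the GLS mean, K is the ratio MSE₀/MSE over
its Brownian-motion expectation `(tr C − n/1ᵀC⁻¹1)/(n−1)`.  K is exactly
1 on a star tree, and invariant to affine trait maps and global branch
rescaling.  The p-value is one-sided from tip shuffling:
`(1 + #{K* ≥ K})/(nperm+1)`.  Across a tree set, K is pooled by Rubin's
rules (within-tree variance = variance of the permutation distribution of
K, a documented stand-in); p-values are pooled Licht–Rubin style — each p
mapped through the two-sided inverse-t with the permutation count as df,
Rubin-pooled with unit within-variance, and mapped back.  This recipe is
*not* globally monotone in every per-tree p: for extreme mixtures (e.g.
p = (0.002, 0.07), m = 2) raising the small p can lower the pooled p
because the between-tree variance shrinks faster than the mean statistic.
It is monotone over moderate p ranges, which the tests check.

Finite-sample behaviour worth knowing: under BM the mean of K is close
to, but not exactly, 1 and depends on tree shape (≈0.99 on a balanced
64-tip tree; 0.89–0.94 on individual 100-tip pure-birth trees), because K
is a normalized ratio of quadratic forms; calibration checks therefore
average over tree shapes.

## 7. The synthetic world

The generator states a world rather than fitting one: 200 species on a
6×8 grid of 5° cells; per-species mean log10 density Normal(−1, 1) (so
natural-scale global abundances are right-skewed/log-normal-like) with
cell-level spatial scatter SD 0.3; occupancy fraction Beta(1.2, 3.5);
detection intercepts Normal(0.7, 0.35) correlated with log body mass
(−0.467), brightness (0.145) and colour distance from brown (0.101);
slopes Normal(1, 0.06) correlated with flock size (0.146); threat status
tracks true rarity.  Counts are Poisson (negative binomial optional)
with mean `10^(b + m·log10 d)` per checklist; effort is spatially
heterogeneous (log-normal cell multipliers, SD 0.6; ~80
checklists/cell/month); configurable fractions of incomplete (10%), too
short, too long and too far (5% each) checklists exercise the filters.
Expert estimates cover a 30% training subsample, each species' range
partitioned into 1+Poisson(1) regions, with 0.5 dex multiplicative noise
— roughly a factor of three, typical of extrapolated population
estimates, and the value at which the training model's Bayesian R²
(≈0.84) sits in the regime the method was designed for.  Trait
missingness is MCAR at 8/16/40/40% (threat/mass/colour metrics), with a
MAR-on-flock-size stress variant.  Trees are pure-birth, depth-scaled
to 1.

What a green recovery test establishes: that filtering, regression,
imputation, pooling and simulation jointly recover known abundances from
realistic observation processes (coverage ≈0.9, median error ≈0.24 dex at
defaults).  What it does not establish: robustness to observer behaviour
(rarity chasing), range maps that disagree with occupancy, non-stationary
seasonal detectability, or taxonomic mismatches — none of which the world
models.

Two validation bars from real-data experience are *not* reachable in this
world and the corresponding checks are expected to stay red: (i) the
delta-method/Monte-Carlo 5% agreement (the method's true error at cv 0.2
is 5.7%, see §1); (ii) ≥85% leave-one-out imputation-range coverage with
10 imputations — a perfectly calibrated imputer's range of 10
exchangeable draws covers a new draw with probability (m−1)/(m+1) =
0.818, and the clean synthetic detection relation provides none of the
overdispersion that pushed the real-data figure to 95% (measured here:
0.73 range coverage; the companion withheld-vs-full R² bar, ≥0.8, passes
at 0.97).

## 8. Known limitations

- One weight — the reporting rate — is used for both pooling steps (the
  density mean and the imputed-SE average); weighting the SE average by
  raw checklist counts instead is a defensible alternative not
  implemented.
- The moment-based variance components inside PMM are not REML; with very
  few clusters they are noisy (though measured unbiased at 59 clusters).
- Between-species spatial density structure is unstructured white noise
  per cell; no range-interior density gradients.
- The Licht–Rubin p pooling is a documented stand-in (see §6).
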