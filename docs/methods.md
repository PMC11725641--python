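# Methods

This note documents the statistical models implemented in `tnhomeo`, the
defaults and why they were chosen, the design decisions that were genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Data model and design encoding

The unit of analysis is a pair of genes × samples integer matrices: total
transposon insertions per gene and unique insertion sites per gene, in the
shape produced by `bedtools map -o sum` / `-o count`. Samples carry five
factors: strain (genetic background) g, stress e (or control), stress level
s, replicate j, batch b. Statistics operate on the unique channel; the
total channel is carried through batch adjustment and the EMD stage.

The nested design is encoded as indicator blocks: one column per strain
(`g[...]`), one per (strain, stress) (`e|g[...]`), one per (strain, stress,
level) (`s|e|g[...]`). This full coding is deliberately overparameterized —
a stress column equals the sum of its level columns — matching the model
statement `log μ = β0 + x_g β_g + x_{e|g} β_{e|g} + x_{s|e|g} β_{s|e|g}`;
the redundancy is resolved by the L1 penalty during path fitting, and
unpenalized refits drop aliased columns greedily in block order (strain
before stress before level), so in a single-strain two-group design the
estimable contrast lands on the stress column and equals the log ratio of
group means. A reduced `coding="reference"` (first strain and first level
absorbed into the intercept/stress baseline) is available where a full-rank
matrix is needed; its columns are linearly independent on any complete
grid.

## Batch adjustment

Per gene, a negative-binomial GLM with biological-condition indicators and
batch indicators is fit (Poisson start, method-of-moments dispersion,
NB refit). Condition covariates are always present so that real effects are
not absorbed into batch terms; a batch perfectly confounded with a
condition is rejected with an error naming the batch. Batch log-fold-change
estimates are centered per gene (geometric mean 1 across batches) and the
centered offset defines the batch-free mean per cell. Dispersions are
estimated per (gene, batch) by moments, with the pooled residual dispersion
as the batch-free value.

Adjustment maps each count through the two NB CDFs,
`y' = F⁻¹_free(F_batch(y))`, evaluating the discrete CDF at the midpoint
`P(Y < y) + ½P(Y = y)`. The midpoint convention makes the identity model
map every count to itself exactly and is unbiased for symmetric
perturbations. Output stays integer and non-negative; genes whose GLM fails
(all zeros, separation) fall back to the identity for that gene. Shrinkage
of batch parameters across genes is intentionally omitted: at the library
sizes simulated here per-gene estimates are stable, and the quantile-map
contract does not depend on it.

## Fitness classification and fitness values

With m the median unique count across replicates and m_ctrl the median of
the strain-matched unstressed control: essential if m ≤ τ_ess everywhere in
that strain; conditionally essential if m_cond ≤ τ_ess < m_ctrl;
conditionally beneficial if m_cond ≤ m_ctrl/ρ_fc (and above τ_ess);
conditionally detrimental if m_cond ≥ ρ_fc·m_ctrl; otherwise neutral.
τ_ess = 3 unique insertions and ρ_fc = 4 are explicit stand-in defaults —
the classification boundaries are not canonical constants — and every
output records the values used. Medians, not means, for robustness to
jackpot insertions.

Fitness values are `log2((y+1)/(ref+1))`; the pseudocount keeps the value
finite at zero counts. The reference for a stressed sample is the median of
the strain's unstressed controls in the same batch when that batch has
controls, else all the strain's controls — strain matching mirrors the
GLM's conditioning on background.

Downstream selection retains, per strain, the union of genes called
conditionally essential by the median rule and genes called
beneficial/detrimental by the GLM local-FDR analysis.

## Negative-binomial GLM with local FDR

Counts for gene l follow NB(μ, φ_l) with Var = μ + μ²/φ_l and the nested
linear predictor above. Dispersion is per gene (per-condition dispersion is
not estimable at quadruplicate depth): method-of-moments from a Poisson
fit, refined by maximizing the Cox-Reid adjusted profile likelihood
(−½ log|XᵀWX| correction) over log φ.

Fitting is an L1-penalized IRLS/coordinate-descent path (statsmodels
elastic-net machinery, L1_wt = 1, intercept unpenalized) over a decreasing
λ grid from just above the entry point of the first coefficient. Each
distinct support on the path is refit unpenalized; BIC selects among the
refits (λ-selection by BIC rather than cross-validation because n per gene
is ~40 and CV folds would be unstable). The refit supplies debiased
coefficients and Wald z-values — penalized coefficients are shrunk and
their z-values are not pivotal, which would distort the pooled null.
Coefficients of interest that fall outside the selected support get their
z-value from a refit of support ∪ {that coefficient}, so every (gene,
family coefficient) contributes one z to the pooling.

Local FDR: z-values of one coefficient family (stress-within-strain, or
level-within-stress) are pooled across genes; the marginal density f(z)
comes from Lindsey's method (Poisson polynomial fit, degree 7, ~90
histogram bins); the empirical null N(μ̂0, σ̂0) and null fraction π̂0 come
from a quadratic fit to log f̂ in the central window (central matching);
lfdr(z) = π̂0 f0(z)/f(z), capped at 1 and forced monotone moving away from
the null center. Calls at lfdr ≤ 0.2 by default: z > μ̂0 → detrimental
(insertions enriched, gene loss helps), z < μ̂0 → beneficial. Below 200
pooled z-values the theoretical null is used and the lfdr degenerates to 1
(no calls), logged — small pools cannot support empirical-null estimation.

## Earth Mover's Distance and synergy tiers

A condition profile is the vector of per-gene replicate-median counts over
the retained gene set. Profiles are compared as unlabeled 1-D
distributions with weight 1/m per point (genes are not paired across
conditions); the Wasserstein-1 distance is computed exactly as
∫|F_P − F_Q|. No normalization is applied by default; a mean-scaling flag
exists and is logged when used. Pairs are ranked within strain and channel;
tiers (low/moderate/high) are tertiles of the within-strain EMD
distribution — an artifact convention for display; the high tier in the
unique channel is the synergy prediction. Ties break lexicographically by
pair label for determinism.

## Model-Y knockoffs

For one strain, the swapped dataset has one row per stressed sample: label
= stress class, features = standardized fitness values of the retained
genes (constant genes dropped with a log entry). Knockoffs are second-order
Gaussian: mean and covariance from Ledoit-Wolf shrinkage (required since
retained genes usually outnumber the ~36 samples; a known covariance can be
supplied), `s` from the equicorrelated rule min(1, 2λ_min) by default or a
coordinate-ascent SDP approximation, and the usual conditional-Gaussian
construction with the cross-covariance target Σ − diag(s). Selection uses
the knockoff+ threshold `τ_q = min{t : (1 + #{W ≤ −t}) / #{W ≥ t} ≤ q}`,
q = 0.1 by default.

The default statistic is W_l = F_l − F̃_l, the difference of one-way
ANOVA F statistics of the feature and its knockoff across stress classes.
Any statistic that flips sign when a feature is swapped with its knockoff
preserves the FDR guarantee; a marginal statistic was chosen as the default
after lasso-path statistics (coefficient difference at the BIC-selected
penalty, entry-λ) proved structurally underpowered at desk scale: the
knockoff+ threshold needs at least ⌈1/q⌉ candidate features, and with ~36
samples a sparse multinomial fit rarely carries that many nonzero
coefficients — selections collapse to empty even when individual planted
genes are individually highly significant. Genes with near-duplicate class
profiles are also conditionally redundant (the 3-class mean space is
low-dimensional), which lasso statistics cannot resolve. The lasso-path
statistics remain available (`statistic="bic_coef_diff"`, with a
density-constrained BIC so the threshold can fire, and
`statistic="entry_lambda"`) for larger designs.

## Hierarchical Gamma-Poisson co-essentiality model

Counts of retained genes follow `y_ijl ~ Pois(Σ_k θ_ijk φ_lk)` with
`φ_lk = T[l, 0]` (essential regime) when `h_lk = 1` else `T[l, 1]`
(nonessential). The T matrix is estimated per gene by a two-component
Gaussian mixture on batch-adjusted unique counts (scikit-learn
GaussianMixture, 2 components, seeded); the smaller mean is the essential
regime, capped at 10 insertions; genes where EM collapses take
min(counts)+ε vs the mean of counts above τ_ess. The deep Gamma prior
θ″_k ~ Γ(ρ0/K, τ), θ′_ik ~ Γ(θ″_k, 1), θ_ijk ~ Γ(θ′_ik, 1) with
ρ0, τ ~ Γ(ε0, ε0) realizes the nonparametric intent at a finite truncation:
the ρ0/K shape shrinks superfluous components toward zero mass. Defaults:
K = 20, ε0 = 0.1, a_l = 0.1 (sparse prior essentiality), 2,000 sweeps with
1,000 burn-in and thinning 5; all in config and echoed in outputs.

One Gibbs sweep: (1) collapsed Bernoulli update of each h_lk comparing the
Poisson likelihood of the observed counts under the two regimes (the
allocation variables are marginal at this point — H is updated before the
allocation step, so no allocation persists across a flip); (2) multinomial
allocation of each count over components with probabilities ∝ θ_ijk φ_lk;
(3) upward pass of Chinese-restaurant-table counts collapsing each Gamma
level against its marginalized negative-binomial representation; (4)
downward conjugate draws of ρ0, θ″, τ, θ′, θ. An update of H conditioned on
allocated counts is also a valid scheme but proved sticky in practice (the
chain settles in a merged mode where components share near-uniform θ and H
empties); the collapsed form escapes it. The whole kernel passes a
Geweke-style joint-distribution test (forward prior draws vs
successive-conditional chain on an L=10 instance, statistics compared with
autocorrelation-adjusted standard errors).

Initialization matters: from a diffuse prior state the merged mode is
self-reinforcing. The default start clusters the per-gene binary
essentiality pattern (mean count below the geometric midpoint of the two T
regimes, per condition) with k-means and warms θ with a few H-frozen
sweeps. This is initialization only; the stationary distribution is
untouched, and `init="prior"` remains available (and is what the
joint-distribution test uses).

Components are exchangeable; summaries align draws to the first retained
draw by Hungarian matching on H. A finite truncation can also split one
gene network across several components with identical essential-gene sets
(atoms are exchangeable and nothing in the likelihood favors merging);
`summarize_components` therefore merges components whose essential-gene
sets overlap at Jaccard ≥ 0.5 (loadings summed, membership averaged with
loading weights, merge logged). Empty components are reported as empty,
never dropped silently, and never merged. Condition loadings are
posterior-mean θ averaged within condition and normalized per condition for
display. Effective sample size of the log-likelihood trace is reported
using the initial-positive-sequence estimator.

## Synthetic data

`simdata.simulate_experiment` draws NB totals with
log-mean = baseline + nested design effects + centered per-(batch, gene)
log factors, and a unique channel as Binomial(total, p_unique = 0.6) —
a thinning model that preserves unique ≤ total by construction (the
total↔unique coupling is not otherwise constrained). Defaults mirror the
study layout: 5 backgrounds × (control + 3 stresses × 3 levels) × 4
replicates in 2 batches; baseline total mean 80 (log-normal spread 0.3),
essential-regime mean 1, conditional effects ±1.6 on the log scale growing
25%/50% at medium/high levels, per-gene dispersion log-uniform on a
configurable range (φ ∈ [0.1, 10] available; test fixtures use narrower
ranges stated per experiment) — per-gene dispersion magnitudes of the real
libraries are not claimed. Class fractions are assigned deterministically
(round(f·L) genes each, placed by a seeded permutation). Conditionally
essential genes form K_true clusters mapped to stresses; a configurable
cluster→stress map lets experiments plant shared vs private essentiality
(used to test the EMD synergy ranking).

What the generator does **not** emulate: insertion-site-level structure
within genes, positional/GC bias, growth dynamics during selection,
library-size drift between conditions, or correlated dispersion across
neighboring genes. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not performance on any real
library.

## Verification experiments and problem sizes

The acceptance suite (tests/test_acceptance.py, scripts/acceptance.py)
recomputes from scratch: the λ=0 GLM against a Nelder-Mead MLE oracle on
5 toy genes (agreement 1e-4); local-FDR calibration on 20 replicates of
5,000 pure-null z (≤1% calls at lfdr ≤ 0.2) and a 10% ±4 mixture
(FDP ≤ 0.25, power ≥ 0.6); knockoff FDR/power over 50 replicates at
r = 200, n = 36, 10 planted predictors with 2-SD class shifts
(mean FDP ≤ q + 2·MC-SE, power ≥ 0.5); the EMD against an LP min-cost
transport oracle on 1,000 random instances (1e-9); Gamma-Poisson recovery
at L = 200, K_true = 2, 6 conditions × 4 replicates (H accuracy ≥ 0.9)
plus the Geweke test at L = 10; batch-shift recovery over 500 genes
(γ̂ within ±0.15 of log 2, residual batch difference < 10%); and a full
pipeline run on an L = 500 single-strain fixture (≥ 90% of planted
conditionally essential calls recovered; the top EMD pair separates the
planted-dissimilar stress). Reduced MCMC settings in the end-to-end fixture
(K = 6, 300 sweeps) are the fixture's own choice of problem size; the
recovery experiments show these suffice at that scale.

## Known limitations

- The classification thresholds and the lfdr cutoff are conventions, not
  estimates; sensitivity to them is the user's responsibility.
- Second-order knockoffs with shrinkage-estimated covariance give
  approximate, not exact, exchangeability; the null simulations bound the
  practical FDR behavior at the simulated scale.
- The Gibbs sampler's truncation K must exceed the number of real networks;
  the shrinkage prior empties extra components but cannot create missing
  ones.
- Batch adjustment assumes batches share the biological design (no
  confounding); confounded designs are rejected rather than guessed at.
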