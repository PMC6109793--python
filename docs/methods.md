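# Methods

`bayesgp` implements a two-stage genomic-prediction analysis for
multi-environment plant breeding trials, of the kind used for agronomic and
forage-quality traits in outbred perennial crops genotyped by sequencing:
first a mixed model distils multi-year plot means into one estimated
breeding value (EBV) per genotype, then Bayesian whole-genome regression
maps those EBVs onto SNP dosages so that breeding values can be predicted
for genotyped-only material. This note records the models, the defaults and
the reasoning behind the choices that were genuinely open.

## Stage 1 — EBV extraction by mixed model

For the plot mean of genotype *i* in environment (year) *t*,

y_it = μ + g_i + e_t + ε_it,  g_i ~ N(0, σ²_g), e_t ~ N(0, σ²_env),
ε_it ~ N(0, σ²_ε),

with all effects independent. Both genotype and environment are random:
with only three years, treating year as fixed would cost little, but the
symmetric random treatment matches how such trials are usually analysed
(an `lmer`-style two-random-effect fit) and keeps the solver uniform.
Plot means, not individual plants, are the observational unit.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations: each iteration solves the equations at the current variance
ratios, updates σ²_g and σ²_env from the sum of squared BLUPs plus their
prediction-error trace, and σ²_ε from the residual sum of squares over
n − 1. Convergence is declared when the REML log-likelihood (computed in
Woodbury form, cheap in the number of genotypes + environments) changes by
less than `tol` (default 1e-8), with at most 1000 iterations and all
variances floored at 1e-10 to avoid singular systems. EM-REML is slower
than average-information REML but is monotone and cannot step outside the
parameter space, which matters when a component is truly near zero (e.g. a
noiseless simulated trait). The solver never assumes balance.

The EBVs are the genotype BLUPs at the converged variances. They are
shrunken genotype-mean deviations, centered by construction, and they are
the *response* of stage 2 — so stage 2 sees data already corrected for
year effects and replication.

Accuracy of the variance components themselves is limited by design, not
by the solver: with three environment levels, σ²_env is estimated with
roughly two degrees of freedom and has a relative sampling SD near 100%.
Tests therefore hold σ²_g and σ²_ε to quantitative recovery bands but only
an order-of-magnitude statement for σ²_env; no amount of implementation
quality could tighten the latter.

## Stage 2 — Bayesian whole-genome regression

With y the EBV vector and Z the column-centered dosage matrix
(dosages count alternate alleles, 0/1/2),

y_i = μ + Σ_j Z_ij α_j + e_i,  e_i ~ N(0, σ²_e).

Three priors on α_j are implemented:

* **BayesA** — α_j | σ²_j ~ N(0, σ²_j), σ²_j ~ ScaledInv-χ²(ν_α, S²_α)
  per locus. Every marker has an effect.
* **BayesB** — with probability π, α_j = 0; otherwise as in BayesA.
  Implemented as stochastic-search variable selection: the indicator δ_j is
  sampled from its Bernoulli full conditional with α_j integrated out (the
  slab-vs-spike marginal-likelihood ratio, computed in log space), rather
  than by the original joint Metropolis–Hastings move; the stationary
  distribution is the same mixture prior. π is sampled by default
  (`pi_fixed` holds it).
* **BayesCπ** — the mixture with one common slab variance σ²_α and π
  unknown with a uniform prior, updated as π ~ Beta(m − k + 1, k + 1) for
  k included markers. The common variance update is
  ScaledInv-χ²(ν_α + k, (ν_α S²_α + Σ_{δ=1} α_j²)/(ν_α + k)).

The sampler is a systematic-scan Gibbs chain with fixed update order —
intercept (flat prior), markers in index order, effect variances, π,
residual variance — so a seed pins the whole trajectory bit-for-bit.
Marker updates use the sufficient statistics r_j = z_j'e + α_j z_j'z_j and
z_j'z_j, avoiding residual-vector restores; the inner loop is plain NumPy,
which keeps a 3000-iteration chain on 300 × 1000 data near ten seconds on
one core.

Defaults are 30,000 iterations, 10,000 burn-in, thinning 20 (1,000
retained draws); chain configuration refuses settings that would retain
fewer than 50 draws. Degenerate mixture weights (π of exactly 0 or 1) are
handled as exact limits, not clamped.

**Hyperparameters.** Degrees of freedom ν_α = ν_e = 5 and scales derived
from an assumed R² = 0.5 split of var(y) between markers and residual:

S²_e = var(y)(1 − R²)(ν_e + 2)/ν_e,
S²_α = var(y) R² (ν_α + 2)/(ν_α · MS_x · (1 − π_init)),

where MS_x is the summed column variance of centered Z. This is the
standard default rule of Bayesian-alphabet software when nothing else is
specified; the (ν + 2)/ν factors make the *prior modes* match the
partition. Prior scales are re-derived per training set during
cross-validation, which makes accuracy invariant to affine rescaling of
the trait.

**Prediction.** GEBV_i = Σ_j (Z_ij − c_j) α̂_j with c_j the *training*
column means and α̂ the posterior-mean effects. The intercept is omitted:
accuracy is a Pearson correlation and indifferent to translation. Dosage
columns are centered but not variance-standardized, keeping effects in
trait-units per allele copy.

**Ridge check.** With π ≡ 0 and both variances held fixed, BayesCπ's
posterior mean is analytically the ridge estimator
(Z'Z + λI)⁻¹Z'y, λ = σ²_e/σ²_α. This equivalence is the package's main
whole-chain oracle (correlation > 0.99, slope within 5% on 100 × 50 data)
and is exposed as `evaluation.ridge_equivalence`.

## Stage 3 — cross-validated accuracy

Accuracy is the Pearson correlation between held-out EBVs and GEBVs.
The default protocol is 10 folds × 10 repeats, where each repeat redraws
the entire random split (fold sizes differ by at most one; the first
n mod k folds take the extra sample). The redraw-per-repeat reading was
chosen because what is repeated is the random sampling of training and
validation sets; `redraw_folds=False` gives the one-split alternative.
Folds with an undefined correlation (zero variance on either side) are
dropped from the means with a warning and counted, rather than scored
zero, to avoid biasing the mean. Seeding uses one root `SeedSequence`
with spawned streams per repeat and per fold, so results are reproducible
yet folds are independent.

## The synthetic-data generator

The generator emulates the *structure* of a GBS panel of a few hundred
outbred genotypes scored as plot means over ~3 years: unlinked biallelic
SNPs with allele frequency p_j ~ U(maf_low, maf_high) (defaults
0.05–0.5), dosages Binomial(2, p_j), optional uniform missingness;
spike-and-slab marker effects (π_true = 0 "polygenic", 0.9 "sparse");
year effects N(0, env_sd²); residual noise scaled so that
var(bv)/(var(bv) + σ²_ε) equals the target h² at the plot-mean,
within-environment level. Defaults (322 genotypes, 3 environments, 2,000
markers) mirror the scale of a real diversity panel, with the marker count
scaled down from the tens of thousands a GBS pipeline yields because
unlinked simulated markers carry far more information per marker than
LD-redundant real ones.

What it deliberately does **not** emulate: linkage disequilibrium,
population/accession structure, genotype × environment interaction,
tetraploid dosage, and informative missingness. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not field performance on a structured tetraploid panel — on real
data, accuracy is also shaped by LD decay and relatedness between training
and validation sets, which k-fold CV on a structured panel partly absorbs.
Genotype coding is diploidized {0,1,2} throughout, matching what tag-based
GBS SNP callers emit for autotetraploids; true tetraploid dosage (0–4)
is out of scope.

Missing-call imputation is per-marker mode (ties toward the smaller
dosage): a deliberately simple, deterministic utility — not a
reimplementation of kNN-style GBS imputers — adequate for the low
missingness the simulator produces.

## Evaluation studies and problem sizes

`bayesgp.evaluation` packages the validation protocol: kernel moment
checks at 20,000 draws; ridge equivalence at n=100, m=50; the Henderson
brute-force oracle on a 4 × 2 table; sparse recovery at n=300, m=1000,
π=0.9, h²=0.5 with 3,000-iteration chains (median over 5 replicates);
a heritability sweep at h² ∈ {0.1, 0.5, 0.9} (one shared 300 × 150 panel,
5 traits per level, 10-fold CV with 800-iteration chains); a noiseless
(h²=1, m<n) and a null trait; and a three-method agreement study on a
polygenic trait. Chain lengths in the simulation studies are shortened
from the 30,000-iteration default — several hundred retained draws put
Monte Carlo error well inside every decision band, and the studies stay
in the minutes range on a single core. `scripts/acceptance.py` reruns all
of them from scratch and writes the numbers as JSON.

## Known limitations

* EM-REML convergence is slow near variance boundaries; the iteration cap
  (1000) is reported via `converged` rather than raised.
* Single-chain inference only; no formal convergence diagnostics beyond
  the stored π/σ²_e/μ traces.
* The spike-and-slab marginal-likelihood ratio assumes one marker updated
  at a time; heavily collinear marker pairs mix slowly, as with all
  single-site Gibbs samplers of this family.
* `pearson_accuracy` requires ≥ 3 held-out genotypes and nonzero variance;
  degenerate folds are dropped, not imputed.
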