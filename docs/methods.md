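# Methods

## Model

`ibag` relates a clinical outcome to gene expression while attributing
expression changes to promoter DNA methylation or to other regulatory
mechanisms. It is a two-layer hierarchical regression.

**Mechanistic layer.** For gene k with J_k promoter methylation probes
(beta-values M_(k), mean-centered),

    g_k = M_(k) ω_k + m̄_k,        m̄_k ~ N(0, σ_k² I_N),

so centered expression splits exactly into a methylation-modulated
component M_(k)ω_k and a residual component m̄_k driven by other
mechanisms (copy number, microRNA, ...). Genes with no mapped probe
contribute their whole centered expression as an "other mechanisms"
predictor.

**Clinical layer.** With clinical covariates X (effects γ) and the two
expression components as predictors,

    Y = X γ + Σ_k β^M_k (M_(k) ω_k) + Σ_k β^M̄_k m̄_k + ε,   ε ~ N(0, σ² I_N).

β^M_k is the *type M* effect of gene k (outcome effect of the
methylation-modulated expression), β^M̄_k the *type M̄* effect. Binary
outcomes use probit data augmentation (latent Z ~ N(Xγ + ..., 1),
thresholded at 0); right-censored survival outcomes use a log-normal
accelerated failure time model with truncated-normal imputation of the
censored log-times.

**Priors.** The β coefficients carry Bayesian lasso
(double-exponential) priors written as scale mixtures of normals:
β_p | σ², τ²_p ~ N(0, σ²τ²_p), τ²_p ~ Exp(λ²/2), with separate
shrinkage parameters λ_M, λ_M̄ for the two blocks and Gamma(α, ξ)
hyperpriors (shape/rate, both 1 by default) on the squared shrinkage
parameters. γ is N(0, v_γ) with v_γ = 10⁶ (effectively flat for
unit-scale covariates); ω_jk is N(0, v_ω) with v_ω = 10² on centered
data when J_k < N, and gets its own lasso prior when J_k ≥ N. Error
variances σ², σ_k² carry the improper 1/σ² prior by default; an
optional proper inverse-gamma prior (shape/rate in `HyperConfig`) is
available and is required by the joint-distribution diagnostic in the
test suite.

Everything is conditionally conjugate, so estimation is a
systematic-scan Gibbs sampler (fixed update order: ω blocks, γ, β
blocks, τ², λ², σ² and σ_k², latents). The fixed order makes runs
reproducible draw-for-draw from the seed; correctness does not depend
on it.

## Model variants

* `unified` — the joint sampler above; clinical information feeds back
  into ω_k. The ω_k conditional combines the mechanistic likelihood,
  the clinical likelihood (through the channel
  (β^M_k − β^M̄_k)·M_(k)ω_k after absorbing β^M̄_k g_k), and the prior.
* `two_stage` — per-gene OLS first, then the clinical Bayesian lasso
  on the frozen partition.
* `nonint` — expression-only Bayesian lasso (single λ).
* `add` — Bayesian lasso on [expression | methylation] with a separate
  λ for the methylation block.
* `sg` — per-gene classical regression (outcome on the gene's
  expression, its probes, covariates), F-test for continuous outcomes,
  likelihood-ratio tests under probit (binary) or log-normal AFT
  (survival) otherwise.

## Gene selection

The lasso prior shrinks but never zeroes coefficients, so selection
uses per-draw *conditional MAP* estimates: conditional on draw s's
ω, γ, λ_M, λ_M̄, σ and latent Z, the posterior mode of (β^M, β^M̄)
minimizes

    ‖r − D_M b_M − D_M̄ b_M̄‖² + 2σλ_M‖b_M‖₁ + 2σλ_M̄‖b_M̄‖₁,

(the −2σ²·log conditional posterior up to constants), which is exactly
sparse. The two penalty levels are folded into one by rescaling
columns (d_j ← d_j/λ_j, b_j ← λ_j b_j) and the single-penalty problem
is solved exactly on the least-angle-regression homotopy path
(`sklearn.LassoLars`; weights below 1e−10, or σ below it, fall back to
OLS). The per-gene, per-type posterior inclusion probability p is the
frequency of a non-zero estimate across draws; 1 − p estimates the
local false discovery rate. Given target FDR α, probabilities are
sorted descending and the longest prefix whose mean (1 − p) is ≤ α
sets the cutoff φ_α; selection is inclusive at ties (p ≥ φ_α). With
ties exactly at φ_α the selected-set average can exceed α even though
the defining prefix satisfies it; the test suite checks the prefix
property.

γ is held at the draw's value inside the conditional-MAP problem
rather than refit; "conditional on all other parameters" is read
literally, and refitting would only perturb the intercept-like part of
the residual.

## Numerical choices

* **Centering.** Expression, methylation and covariate columns are
  mean-centered; a continuous outcome is centered too (no intercepts).
  Binary/survival fits keep an explicit intercept in the γ block
  because the latent response mean is not removed by centering.
* **Column standardization.** Clinical lasso design columns are scaled
  to unit L2 norm. One shrinkage parameter per block is only
  exchangeable across columns of comparable scale, and the Gamma(1, 1)
  hyperprior on λ² presumes a normalized design. For the integrative
  models the norms come from the stage-1 OLS partition and are then
  held fixed, so the scaling remains a pure (fixed diagonal)
  reparameterization even while ω moves. Draws are stored on the
  standardized basis; `summary()` reports effects on the original
  scale. Disable with `McmcConfig(standardize=False)`.
* **Initialization.** Coefficients 0, σ² = var(response), τ² = 1,
  λ² = 1, ω and σ_k from stage-1 OLS — the chain settles within a few
  hundred scans at desk scale.
* **Degenerate mechanistic fits.** An exact per-gene fit floors σ̂_k at
  1e−8 (with a warning) so the downstream variance conditionals stay
  proper; rank-deficient probe designs use the minimum-norm solution
  with a warning, or raise under `strict=True`.
* **Truncated normals** are drawn via `scipy.stats.truncnorm`, which
  is robust eight-plus standard deviations into the tail (tested).
* **Empty blocks are dropped** from the update path, so the unified
  model with zero mapped probes and the additive model with J = 0
  reduce to the non-integrative fit draw-for-draw at equal seeds.
* **Promoter mapping** uses 0-based half-open (BED) coordinates and a
  strand-aware TSS window of 1500 bp upstream / 500 bp downstream by
  default (configurable); a probe maps to every gene whose window its
  interval intersects. Complete-case analysis: validation intersects
  samples across all tables, ordered as in the outcome table.

## Synthetic data generator

`simulation.simulate_dataset` emulates a two-platform tumor cohort:
N = 200 patients; K genes (grid 400–1000) of which the first J = 200
carry one promoter probe each; methylation ~ Uniform(0, 1) (the
empirical beta-value spread of a heterogeneous cohort); regulated-gene
expression slope·m + N(0, σ_m²) with slope −1 (methylation represses
transcription); unregulated expression N(0, 1). σ_m comes from the
closed form σ_m = |slope|·√((1/ρ² − 1)/12), targeting
methylation–expression correlation ρ ∈ {−0.8, −0.6, −0.4}; the grid of
four K values by three ρ values gives twelve scenarios. Three disjoint
20-gene truth groups drive the outcome: group 1 (first mapped genes)
type-M effects only, group 2 (first unmapped genes) type-M̄ only,
group 3 (last mapped genes) both; default effect sizes
b_M = b_M̄ = 1 and outcome noise σ_y = 1. Survival outcomes exponentiate
the linear predictor plus noise; censoring times are drawn from the
same distribution shifted by −√2·σ_y·Φ⁻¹(q) so the censoring fraction
hits the target q (default 0.3) in closed form.

What the generator does **not** emulate: probe-level measurement error
structure, correlated methylation between neighboring probes,
multi-probe promoters (one probe per mapped gene), heavy-tailed or
batch-structured expression, and non-linear methylation–expression
relationships. Passing tests therefore demonstrate correctness of the
machinery and behavior under the idealized generative model, not
performance on real array data.

## Problem sizes used in the automated checks

The replicated acceptance experiments run a desk-scale rendition of
the simulation study: N = 200 kept at full scale, K = 100 genes with
J = 40 methylation-measured, ρ = −0.6, chains of 1,200 iterations
(400 burn-in, thin 4), 10 replicates for the power comparison and 20
for FDR calibration; `scripts/acceptance.py` uses 3 replicates per
quantity. These sizes keep a full run in minutes on one CPU while
preserving the qualitative regime of the full-scale study, with one
caveat noted below.

## Known limitations

* With K and J reduced while the 20-gene truth groups stay at full
  size, 60 of 100 genes carry signal — a far denser signal than the
  full-scale study (60 of 400–1000). The shrinkage parameters adapt to
  total signal mass, so the per-draw conditional-MAP estimates are
  denser than at full scale and the empirical inclusion probabilities
  become nearly 0/1 for a continuous outcome (the per-draw active set
  is driven mostly by the fixed noise alignment in y; only ω, λ, σ
  jitter across draws). Consequently the BFDR rule — which treats the
  empirical frequencies as calibrated local FDRs — is anti-conservative
  in realized false-discovery terms in this regime, and its realized
  FDP on replicated desk-scale data exceeds the nominal α (=0.2)
  substantially. The corresponding acceptance check is left failing
  rather than recalibrated: the FDR statement is exact only as a
  model-based identity on calibrated probabilities, and the replicated
  study here scores it by realized FDP against ground truth. Ranking
  power (group-detection AUC) is much less affected; the comparative
  claim — the unified model dominating the non-integrative model for
  methylation-driven genes — is robust in every run we performed.
  Latent-response outcomes (binary/survival) re-randomize the
  conditional-MAP problem every draw and spread the probabilities.
* The per-block shrinkage parameter is global; a gene with many strong
  neighbors is shrunk more than in a sparser panel.
* The AFT latent scale is the clinical σ (shared), and the probit
  latent variance is fixed at 1 for identifiability.
* `fit_sg` refits lifelines AFT models gene by gene; it is the slowest
  comparator at large K.
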