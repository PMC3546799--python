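# ibag — integrative Bayesian analysis of expression, methylation and clinical outcome

`ibag` is a toolkit for finding outcome-associated genes by modeling
gene expression and promoter DNA methylation *jointly* instead of as
competing predictor lists. It is aimed at statistical-genomics
analysts working with matched multi-platform tumor profiles (e.g.
expression arrays plus methylation beta-values plus survival).

The core is a two-layer hierarchical Bayesian model. A **mechanistic**
layer regresses each gene's (centered) expression on the methylation
probes mapped to its promoter,

    g_k = M_(k) ω_k + m̄_k,        m̄_k ~ N(0, σ_k² I),

splitting expression into a methylation-modulated component M_(k)ω_k
and a component m̄_k driven by other mechanisms. A **clinical** layer
then regresses the outcome on *both* components of every gene plus
clinical covariates,

    Y = X γ + Σ_k β^M_k (M_(k)ω_k) + Σ_k β^M̄_k m̄_k + ε,

under Bayesian lasso (normal–exponential scale-mixture) priors with
separate shrinkage parameters λ_M, λ_M̄ for the two effect types.
β^M_k is gene k's *type M* effect (acting through methylation), β^M̄_k
its *type M̄* effect (acting through other mechanisms). Everything is
conditionally conjugate and fit by Gibbs sampling; binary outcomes use
probit augmentation and right-censored survival times a log-normal AFT
model with truncated-normal imputation. Genes are selected by
per-draw conditional-MAP lasso estimates: the frequency p with which a
coefficient is non-zero across draws is its posterior inclusion
probability, and a sorted-probability threshold φ_α controls the
average Bayesian FDR at a target α.

The package also implements the comparator models used in the
accompanying simulation study (two-stage, non-integrative, additive
and single-gene fits), a synthetic-data generator with known truth,
and evaluation metrics (per-group ROC/AUC, Harrell's concordance
index, realized false-discovery proportion).

## Worked example

Simulate one replicate of the study design at desk scale, fit the
unified model, and select genes at FDR 0.2:

```sh
ibag simulate --out-dir data --n 200 --k 100 --j 40 --rho -0.6 --seed 1
ibag fit      --data-dir data --out-dir fit --model unified \
              --iterations 1200 --burnin 400 --thin 4 --seed 1
ibag select   --fit-dir fit --data-dir data --alpha 0.2
```

which prints

```
selected 140 effects at FDR 0.2 (threshold 0.000)
```

`fit/summary.tsv` holds one row per (feature, effect type) with the
posterior mean, SD and 95% interval of the effect on the original data
scale, e.g.

```
feature    type  mean   sd     q2.5    q97.5
gene_0001  m     0.407  0.383  -0.367  1.152
gene_0002  m     1.316  0.466   0.352  2.092
```

(the generative type-M effect of both genes is 1.0), and
`fit/selection.tsv` holds the per-gene, per-type inclusion
probabilities with the selection flag, target α and threshold. The
planted genes (the simulator writes them to `data/truth.tsv`) sit at
inclusion probability ≈ 1 and ranking by probability recovers the
truth groups; the all-inclusive selection printed above — 60 of the
100 genes carry signal at this reduced scale, which drives the
adaptive shrinkage down and makes the per-draw MAP estimates dense —
is a real caveat of the probability-threshold rule in dense-signal
regimes, quantified in `docs/methods.md` (Known limitations).

Every command records a `manifest.json` (config, seed, input hashes);
re-running with the recorded seed reproduces outputs byte-for-byte.
The same pipeline is available as a library (`ibag.simulate_dataset`,
`ibag.run_unified`, `ibag.select_genes`, ...), and
`ibag benchmark --out-dir bench` runs the four-model detection
comparison on replicated synthetic data.

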