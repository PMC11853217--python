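# methmix

Differential-methylation analysis for bisulfite-sequencing count data with a
penalized trans-dimensional hidden Markov model, followed by sparse
finite-mixture accelerated-failure-time (AFT) survival modelling of the genes
whose promoters change. The package is aimed at statistical genomicists who
want the full two-stage pipeline — simulate, smooth, call, annotate, model
survival — runnable and testable on synthetic data with known truth.

## The models

**Stage 1 — smoothing and DMC calling.** For one sample, the methylated read
count at CpG `l` with depth `m_l` is

    y_l | s_l = k  ~  Binomial(m_l, θ_k),       θ_1 < … < θ_K,

where the hidden state path `s` follows a first-order Markov chain with
initial/transition probabilities `p`. The order `K` is unknown:
`K ~ Uniform{1,…,K_max}`, `θ_k ~ Beta(α,β)`, transition rows
`~ Dirichlet(γ)`. A reversible-jump MCMC samples `(K, θ, p, s)` jointly —
conjugate Gibbs sweeps, forward-filtering backward-sampling for the path, and
a split–merge move for the order, accepted by the Metropolis–Hastings ratio
`min{1, likelihood × prior × proposal ratio}`. Two penalties steer the order:
states with `|θ_i − θ_j| < δ` are collapsed (over-fit control), and the
split-proposal weight is boosted while the within-state binomial deviance
exceeds its parametric-bootstrap reference (under-fit control). Missing
entries contribute likelihood factor 1, so partially observed positions are
never dropped; depths above 500 are masked at load as PCR artefacts. The
per-position fitted level is the posterior mean of `θ_{s_l}`; a conjugate
two-group linear model on logit fitted levels gives per-CpG p-values, and
Benjamini–Hochberg control at FDR 0.05 yields hyper/hypo calls
(case − control). Promoter DMCs roll up to differentially methylated genes
(DMGs).

**Stage 2 — survival.** With right-censored times `t_i` (event indicator
`δ_i`) and centred promoter-methylation covariates `x_i`, log survival time
follows a K-component mixture of log-normal AFT regressions,

    ℓ(Ψ) = Σ_i log Σ_k π_k f(log t_i; x_iβ_k, σ_k²)^{δ_i} S(log t_i; x_iβ_k, σ_k²)^{1−δ_i},

maximized under the sparsity penalty `n Σ_k π_k Σ_j p_λ(|β_kj|)` by a
penalized EM (censored latent log-times imputed by truncated-normal moments;
coordinate-descent soft-thresholding with lasso/adaptive-lasso/SCAD/MCP).
`K` is chosen by BIC. Before fitting, covariates are screened by
correlation-adjusted regression survival (CARS) scores: IPC-weighted
correlations with log time after decorrelating the design by `R^{−1/2}`.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
with known truth and write their tables under `results/`:

```
python analysis/01_simulate_data.py
python analysis/02_smooth_methylation.py
python analysis/03_call_dmcs.py
python analysis/04_annotate_genes.py
python analysis/05_survival_mixture.py
```

Representative output:

```
panel: 800 CpGs x 20 samples, 30% missing, 8.2% of positions in DMC blocks
posterior modal orders per sample: [4, 4, 4, 5, 4, 5, 4, 3, 3, 4, ...]
35 DMCs of 800 CpGs (35 hyper, 0 hypo)
against truth: sensitivity 0.515, realized FDR 0.029
direction concordance on true positives: 1.000 hyper (injected shift is +1.5 logit units)
2 DMGs (2 hyper, 0 hypo, 0 mixed)
survival-time density has 2 mode(s) -> mixture modelling
BIC selects K = 2
component intercepts: [1.69 5.21], sigmas [0.94 1.  ], pi [0.39 0.61]
active effects (gene, component, beta): [('CDH11', 1, -3.62), ('EPB41L3', 1, 2.06),
  ('DOCK2', 1, -3.65), ('TMEM215', 2, -2.9), ('PPP1R14A', 2, -2.37),
  ('GPR158', 2, 1.67), ('NAPSB', 2, -2.57), ...]
```

Reading this: the sampler recovers a 3–5 state methylation landscape per
sample; calls at 5% FDR are direction-correct with realized FDR under the
nominal level; and the survival stage recovers the generating two-component
structure — the short-survival component (intercept ≈ 1.7) carries CDH11,
EPB41L3 and DOCK2, the long-survival component (intercept ≈ 5.2) carries
TMEM215, PPP1R14A, GPR158 and NAPSB, matching the generating coefficients.

The same pipeline is available as a CLI (`methmix all --out run --seed 7`)
with per-stage subcommands, content-hash caching and YAML configs.

## Layout

- `src/methmix/` — library: `simulate`, `hmm`, `dmc`, `annotation`,
  `survival`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers (see above)
- `tests/` — pytest suite, including end-to-end acceptance checks
- `docs/methods.md` — modelling assumptions, algorithm details, design
  choices and known limitations
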