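# Methods

## Scope and data model

The package analyses two-group (case/control) bisulfite-sequencing count
panels: per CpG and sample, a methylated read count and a read depth, with
heavy partial missingness. Depths above 500 are masked at load time as
PCR-bias artefacts. Internally states are 0-based, genomic positions 1-based
in tables, and annotation intervals 0-based half-open (BED dialect).

## Trans-dimensional HMM smoothing

Each sample is smoothed by its own chain (the per-sample reading of the
model; profiles are never pooled across samples). Counts are binomial given
a hidden methylation state with propensity `θ_k`; the state path is Markov.
Priors: `K ~ Uniform{1..K_max}` (default `K_max = 10`), `θ_k ~ Beta(1,1)`,
Dirichlet(1) transition rows, all fixed for determinism. Missing sites have
emission factor 1, which is exactly marginalization — the forward recursion
passes probability through unchanged, and a fully missing site does not
change the marginal likelihood.

One iteration = conjugate Gibbs sweep (θ | s, p | s, then s | θ,p by
forward-filtering backward-sampling), the two penalties, then one
reversible-jump split–merge move. Thetas are kept sorted ascending with
states relabelled; this resolves label switching and makes posterior means
of `θ_{s_l}` well defined.

### Split–merge proposal

The proposal distribution is not fully determined by the model, so it is a
design choice of this package, made for mixing and verified against
marginal-likelihood oracles:

- **Split**: choose a state `j` uniformly; draw `u ~ Uniform(0, u_max)` with
  `u_max` half the gap to `j`'s neighbouring thetas (clipped to keep both
  offspring inside (0,1)); replace `θ_j` by `θ_j − u, θ_j + u`. Sites of `j`
  are reallocated to the two offspring with probability proportional to
  their binomial emissions (this reduces to a fair coin as `u → 0`); the
  realized allocation probability enters the proposal density exactly.
  Transition rows for the K+1 model are drawn from their Dirichlet full
  conditional given the proposed path, with the Dirichlet densities in both
  proposal directions included in the ratio. The continuous map
  `(θ, u) → (θ−u, θ+u)` contributes Jacobian 2.
- **Merge**: choose an adjacent-in-theta pair uniformly (probability
  `1/(K−1)`, in the ratio) and replace it by its midpoint — the exact
  inverse of the split — with sites relabelled deterministically and
  transition rows redrawn from the Dirichlet full conditional.

Earlier variants (uniform Bernoulli(½) reallocation; a global min-gap bound
on `u`; a deterministic smallest-gap merge pair) were rejected because they
provably made supported configurations unreachable: the reverse of a wide
split could never be proposed, so such splits were always rejected and the
sampler could not reach states the data favoured by tens of nats.

### Penalties

- **Over-fit control**: after each sweep, any adjacent theta pair closer
  than `collapse_tol` (default `δ = 0.02` on the theta scale) is merged
  deterministically (occupancy-weighted mean; transition rows combined by
  column sums and occupancy-weighted row means).
- **Under-fit control**: the within-state binomial deviance is compared with
  the 95th percentile of its parametric-bootstrap null (default 50
  replicates, recomputed every 10 sweeps); while it exceeds the reference,
  the split-move weight is multiplied by `underfit_penalty_weight`
  (default 2).

### Initialization and seeding

Chains start rich: up to six initial states at empirical quantiles of the
observed ratios (pruned to respect the collapse tolerance), sticky initial
transitions, nearest-theta state assignment. Merging spurious states is far
easier for the sampler than splitting new ones out, so this accelerates
convergence without changing the target. Per-sample seeds derive from the
master seed by a fixed affine map, so panels are reproducible bit-for-bit.

Chain defaults are `n_iter = 5000, burn_in = 2000, thin = 5`. The test and
analysis runs use shorter chains (300–600 iterations, burn-in half) at
panel sizes of 200–2000 positions; order recovery and smoothing gains are
stable at these sizes, which keeps the full suite comfortably desk-scale.

## DMC calling

Fitted levels (posterior means of Beta-supported propensities, hence
strictly inside (0,1)) are logit transformed. Each CpG gets a conjugate
two-group normal linear model with a Zellner-style weak prior (`g = n`):
the reported effect is the shrunk posterior-mean contrast
(case − control, factor `g/(1+g)`), and the p-value refers the posterior t
statistic to its exact null law — equivalent to the classical t reference —
so the null calibration is exact, which the suite checks by
Kolmogorov–Smirnov on null panels. CpGs with fewer than two usable samples
in either group are flagged untestable and excluded from the
Benjamini–Hochberg family (assigning them p = 1 would deflate the q-values
of real signals). Benjamini–Yekutieli is available by flag.

## Genomic annotation and accounting

Contexts are assigned by precedence promoter > island > shore > shelf >
exon > intron > intergenic via interval trees (verified against a
brute-force scan). Genes whose genic intervals sit on both strands or on
multiple reference sequences are dropped at load. A gene is a DMG when at
least `min_promoter_dmcs` (default 1 — the minimal reading of "gene with a
differentially methylated promoter") of its promoter CpGs is significant;
gene direction is the majority of significant promoter CpGs, ties "mixed".
Agreement tables, overlap/direction summaries and Venn counts are exact
integer arithmetic; every percentage recomputes from the stored counts.

## Survival stage

**CARS screening.** The design is standardized and decorrelated by
`R^{−1/2}` using the Schäfer–Strimmer shrinkage of the correlation matrix
toward the identity (analytic intensity from the data products; with an
orthonormal design and no censoring this is the identity, and scores reduce
to squared Pearson correlations). Relevance is the squared IPC-weighted
correlation with log observed time; the Kaplan–Meier censoring-survival
estimate is truncated below at 0.2 — the usual IPCW stabilization — so late
events cannot receive explosive weights. The top `ceil((1−q)·d)` covariates
by score are selected (default q = 0.95).

**Penalized mixture-AFT EM.** All likelihood evaluation happens on the
log-time scale; the 1/t Jacobian of the log transform is constant in the
parameters and dropped, so BIC comparisons across K are unaffected. E-step:
posterior memberships from `π_k f^δ S^{1−δ}`, plus truncated-normal
conditional mean and variance of the latent log-time for censored subjects
within each component. M-step: the mixing weights maximize the
penalty-aware simplex problem (`π_k ∝ t_k/(μ + n c_k)` with `μ` solved by
root finding); per component, coordinate-descent soft-thresholding solves
the penalized weighted least squares (adaptive-lasso weights from an
unpenalized pilot fit; SCAD `a = 3.7` and MCP via local linear
approximation, which majorizes the penalty so the penalized objective is
monotone across iterations — asserted in the tests); `σ_k` closed form
including the censored-variance term. Coefficients below `zero_tol = 1e−5`
are set exactly to zero. `σ_k` is floored at 0.05: log-normal mixtures have
the classic unbounded-likelihood degeneracy (a component collapsing on a few
points drives `σ → 0` and BIC monotonically down in K), and the floor
removes it without affecting interior solutions.

λ is chosen on a grid by BIC — first a common λ, then one component-wise
refinement sweep over the same grid (the component-wise reading of
BIC-driven tuning). `K` is selected by BIC over `K = 1..7` with k-means
multi-start initialization on (log t, δ); components are reported in
ascending-intercept order, so component 1 is the short-survival
subpopulation. `BIC = −2ℓ + df·log n` with
`df = #nonzero β + K intercepts + K sigmas + (K−1) mixing weights`;
intercepts are per-component and unpenalized.

## Synthetic data generator

The generator produces exactly the structure the pipeline assumes:

- One hidden Markov state path per chromosome, shared by all samples — the
  common methylation landscape; counts are conditionally independent
  binomials given the path.
- Negative-binomial depths (mean 30, dispersion 5 by default) hard-capped at
  500 to mirror the load-time filter.
- Independent Bernoulli missingness per (position, sample), default 30%.
  Real missingness is coverage-driven and spatially structured; independence
  is the simplest mechanism consistent with the observed missingness rates,
  and the data provenance records it.
- Differential methylation in Markov blocks (mean run length 5, stationary
  frequency `dmc_fraction`), shifting the case-group propensity by
  `effect_size` on the logit scale — differential methylation is regionally
  coherent, and block injection is what a region-aware smoother should be
  tested against. The generating path, flags and memberships are retained
  for recovery scoring.
- Survival data: component membership Categorical(π), log-time
  `intercept_k + xβ_k + σ_k ε`, exchangeable covariate correlation, and
  exponential censoring whose rate is solved numerically to hit the target
  censoring fraction. The reference generator uses the fitted two-component
  coefficients (three active genes in the short-survival component, four in
  the long-survival component, twelve inactive), `σ = 1`, ρ = 0.3, π =
  (0.4, 0.6) — the mixing weights are not part of the published fit, and
  (0.4, 0.6) matches the reported pattern of a smaller aggressive
  subpopulation.

What the generator does not emulate: read-level bisulfite chemistry, strand
effects, realistic CpG spacing, coverage-driven missingness, or
batch/covariate structure in survival. Green tests therefore demonstrate
correctness of the algorithms under the stated generative assumptions, not
performance on any particular real cohort.

## Known limitations

- Per-sample smoothing attenuates weak contrasts near the propensity
  boundary: a +1.5-logit shift of a `θ = 0.9` state lands at 0.976, worth
  only ~1 nat per position at depth 30, and a single sample's posterior can
  legitimately prefer the merged state — those DMCs are then invisible to
  the downstream test. The sensitivity acceptance check measures this
  honestly; detection of interior-state DMCs is high while
  boundary-state detection is poor, and the overall figure depends on the
  state landscape. This is a property of per-sample smoothing at moderate
  depth, not of the sampler (verified against marginal-likelihood oracles).
- Split–merge acceptance rates are low (<1%) once chains reach a supported
  order; order mixing relies on the rich initialization plus the collapse
  penalty, which the order-recovery tests exercise directly.
- The mixture-AFT membership accuracy is bounded by the Bayes classifier
  under the generating overlap; with the reference coefficients the
  components overlap substantially through the covariate effects, so hard
  labels cannot be near-perfect for any method.
- CARS screening with few events or near-deterministic censoring patterns
  inherits IPCW instability; the 0.2 truncation trades a small bias for
  bounded variance.
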