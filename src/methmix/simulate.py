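"""Synthetic bisulfite-count panels and censored survival data.

The generators reproduce the statistical structure the downstream stages
assume: a hidden Markov path of methylation states shared by all samples of a
chromosome (the biological methylation landscape), binomial read counts given
negative-binomial depths, heavy independent partial missingness, a two-group
case/control design with differential methylation injected on the logit scale,
and a finite mixture of censored log-normal accelerated-failure-time (AFT)
regressions with sparse coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import DEPTH_CAP, MethylationPanel, TruthRecord, ValidationError


@dataclass
class PanelSimSpec:
    """Generating configuration for a two-group methylation count panel."""

    n_positions: int = 2000
    n_samples_per_group: int = 10
    true_order: int = 3
    true_thetas: tuple = (0.1, 0.5, 0.9)
    transition_matrix: np.ndarray | None = None   # K* x K*, row-stochastic
    initial_probs: np.ndarray | None = None
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0                 # NB size parameter; smaller = heavier tail
    missing_rate: float = 0.3
    dmc_fraction: float = 0.1
    dmc_run_length: float = 5.0                   # mean run length of DMC blocks (DMR-like)
    effect_size: float = 1.5                      # logit-scale shift of case-group theta at DMCs
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        K = self.true_order
        if K < 1:
            raise ValidationError("true_order must be >= 1")
        self.true_thetas = np.asarray(self.true_thetas, dtype=float)
        if self.true_thetas.shape != (K,):
            raise ValidationError("true_thetas must have length true_order")
        if np.any(self.true_thetas <= 0) or np.any(self.true_thetas >= 1):
            raise ValidationError("true_thetas must lie in (0,1)")
        if np.any(np.diff(self.true_thetas) <= 0):
            raise ValidationError("true_thetas must be strictly increasing")
        if self.transition_matrix is None:
            # sticky chain: stay with prob .9, leave uniformly
            T = np.full((K, K), 0.1 / max(K - 1, 1))
            np.fill_diagonal(T, 0.9 if K > 1 else 1.0)
            self.transition_matrix = T
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (K, K):
            raise ValidationError("transition_matrix must be K x K")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValidationError("transition_matrix rows must sum to 1")
        if self.initial_probs is None:
            self.initial_probs = np.full(K, 1.0 / K)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        if self.initial_probs.shape != (K,) or np.any(self.initial_probs < 0) or abs(
            self.initial_probs.sum() - 1.0
        ) > 1e-12:
            raise ValidationError("initial_probs must be a simplex vector of length K")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0,1)")
        if not (0.0 <= self.dmc_fraction <= 1.0):
            raise ValidationError("dmc_fraction must be in [0,1]")


def _markov_flags(L, fraction, run_length, rng):
    """Blocky DMC indicator with stationary frequency ``fraction`` and mean
    run length ``run_length`` (differential methylation is regionally
    coherent, as in differentially methylated regions)."""
    if fraction <= 0.0:
        return np.zeros(L, dtype=bool)
    if fraction >= 1.0:
        return np.ones(L, dtype=bool)
    p10 = min(1.0 / max(run_length, 1.0), 1.0)          # leave a DMC run
    p01 = min(fraction * p10 / (1.0 - fraction), 1.0)   # enter a DMC run
    flags = np.empty(L, dtype=bool)
    u = rng.random(L)
    flags[0] = u[0] < fraction
    for l in range(1, L):
        flags[l] = u[l] < (1.0 - p10 if flags[l - 1] else p01)
    return flags


def simulate_panel(spec: PanelSimSpec) -> tuple[MethylationPanel, TruthRecord]:
    """Draw a two-group count panel plus the generating truth.

    The hidden state path is drawn once from the Markov chain and shared by
    every sample; control counts are Binomial(depth, theta_state); at injected
    DMC positions the case-group propensity is shifted by ``effect_size`` on
    the logit scale. Depths are negative-binomial hard-capped at the standard
    depth filter; entries go missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    L, K = spec.n_positions, spec.true_order
    n_per = spec.n_samples_per_group
    n = 2 * n_per

    # hidden path
    states = np.empty(L, dtype=np.int64)
    states[0] = rng.choice(K, p=spec.initial_probs)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random(L)
    for l in range(1, L):
        states[l] = np.searchsorted(cum[states[l - 1]], u[l])

    dmc_flags = _markov_flags(L, spec.dmc_fraction, spec.dmc_run_length, rng)
    theta_control = spec.true_thetas[states]
    theta_case = theta_control.copy()
    theta_case[dmc_flags] = expit(logit(theta_control[dmc_flags]) + spec.effect_size)

    # depths: negative binomial with mean mu and size r, capped
    r = spec.depth_dispersion
    p_nb = r / (r + spec.depth_mean)
    depths = rng.negative_binomial(r, p_nb, size=(L, n))
    depths = np.minimum(depths, DEPTH_CAP)

    theta_mat = np.empty((L, n))
    theta_mat[:, :n_per] = theta_case[:, None]
    theta_mat[:, n_per:] = theta_control[:, None]
    counts = rng.binomial(depths, theta_mat)

    missing = rng.random((L, n)) < spec.missing_rate
    counts = np.where(missing, 0, counts)
    depths = np.where(missing, 0, depths)

    gaps = rng.integers(2, 200, size=L)
    positions = np.cumsum(gaps)

    sample_ids = [f"case_{i+1:02d}" for i in range(n_per)] + [
        f"control_{i+1:02d}" for i in range(n_per)
    ]
    labels = ["case"] * n_per + ["control"] * n_per
    panel = MethylationPanel(spec.chrom, positions, counts, depths, missing, labels, sample_ids)
    return panel, TruthRecord(states=states, dmc_flags=dmc_flags)


@dataclass
class SurvivalSimSpec:
    """Generating configuration for mixture-AFT survival data.

    Log survival time in component k is ``intercept_k + x beta_k + sigma_k eps``
    with standard-normal ``eps``; censoring times are exponential on the time
    scale with a rate solved numerically to hit ``censoring_rate``.
    """

    n_subjects: int = 252
    n_covariates: int = 19
    component_probs: tuple = (0.4, 0.6)
    intercepts: tuple = (1.83, 5.48)
    coefficients: np.ndarray | None = None        # K x d sparse matrix
    sigmas: tuple = (1.0, 1.0)
    censoring_rate: float = 0.3
    covariate_correlation: float = 0.3
    covariate_names: list | None = None
    seed: int = 0

    def __post_init__(self):
        self.component_probs = np.asarray(self.component_probs, dtype=float)
        K = self.component_probs.shape[0]
        if abs(self.component_probs.sum() - 1.0) > 1e-12 or np.any(self.component_probs < 0):
            raise ValidationError("component_probs must be a simplex vector")
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.intercepts.shape != (K,) or self.sigmas.shape != (K,):
            raise ValidationError("intercepts/sigmas must have one entry per component")
        if np.any(self.sigmas <= 0):
            raise ValidationError("sigmas must be positive")
        if self.coefficients is None:
            self.coefficients = np.zeros((K, self.n_covariates))
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (K, self.n_covariates):
            raise ValidationError("coefficients must be K x n_covariates")
        if not (0.0 < self.censoring_rate < 1.0):
            raise ValidationError("censoring_rate must be in (0,1)")
        if not (0.0 <= self.covariate_correlation < 1.0):
            raise ValidationError("covariate_correlation must be in [0,1)")
        if self.covariate_names is None:
            self.covariate_names = [f"g{j+1:03d}" for j in range(self.n_covariates)]
        if len(self.covariate_names) != self.n_covariates:
            raise ValidationError("one covariate name per column required")


def reference_survival_spec(seed: int = 0, **overrides) -> SurvivalSimSpec:
    """Two-component sparse generating model used throughout the survival tests.

    Component 1 (short survival, intercept 1.83) carries CDH11 -3.60,
    EPB41L3 2.11, DOCK2 -3.71; component 2 (long survival, intercept 5.48)
    carries TMEM215 -3.08, PPP1R14A -2.36, GPR158 1.86, NAPSB -2.93; the
    remaining 12 promoter-methylation covariates are inactive.
    """
    names = ["CDH11", "FOXF1", "TRIM29", "DCHS2", "TMEM215", "GALNT13", "MIR34B",
             "CHST10", "TFAP2B", "EPB41L3", "DOCK2", "SLC4A11", "PPP1R14A",
             "GPR158", "TFAP2C", "STX18", "RAMP3", "MEF2D", "NAPSB"]
    beta = np.zeros((2, 19))
    beta[0, names.index("CDH11")] = -3.60
    beta[0, names.index("EPB41L3")] = 2.11
    beta[0, names.index("DOCK2")] = -3.71
    beta[1, names.index("TMEM215")] = -3.08
    beta[1, names.index("PPP1R14A")] = -2.36
    beta[1, names.index("GPR158")] = 1.86
    beta[1, names.index("NAPSB")] = -2.93
    kw = dict(n_subjects=252, n_covariates=19, component_probs=(0.4, 0.6),
              intercepts=(1.83, 5.48), coefficients=beta, sigmas=(1.0, 1.0),
              censoring_rate=0.3, covariate_correlation=0.3,
              covariate_names=names, seed=seed)
    kw.update(overrides)
    return SurvivalSimSpec(**kw)


@dataclass
class SurvivalDataset:
    """Right-censored survival table with mean-centred covariates."""

    time: np.ndarray            # observed time, > 0
    status: np.ndarray          # 1 = event, 0 = right-censored
    X: np.ndarray               # n x d, columns centred to mean 0
    covariate_names: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=float)
        if np.any(self.time <= 0):
            raise ValidationError("times must be positive")
        n, d = self.X.shape
        if self.time.shape != (n,) or self.status.shape != (n,):
            raise ValidationError("time/status length must match X rows")
        if n > 1 and np.any(np.abs(self.X.mean(axis=0)) > 1e-8):
            raise ValidationError("covariate columns must be mean-centred")
        if not self.covariate_names:
            self.covariate_names = [f"x{j+1}" for j in range(d)]
        if not self.subject_ids:
            self.subject_ids = [f"s{i+1:04d}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def log_time(self) -> np.ndarray:
        return np.log(self.time)


def simulate_survival(spec: SurvivalSimSpec) -> tuple[SurvivalDataset, TruthRecord]:
    """Draw a censored mixture-AFT dataset plus the true memberships."""
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_subjects, spec.n_covariates
    K = spec.component_probs.shape[0]

    rho = spec.covariate_correlation
    # exchangeable correlation: sqrt(rho) shared factor + sqrt(1-rho) idiosyncratic
    shared = rng.standard_normal(n)
    X = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, d))
    X = X - X.mean(axis=0)

    z = rng.choice(K, size=n, p=spec.component_probs)
    log_t = (spec.intercepts[z] + np.einsum("ij,ij->i", X, spec.coefficients[z])
             + spec.sigmas[z] * rng.standard_normal(n))
    t_event = np.exp(log_t)

    # exponential censoring rate solved so that P(C < T) hits the target
    def realized(rate):
        return np.mean(1.0 - np.exp(-rate * t_event)) - spec.censoring_rate

    lo, hi = 1e-12, 1.0 / max(t_event.min(), 1e-12)
    while realized(hi) < 0:
        hi *= 10
        if hi > 1e12:
            break
    rate = brentq(realized, lo, hi)
    c = rng.exponential(1.0 / rate, size=n)
    status = (t_event <= c).astype(np.int64)
    time = np.minimum(t_event, c)

    data = SurvivalDataset(time=time, status=status, X=X,
                           covariate_names=list(spec.covariate_names))
    return data, TruthRecord(memberships=z)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_annotation(panel: MethylationPanel, gene_span: int = 8,
                        seed: int = 0):
    """Tile a plausible feature annotation over a panel's coordinate range.

    Lays down gene models (promoter followed by alternating exon/intron blocks)
    with CpG islands/shores/shelves interleaved, covering roughly half the
    span so some CpGs fall through to intergenic. Returns a DataFrame in the
    annotation module's interval layout (0-based half-open).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    lo, hi = int(panel.positions[0]) - 1, int(panel.positions[-1]) + 1
    rows = []
    cursor = lo
    gene_no = 0
    while cursor < hi:
        if rng.random() < 0.5:   # intergenic gap
            cursor += int(rng.integers(200, 2000))
            continue
        gene_no += 1
        gid = f"GENE{gene_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        prom_len = int(rng.integers(300, 1500))
        rows.append((panel.chrom, cursor, cursor + prom_len, strand, "promoter", gid))
        # island overlapping the promoter boundary, flanked by shores and shelves
        isl = int(rng.integers(200, 800))
        rows.append((panel.chrom, cursor + prom_len // 2, cursor + prom_len // 2 + isl,
                     ".", "island", ""))
        rows.append((panel.chrom, cursor + prom_len // 2 + isl,
                     cursor + prom_len // 2 + isl + 2000, ".", "shore", ""))
        rows.append((panel.chrom, cursor + prom_len // 2 + isl + 2000,
                     cursor + prom_len // 2 + isl + 4000, ".", "shelf", ""))
        cursor += prom_len
        for b in range(int(rng.integers(2, gene_span))):
            blen = int(rng.integers(150, 1200))
            cls = "exon" if b % 2 == 0 else "intron"
            rows.append((panel.chrom, cursor, cursor + blen, strand, cls, gid))
            cursor += blen
        cursor += int(rng.integers(100, 1000))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "feature_class", "gene_id"])
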