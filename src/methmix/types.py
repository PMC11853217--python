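"""Core domain containers shared across the pipeline stages.

Conventions
-----------
* Genomic positions are 1-based in tabular interfaces and kept 1-based on the
  panel; annotation intervals are 0-based half-open internally (BED dialect).
* Hidden methylation states are 0-based integers ``0..K-1`` in memory.
* All count matrices are positions x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


DEPTH_CAP = 500  # reads; positions deeper than this are treated as PCR artefacts


def _as_array(x, dtype=float):
    return np.asarray(x, dtype=dtype)


@dataclass
class MethylationPanel:
    """Positions x samples matrix of (methylated count, read depth).

    ``counts`` and ``depths`` are integer matrices of shape (L, n); entries at
    ``missing_mask`` are undefined (stored as 0) and carry no likelihood.
    ``group_labels`` holds ``"case"``/``"control"`` per sample.
    """

    chrom: str
    positions: np.ndarray
    counts: np.ndarray
    depths: np.ndarray
    missing_mask: np.ndarray
    group_labels: list
    sample_ids: list

    def __post_init__(self):
        self.positions = _as_array(self.positions, np.int64)
        self.counts = _as_array(self.counts, np.int64)
        self.depths = _as_array(self.depths, np.int64)
        self.missing_mask = _as_array(self.missing_mask, bool)
        L = self.positions.shape[0]
        if L < 1:
            raise ValidationError("panel must contain at least one position")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if self.counts.shape != self.depths.shape or self.counts.shape != self.missing_mask.shape:
            raise ValidationError("counts/depths/missing_mask shapes differ")
        if self.counts.shape[0] != L:
            raise ValidationError("matrix row count does not match positions")
        obs = ~self.missing_mask
        if np.any(self.counts[obs] < 0) or np.any(self.counts[obs] > self.depths[obs]):
            raise ValidationError("need 0 <= meth count <= depth at observed entries")
        if len(self.group_labels) != self.counts.shape[1]:
            raise ValidationError("one group label per sample required")
        for g in self.group_labels:
            if g not in ("case", "control"):
                raise ValidationError(f"unknown group label {g!r}")

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])

    def apply_depth_filter(self, cap: int = DEPTH_CAP) -> "MethylationPanel":
        """Mask entries deeper than ``cap`` (PCR-bias filter applied at load)."""
        mask = self.missing_mask | (self.depths > cap)
        counts = np.where(mask, 0, self.counts)
        depths = np.where(mask, 0, self.depths)
        return MethylationPanel(self.chrom, self.positions, counts, depths, mask,
                                list(self.group_labels), list(self.sample_ids))


@dataclass
class TruthRecord:
    """Generating truth kept alongside a simulated object for recovery tests."""

    states: np.ndarray | None = None       # hidden path, 0-based, shape (L,)
    dmc_flags: np.ndarray | None = None    # bool, shape (L,)
    memberships: np.ndarray | None = None  # component labels, shape (n,)


@dataclass
class HMMHyper:
    """Fixed hyperparameters of the trans-dimensional HMM prior."""

    gamma: float = 1.0   # flat Dirichlet on transition rows
    alpha: float = 1.0   # Beta(alpha, beta) on each theta_k
    beta: float = 1.0
    k_max: int = 10


@dataclass
class HMMParameterState:
    """Order K, methylation propensities and transition structure.

    ``trans`` has K+1 rows: row 0 is the initial distribution, rows 1..K are
    the transition probabilities out of each state. Thetas are kept sorted
    ascending (the label-switching canon); states are relabelled accordingly.
    """

    K: int
    thetas: np.ndarray
    trans: np.ndarray
    hyper: HMMHyper = field(default_factory=HMMHyper)

    def __post_init__(self):
        self.thetas = _as_array(self.thetas)
        self.trans = _as_array(self.trans)
        if not (1 <= self.K <= self.hyper.k_max):
            raise ValidationError(f"order K={self.K} outside 1..{self.hyper.k_max}")
        if self.thetas.shape != (self.K,):
            raise ValidationError("thetas must have length K")
        if np.any(self.thetas <= 0) or np.any(self.thetas >= 1):
            raise ValidationError("thetas must lie strictly inside (0,1)")
        if np.any(np.diff(self.thetas) < 0):
            raise ValidationError("thetas must be sorted ascending")
        if self.trans.shape != (self.K + 1, self.K):
            raise ValidationError("trans must be (K+1) x K (row 0 = initial)")
        if np.any(self.trans < 0) or np.any(np.abs(self.trans.sum(axis=1) - 1) > 1e-10):
            raise ValidationError("trans rows must be probability vectors")

    def copy(self) -> "HMMParameterState":
        return HMMParameterState(self.K, self.thetas.copy(), self.trans.copy(), self.hyper)


@dataclass
class MCMCConfig:
    """Chain settings for per-sample smoothing.

    ``collapse_tol`` is the theta-scale tolerance below which neighbouring
    states are merged deterministically (over-fit control); the under-fit
    penalty multiplies the split-proposal weight by ``underfit_penalty_weight``
    whenever the within-state binomial deviance exceeds the
    ``deviance_quantile`` of its parametric-bootstrap null.
    """

    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 5
    collapse_tol: float = 0.02
    underfit_penalty_weight: float = 2.0
    deviance_quantile: float = 0.95
    deviance_bootstrap: int = 50
    boost_every: int = 10          # recompute the bootstrap reference every so many sweeps
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValidationError("burn_in must be smaller than n_iter")
        if self.collapse_tol <= 0:
            raise ValidationError("collapse_tol must be positive")


@dataclass
class SmoothedProfile:
    """Posterior-mean methylation level per position and sample."""

    chrom: str
    positions: np.ndarray
    fitted: np.ndarray          # (L, n), strictly inside (0,1)
    sample_ids: list
    group_labels: list
    order_traces: list          # per sample: 1-D array of retained K draws
    acceptance_rates: list      # per sample: split/merge acceptance fraction

    def __post_init__(self):
        if np.any(self.fitted <= 0) or np.any(self.fitted >= 1):
            raise ValidationError("fitted levels must lie strictly inside (0,1)")
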