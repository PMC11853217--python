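"""Per-CpG differential methylation calls from smoothed profiles.

Smoothed per-sample methylation levels are logit-transformed, a conjugate
two-group Bayesian linear model is fitted at every CpG, and calls are made by
Benjamini-Hochberg FDR control with hyper/hypo direction taken as case minus
control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import SmoothedProfile, ValidationError

__all__ = ["logit_transform", "per_cpg_test", "fdr_adjust", "call_dmcs",
           "volcano_table"]


def logit_transform(fitted: np.ndarray) -> np.ndarray:
    """Elementwise log(x / (1-x)); NaNs pass through (untestable entries).

    Values at exactly 0 or 1 signal an upstream bug (posterior means of Beta
    propensities are strictly interior) and raise.
    """
    x = np.asarray(fitted, dtype=float)
    finite = ~np.isnan(x)
    if np.any((x[finite] <= 0) | (x[finite] >= 1)):
        raise ValidationError("fitted levels must lie strictly inside (0,1)")
    out = np.full_like(x, np.nan)
    out[finite] = np.log(x[finite] / (1.0 - x[finite]))
    return out


def per_cpg_test(logit_levels: np.ndarray, group_labels, g: float | None = None):
    """Two-group conjugate Bayesian linear model at each CpG.

    A Zellner-style weak prior (g = n by default) is placed on the group
    contrast; the reported effect is the shrunk posterior-mean difference
    (case minus control) and the p-value refers the posterior t statistic to
    its exact null distribution, so the test is calibrated under the null.
    NaN entries are treated as unobserved; CpGs with fewer than two usable
    samples in either group are returned with NaN effect and p (untestable,
    excluded from the FDR family downstream).

    Returns (effect, p, mean_case, mean_control) arrays of length L.
    """
    X = np.asarray(logit_levels, dtype=float)
    labels = np.asarray(group_labels)
    case = labels == "case"
    ctrl = labels == "control"
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValidationError("both groups must be present")

    L = X.shape[0]
    effect = np.full(L, np.nan)
    pval = np.full(L, np.nan)
    mean_case = np.full(L, np.nan)
    mean_ctrl = np.full(L, np.nan)

    ok = ~np.isnan(X)
    n1 = (ok & case).sum(axis=1)
    n2 = (ok & ctrl).sum(axis=1)
    testable = (n1 >= 2) & (n2 >= 2)

    Xc = np.where(ok & case, X, 0.0)
    Xk = np.where(ok & ctrl, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = Xc.sum(axis=1) / n1
        m2 = Xk.sum(axis=1) / n2
        ss = (np.where(ok & case, (X - m1[:, None]) ** 2, 0.0).sum(axis=1)
              + np.where(ok & ctrl, (X - m2[:, None]) ** 2, 0.0).sum(axis=1))
    n = n1 + n2
    df = n - 2
    t_idx = testable & (df > 0)
    s2 = np.where(t_idx, ss / np.maximum(df, 1), np.nan)
    se = np.sqrt(s2 * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    diff = m1 - m2
    gg = n.astype(float) if g is None else np.full(L, float(g))
    shrink = gg / (1.0 + gg)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = diff / se
    # posterior t = shrink^(1/2-ish) * classical t; its null law is a scaled
    # Student t, so the p-value reduces to the classical reference
    p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))

    effect[t_idx] = (shrink * diff)[t_idx]
    pval[t_idx] = p[t_idx]
    mean_case[t_idx] = m1[t_idx]
    mean_ctrl[t_idx] = m2[t_idx]
    return effect, pval, mean_case, mean_ctrl


def fdr_adjust(p_vector, alpha: float = 0.05, method: str = "bh"):
    """Benjamini-Hochberg (or Benjamini-Yekutieli) step-up adjustment.

    NaN p-values (untestable CpGs) are excluded from the family and come back
    as NaN q with no call. Returns (q_vector, significant_mask).
    """
    p = np.asarray(p_vector, dtype=float)
    q = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q, sig
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0,1]")
    mm = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method=mm)
    q[ok] = qv
    sig[ok] = rej
    return q, sig


def call_dmcs(profile: SmoothedProfile, alpha: float = 0.05,
              fdr_method: str = "bh", missing_mask=None) -> pd.DataFrame:
    """Full per-CpG pipeline: logit transform, Bayesian linear model, FDR.

    ``missing_mask`` optionally marks entries to exclude from testing (e.g.
    to test on observed data only); by default every smoothed entry is used,
    which is the point of model-based imputation.

    Returns a DMC table with columns chrom, pos, mean_case, mean_control,
    effect (logit case - control), p_value, q_value, call in
    {NDMC, hyper, hypo, untestable}.
    """
    lv = logit_transform(profile.fitted)
    if missing_mask is not None:
        lv = np.where(np.asarray(missing_mask, dtype=bool), np.nan, lv)
    effect, p, mc, mk = per_cpg_test(lv, profile.group_labels)
    q, sig = fdr_adjust(p, alpha=alpha, method=fdr_method)
    call = np.where(np.isnan(p), "untestable",
                    np.where(sig & (effect > 0), "hyper",
                             np.where(sig & (effect < 0), "hypo", "NDMC")))
    return pd.DataFrame({
        "chrom": profile.chrom,
        "pos": profile.positions,
        "mean_case": mc,
        "mean_control": mk,
        "effect": effect,
        "p_value": p,
        "q_value": q,
        "call": call,
    })


def volcano_table(dmc_table: pd.DataFrame) -> pd.DataFrame:
    """Projection for volcano plotting: effect vs -log10 q, with the call."""
    t = dmc_table.loc[dmc_table["call"] != "untestable",
                      ["chrom", "pos", "effect", "q_value", "call"]].copy()
    with np.errstate(divide="ignore"):
        t["neg_log10_q"] = -np.log10(t["q_value"])
    return t[["chrom", "pos", "effect", "neg_log10_q", "call"]]
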