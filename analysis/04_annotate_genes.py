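#!/usr/bin/env python
"""Assign genomic contexts, call differentially methylated genes, and compare
the smoothed pipeline's calls with a naive per-CpG t-test on raw ratios.

Writes results/dmc_context.tsv, results/dmgs.tsv, results/agreement.csv and
results/venn.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from methmix import io
from methmix.annotation import (FeatureAnnotation, agreement_table,
                                assign_context, call_dmgs, venn_counts)
from methmix.dmc import fdr_adjust

OUT = Path("results")


def ttest_baseline(panel):
    """Per-CpG Welch-free t-test on logit raw ratios, observed entries only."""
    with np.errstate(all="ignore"):
        ratio = (panel.counts + 0.5) / (panel.depths + 1.0)
        lg = np.where(panel.missing_mask | (panel.depths == 0), np.nan,
                      np.log(ratio / (1 - ratio)))
    case = np.array(panel.group_labels) == "case"
    p = np.full(panel.n_positions, np.nan)
    eff = np.full(panel.n_positions, np.nan)
    for l in range(panel.n_positions):
        a = lg[l, case]
        b = lg[l, ~case]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) >= 2 and len(b) >= 2:
            p[l] = stats.ttest_ind(a, b, equal_var=True).pvalue
            eff[l] = a.mean() - b.mean()
    q, sig = fdr_adjust(p, alpha=0.05)
    return np.where(np.isnan(p), "untestable",
                    np.where(sig & (eff > 0), "hyper",
                             np.where(sig & (eff < 0), "hypo", "NDMC")))


def main():
    panel = io.read_panel(OUT / "data" / "panel.tsv")
    dmc = pd.read_csv(OUT / "dmc.bed", sep="\t").rename(columns={"end": "pos"})
    anno = FeatureAnnotation.from_bed(OUT / "data" / "annotation.bed")

    ctx = assign_context(dmc, anno)
    ctx.to_csv(OUT / "dmc_context.tsv", sep="\t", index=False)
    dist = ctx.loc[ctx["call"].isin(["hyper", "hypo"]),
                   "context"].value_counts().to_dict()
    print(f"DMC genomic contexts: {dist}")

    dmgs = call_dmgs(ctx, alpha=0.05)
    dmgs.to_csv(OUT / "dmgs.tsv", sep="\t", index=False)
    print(f"{len(dmgs)} DMGs "
          f"({(dmgs['direction'] == 'hyper').sum()} hyper, "
          f"{(dmgs['direction'] == 'hypo').sum()} hypo, "
          f"{(dmgs['direction'] == 'mixed').sum()} mixed)")

    t_calls = ttest_baseline(panel)
    agree = agreement_table(pd.Series(ctx["call"].to_numpy()),
                            pd.Series(t_calls))
    agree.to_frame().to_csv(OUT / "agreement.csv", index=False)
    print(f"agreement with raw t-test: captured "
          f"{agree.pct_of_b_dmc_captured}% of its DMCs; "
          f"called DMC at {agree.pct_of_b_ndmc_captured}% of its non-DMCs")

    smoothed_genes = set(dmgs["gene_id"])
    t_ctx = ctx.assign(call=t_calls)
    t_genes = set(call_dmgs(t_ctx, alpha=0.05)["gene_id"])
    venn = venn_counts({"smoothed": smoothed_genes, "t_test": t_genes}) \
        if smoothed_genes | t_genes else {}
    (OUT / "venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
    print(f"DMG set overlap: {venn}")


if __name__ == "__main__":
    main()
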