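#!/usr/bin/env python
"""Call differentially methylated cytosines from the smoothed profiles.

Logit-transforms the fitted levels, fits the conjugate two-group linear model
per CpG, applies Benjamini-Hochberg control at 5% FDR, and scores the calls
against the generating truth. Writes results/dmc.bed and results/volcano.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methmix import io
from methmix.dmc import call_dmcs, volcano_table

OUT = Path("results")


def main():
    profile = io.read_profile(OUT / "profile.tsv")
    table = call_dmcs(profile, alpha=0.05)
    io.write_dmc_bed(table, OUT / "dmc.bed")
    volcano_table(table).to_csv(OUT / "volcano.tsv", sep="\t", index=False)

    called = table["call"].isin(["hyper", "hypo"]).to_numpy()
    print(f"{called.sum()} DMCs of {len(table)} CpGs "
          f"({(table['call'] == 'hyper').sum()} hyper, "
          f"{(table['call'] == 'hypo').sum()} hypo)")

    truth = pd.read_csv(OUT / "data" / "panel_truth.tsv", sep="\t")
    flags = truth["dmc"].astype(bool).to_numpy()
    tp = int((called & flags).sum())
    fp = int((called & ~flags).sum())
    fn = int((~called & flags).sum())
    sens = tp / max(tp + fn, 1)
    fdr = fp / max(tp + fp, 1)
    print(f"against truth: sensitivity {sens:.3f}, realized FDR {fdr:.3f}")
    tp_rows = table.loc[called & flags]
    if len(tp_rows):
        print(f"direction concordance on true positives: "
              f"{(tp_rows['call'] == 'hyper').mean():.3f} hyper "
              f"(injected shift is +1.5 logit units)")


if __name__ == "__main__":
    main()
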