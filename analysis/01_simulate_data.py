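#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a two-group bisulfite count panel (HMM-structured methylation states,
negative-binomial depths capped at 500, 30% independent missingness, DMC
blocks shifted by 1.5 logit units in the case group), a tiled genomic feature
annotation, and a censored two-component mixture-AFT survival dataset with
the reference sparse coefficients, into results/data/.
"""

from pathlib import Path

import pandas as pd

from methmix import (PanelSimSpec, reference_survival_spec,
                     simulate_annotation, simulate_panel, simulate_survival)
from methmix import io
from methmix.annotation import FeatureAnnotation

SEED = 20260923
OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    spec = PanelSimSpec(n_positions=800, n_samples_per_group=10,
                        dmc_fraction=0.15, seed=SEED)
    panel, truth = simulate_panel(spec)
    io.write_panel(panel, OUT / "panel.tsv")
    io.write_truth(truth, panel.positions, OUT / "panel_truth.tsv")
    print(f"panel: {panel.n_positions} CpGs x {panel.n_samples} samples, "
          f"{panel.missing_mask.mean():.0%} missing, "
          f"{truth.dmc_flags.mean():.1%} of positions in DMC blocks")

    anno = FeatureAnnotation.from_frame(simulate_annotation(panel, seed=SEED + 1))
    anno.to_bed(OUT / "annotation.bed")
    counts = anno.intervals["feature_class"].value_counts().to_dict()
    print(f"annotation: {len(anno.intervals)} intervals {counts}")

    sdata, struth = simulate_survival(reference_survival_spec(seed=SEED + 2))
    io.write_survival(sdata, OUT / "survival.tsv")
    pd.DataFrame({"id": sdata.subject_ids,
                  "component": struth.memberships + 1}).to_csv(
        OUT / "survival_truth.tsv", sep="\t", index=False)
    print(f"survival: n={sdata.n}, d={sdata.d}, "
          f"censoring={1 - sdata.status.mean():.1%}, "
          f"component sizes={pd.Series(struth.memberships + 1).value_counts().to_dict()}")


if __name__ == "__main__":
    main()
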