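"""Plain-text table interfaces (TSV/BED/CSV/JSON) between pipeline stages."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .simulate import SurvivalDataset
from .types import (DEPTH_CAP, MethylationPanel, SmoothedProfile, TruthRecord,
                    ValidationError)


def write_panel(panel: MethylationPanel, path) -> None:
    """Panel TSV: chrom, pos (1-based), then one `meth,depth` pair per sample
    with missing entries encoded as `NA,NA`."""
    cols = {"chrom": panel.chrom, "pos": panel.positions}
    for i, sid in enumerate(panel.sample_ids):
        pair = np.where(panel.missing_mask[:, i], "NA,NA",
                        pd.Series(panel.counts[:, i]).astype(str) + ","
                        + pd.Series(panel.depths[:, i]).astype(str))
        cols[sid] = pair
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_panel(path, group_of=None, depth_cap: int = DEPTH_CAP) -> MethylationPanel:
    """Read a panel TSV; the depth filter (depth > cap -> masked) is applied
    at load time. ``group_of`` maps sample id -> group; by default the id
    prefix before the first underscore is used."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValidationError("panel TSV must start with chrom, pos columns")
    sample_ids = list(df.columns[2:])
    if not sample_ids:
        raise ValidationError("panel TSV has no sample columns")
    chrom = df["chrom"].iloc[0]
    positions = df["pos"].astype(np.int64).to_numpy()
    L, n = len(df), len(sample_ids)
    counts = np.zeros((L, n), dtype=np.int64)
    depths = np.zeros((L, n), dtype=np.int64)
    missing = np.zeros((L, n), dtype=bool)
    for i, sid in enumerate(sample_ids):
        parts = df[sid].str.split(",", expand=True)
        miss = (parts[0] == "NA") | parts[0].isna()
        missing[:, i] = miss.to_numpy()
        counts[~missing[:, i], i] = parts.loc[~miss, 0].astype(np.int64)
        depths[~missing[:, i], i] = parts.loc[~miss, 1].astype(np.int64)
    if group_of is None:
        labels = [sid.split("_")[0] for sid in sample_ids]
    else:
        labels = [group_of[sid] for sid in sample_ids]
    panel = MethylationPanel(chrom, positions, counts, depths, missing,
                             labels, sample_ids)
    return panel.apply_depth_filter(depth_cap)


def write_truth(truth: TruthRecord, positions, path) -> None:
    pd.DataFrame({
        "pos": positions,
        "state": truth.states,
        "dmc": truth.dmc_flags.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthRecord:
    df = pd.read_csv(path, sep="\t")
    return TruthRecord(states=df["state"].to_numpy(),
                       dmc_flags=df["dmc"].astype(bool).to_numpy())


def write_profile(profile: SmoothedProfile, path, sidecar_path=None) -> None:
    """Smoothed profile TSV (chrom, pos, one fitted column per sample) plus an
    optional JSON sidecar with chain diagnostics."""
    cols = {"chrom": profile.chrom, "pos": profile.positions}
    for i, sid in enumerate(profile.sample_ids):
        cols[sid] = profile.fitted[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8g")
    if sidecar_path is not None:
        diag = {
            "sample_ids": list(profile.sample_ids),
            "group_labels": list(profile.group_labels),
            "acceptance_rates": [float(r) for r in profile.acceptance_rates],
            "order_histograms": [
                {str(k): int(c) for k, c in
                 zip(*np.unique(np.asarray(tr), return_counts=True))}
                for tr in profile.order_traces
            ],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)


def read_profile(path, group_of=None) -> SmoothedProfile:
    df = pd.read_csv(path, sep="\t")
    sample_ids = list(df.columns[2:])
    fitted = df[sample_ids].to_numpy(dtype=float)
    if group_of is None:
        labels = [sid.split("_")[0] for sid in sample_ids]
    else:
        labels = [group_of[sid] for sid in sample_ids]
    return SmoothedProfile(df["chrom"].iloc[0], df["pos"].to_numpy(np.int64),
                           fitted, sample_ids, labels, [], [])


def write_dmc_bed(dmc_table: pd.DataFrame, path) -> None:
    """DMC table as BED-compatible TSV: chrom, 0-based start, end=start+1,
    name, score = -log10 q, strand '.', then the call columns."""
    t = dmc_table
    with np.errstate(divide="ignore"):
        score = np.where(t["q_value"].notna(), -np.log10(t["q_value"]), 0.0)
    out = pd.DataFrame({
        "chrom": t["chrom"],
        "start": t["pos"].astype(np.int64) - 1,
        "end": t["pos"].astype(np.int64),
        "name": ["cpg_%d" % p for p in t["pos"]],
        "score": np.round(np.clip(score, 0, 1000), 4),
        "strand": ".",
        "call": t["call"],
        "effect": np.round(t["effect"], 6),
        "p_value": t["p_value"],
        "q_value": t["q_value"],
    })
    out.to_csv(path, sep="\t", index=False)


def write_survival(data: SurvivalDataset, path) -> None:
    """Survival TSV: id, time, status (1=event, 0=censored), covariates."""
    df = pd.DataFrame({"id": data.subject_ids, "time": data.time,
                       "status": data.status})
    for j, name in enumerate(data.covariate_names):
        df[name] = data.X[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_survival(path) -> SurvivalDataset:
    df = pd.read_csv(path, sep="\t")
    cov = [c for c in df.columns if c not in ("id", "time", "status")]
    X = df[cov].to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # re-centre against round-trip rounding drift
    return SurvivalDataset(time=df["time"].to_numpy(float),
                           status=df["status"].to_numpy(np.int64),
                           X=X, covariate_names=cov,
                           subject_ids=[str(x) for x in df["id"]])
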