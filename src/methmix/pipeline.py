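"""End-to-end orchestration: simulate -> smooth -> call DMCs -> annotate ->
survival, with a resolved-config manifest and content-hash stage caching so a
run directory can always be regenerated from its manifest alone."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import dmc as dmc_mod
from . import hmm, io, survival
from .simulate import (PanelSimSpec, SurvivalSimSpec, simulate_annotation,
                       simulate_panel, simulate_survival)
from .types import MCMCConfig, ValidationError

log = logging.getLogger("methmix")

STAGES = ["simulate", "smooth", "call-dmc", "annotate", "survival", "report"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run; YAML round-trippable."""

    out_dir: str = "run"
    seed: int = 1
    stages: list = field(default_factory=lambda: list(STAGES))
    panel: dict = field(default_factory=dict)          # PanelSimSpec overrides
    chain: dict = field(default_factory=dict)          # MCMCConfig overrides
    dmc: dict = field(default_factory=lambda: {"alpha": 0.05, "fdr_method": "bh"})
    annotation: dict = field(default_factory=lambda: {"min_promoter_dmcs": 1})
    survival_sim: dict = field(default_factory=dict)   # SurvivalSimSpec overrides
    survival_fit: dict = field(default_factory=lambda: {
        "penalty": "adaptive_lasso", "k_min": 1, "k_max": 7})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        return (rec is not None and rec["key"] == key
                and all(Path(p).exists() for p in rec["outputs"])
                and rec["outputs"] == [str(p) for p in outputs])

    def record(self, stage: str, key: str, outputs: list[Path]) -> None:
        self.data[stage] = {"key": key, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages into ``config.out_dir``.

    Deterministic given the seed; stages whose config and inputs are
    unchanged (by content hash) are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    man = _Manifest(out / "manifest.json")

    paths = {
        "panel": out / "panel.tsv", "truth": out / "truth.tsv",
        "annotation": out / "annotation.bed",
        "survival": out / "survival.tsv", "survival_truth": out / "survival_truth.tsv",
        "profile": out / "profile.tsv", "diag": out / "chain_diagnostics.json",
        "dmc": out / "dmc.bed", "volcano": out / "volcano.tsv",
        "context": out / "dmc_context.tsv", "dmg": out / "dmgs.tsv",
        "screen": out / "screening.csv", "model_sel": out / "model_selection.csv",
        "coef": out / "coefficients.tsv", "member": out / "membership.tsv",
        "summary": out / "summary.json",
    }

    if "simulate" in config.stages:
        key = _hash_obj(["simulate", config.seed, config.panel, config.survival_sim])
        outs = [paths[k] for k in ("panel", "truth", "annotation",
                                   "survival", "survival_truth")]
        if not man.fresh("simulate", key, outs):
            log.info("stage simulate: generating synthetic panel and survival data")
            pspec = PanelSimSpec(**{"seed": config.seed, **config.panel})
            panel, truth = simulate_panel(pspec)
            io.write_panel(panel, paths["panel"])
            io.write_truth(truth, panel.positions, paths["truth"])
            anno = simulate_annotation(panel, seed=config.seed + 1)
            ann.FeatureAnnotation.from_frame(anno).to_bed(paths["annotation"])
            sspec_kw = {"seed": config.seed + 2, **config.survival_sim}
            sdata, struth = simulate_survival(SurvivalSimSpec(**sspec_kw))
            io.write_survival(sdata, paths["survival"])
            pd.DataFrame({"id": sdata.subject_ids,
                          "component": struth.memberships + 1}).to_csv(
                paths["survival_truth"], sep="\t", index=False)
            man.record("simulate", key, outs)
        else:
            log.info("stage simulate: cached")

    if "smooth" in config.stages:
        key = _hash_obj(["smooth", config.seed, config.chain,
                         _hash_file(paths["panel"])])
        outs = [paths["profile"], paths["diag"]]
        if not man.fresh("smooth", key, outs):
            log.info("stage smooth: RJ-MCMC smoothing per sample")
            panel = io.read_panel(paths["panel"])
            cfg = MCMCConfig(**{"seed": config.seed, **config.chain})
            profile = hmm.smooth_panel(panel, cfg)
            io.write_profile(profile, paths["profile"], paths["diag"])
            man.record("smooth", key, outs)
        else:
            log.info("stage smooth: cached")

    if "call-dmc" in config.stages:
        key = _hash_obj(["call-dmc", config.dmc, _hash_file(paths["profile"])])
        outs = [paths["dmc"], paths["volcano"]]
        if not man.fresh("call-dmc", key, outs):
            log.info("stage call-dmc: per-CpG tests and FDR")
            profile = io.read_profile(paths["profile"])
            table = dmc_mod.call_dmcs(profile, **config.dmc)
            io.write_dmc_bed(table, paths["dmc"])
            dmc_mod.volcano_table(table).to_csv(paths["volcano"], sep="\t",
                                                index=False)
            man.record("call-dmc", key, outs)
        else:
            log.info("stage call-dmc: cached")

    if "annotate" in config.stages:
        key = _hash_obj(["annotate", config.annotation,
                         _hash_file(paths["dmc"]), _hash_file(paths["annotation"])])
        outs = [paths["context"], paths["dmg"]]
        if not man.fresh("annotate", key, outs):
            log.info("stage annotate: genomic contexts and DMGs")
            table = pd.read_csv(paths["dmc"], sep="\t").rename(
                columns={"end": "pos"})
            anno = ann.FeatureAnnotation.from_bed(paths["annotation"])
            ctx = ann.assign_context(table, anno)
            ctx.to_csv(paths["context"], sep="\t", index=False)
            dmgs = ann.call_dmgs(ctx, **config.annotation)
            dmgs.to_csv(paths["dmg"], sep="\t", index=False)
            man.record("annotate", key, outs)
        else:
            log.info("stage annotate: cached")

    if "survival" in config.stages:
        key = _hash_obj(["survival", config.survival_fit,
                         _hash_file(paths["survival"])])
        outs = [paths[k] for k in ("screen", "model_sel", "coef", "member")]
        if not man.fresh("survival", key, outs):
            log.info("stage survival: CARS screening and FM-AFT fits")
            sdata = io.read_survival(paths["survival"])
            fitcfg = dict(config.survival_fit)
            k_rng = range(int(fitcfg.pop("k_min", 1)), int(fitcfg.pop("k_max", 7)) + 1)
            quantile = float(fitcfg.pop("screen_quantile", 0.95))
            scores = survival.cars_screen(sdata, quantile=quantile)
            pd.DataFrame({
                "gene": scores.covariate_names, "score": scores.scores,
                "selected": [int(j in set(scores.selected))
                             for j in range(sdata.d)],
            }).to_csv(paths["screen"], index=False)
            sub = SurvivalDatasetView(sdata, scores.selected)
            best_k, fits = survival.select_order(sub.data, k_rng,
                                                 seed=config.seed, **fitcfg)
            pd.DataFrame({
                "K": list(fits), "logLik": [fits[k].loglik for k in fits],
                "df": [fits[k].df for k in fits],
                "BIC": [fits[k].bic for k in fits],
            }).to_csv(paths["model_sel"], index=False)
            fit = fits[best_k]
            fit.coefficient_table().to_csv(paths["coef"], sep="\t", index=False,
                                           float_format="%.6g")
            tau, labels, _ = survival.posterior_membership(fit, sub.data)
            mem = pd.DataFrame(tau, columns=[f"tau_{k+1}" for k in range(fit.K)])
            mem.insert(0, "id", sdata.subject_ids)
            mem["component"] = labels + 1
            mem.to_csv(paths["member"], sep="\t", index=False,
                       float_format="%.6g")
            man.record("survival", key, outs)
        else:
            log.info("stage survival: cached")

    if "report" in config.stages:
        _write_report(paths, man)
    return out


class SurvivalDatasetView:
    """Column-subset view of a survival dataset (screened covariates)."""

    def __init__(self, data, selected):
        from .simulate import SurvivalDataset
        sel = np.asarray(selected, dtype=int)
        X = data.X[:, sel]
        X = X - X.mean(axis=0)
        self.data = SurvivalDataset(
            time=data.time, status=data.status, X=X,
            covariate_names=[data.covariate_names[j] for j in sel],
            subject_ids=list(data.subject_ids))


def _write_report(paths, man) -> None:
    """Headline numbers of a run, including truth-based error rates when the
    generating truth is present."""
    summary = {}
    dmc = pd.read_csv(paths["dmc"], sep="\t")
    called = dmc["call"].isin(["hyper", "hypo"])
    summary["n_positions"] = int(len(dmc))
    summary["n_dmc"] = int(called.sum())
    summary["n_hyper"] = int((dmc["call"] == "hyper").sum())
    summary["n_hypo"] = int((dmc["call"] == "hypo").sum())
    if paths["truth"].exists():
        truth = pd.read_csv(paths["truth"], sep="\t")
        true_flags = truth["dmc"].astype(bool).to_numpy()
        pred = called.to_numpy()
        tp = int(np.sum(pred & true_flags))
        fp = int(np.sum(pred & ~true_flags))
        fn = int(np.sum(~pred & true_flags))
        summary["dmc_sensitivity"] = round(tp / max(tp + fn, 1), 4)
        summary["dmc_fdr"] = round(fp / max(tp + fp, 1), 4)
    if paths["dmg"].exists():
        dmg = pd.read_csv(paths["dmg"], sep="\t")
        summary["n_dmg"] = int(len(dmg))
    if paths["model_sel"].exists():
        sel = pd.read_csv(paths["model_sel"])
        summary["selected_K"] = int(sel.loc[sel["BIC"].idxmin(), "K"])
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    man.record("report", "report", [paths["summary"]])
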