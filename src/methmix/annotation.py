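"""Genomic context assignment, DMG calling, and cross-method accounting.

Intervals are 0-based half-open internally (BED dialect); CpG positions are
1-based. Each CpG receives exactly one context by the precedence
promoter > island > shore > shelf > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import ValidationError

FEATURE_PRECEDENCE = ["promoter", "island", "shore", "shelf", "exon", "intron"]

__all__ = ["FeatureAnnotation", "assign_context", "call_dmgs",
           "agreement_table", "AgreementTable", "overlap_summary",
           "OverlapSummary", "venn_counts"]


@dataclass
class FeatureAnnotation:
    """Feature intervals with class labels and (for genic classes) gene ids."""

    intervals: pd.DataFrame   # chrom, start, end, strand, feature_class, gene_id
    n_dropped_genes: int = 0
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.intervals
        required = {"chrom", "start", "end", "feature_class"}
        if not required.issubset(df.columns):
            raise ValidationError(f"annotation needs columns {sorted(required)}")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        if "gene_id" not in df.columns:
            df = df.assign(gene_id="")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("intervals must satisfy start < end")
        bad = ~df["feature_class"].isin(FEATURE_PRECEDENCE)
        if bad.any():
            raise ValidationError(
                f"unknown feature classes: {sorted(df.loc[bad, 'feature_class'].unique())}")
        self.intervals = df.reset_index(drop=True)
        for cls in FEATURE_PRECEDENCE:
            sub = self.intervals[self.intervals["feature_class"] == cls]
            for chrom, grp in sub.groupby("chrom"):
                tree = IntervalTree()
                for s, e, gid in zip(grp["start"], grp["end"], grp["gene_id"]):
                    tree[int(s):int(e)] = gid
                self._trees[(chrom, cls)] = tree

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drop_inconsistent_genes: bool = True):
        """Build from an interval frame, dropping genes whose genic intervals
        sit on both strands or on more than one reference sequence."""
        df = df.copy()
        dropped = 0
        if drop_inconsistent_genes and "gene_id" in df.columns:
            genic = df[(df["gene_id"] != "") & df["gene_id"].notna()]
            by_gene = genic.groupby("gene_id").agg(
                n_chrom=("chrom", "nunique"),
                n_strand=("strand", lambda s: s[s.isin(["+", "-"])].nunique()))
            bad = by_gene[(by_gene["n_chrom"] > 1) | (by_gene["n_strand"] > 1)].index
            dropped = len(bad)
            df = df[~df["gene_id"].isin(bad)]
        return cls(intervals=df.reset_index(drop=True), n_dropped_genes=dropped)

    @classmethod
    def from_bed(cls, path, drop_inconsistent_genes: bool = True):
        """Read BED6+2 (chrom start end name score strand feature_class gene_id)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score",
                                "strand", "feature_class", "gene_id"],
                         dtype={"chrom": str, "gene_id": str})
        df["gene_id"] = df["gene_id"].fillna("")
        return cls.from_frame(df.drop(columns=["name", "score"]),
                              drop_inconsistent_genes=drop_inconsistent_genes)

    def to_bed(self, path):
        df = self.intervals
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": df["feature_class"], "score": 0, "strand": df["strand"],
            "feature_class": df["feature_class"], "gene_id": df["gene_id"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)

    def lookup(self, chrom: str, pos_1based: int):
        """(feature_class, gene_id) for one CpG; intergenic if uncovered."""
        p = int(pos_1based) - 1
        for cls in FEATURE_PRECEDENCE:
            tree = self._trees.get((chrom, cls))
            if tree is None:
                continue
            hits = tree[p]
            if hits:
                return cls, sorted(iv.data for iv in hits)[0]
        return "intergenic", ""


def assign_context(dmc_table: pd.DataFrame, annotation: FeatureAnnotation) -> pd.DataFrame:
    """Label each CpG of a DMC table with its single genomic context."""
    ctx, genes = [], []
    for chrom, pos in zip(dmc_table["chrom"], dmc_table["pos"]):
        c, g = annotation.lookup(chrom, pos)
        ctx.append(c)
        genes.append(g)
    out = dmc_table.copy()
    out["context"] = ctx
    out["gene_id"] = genes
    return out


def call_dmgs(context_table: pd.DataFrame, alpha: float = 0.05,
              min_promoter_dmcs: int = 1) -> pd.DataFrame:
    """Genes with differentially methylated promoters.

    A gene is a DMG iff at least ``min_promoter_dmcs`` of its promoter CpGs
    carry a significant call; direction is the majority direction of its
    significant promoter CpGs, ties reported as "mixed".
    """
    prom = context_table[(context_table["context"] == "promoter")
                         & (context_table["gene_id"] != "")]
    rows = []
    for gid, grp in prom.groupby("gene_id"):
        n_hyper = int((grp["call"] == "hyper").sum())
        n_hypo = int((grp["call"] == "hypo").sum())
        n_sig = n_hyper + n_hypo
        if n_sig < min_promoter_dmcs:
            continue
        if n_hyper > n_hypo:
            direction = "hyper"
        elif n_hypo > n_hyper:
            direction = "hypo"
        else:
            direction = "mixed"
        rows.append((gid, n_hyper, n_hypo, n_sig, int(len(grp)), direction))
    return pd.DataFrame(rows, columns=["gene_id", "n_hyper", "n_hypo",
                                       "n_sig_promoter_cpgs",
                                       "n_promoter_cpgs", "direction"])


@dataclass
class AgreementTable:
    """2x2 DMC-call agreement between a method A and a reference method B.

    Counts: ``a_ndmc_b_ndmc`` etc.; the derived percentages recompute exactly
    from the integer counts (cell / total * 100 and the share of B's
    NDMC/DMC column that A calls DMC), rounded to 2 decimals as reported.
    """

    a_ndmc_b_ndmc: int
    a_ndmc_b_dmc: int
    a_dmc_b_ndmc: int
    a_dmc_b_dmc: int

    @property
    def total(self) -> int:
        return (self.a_ndmc_b_ndmc + self.a_ndmc_b_dmc
                + self.a_dmc_b_ndmc + self.a_dmc_b_dmc)

    def percent_of_table(self):
        t = self.total
        return {k: round(getattr(self, k) / t * 100.0, 2)
                for k in ("a_ndmc_b_ndmc", "a_ndmc_b_dmc",
                          "a_dmc_b_ndmc", "a_dmc_b_dmc")}

    @property
    def pct_of_b_ndmc_captured(self) -> float:
        """Share of B's non-DMCs that method A calls DMC (percent)."""
        den = self.a_ndmc_b_ndmc + self.a_dmc_b_ndmc
        return round(self.a_dmc_b_ndmc / den * 100.0, 2) if den else float("nan")

    @property
    def pct_of_b_dmc_captured(self) -> float:
        """Share of B's DMCs that method A also calls DMC (percent)."""
        den = self.a_ndmc_b_dmc + self.a_dmc_b_dmc
        return round(self.a_dmc_b_dmc / den * 100.0, 2) if den else float("nan")

    @property
    def pct_a_dmc(self) -> float:
        """Method A's DMC share of all co-tested positions (percent)."""
        return round((self.a_dmc_b_ndmc + self.a_dmc_b_dmc) / self.total * 100.0, 2)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percent_of_table()
        return pd.DataFrame({
            "cell": list(pct.keys()),
            "count": [getattr(self, k) for k in pct],
            "pct_of_table": list(pct.values()),
        })


def agreement_table(calls_a: pd.Series, calls_b: pd.Series,
                    context: pd.Series | None = None,
                    context_filter: str | None = None) -> AgreementTable:
    """Cross-tabulate two call sets indexed by identical positions.

    Calls are truthy for DMC (either boolean, or strings where "hyper"/"hypo"
    count as DMC). Untestable positions in either set are excluded.
    """
    if not calls_a.index.equals(calls_b.index):
        raise ValidationError("call sets must be indexed by identical positions")

    def as_dmc(s):
        if s.dtype == bool:
            return s, np.ones(len(s), dtype=bool)
        return s.isin(["hyper", "hypo"]).to_numpy(), (s != "untestable").to_numpy()

    a, ok_a = as_dmc(calls_a)
    b, ok_b = as_dmc(calls_b)
    keep = ok_a & ok_b
    if context_filter is not None:
        if context is None:
            raise ValidationError("context labels required for a context filter")
        keep &= (context == context_filter).to_numpy()
    a, b = np.asarray(a)[keep], np.asarray(b)[keep]
    return AgreementTable(
        a_ndmc_b_ndmc=int(np.sum(~a & ~b)),
        a_ndmc_b_dmc=int(np.sum(~a & b)),
        a_dmc_b_ndmc=int(np.sum(a & ~b)),
        a_dmc_b_dmc=int(np.sum(a & b)),
    )


@dataclass
class OverlapSummary:
    """Direction bookkeeping on the intersection of two called sets."""

    n_overlap: int
    n_consistent: int
    n_consistent_hyper: int
    n_consistent_hypo: int
    table: pd.DataFrame

    @property
    def pct_consistent_hyper(self) -> float:
        """Hyper share of direction-consistent overlap (percent, 1 decimal)."""
        if self.n_consistent == 0:
            return float("nan")
        return round(self.n_consistent_hyper / self.n_consistent * 100.0, 1)

    @property
    def pct_consistent_hypo(self) -> float:
        if self.n_consistent == 0:
            return float("nan")
        return round(self.n_consistent_hypo / self.n_consistent * 100.0, 1)


def overlap_summary(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                    key: str = "pos", direction: str = "call") -> OverlapSummary:
    """Intersect two significant-call tables and account for direction.

    Both frames need a ``key`` identifier column and a ``direction`` column
    with values in {hyper, hypo}; rows are assumed pre-filtered to
    significant calls.
    """
    a = calls_a[[key, direction]].rename(columns={direction: "dir_a"})
    b = calls_b[[key, direction]].rename(columns={direction: "dir_b"})
    merged = a.merge(b, on=key, how="inner")
    merged["consistent"] = merged["dir_a"] == merged["dir_b"]
    cons = merged[merged["consistent"]]
    return OverlapSummary(
        n_overlap=int(len(merged)),
        n_consistent=int(len(cons)),
        n_consistent_hyper=int((cons["dir_a"] == "hyper").sum()),
        n_consistent_hypo=int((cons["dir_a"] == "hypo").sum()),
        table=merged,
    )


def venn_counts(named_sets: dict) -> dict:
    """Exact region counts for >= 2 named sets.

    Keys of the result are '+'-joined sorted member names for every non-empty
    membership pattern (exclusive regions), e.g. ``{"A": 2, "A+B": 1}``.
    """
    if len(named_sets) < 2:
        raise ValidationError("need at least two sets")
    names = sorted(named_sets)
    universe = set().union(*named_sets.values())
    out = {}
    for x in universe:
        members = tuple(n for n in names if x in named_sets[n])
        label = "+".join(members)
        out[label] = out.get(label, 0) + 1
    return out
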