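"""Three-condition gene response classification.

From a gene x sample count matrix over {control, stimulated, stimulated +
kinase knockdown}: filter weakly expressed genes, call stimulation-up-
regulated genes (log fold change > 0.5 and BH-adjusted p < 0.05), cluster
their per-condition profiles hierarchically, and split the up-regulated set
into knockdown-dependent genes (induction significantly reduced by the
knockdown) and knockdown-independent genes.

The default differential test is Welch's t on log2(CPM + 1); externally
computed DE tables (gene, lfc, adjusted p) can be plugged in instead, so a
negative-binomial test (e.g. edgeR) can drive the same classification
logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from . import io as cio
from .domains import bh_adjust

log = logging.getLogger(__name__)

CONDITIONS = ("control", "treated_30", "treated_60", "treated_60_KD")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) plus sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame  # sample_id, condition, replicate

    def __post_init__(self):
        if not set(self.metadata["sample_id"]) <= set(self.counts.columns):
            raise ValueError("metadata names samples absent from the count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, condition: str) -> list[str]:
        sel = self.metadata[self.metadata["condition"] == condition]
        return list(sel["sample_id"])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["condition"]))

    def cpm(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"samples with zero library size: {bad}")
        return self.counts / totals * 1e6

    def log2_cpm(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.cpm() + pseudocount)


@dataclass
class GeneSets:
    """Named gene ID sets produced by the classification."""

    up_30: set[str] = field(default_factory=set)
    up_60: set[str] = field(default_factory=set)
    dependent: set[str] = field(default_factory=set)
    independent: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.dependent & self.independent:
            raise ValueError("dependent and independent sets overlap")
        if self.dependent | self.independent != self.up_60:
            raise ValueError("dependent + independent must partition up_60")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("up_30", "up_60", "dependent", "independent"):
            cio.write_gene_set(getattr(self, name), outdir / f"{name}.txt")

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "up_30": set(self.up_30),
            "up_60": set(self.up_60),
            "dependent": set(self.dependent),
            "independent": set(self.independent),
        }


def filter_genes(
    m: ExpressionMatrix, cpm_threshold: float = 10.0, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with CPM above the threshold in at least ``min_samples``
    samples (the standard low-expression filter)."""
    keep = (m.cpm() > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    return ExpressionMatrix(m.counts.loc[keep], m.metadata)


def de_test(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
    equal_var: bool = False,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-gene differential expression, group A vs group B.

    lfc is the mean log2(CPM + pseudocount) difference (A minus B); the
    p-value is a two-sided Welch t by default; adjustment is BH over the
    tested genes. Returns columns lfc, mean_a, mean_b, p, p_adj.
    """
    sa = m.samples_of(group_a)
    sb = m.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >= 2 replicates per group ({group_a}: {len(sa)}, "
            f"{group_b}: {len(sb)})"
        )
    lc = m.log2_cpm(pseudocount)
    A = lc[sa].to_numpy()
    B = lc[sb].to_numpy()
    res = sps.ttest_ind(A, B, axis=1, equal_var=equal_var)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    # zero-variance, equal-mean genes: no evidence of change
    diff = A.mean(axis=1) - B.mean(axis=1)
    degenerate = (A.var(axis=1) + B.var(axis=1) == 0) & (np.abs(diff) < 1e-12)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "lfc": diff,
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
            "p": p,
            "p_adj": bh_adjust(p, method=adjust),
        },
        index=m.counts.index,
    )


def call_up(de: pd.DataFrame, lfc_min: float = 0.5, alpha: float = 0.05) -> set[str]:
    """Up-regulated genes: lfc > ``lfc_min`` and adjusted p < ``alpha``."""
    mask = (de["lfc"] > lfc_min) & (de["p_adj"] < alpha)
    return set(de.index[mask])


def call_down(de: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Down-regulated genes (lfc < 0, adjusted p < alpha); reported only."""
    mask = (de["lfc"] < 0) & (de["p_adj"] < alpha)
    return set(de.index[mask])


def condition_profiles(
    m: ExpressionMatrix,
    genes,
    conditions=("control", "treated_60", "treated_60_KD"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Row-scaled per-condition mean log2-CPM profiles (z across the row).

    Zero-variance rows (flat profiles) are set to 0 and flagged by a
    warning; they carry no shape information for clustering.
    """
    lc = m.log2_cpm(pseudocount)
    means = pd.DataFrame(
        {c: lc[m.samples_of(c)].mean(axis=1) for c in conditions}
    ).loc[list(genes)]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    flat = sd <= 0
    if flat.any():
        log.warning("%d flat expression profiles scaled to zero", int(flat.sum()))
    sd = sd.where(~flat, 1.0)
    scaled = means.sub(mu, axis=0).div(sd, axis=0)
    scaled[flat] = 0.0
    return scaled


def cluster_up_genes(
    m: ExpressionMatrix,
    up_genes,
    conditions=("control", "treated_60", "treated_60_KD"),
    k: int = 2,
    method: str = "complete",
) -> pd.Series:
    """Hierarchical clustering of up-regulated genes across conditions.

    Euclidean distance on row-scaled per-condition mean profiles, complete
    linkage by default, tree cut into ``k`` clusters. Returns a gene ->
    cluster-label Series (labels 1..k).
    """
    genes = sorted(up_genes)
    if len(genes) == 0:
        raise ValueError("no genes to cluster")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(genes) < k:
        raise ValueError(f"fewer genes ({len(genes)}) than clusters ({k})")
    prof = condition_profiles(m, genes, conditions)
    if len(genes) == k:
        labels = np.arange(1, k + 1)  # singleton clusters
    else:
        Z = linkage(prof.to_numpy(), method=method, metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=prof.index, name="cluster")


def classify_dependence(
    m: ExpressionMatrix,
    up_60,
    clusters: pd.Series,
    alpha: float = 0.05,
    treated: str = "treated_60",
    knockdown: str = "treated_60_KD",
    pseudocount: float = 1.0,
    up_30=frozenset(),
) -> GeneSets:
    """Split up-regulated genes into knockdown-dependent and -independent.

    The candidate cluster is the one whose scaled profiles drop most from
    the stimulated to the stimulated+knockdown condition. Within it, genes
    whose stimulated-vs-knockdown contrast has adjusted p < ``alpha`` and
    lower expression under knockdown are dependent; every other
    up-regulated gene is independent. Only the candidate cluster is put
    through this secondary test, so the multiple-testing adjustment spans
    the cluster's genes.
    """
    if knockdown not in m.conditions():
        raise ValueError(
            f"condition {knockdown!r} absent: classification impossible"
        )
    up_60 = set(up_60)
    prof = condition_profiles(m, sorted(up_60), (
        "control", treated, knockdown))
    drop = prof[treated] - prof[knockdown]
    candidate = (
        drop.groupby(clusters.loc[prof.index]).mean().idxmax()
    )
    cluster_genes = set(clusters.index[clusters == candidate]) & up_60

    kd_de = de_test(m, treated, knockdown, pseudocount=pseudocount)
    tested = kd_de.loc[sorted(cluster_genes)]
    p_adj = pd.Series(bh_adjust(tested["p"]), index=tested.index)
    sig = (p_adj < alpha) & (tested["lfc"] > 0)  # lower under KD
    dependent = set(tested.index[sig])
    independent = up_60 - dependent
    return GeneSets(
        up_30=set(up_30), up_60=up_60,
        dependent=dependent, independent=independent,
    )


def classify_from_counts(
    m: ExpressionMatrix,
    lfc_min: float = 0.5,
    alpha: float = 0.05,
    k: int = 2,
    cpm_threshold: float = 10.0,
    min_samples: int = 2,
    external_de: dict[str, pd.DataFrame] | None = None,
) -> tuple[GeneSets, pd.Series, dict[str, pd.DataFrame]]:
    """Full classification: filter, DE vs control, up calls, clustering,
    dependence split.

    ``external_de`` may supply precomputed DE tables keyed by condition
    (columns lfc, p_adj) to replace the built-in test for the up calls.
    Returns (gene sets, cluster assignment, DE tables).
    """
    filt = filter_genes(m, cpm_threshold, min_samples)
    de_tables: dict[str, pd.DataFrame] = {}
    up: dict[str, set[str]] = {}
    for cond in ("treated_30", "treated_60"):
        if cond not in filt.conditions():
            continue
        if external_de and cond in external_de:
            de = external_de[cond].loc[
                external_de[cond].index.intersection(filt.counts.index)
            ]
        else:
            de = de_test(filt, cond, "control")
        de_tables[cond] = de
        up[cond] = call_up(de, lfc_min, alpha)
    if "treated_60" not in up:
        raise ValueError("condition 'treated_60' is required")
    up_60 = up["treated_60"]
    if not up_60:
        log.info("no up-regulated genes at 60 min; empty gene sets returned")
        return (
            GeneSets(up_30=up.get("treated_30", set())),
            pd.Series(dtype=int, name="cluster"),
            de_tables,
        )
    if len(up_60) < 2:
        # cannot cluster a single gene; treat it as its own candidate cluster
        clusters = pd.Series([1] * len(up_60), index=sorted(up_60), name="cluster")
    else:
        clusters = cluster_up_genes(filt, up_60, k=min(k, len(up_60)))
    sets = classify_dependence(
        filt, up_60, clusters, alpha=alpha, up_30=up.get("treated_30", set())
    )
    return sets, clusters, de_tables
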