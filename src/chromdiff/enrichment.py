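"""Permutation-based genomic interval enrichment.

Tests whether a query set (e.g. called domains) overlaps an annotation
category by more base pairs than expected by chance, by repeatedly placing
length-matched segments uniformly at random within a mappable workspace
(the GAT-style observed/expected statistic). Empirical p-values use the
(k + 1)/(n + 1) correction so they are never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, coverage_index, covered_before
from .synthetic import AnnotationBundle

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    category: str
    observed_bp: int
    expected_bp: float
    fold: float | None  # None when expected == 0 (annotation misses workspace)
    p_enrich: float | None
    p_deplete: float | None
    n_simulations: int
    seed: int
    sim_overlaps: np.ndarray | None = None  # null distribution (bp per sim)

    def to_row(self) -> dict:
        return {
            "category": self.category,
            "observed_bp": self.observed_bp,
            "expected_bp": self.expected_bp,
            "fold": self.fold,
            "p_enrich": self.p_enrich,
            "p_deplete": self.p_deplete,
            "n_sim": self.n_simulations,
            "seed": self.seed,
        }


def overlap_bp(query: IntervalSet, annotation: IntervalSet) -> int:
    """Total base pairs shared between two interval sets."""
    return query.intersect_bp(annotation)


class SegmentSampler:
    """Uniform length-preserving placement of segments within a workspace.

    Each placement keeps the segment's length, falls entirely within a
    single workspace interval, and is uniform over all legal start
    positions: a workspace interval of length L contributes L - l + 1 valid
    starts for a segment of length l, and is chosen with probability
    proportional to that count. Placements are mutually independent, so
    sampled segments may overlap one another.
    """

    def __init__(self, workspace: IntervalSet) -> None:
        ws = workspace.merge()
        if len(ws) == 0:
            raise ValueError("empty workspace")
        self.ws = ws
        self.ws_chroms = ws.chroms
        self.ws_starts = ws.starts
        self.ws_lengths = ws.lengths
        # linear axis offsets for fast annotation lookups
        self.offsets: dict[str, int] = {}
        running = 0
        for c in ws.chrom_order():
            self.offsets[c] = running
            running += int(ws.df.loc[ws.df["chrom"] == c, "end"].max()) + 1
        self._ws_global_starts = np.array(
            [self.offsets[c] for c in ws.chroms], dtype=np.int64
        ) + self.ws_starts

    def valid_starts(self, seg_len: int) -> np.ndarray:
        return np.maximum(self.ws_lengths - seg_len + 1, 0)

    def place(self, seg_len: int, rng: np.random.Generator, size: int = 1):
        """Global-axis start positions of ``size`` placements."""
        counts = self.valid_starts(seg_len)
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"segment of {seg_len} bp longer than every workspace interval"
            )
        p = counts / total
        which = rng.choice(len(counts), size=size, p=p)
        offset = rng.integers(0, counts[which])
        return self._ws_global_starts[which] + offset

    def permute(self, query: IntervalSet, rng: np.random.Generator) -> IntervalSet:
        """One random placement per query segment (genome coordinates)."""
        rows = []
        inv = {v: k for k, v in self.offsets.items()}
        bounds = sorted(self.offsets.values())
        keys = [inv[b] for b in bounds]
        for l in query.lengths:
            g = int(self.place(int(l), rng, size=1)[0])
            k = int(np.searchsorted(bounds, g, side="right") - 1)
            chrom = keys[k]
            start = g - self.offsets[chrom]
            rows.append((chrom, start, start + int(l)))
        return IntervalSet.from_records(rows)


def permute_segments(
    query: IntervalSet, workspace: IntervalSet, rng: np.random.Generator
) -> IntervalSet:
    """Length-preserving uniform random placement of ``query`` segments."""
    return SegmentSampler(workspace).permute(query, rng)


def enrichment_test(
    query: IntervalSet,
    annotation: IntervalSet,
    workspace: IntervalSet,
    n_sim: int = 1000,
    seed: int = 0,
    category: str = "annotation",
) -> EnrichmentResult:
    """Observed vs expected base-pair overlap under random placement.

    ``expected`` is the mean overlap across ``n_sim`` placements of
    length-matched segments in the workspace; ``fold = observed/expected``;
    the enrichment p-value is ``(1 + #{sim >= obs}) / (1 + n_sim)`` and the
    depletion p-value is the analogue with <=.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    ann = annotation.clip_to(workspace)
    if len(query) == 0:
        log.info("empty query for category %s; test skipped", category)
        return EnrichmentResult(category, 0, 0.0, None, None, None, n_sim, seed)

    observed = overlap_bp(query, ann)
    sampler = SegmentSampler(workspace)
    gs, ge, cum = coverage_index(ann.merge(), sampler.offsets)
    lengths = query.lengths.astype(np.int64)

    sims = np.zeros(n_sim, dtype=np.int64)
    for l in lengths:
        starts = sampler.place(int(l), rng, size=n_sim)
        ends = starts + int(l)
        sims += covered_before(ends, gs, ge, cum) - covered_before(starts, gs, ge, cum)

    expected = float(sims.mean())
    if expected == 0.0:
        log.warning("annotation %s misses the workspace; fold undefined", category)
        return EnrichmentResult(category, int(observed), 0.0, None, None, None,
                                n_sim, seed, sims)
    p_enr = (1 + int((sims >= observed).sum())) / (1 + n_sim)
    p_dep = (1 + int((sims <= observed).sum())) / (1 + n_sim)
    return EnrichmentResult(
        category=category,
        observed_bp=int(observed),
        expected_bp=expected,
        fold=float(observed / expected),
        p_enrich=p_enr,
        p_deplete=p_dep,
        n_simulations=n_sim,
        seed=seed,
        sim_overlaps=sims,
    )


def build_categories(
    annotation: AnnotationBundle,
    gene_sets: dict[str, set[str]] | None = None,
    known_genes: set[str] | None = None,
) -> dict[str, IntervalSet]:
    """Annotation categories for enrichment, clipped to the workspace.

    Always includes ``all_enhancers``, ``promoters`` and ``gene_bodies``;
    each entry of ``gene_sets`` adds an ``enhancers_of:<name>`` category
    holding the merged enhancers linked to any gene in the set. Unknown
    gene IDs are logged and skipped; an empty resulting category is kept
    (and flagged) so downstream reporting stays complete.
    """
    ws = annotation.workspace
    cats = {
        "all_enhancers": annotation.enhancers.clip_to(ws).merge(),
        "promoters": annotation.promoters.clip_to(ws).merge(),
        "gene_bodies": annotation.gene_bodies.clip_to(ws).merge(),
    }
    if gene_sets:
        links = annotation.enhancer_links()
        known = known_genes if known_genes is not None else set(links["gene_id"])
        for name, genes in gene_sets.items():
            unknown = set(genes) - known
            if unknown:
                log.warning(
                    "category %s: %d unknown gene IDs skipped", name, len(unknown)
                )
            sel = links[links["gene_id"].isin(set(genes) & known)]
            ivs = IntervalSet(
                sel["chrom"].to_numpy(), sel["start"].to_numpy(),
                sel["end"].to_numpy(),
            ) if len(sel) else IntervalSet()
            cat = ivs.clip_to(ws).merge() if len(ivs) else IntervalSet()
            if len(cat) == 0:
                log.warning("category enhancers_of:%s is empty", name)
            cats[f"enhancers_of:{name}"] = cat
    return cats


def enrichment_table(
    query: IntervalSet,
    categories: dict[str, IntervalSet],
    workspace: IntervalSet,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the enrichment test per category; one row each.

    Per-category seeds are derived from ``seed`` by enumeration order so a
    single integer reproduces the whole table.
    """
    rows = []
    for i, (name, ann) in enumerate(categories.items()):
        res = enrichment_test(
            query, ann, workspace, n_sim=n_sim, seed=int(seed) + i, category=name
        )
        rows.append(res.to_row())
    return pd.DataFrame(rows)
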