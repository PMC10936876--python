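"""Synthetic mini-genome benchmark with recorded ground truth.

Emulates the data the analysis consumes, at desk scale:

* a small multi-chromosome genome with gene bodies, promoters, linked
  enhancers, a sparse denylist and a mappable workspace;
* replicate coverage tracks (one bedGraph record per fixed-width bin) for a
  control and a stimulated condition plus IgG background tracks, with
  multiplicative signal planted in short domains that preferentially fall at
  enhancers of "responsive" genes when an enhancer bias is requested;
* a gene x sample negative-binomial count matrix across control, stimulated
  and stimulated+knockdown conditions, with a planted subset of responsive
  genes whose induction is abolished by the knockdown (the
  kinase-dependent set).

Every generator takes an explicit seed and is byte-deterministic. Planted
truth (domain locations and effects, responsive / dependent gene sets) is
recorded in :class:`SimulationTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .intervals import IntervalSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------- #
# types
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths and the analysis bin width (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 1000

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def chrom_intervals(self) -> IntervalSet:
        return IntervalSet(
            list(self.chrom_names),
            [0] * len(self.chrom_names),
            list(self.chrom_lengths),
        )


@dataclass
class AnnotationBundle:
    """Genome annotation: enhancers (name = linked gene IDs, comma separated),
    promoters and gene bodies (name = gene ID), denylist, and the mappable
    workspace (chromosomes minus denylist)."""

    enhancers: IntervalSet
    promoters: IntervalSet
    gene_bodies: IntervalSet
    denylist: IntervalSet
    workspace: IntervalSet

    def validate(self, layout: GenomeLayout, gene_ids=None) -> None:
        bounds = {c: l for c, l in zip(layout.chrom_names, layout.chrom_lengths)}
        for label in ("enhancers", "promoters", "gene_bodies", "denylist", "workspace"):
            ivs: IntervalSet = getattr(self, label)
            for chrom, start, end, _ in ivs:
                if chrom not in bounds or start < 0 or end > bounds[chrom]:
                    raise ValueError(f"{label} interval out of bounds: {chrom}:{start}-{end}")
        if self.workspace.intersect_bp(self.denylist) != 0:
            raise ValueError("workspace and denylist must be disjoint")
        if gene_ids is not None:
            known = set(gene_ids)
            for _, _, _, name in self.enhancers:
                for g in str(name).split(","):
                    if g != "." and g not in known:
                        raise ValueError(f"enhancer linked to unknown gene {g}")

    def enhancer_links(self) -> pd.DataFrame:
        """One row per (enhancer interval, linked gene) pair."""
        rows = []
        for chrom, start, end, name in self.enhancers:
            for g in str(name).split(","):
                if g and g != ".":
                    rows.append((chrom, start, end, g))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery scoring."""

    planted_domains: IntervalSet
    effects: np.ndarray  # per-domain fold increase of treated mean, >= 1
    enhancer_bias: float
    responsive_genes: set[str]
    dependent_genes: set[str]
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.planted_domains):
            raise ValueError("one effect per planted domain required")
        if len(self.effects) and (self.effects < 1).any():
            raise ValueError("effect multipliers must be >= 1")
        if not set(self.dependent_genes) <= set(self.responsive_genes):
            raise ValueError("dependent_genes must be a subset of responsive_genes")

    @property
    def independent_genes(self) -> set[str]:
        return set(self.responsive_genes) - set(self.dependent_genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_domains": [
                [c, int(s), int(e)] for c, s, e, _ in self.planted_domains
            ],
            "effects": [float(x) for x in self.effects],
            "enhancer_bias": self.enhancer_bias,
            "responsive_genes": sorted(self.responsive_genes),
            "dependent_genes": sorted(self.dependent_genes),
            "seeds": self.seeds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        doms = IntervalSet.from_records(
            [(c, s, e) for c, s, e in payload["planted_domains"]]
        )
        return cls(
            planted_domains=doms,
            effects=np.asarray(payload["effects"]),
            enhancer_bias=payload["enhancer_bias"],
            responsive_genes=set(payload["responsive_genes"]),
            dependent_genes=set(payload["dependent_genes"]),
            seeds=payload["seeds"],
        )


# ---------------------------------------------------------------------- #
# configuration (defaults are the benchmark's study conditions)
# ---------------------------------------------------------------------- #
@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 25_000_000
    bin_size: int = 1000
    n_genes: int = 500
    gene_length: int = 2000
    enhancers_per_gene: int = 2
    enhancer_length: int = 1000
    enhancer_min_distance: int = 2000  # from TSS
    enhancer_max_distance: int = 50_000
    n_denylist: int = 50
    denylist_length: int = 10_000
    promoter_upstream: int = 1000
    promoter_downstream: int = 500


@dataclass
class TruthConfig:
    n_domains: int = 50
    domain_length_bins: tuple[int, int] = (10, 20)
    effect: float = 3.0
    enhancer_bias: float = 1.0
    responsive_fraction: float = 0.2
    dependent_fraction: float = 0.2


@dataclass
class CoverageConfig:
    baseline_rate: float = 20.0
    noise_model: str = "poisson"  # or "negative_binomial"
    dispersion: float = 0.1
    replicates_per_condition: int = 3
    igg_rate: float = 10.0
    igg_mode: str = "shared"  # or "per_condition"


@dataclass
class ExpressionConfig:
    n_reps: int = 4
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    induced_fold: float = 4.0
    gene_baseline_sigma: float = 0.5  # log-normal spread of per-gene baselines
    conditions: tuple[str, ...] = ("control", "treated_60", "treated_60_KD")


# ---------------------------------------------------------------------- #
# generators
# ---------------------------------------------------------------------- #
def simulate_genome(
    config: GenomeConfig, seed: int
) -> tuple[GenomeLayout, AnnotationBundle, pd.DataFrame]:
    """Generate a genome layout, annotation bundle and gene table.

    Gene bodies are non-overlapping (placed on a jittered grid), promoters
    extend upstream/downstream of the TSS by the configured amounts, and
    each gene gets ``enhancers_per_gene`` linked distal enhancers placed
    within the mappable workspace. The denylist is drawn first as sparse
    random intervals and the workspace is the complement.
    """
    if config.n_chroms < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    lengths = tuple([config.chrom_length] * config.n_chroms)
    layout = GenomeLayout(names, lengths, config.bin_size)

    if config.n_genes * 2 * config.gene_length > layout.total_bp:
        raise ValueError("requested annotation length exceeds genome length")

    # denylist, then workspace = chromosomes - denylist
    deny_rows = []
    if config.n_denylist > 0 and config.denylist_length > 0:
        probs = np.asarray(lengths, dtype=float) / layout.total_bp
        for _ in range(config.n_denylist):
            ci = int(rng.choice(len(names), p=probs))
            start = int(rng.integers(0, lengths[ci] - config.denylist_length))
            deny_rows.append((names[ci], start, start + config.denylist_length))
    denylist = IntervalSet.from_records(deny_rows).merge()
    workspace = layout.chrom_intervals().subtract(denylist)

    # genes on a jittered grid of step 2*gene_length -> never overlapping
    per_chrom = _split_counts(config.n_genes, np.asarray(lengths, float), rng)
    gene_rows = []
    gid = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        if n_on_chrom == 0:
            continue
        step = 2 * config.gene_length
        n_slots = lengths[ci] // step
        if n_on_chrom > n_slots:
            raise ValueError("requested annotation length exceeds genome length")
        slots = np.sort(rng.choice(n_slots, size=n_on_chrom, replace=False))
        for slot in slots:
            jitter = int(rng.integers(0, config.gene_length))
            start = int(slot) * step + jitter
            end = min(start + config.gene_length, lengths[ci])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene{gid:04d}", names[ci], start, end, strand))
            gid += 1
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    if len(gene_table):
        gene_table["tss"] = np.where(
            gene_table["strand"] == "+", gene_table["start"], gene_table["end"]
        )
    else:
        gene_table["tss"] = pd.Series(dtype=np.int64)

    bounds = dict(zip(names, lengths))
    gene_bodies = IntervalSet(
        gene_table["chrom"], gene_table["start"], gene_table["end"],
        gene_table["gene_id"],
    ) if len(gene_table) else IntervalSet()

    promoters = _make_promoters(gene_table, bounds, config)
    enhancers = _make_enhancers(gene_table, bounds, workspace, config, rng)

    bundle = AnnotationBundle(
        enhancers=enhancers,
        promoters=promoters,
        gene_bodies=gene_bodies,
        denylist=denylist,
        workspace=workspace,
    )
    bundle.validate(layout, gene_table["gene_id"])
    return layout, bundle, gene_table


def _split_counts(total: int, weights: np.ndarray, rng) -> np.ndarray:
    """Deterministically split ``total`` items across weighted groups."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    base = np.floor(total * weights / weights.sum()).astype(int)
    short = total - base.sum()
    if short > 0:
        extra = rng.choice(len(weights), size=short, replace=False)
        base[extra] += 1
    return base


def _make_promoters(gene_table, bounds, config: GenomeConfig) -> IntervalSet:
    rows = []
    for g in gene_table.itertuples(index=False):
        if g.strand == "+":
            lo = g.tss - config.promoter_upstream
            hi = g.tss + config.promoter_downstream
        else:
            lo = g.tss - config.promoter_downstream
            hi = g.tss + config.promoter_upstream
        lo = max(0, int(lo))
        hi = min(bounds[g.chrom], int(hi))
        if lo < hi:
            rows.append((g.chrom, lo, hi, g.gene_id))
    return IntervalSet.from_records(rows)


def _make_enhancers(gene_table, bounds, workspace, config: GenomeConfig, rng) -> IntervalSet:
    rows = []
    ws_by_chrom = {c: g for c, g in workspace.df.groupby("chrom", sort=False)}
    for g in gene_table.itertuples(index=False):
        for _ in range(config.enhancers_per_gene):
            placed = None
            for _attempt in range(200):
                d = int(rng.integers(config.enhancer_min_distance,
                                     config.enhancer_max_distance))
                side = -1 if rng.random() < 0.5 else 1
                start = int(g.tss) + side * d
                start = min(max(start, 0), bounds[g.chrom] - config.enhancer_length)
                end = start + config.enhancer_length
                if _within_workspace(ws_by_chrom.get(g.chrom), start, end):
                    placed = (g.chrom, start, end)
                    break
            if placed is None:
                # dense denylist near the gene: fall back to any workspace slot
                placed = _random_workspace_slot(
                    ws_by_chrom.get(g.chrom), g.chrom, config.enhancer_length, rng
                )
            rows.append((*placed, g.gene_id))
    return IntervalSet.from_records(rows)


def _within_workspace(ws_group, start: int, end: int) -> bool:
    if ws_group is None:
        return False
    s = ws_group["start"].to_numpy()
    e = ws_group["end"].to_numpy()
    return bool(np.any((s <= start) & (e >= end)))


def _random_workspace_slot(ws_group, chrom: str, length: int, rng):
    if ws_group is None:
        raise ValueError(f"no workspace on {chrom} to place an enhancer")
    s = ws_group["start"].to_numpy()
    e = ws_group["end"].to_numpy()
    valid = e - s - length + 1
    valid = np.maximum(valid, 0)
    if valid.sum() == 0:
        raise ValueError(f"workspace on {chrom} too fragmented for enhancer")
    k = int(rng.choice(len(s), p=valid / valid.sum()))
    start = int(s[k] + rng.integers(0, valid[k]))
    return chrom, start, start + length


def plant_truth(
    layout: GenomeLayout,
    annotation: AnnotationBundle,
    gene_table: pd.DataFrame,
    params: TruthConfig,
    seed: int,
) -> SimulationTruth:
    """Plant differential-signal domains and responsive/dependent gene sets.

    Placement model: each domain is a run of whole bins lying entirely inside
    the workspace. With probability ``1 - 1/enhancer_bias`` (0 when bias <= 1)
    the domain is relocated to the bin containing the midpoint of a randomly
    chosen enhancer of a responsive gene; otherwise it is placed uniformly
    over all bin-aligned workspace positions. Bias 1 therefore yields exactly
    uniform placement, and the expected fraction of domains at responsive
    enhancers increases monotonically with the bias. Placements are drawn
    independently (they may overlap; coverage simulation takes the maximum
    effect per bin).
    """
    if params.enhancer_bias < 0:
        raise ValueError("enhancer_bias must be >= 0")
    for frac in (params.responsive_fraction, params.dependent_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    gene_ids = list(gene_table["gene_id"])
    n_resp = int(round(params.responsive_fraction * len(gene_ids)))
    responsive = set(rng.choice(gene_ids, size=n_resp, replace=False)) if n_resp else set()
    n_dep = int(round(params.dependent_fraction * len(responsive)))
    dependent = (
        set(rng.choice(sorted(responsive), size=n_dep, replace=False)) if n_dep else set()
    )

    from .binning import make_bins  # local import to avoid a cycle

    bins = make_bins(layout, layout.bin_size)
    in_ws = ~bins.overlaps_any(annotation.denylist)
    full_width = bins.lengths == layout.bin_size
    # candidate start bins per domain length: run of L usable bins on one chrom
    chrom_arr = bins.chroms
    usable = in_ws & full_width

    links = annotation.enhancer_links()
    resp_links = links[links["gene_id"].isin(responsive)] if len(links) else links

    lmin, lmax = params.domain_length_bins
    if lmin < 1 or lmax < lmin:
        raise ValueError("invalid domain_length_bins")
    reloc_p = max(0.0, 1.0 - 1.0 / params.enhancer_bias) if params.enhancer_bias > 0 else 0.0

    # precompute valid uniform start indices per length
    valid_starts: dict[int, np.ndarray] = {}
    for L in range(lmin, lmax + 1):
        ok = usable.copy()
        for off in range(1, L):
            shifted = np.zeros_like(usable)
            shifted[:-off] = usable[off:] & (chrom_arr[:-off] == chrom_arr[off:])
            ok &= shifted
        valid_starts[L] = np.flatnonzero(ok)
        if len(valid_starts[L]) == 0:
            raise ValueError(
                f"cannot place domains of {L} bins within the workspace"
            )

    bin_starts = bins.starts
    bin_ends = bins.ends
    dom_rows = []
    for _ in range(params.n_domains):
        L = int(rng.integers(lmin, lmax + 1))
        placed = False
        if reloc_p > 0 and len(resp_links) and rng.random() < reloc_p:
            e = resp_links.iloc[int(rng.integers(0, len(resp_links)))]
            mid = (int(e["start"]) + int(e["end"])) // 2
            b0 = _bin_index_at(bins, str(e["chrom"]), mid)
            if b0 is not None:
                cand = b0 - int(rng.integers(0, L))  # domain covers the enhancer bin
                if cand in valid_starts[L] or _run_ok(cand, L, usable, chrom_arr):
                    dom_rows.append(
                        (chrom_arr[cand], int(bin_starts[cand]), int(bin_ends[cand + L - 1]))
                    )
                    placed = True
        if not placed:
            idx = int(rng.choice(valid_starts[L]))
            dom_rows.append(
                (chrom_arr[idx], int(bin_starts[idx]), int(bin_ends[idx + L - 1]))
            )
    domains = IntervalSet.from_records(dom_rows)
    effects = np.full(len(domains), float(params.effect))
    if len(effects) and (effects < 1).any():
        raise ValueError("effect must be >= 1")
    return SimulationTruth(
        planted_domains=domains,
        effects=effects,
        enhancer_bias=params.enhancer_bias,
        responsive_genes=responsive,
        dependent_genes=dependent,
        seeds={"plant_truth": int(seed)},
    )


def _bin_index_at(bins: IntervalSet, chrom: str, pos: int) -> int | None:
    hit = np.flatnonzero(
        (bins.chroms == chrom) & (bins.starts <= pos) & (bins.ends > pos)
    )
    return int(hit[0]) if len(hit) else None


def _run_ok(start_idx: int, L: int, usable: np.ndarray, chrom_arr: np.ndarray) -> bool:
    if start_idx < 0 or start_idx + L > len(usable):
        return False
    if not usable[start_idx : start_idx + L].all():
        return False
    return bool((chrom_arr[start_idx : start_idx + L] == chrom_arr[start_idx]).all())


def simulate_coverage(
    layout: GenomeLayout,
    truth: SimulationTruth,
    params: CoverageConfig,
    seed: int,
    outdir: str | Path | None = None,
):
    """Draw per-bin counts per replicate and (optionally) write bedGraphs.

    Treated-condition target replicates have mean ``baseline_rate x effect``
    in bins overlapped by a planted domain and ``baseline_rate`` elsewhere;
    control targets sit at baseline everywhere; one IgG track per condition
    has mean ``igg_rate`` everywhere. Counts are i.i.d. Poisson or
    gamma-Poisson (negative binomial) per bin and replicate.

    Returns ``(BinMatrix(stage="raw"), sample_sheet)``.
    """
    from .binning import BinMatrix, make_bins

    if params.replicates_per_condition < 1:
        raise ValueError("need at least one replicate per condition")
    if params.baseline_rate <= 0 or params.igg_rate < 0:
        raise ValueError("rates must be positive")
    if params.noise_model not in ("poisson", "negative_binomial"):
        raise ValueError(f"unknown noise model {params.noise_model!r}")
    if params.noise_model == "negative_binomial" and params.dispersion <= 0:
        raise ValueError("negative binomial dispersion must be > 0")

    rng = np.random.default_rng(seed)
    bins = make_bins(layout, layout.bin_size)
    width_frac = bins.lengths / layout.bin_size  # terminal bins scaled down

    effect = np.ones(len(bins))
    hit = bins.overlaps_any(truth.planted_domains)
    if hit.any() and len(truth.planted_domains):
        # per-bin effect = max effect over covering domains
        for (chrom, s, e, _), f in zip(truth.planted_domains, truth.effects):
            m = (bins.chroms == chrom) & (bins.starts < e) & (bins.ends > s)
            effect[m] = np.maximum(effect[m], f)

    if params.igg_mode not in ("shared", "per_condition"):
        raise ValueError(f"unknown igg_mode {params.igg_mode!r}")
    nrep = params.replicates_per_condition
    rows = []
    sample_means = {}
    for cond in ("control", "treated"):
        cond_effect = effect if cond == "treated" else 1.0
        for r in range(1, nrep + 1):
            sid = f"{cond}_rep{r}"
            rows.append((sid, cond, r, "target"))
            sample_means[sid] = params.baseline_rate * cond_effect * width_frac
        if params.igg_mode == "per_condition":
            sid = f"igg_{cond}"
            rows.append((sid, cond, 1, "igg_control"))
            sample_means[sid] = params.igg_rate * width_frac
    if params.igg_mode == "shared":
        rows.append(("igg", "shared", 1, "igg_control"))
        sample_means["igg"] = params.igg_rate * width_frac

    sheet = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "role"])
    values = np.empty((len(bins), len(sheet)))
    for j, sid in enumerate(sheet["sample_id"]):
        mean = np.broadcast_to(sample_means[sid], (len(bins),))
        if params.noise_model == "poisson":
            values[:, j] = rng.poisson(mean)
        else:
            lam = rng.gamma(1.0 / params.dispersion, mean * params.dispersion)
            values[:, j] = rng.poisson(lam)

    matrix = BinMatrix(bins=bins, values=values,
                       samples=list(sheet["sample_id"]), stage="raw")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for j, sid in enumerate(sheet["sample_id"]):
            df = bins.df[["chrom", "start", "end"]].copy()
            df["value"] = values[:, j]
            cio.write_bedgraph(df, outdir / f"{sid}.bedgraph")
        cio.write_sample_sheet(sheet, outdir / "samples.tsv")
    return matrix, sheet


def simulate_expression(
    gene_table: pd.DataFrame,
    truth: SimulationTruth,
    params: ExpressionConfig,
    seed: int,
    outdir: str | Path | None = None,
):
    """Negative-binomial counts across the three conditions.

    Per-gene baselines are drawn log-normally around ``baseline_mean``.
    Responsive genes have mean ``baseline x induced_fold`` under stimulation;
    for knockdown-dependent genes the mean reverts to baseline under
    stimulation+knockdown, while independent responsive genes stay induced.

    Returns ``(counts DataFrame genes x samples, sample metadata DataFrame)``.
    """
    if params.dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if params.induced_fold < 1:
        raise ValueError("induced_fold must be >= 1")
    if params.n_reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)

    genes = list(gene_table["gene_id"])
    base = params.baseline_mean * np.exp(
        rng.normal(0.0, params.gene_baseline_sigma, size=len(genes))
    )
    responsive = np.array([g in truth.responsive_genes for g in genes])
    dependent = np.array([g in truth.dependent_genes for g in genes])

    cond_means = {}
    for cond in params.conditions:
        mu = base.copy()
        if cond.startswith("treated"):
            induced = responsive.copy()
            if cond.endswith("_KD"):
                induced &= ~dependent  # knockdown abolishes dependent induction
            mu[induced] *= params.induced_fold
        cond_means[cond] = mu

    cols, meta_rows = [], []
    data = []
    for cond in params.conditions:
        for r in range(1, params.n_reps + 1):
            sid = f"{cond}_rep{r}"
            cols.append(sid)
            meta_rows.append((sid, cond, r))
            lam = rng.gamma(1.0 / params.dispersion,
                            cond_means[cond] * params.dispersion)
            data.append(rng.poisson(lam))
    counts = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene_id"),
                          columns=cols)
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "replicate"])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_counts_tsv(counts, outdir / "counts.tsv")
        metadata.to_csv(outdir / "expression_samples.tsv", sep="\t", index=False)
    return counts, metadata


def write_annotation(bundle: AnnotationBundle, outdir: str | Path) -> None:
    """Write the annotation bundle as BED files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label in ("enhancers", "promoters", "gene_bodies", "denylist", "workspace"):
        cio.write_bed(getattr(bundle, label), outdir / f"{label}.bed")


def read_annotation(indir: str | Path) -> AnnotationBundle:
    indir = Path(indir)
    return AnnotationBundle(
        enhancers=cio.read_bed(indir / "enhancers.bed"),
        promoters=cio.read_bed(indir / "promoters.bed"),
        gene_bodies=cio.read_bed(indir / "gene_bodies.bed"),
        denylist=cio.read_bed(indir / "denylist.bed"),
        workspace=cio.read_bed(indir / "workspace.bed"),
    )
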