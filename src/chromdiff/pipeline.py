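"""End-to-end orchestration from a single YAML config.

Runs (optionally) the synthetic benchmark generators, then binning ->
domain calling -> gene classification (when counts exist) -> category
building -> enrichment, writing every stage artifact plus a JSON/text
report. A single global seed deterministically derives per-stage seeds so
any stage can be rerun in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import binning, classify, domains, enrichment, io as cio, synthetic

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (CRC32 of 'seed:stage')."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Validated parameters for a full run.

    ``synthetic: true`` generates the benchmark inputs; otherwise ``paths``
    must point at coverage tracks, a sample sheet, annotation BEDs and
    (optionally) a count matrix with sample metadata.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    synthetic: bool = True
    # analysis parameters (defaults are the published pipeline's values)
    bin_size: int = 1000
    window: int = 10
    alpha_domains: float = 0.005
    alpha_de: float = 0.05
    lfc_min: float = 0.5
    n_sim: int = 1000
    k_clusters: int = 2
    direction: str = "up"
    with_expression: bool = True
    # generator parameters (used when synthetic)
    genome: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    # external inputs (used when not synthetic)
    paths: dict = field(default_factory=dict)

    _RANGES = {
        "alpha_domains": (0.0, 1.0),
        "alpha_de": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.bin_size <= 0 or self.window < 1 or self.n_sim < 1:
            raise ValueError("bin_size, window and n_sim must be positive")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if not self.synthetic:
            required = ["tracks_dir", "sample_sheet", "annotation_dir"]
            missing = [
                k for k in required
                if k not in self.paths or not Path(self.paths[k]).exists()
            ]
            if missing:
                raise ValueError(f"missing required paths: {missing}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, fill defaults, reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded
    so identical analyses hash identically wherever they are written)."""
    payload = dataclasses.asdict(cfg)
    payload.pop("outdir", None)
    return hashlib.sha256(
        yaml.safe_dump(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _generator_configs(cfg: PipelineConfig):
    return (
        synthetic.GenomeConfig(**cfg.genome),
        synthetic.TruthConfig(**cfg.truth),
        synthetic.CoverageConfig(**cfg.coverage),
        synthetic.ExpressionConfig(**cfg.expression),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the machine-readable report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "chromdiff_version": __version__,
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
        }
    }

    try:
        if cfg.synthetic:
            (layout, bundle, gene_table, truth, raw, sheet,
             counts, meta) = _simulate_inputs(cfg, outdir)
        else:
            (layout, bundle, gene_table, truth, raw, sheet,
             counts, meta) = _load_inputs(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # ---- binning -------------------------------------------------- #
    try:
        targets = raw.select_samples(
            list(sheet.loc[sheet["role"] == "target", "sample_id"])
        )
        controls = raw.select_samples(
            list(sheet.loc[sheet["role"] == "igg_control", "sample_id"])
        )
        smoothed = binning.preprocess(
            targets, controls, bundle.denylist, sheet, window=cfg.window
        )
        smoothed.to_tsv(outdir / "bin_matrix_smoothed.tsv")
        binning.condition_mean_tracks(smoothed, sheet, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 'binning' failed: {exc}") from exc

    # ---- domain calling ------------------------------------------- #
    try:
        stats = domains.per_bin_test(smoothed, sheet, ("treated", "control"))
        call = domains.call_domains(
            stats, smoothed.bins, alpha=cfg.alpha_domains, direction=cfg.direction
        )
        summary = domains.summarize_domains(call, bundle.workspace)
        call.write(outdir)
        report["domains"] = summary
        if truth is not None:
            report["domain_recovery"] = domains.recovery_scores(
                call.domains, truth.planted_domains
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'domain_caller' failed: {exc}") from exc

    # ---- classification (optional) -------------------------------- #
    gene_sets = None
    if counts is not None:
        try:
            em = classify.ExpressionMatrix(counts, meta)
            gene_sets, clusters, _ = classify.classify_from_counts(
                em, lfc_min=cfg.lfc_min, alpha=cfg.alpha_de, k=cfg.k_clusters
            )
            gene_sets.write(outdir / "gene_sets")
            clusters.to_csv(outdir / "gene_sets" / "clusters.tsv", sep="\t")
            report["gene_sets"] = {
                k: len(v) for k, v in gene_sets.as_dict().items()
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'response_classifier' failed: {exc}") from exc

    # ---- enrichment ------------------------------------------------ #
    try:
        named_sets = {}
        if gene_sets is not None:
            named_sets = {
                "up_60": gene_sets.up_60,
                "dependent": gene_sets.dependent,
                "independent": gene_sets.independent,
            }
            named_sets = {k: v for k, v in named_sets.items() if v}
        cats = enrichment.build_categories(
            bundle, named_sets,
            known_genes=set(gene_table["gene_id"]) if gene_table is not None else None,
        )
        table = enrichment.enrichment_table(
            call.domains, cats, bundle.workspace,
            n_sim=cfg.n_sim, seed=stage_seed(cfg.seed, "enrichment"),
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            r["category"]: {
                "observed_bp": r["observed_bp"],
                "expected_bp": r["expected_bp"],
                "fold": r["fold"],
                "p_enrich": r["p_enrich"],
            }
            for r in table.to_dict("records")
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    _write_report(report, outdir)
    return report


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    gcfg, tcfg, ccfg, ecfg = _generator_configs(cfg)
    if cfg.bin_size != gcfg.bin_size:
        gcfg = dataclasses.replace(gcfg, bin_size=cfg.bin_size)
    layout, bundle, gene_table = synthetic.simulate_genome(
        gcfg, stage_seed(cfg.seed, "genome")
    )
    truth = synthetic.plant_truth(
        layout, bundle, gene_table, tcfg, stage_seed(cfg.seed, "truth")
    )
    simdir = outdir / "simulated"
    raw, sheet = synthetic.simulate_coverage(
        layout, truth, ccfg, stage_seed(cfg.seed, "coverage"), outdir=simdir
    )
    counts = meta = None
    if cfg.with_expression:
        counts, meta = synthetic.simulate_expression(
            gene_table, truth, ecfg, stage_seed(cfg.seed, "expression"),
            outdir=simdir,
        )
    synthetic.write_annotation(bundle, simdir / "annotation")
    gene_table.to_csv(simdir / "genes.tsv", sep="\t", index=False)
    truth.to_json(simdir / "truth.json")
    return layout, bundle, gene_table, truth, raw, sheet, counts, meta


def _load_inputs(cfg: PipelineConfig):
    import pandas as pd

    paths = cfg.paths
    bundle = synthetic.read_annotation(paths["annotation_dir"])
    sheet = cio.read_sample_sheet(paths["sample_sheet"])
    chrom_iv = bundle.workspace.merge()
    chrom_names, chrom_lengths = [], []
    for c in chrom_iv.chrom_order():
        chrom_names.append(c)
        chrom_lengths.append(int(chrom_iv.df.loc[chrom_iv.df["chrom"] == c, "end"].max()))
    layout = synthetic.GenomeLayout(
        tuple(chrom_names), tuple(chrom_lengths), cfg.bin_size
    )
    bins = binning.make_bins(layout, cfg.bin_size)
    tracks = {
        r.sample_id: Path(paths["tracks_dir"]) / f"{r.sample_id}.bedgraph"
        for r in sheet.itertuples(index=False)
    }
    raw = binning.matrix_from_tracks(tracks, bins, layout)
    gene_table = None
    if "gene_table" in paths:
        gene_table = pd.read_csv(paths["gene_table"], sep="\t")
    counts = meta = None
    if "counts" in paths:
        counts = cio.read_counts_tsv(paths["counts"])
        meta = pd.read_csv(paths["expression_samples"], sep="\t")
    truth = None
    if "truth" in paths:
        truth = synthetic.SimulationTruth.from_json(paths["truth"])
    return layout, bundle, gene_table, truth, raw, sheet, counts, meta


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable) + "\n"
    )
    lines = ["chromdiff pipeline report", "=" * 25]
    for section, payload in report.items():
        lines.append(f"\n[{section}]")
        if isinstance(payload, dict):
            for k, v in payload.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {payload}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
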