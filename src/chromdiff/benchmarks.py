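"""Standard synthetic-benchmark experiments.

Each experiment builds its inputs with the generators, runs the analysis
stages, and measures an operating characteristic of the method: type-I
error of the domain caller on null data, recovery of planted domains,
calibration of the permutation enrichment, the enhancer-bias fold gradient,
and recovery of planted knockdown-dependent genes. The analysis drivers,
the test suite and the acceptance script all call these functions so every
reported number comes from one code path.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import binning, classify, domains, enrichment, synthetic as syn
from .intervals import IntervalSet

log = logging.getLogger(__name__)


def domain_call_run(
    gcfg: syn.GenomeConfig,
    tcfg: syn.TruthConfig,
    ccfg: syn.CoverageConfig,
    seed: int,
    alpha: float = 0.005,
    window: int = 10,
):
    """Simulate coverage and run the full calling chain once.

    Returns ``(bundle, gene_table, truth, bin_stats, DomainCallResult)``.
    """
    layout, bundle, gene_table = syn.simulate_genome(gcfg, seed)
    truth = syn.plant_truth(layout, bundle, gene_table, tcfg, seed + 1)
    raw, sheet = syn.simulate_coverage(layout, truth, ccfg, seed + 2)
    targets = raw.select_samples(
        list(sheet.loc[sheet["role"] == "target", "sample_id"])
    )
    controls = raw.select_samples(
        list(sheet.loc[sheet["role"] == "igg_control", "sample_id"])
    )
    smoothed = binning.preprocess(targets, controls, bundle.denylist, sheet,
                                  window=window)
    stats = domains.per_bin_test(smoothed, sheet, ("treated", "control"))
    call = domains.call_domains(stats, smoothed.bins, alpha=alpha)
    domains.summarize_domains(call, bundle.workspace)
    return bundle, gene_table, truth, stats, call


# 10,000-bin genome for null-calibration runs
NULL_GENOME = syn.GenomeConfig(
    n_chroms=2, chrom_length=5_000_000, n_genes=0, n_denylist=0
)


def null_type_one_error(seed: int, n_seeds: int = 20, alpha: float = 0.005) -> dict:
    """Domain caller on data with no planted effect.

    Pools the fraction of raw p < 0.05 over ``n_seeds`` independent null
    simulations and counts how often zero domains survive BH at ``alpha``.
    """
    fracs, zero_runs, n_bins = [], 0, 0
    for k in range(n_seeds):
        _, _, _, stats, call = domain_call_run(
            NULL_GENOME, syn.TruthConfig(n_domains=0), syn.CoverageConfig(),
            seed=seed + 1000 * k, alpha=alpha,
        )
        fracs.append(float((stats["p"] < 0.05).mean()))
        zero_runs += len(call.domains) == 0
        n_bins = len(stats)
    return {
        "raw_p_fraction": float(np.mean(fracs)),
        "zero_domain_fraction": zero_runs / n_seeds,
        "n_bins": n_bins,
        "n_seeds": n_seeds,
    }


def recovery_experiment(
    seed: int,
    n_domains: int = 50,
    effect: float | None = None,
    two_sd_effect: bool = False,
) -> dict:
    """Sensitivity/precision of domain recovery against planted truth.

    ``two_sd_effect=True`` plants a multiplicative effect equal to two
    within-replicate standard deviations of the raw per-bin counts
    (``1 + 2/sqrt(baseline)`` for Poisson noise).
    """
    ccfg = syn.CoverageConfig()
    if two_sd_effect:
        effect = 1.0 + 2.0 / np.sqrt(ccfg.baseline_rate)
    tcfg = syn.TruthConfig(n_domains=n_domains)
    if effect is not None:
        tcfg = dataclasses.replace(tcfg, effect=float(effect))
    _, _, truth, _, call = domain_call_run(
        syn.GenomeConfig(), tcfg, ccfg, seed=seed
    )
    scores = domains.recovery_scores(call.domains, truth.planted_domains)
    scores.update(
        n_called=len(call.domains),
        n_planted=len(truth.planted_domains),
        effect=float(tcfg.effect),
        summary=call.summary,
    )
    return scores


def gradient_experiment(
    seed: int,
    biases=(1.0, 2.0, 4.0),
    n_domains: int = 100,
    n_sim: int = 1000,
    use_classifier_sets: bool = True,
) -> pd.DataFrame:
    """Enrichment folds at responsive-gene enhancers across enhancer biases.

    Runs the full chain per bias: plant domains with the bias, call them,
    classify the expression matrix (or fall back to planted truth when
    ``use_classifier_sets`` is off), and test called domains against the
    responsive-gene enhancer category and all enhancers.
    """
    rows = []
    for i, bias in enumerate(biases):
        run_seed = seed + 10_000 * i
        tcfg = syn.TruthConfig(n_domains=n_domains, enhancer_bias=float(bias))
        bundle, gene_table, truth, _, call = domain_call_run(
            syn.GenomeConfig(), tcfg, syn.CoverageConfig(), seed=run_seed
        )
        if use_classifier_sets:
            counts, meta = syn.simulate_expression(
                gene_table, truth, syn.ExpressionConfig(), seed=run_seed + 5
            )
            sets, _, _ = classify.classify_from_counts(
                classify.ExpressionMatrix(counts, meta)
            )
            responsive = sets.up_60 or truth.responsive_genes
        else:
            responsive = truth.responsive_genes
        cats = enrichment.build_categories(
            bundle, {"responsive": responsive},
            known_genes=set(gene_table["gene_id"]),
        )
        for cat in ("all_enhancers", "enhancers_of:responsive"):
            res = enrichment.enrichment_test(
                call.domains, cats[cat], bundle.workspace,
                n_sim=n_sim, seed=run_seed + 7, category=cat,
            )
            rel_se = (
                res.sim_overlaps.std(ddof=1) / res.expected_bp
                if res.expected_bp else np.nan
            )
            rows.append(
                {
                    "bias": bias,
                    "category": cat,
                    "fold": res.fold,
                    "observed_bp": res.observed_bp,
                    "expected_bp": res.expected_bp,
                    "p_enrich": res.p_enrich,
                    "null_rel_sd": rel_se,
                    "n_domains_called": len(call.domains),
                }
            )
    return pd.DataFrame(rows)


def calibration_experiment(
    seed: int, n_repeats: int = 500, n_sim: int = 199,
    n_segments: int = 10, segment_bp: int = 2000,
) -> dict:
    """Enrichment test on queries drawn from the null placement sampler.

    Fold should average 1 and the enrichment p should fall below 0.05 in
    about 5% of repeats.
    """
    layout, bundle, _ = syn.simulate_genome(
        syn.GenomeConfig(n_chroms=2, chrom_length=5_000_000, n_genes=100),
        seed,
    )
    ws = bundle.workspace
    ann = bundle.enhancers.clip_to(ws).merge()
    template = IntervalSet(
        ["chr1"] * n_segments,
        np.arange(n_segments) * 2 * segment_bp,
        np.arange(n_segments) * 2 * segment_bp + segment_bp,
    )
    rng = np.random.default_rng(seed + 1)
    sampler = enrichment.SegmentSampler(ws)
    folds, low_p = [], 0
    for i in range(n_repeats):
        q = sampler.permute(template, rng)
        res = enrichment.enrichment_test(
            q, ann, ws, n_sim=n_sim, seed=seed + 2 + i
        )
        folds.append(res.fold)
        low_p += res.p_enrich < 0.05
    folds = np.asarray(folds, dtype=float)
    return {
        "fold_mean": float(folds.mean()),
        "fold_se": float(folds.std(ddof=1) / np.sqrt(n_repeats)),
        "p_below_05_fraction": low_p / n_repeats,
        "n_repeats": n_repeats,
        "n_sim": n_sim,
    }


def classifier_experiment(seed: int) -> dict:
    """Recovery of planted knockdown-dependent genes at default conditions
    (100 responsive genes of which 20 dependent; induced fold 4; 4
    replicates; NB dispersion 0.05)."""
    layout, bundle, gene_table = syn.simulate_genome(syn.GenomeConfig(), seed)
    truth = syn.plant_truth(
        layout, bundle, gene_table, syn.TruthConfig(), seed + 1
    )
    counts, meta = syn.simulate_expression(
        gene_table, truth, syn.ExpressionConfig(), seed + 2
    )
    sets, clusters, _ = classify.classify_from_counts(
        classify.ExpressionMatrix(counts, meta)
    )
    dep_true = truth.dependent_genes
    indep_true = truth.independent_genes
    sens = len(sets.dependent & dep_true) / len(dep_true) if dep_true else None
    spec = (
        len(indep_true - sets.dependent) / len(indep_true) if indep_true else None
    )
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_up_60": len(sets.up_60),
        "n_dependent_called": len(sets.dependent),
        "n_independent_called": len(sets.independent),
        "n_dependent_true": len(dep_true),
        "n_independent_true": len(indep_true),
        "partition_ok": sets.dependent | sets.independent == sets.up_60,
    }
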