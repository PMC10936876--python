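import numpy as np
import pandas as pd
import pytest

from chromdiff import binning, domains, synthetic as syn
from chromdiff.intervals import IntervalSet


@pytest.fixture(scope="session")
def small_genome():
    """A 4 Mb / 4000-bin genome with annotations — fast unit-test scale."""
    cfg = syn.GenomeConfig(
        n_chroms=2, chrom_length=2_000_000, n_genes=60,
        n_denylist=6, denylist_length=5000,
    )
    return syn.simulate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    layout, bundle, genes = small_genome
    tcfg = syn.TruthConfig(n_domains=8)
    return syn.plant_truth(layout, bundle, genes, tcfg, seed=12)


@pytest.fixture(scope="session")
def small_run(small_genome, small_truth):
    """Coverage simulation + full preprocessing + per-bin tests."""
    layout, bundle, genes = small_genome
    raw, sheet = syn.simulate_coverage(
        layout, small_truth, syn.CoverageConfig(), seed=13
    )
    targets = raw.select_samples(
        list(sheet.loc[sheet["role"] == "target", "sample_id"])
    )
    controls = raw.select_samples(
        list(sheet.loc[sheet["role"] == "igg_control", "sample_id"])
    )
    smoothed = binning.preprocess(targets, controls, bundle.denylist, sheet)
    stats = domains.per_bin_test(smoothed, sheet)
    return smoothed, stats, sheet


def intervals_from(*triples) -> IntervalSet:
    return IntervalSet.from_records(list(triples))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
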