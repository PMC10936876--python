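"""Ground-truth generators: determinism, planted structure, noise moments."""

import numpy as np
import pandas as pd
import pytest

from chromdiff import binning, classify, domains, io as cio, synthetic as syn
from chromdiff.intervals import IntervalSet


class TestSimulateGenome:
    def test_empty_genome_has_full_workspace(self):
        cfg = syn.GenomeConfig(
            n_chroms=1, chrom_length=10_000, n_genes=0, n_denylist=0,
        )
        layout, bundle, genes = syn.simulate_genome(cfg, seed=0)
        assert list(bundle.workspace) == [("chr1", 0, 10_000, ".")]
        assert len(bundle.enhancers) == 0
        assert len(bundle.promoters) == 0
        assert len(genes) == 0

    def test_deterministic_for_fixed_seed(self, tmp_path):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=500_000, n_genes=20,
                               n_denylist=3, denylist_length=2000)
        out = []
        for d in ("a", "b"):
            layout, bundle, genes = syn.simulate_genome(cfg, seed=42)
            syn.write_annotation(bundle, tmp_path / d)
            genes.to_csv(tmp_path / d / "genes.tsv", sep="\t", index=False)
            out.append(
                b"".join(sorted(p.read_bytes() for p in (tmp_path / d).iterdir()))
            )
        assert out[0] == out[1]

    def test_enhancer_link_count_matches_config(self):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=2_000_000, n_genes=100,
                               enhancers_per_gene=2, n_denylist=0)
        _, bundle, genes = syn.simulate_genome(cfg, seed=5)
        links = bundle.enhancer_links()
        assert len(links) == 200
        assert set(links["gene_id"]) == set(genes["gene_id"])

    def test_gene_bodies_do_not_overlap(self, small_genome):
        _, bundle, _ = small_genome
        merged = bundle.gene_bodies.merge(gap=-1) if len(bundle.gene_bodies) else None
        # merging with no gap tolerance must not fuse distinct bodies
        assert bundle.gene_bodies.total_bp == bundle.gene_bodies.merge().total_bp

    def test_promoters_derive_from_tss_with_strand(self, small_genome):
        _, bundle, genes = small_genome
        prom = {name: (s, e) for _, s, e, name in bundle.promoters}
        for g in genes.itertuples(index=False):
            s, e = prom[g.gene_id]
            if g.strand == "+":
                assert (s, e) == (max(0, g.tss - 1000), g.tss + 500)
            else:
                assert (s, e) == (max(0, g.tss - 500), g.tss + 1000)

    def test_workspace_and_denylist_disjoint(self, small_genome):
        _, bundle, _ = small_genome
        assert bundle.workspace.intersect_bp(bundle.denylist) == 0

    def test_overfull_genome_rejected(self):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=10_000, n_genes=50)
        with pytest.raises(ValueError, match="exceeds genome length"):
            syn.simulate_genome(cfg, seed=0)


class TestPlantTruth:
    def test_no_dependence_requested_gives_empty_set(self, small_genome):
        layout, bundle, genes = small_genome
        truth = syn.plant_truth(
            layout, bundle, genes, syn.TruthConfig(dependent_fraction=0.0), seed=1
        )
        assert truth.dependent_genes == set()

    def test_dependent_subset_of_responsive(self, small_truth):
        assert truth_subset(small_truth)

    def test_domains_lie_within_workspace(self, small_genome, small_truth):
        _, bundle, _ = small_genome
        outside = small_truth.planted_domains.subtract(bundle.workspace)
        assert outside.total_bp == 0

    def test_unbiased_placement_matches_enhancer_density(self, small_genome):
        layout, bundle, genes = small_genome
        tcfg = syn.TruthConfig(n_domains=400, enhancer_bias=1.0,
                               domain_length_bins=(1, 1))
        hits, total = 0, 0
        for s in range(5):
            truth = syn.plant_truth(layout, bundle, genes, tcfg, seed=50 + s)
            hits += int(truth.planted_domains.overlaps_any(bundle.enhancers).sum())
            total += len(truth.planted_domains)
        # a 1-bin domain hits an enhancer iff its bin intersects one;
        # expected probability = fraction of bins touching an enhancer
        bins = binning.make_bins(layout)
        p_exp = float(bins.overlaps_any(bundle.enhancers).mean())
        se = np.sqrt(p_exp * (1 - p_exp) / total)
        assert abs(hits / total - p_exp) < 4 * se

    def test_bias_increases_placement_at_responsive_enhancers(self, small_genome):
        layout, bundle, genes = small_genome
        fracs = []
        for bias in (1.0, 2.0, 4.0):
            f = []
            for s in range(4):
                truth = syn.plant_truth(
                    layout, bundle, genes,
                    syn.TruthConfig(n_domains=200, enhancer_bias=bias), seed=60 + s,
                )
                links = bundle.enhancer_links()
                resp = links[links["gene_id"].isin(truth.responsive_genes)]
                resp_iv = IntervalSet(
                    resp["chrom"].to_numpy(), resp["start"].to_numpy(),
                    resp["end"].to_numpy(),
                )
                f.append(truth.planted_domains.overlaps_any(resp_iv).mean())
            fracs.append(np.mean(f))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_truth_roundtrips_through_json(self, small_truth, tmp_path):
        small_truth.to_json(tmp_path / "t.json")
        back = syn.SimulationTruth.from_json(tmp_path / "t.json")
        assert back.planted_domains == small_truth.planted_domains
        assert back.responsive_genes == small_truth.responsive_genes
        assert back.dependent_genes == small_truth.dependent_genes

    def test_impossible_placement_rejected(self):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=3000, n_genes=0,
                               n_denylist=0)
        layout, bundle, genes = syn.simulate_genome(cfg, seed=0)
        with pytest.raises(ValueError, match="cannot place"):
            syn.plant_truth(layout, bundle, genes,
                            syn.TruthConfig(domain_length_bins=(5, 5)), seed=0)


def truth_subset(truth):
    return set(truth.dependent_genes) <= set(truth.responsive_genes)


class TestSimulateCoverage:
    def test_poisson_mean_matches_baseline(self):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=10_000_000, n_genes=0,
                               n_denylist=0)
        layout, bundle, genes = syn.simulate_genome(cfg, seed=0)
        truth = syn.plant_truth(layout, bundle, genes,
                                syn.TruthConfig(n_domains=0), seed=0)
        m, sheet = syn.simulate_coverage(
            layout, truth, syn.CoverageConfig(baseline_rate=5.0), seed=1
        )
        col = m.column("control_rep1")
        se = np.sqrt(5.0 / len(col))
        assert abs(col.mean() - 5.0) < 3 * se

    def test_treated_mean_scaled_inside_domains(self, small_genome, small_truth):
        layout, bundle, _ = small_genome
        m, sheet = syn.simulate_coverage(
            layout, small_truth, syn.CoverageConfig(), seed=2
        )
        inside = m.bins.overlaps_any(small_truth.planted_domains)
        treated = m.column("treated_rep1")
        assert treated[inside].mean() > 2.0 * treated[~inside].mean()
        control = m.column("control_rep1")
        assert abs(control[inside].mean() - control[~inside].mean()) < 2.0

    def test_bedgraph_bytes_identical_across_runs(self, small_genome,
                                                  small_truth, tmp_path):
        layout, _, _ = small_genome
        blobs = []
        for d in ("x", "y"):
            syn.simulate_coverage(layout, small_truth, syn.CoverageConfig(),
                                  seed=9, outdir=tmp_path / d)
            blobs.append((tmp_path / d / "treated_rep2.bedgraph").read_bytes())
        assert blobs[0] == blobs[1]

    def test_negative_binomial_overdispersion(self):
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=5_000_000, n_genes=0,
                               n_denylist=0)
        layout, bundle, genes = syn.simulate_genome(cfg, seed=0)
        truth = syn.plant_truth(layout, bundle, genes,
                                syn.TruthConfig(n_domains=0), seed=0)
        ccfg = syn.CoverageConfig(baseline_rate=20.0,
                                  noise_model="negative_binomial", dispersion=0.2)
        m, _ = syn.simulate_coverage(layout, truth, ccfg, seed=3)
        col = m.column("control_rep1")
        expected_var = 20.0 + 0.2 * 20.0 ** 2  # mu + a mu^2
        assert abs(col.var() - expected_var) / expected_var < 0.15

    def test_invalid_parameters_rejected(self, small_genome, small_truth):
        layout, _, _ = small_genome
        with pytest.raises(ValueError):
            syn.simulate_coverage(layout, small_truth,
                                  syn.CoverageConfig(replicates_per_condition=0),
                                  seed=0)
        with pytest.raises(ValueError):
            syn.simulate_coverage(layout, small_truth,
                                  syn.CoverageConfig(baseline_rate=-1), seed=0)
        with pytest.raises(ValueError):
            syn.simulate_coverage(
                layout, small_truth,
                syn.CoverageConfig(noise_model="negative_binomial", dispersion=0),
                seed=0,
            )

    def test_null_effect_yields_no_domains(self):
        """Planted effect 1 everywhere: the caller finds ~nothing."""
        cfg = syn.GenomeConfig(n_chroms=1, chrom_length=4_000_000, n_genes=0,
                               n_denylist=0)
        layout, bundle, genes = syn.simulate_genome(cfg, seed=0)
        truth = syn.plant_truth(layout, bundle, genes,
                                syn.TruthConfig(n_domains=20, effect=1.0), seed=1)
        raw, sheet = syn.simulate_coverage(layout, truth, syn.CoverageConfig(),
                                           seed=2)
        targets = raw.select_samples(
            list(sheet.loc[sheet["role"] == "target", "sample_id"]))
        controls = raw.select_samples(
            list(sheet.loc[sheet["role"] == "igg_control", "sample_id"]))
        sm = binning.preprocess(targets, controls, bundle.denylist, sheet)
        stats = domains.per_bin_test(sm, sheet)
        call = domains.call_domains(stats, sm.bins, alpha=0.005)
        assert len(call.domains) <= 1


class TestSimulateExpression:
    def test_dependent_gene_moments(self, small_genome):
        layout, bundle, genes = small_genome
        truth = syn.plant_truth(layout, bundle, genes, syn.TruthConfig(), seed=7)
        ecfg = syn.ExpressionConfig(n_reps=100, induced_fold=4.0,
                                    gene_baseline_sigma=0.0)
        counts, meta = syn.simulate_expression(genes, truth, ecfg, seed=8)
        em = classify.ExpressionMatrix(counts, meta)
        dep = sorted(truth.dependent_genes)[0]
        indep = sorted(truth.independent_genes)[0]
        ctrl = counts.loc[:, em.samples_of("control")].mean(axis=1)
        tr = counts.loc[:, em.samples_of("treated_60")].mean(axis=1)
        kd = counts.loc[:, em.samples_of("treated_60_KD")].mean(axis=1)
        # dependent: induced by stimulation, reverts under knockdown
        assert tr[dep] > 2.5 * ctrl[dep]
        assert abs(kd[dep] - ctrl[dep]) / ctrl[dep] < 0.2
        # independent: stays induced under knockdown
        assert kd[indep] > 2.5 * ctrl[indep]

    def test_null_fold_gives_no_up_calls(self, small_genome):
        layout, bundle, genes = small_genome
        truth = syn.plant_truth(layout, bundle, genes, syn.TruthConfig(), seed=7)
        counts, meta = syn.simulate_expression(
            genes, truth, syn.ExpressionConfig(induced_fold=1.0), seed=9
        )
        em = classify.ExpressionMatrix(counts, meta)
        filt = classify.filter_genes(em)
        de = classify.de_test(filt, "treated_60", "control")
        assert len(classify.call_up(de)) <= 1

    def test_matrix_deterministic(self, small_genome):
        layout, bundle, genes = small_genome
        truth = syn.plant_truth(layout, bundle, genes, syn.TruthConfig(), seed=7)
        a, _ = syn.simulate_expression(genes, truth, syn.ExpressionConfig(), seed=3)
        b, _ = syn.simulate_expression(genes, truth, syn.ExpressionConfig(), seed=3)
        assert a.equals(b)

    def test_invalid_dispersion_rejected(self, small_genome):
        layout, bundle, genes = small_genome
        truth = syn.plant_truth(layout, bundle, genes, syn.TruthConfig(), seed=7)
        with pytest.raises(ValueError, match="dispersion"):
            syn.simulate_expression(genes, truth,
                                    syn.ExpressionConfig(dispersion=0.0), seed=1)
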