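#!/usr/bin/env python
"""Generate the synthetic benchmark dataset with recorded ground truth.

Writes, under results/benchmark/: annotation BEDs (enhancers with linked
gene IDs, promoters, gene bodies, denylist, workspace), per-sample bedGraph
coverage tracks with 50 planted differential domains, the three-condition
expression count matrix with 100 planted responsive genes (20 of them
knockdown-dependent), the gene table, chromosome sizes, and the planted
truth as JSON.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chromdiff import synthetic as syn
from chromdiff.pipeline import stage_seed

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "benchmark"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout, bundle, genes = syn.simulate_genome(
        syn.GenomeConfig(), stage_seed(SEED, "genome")
    )
    truth = syn.plant_truth(
        layout, bundle, genes, syn.TruthConfig(enhancer_bias=4.0),
        stage_seed(SEED, "truth"),
    )
    syn.simulate_coverage(layout, truth, syn.CoverageConfig(),
                          stage_seed(SEED, "coverage"), outdir=OUT / "tracks")
    syn.simulate_expression(genes, truth, syn.ExpressionConfig(),
                            stage_seed(SEED, "expression"), outdir=OUT)
    syn.write_annotation(bundle, OUT / "annotation")
    genes.to_csv(OUT / "genes.tsv", sep="\t", index=False)
    truth.to_json(OUT / "truth.json")
    with open(OUT / "chrom_sizes.tsv", "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")

    print(f"genome: {len(layout.chrom_names)} chromosomes, "
          f"{layout.total_bp/1e6:.0f} Mb, bin size {layout.bin_size} bp")
    print(f"annotation: {len(genes)} genes, {len(bundle.enhancers)} enhancers, "
          f"workspace {bundle.workspace.total_bp/1e6:.1f} Mb")
    print(f"planted: {len(truth.planted_domains)} domains "
          f"(effect x{truth.effects[0]:.0f}, enhancer bias "
          f"{truth.enhancer_bias:.0f}), "
          f"{len(truth.responsive_genes)} responsive genes "
          f"({len(truth.dependent_genes)} knockdown-dependent)")
    print(f"wrote benchmark inputs to {OUT}")


if __name__ == "__main__":
    main()
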