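#!/usr/bin/env python
"""Permutation enrichment of the called domains at annotation categories.

Tests the domains from 02_call_domains against all enhancers, promoters,
gene bodies and the enhancers linked to each classified gene set from
03_classify_genes (up-regulated, knockdown-dependent, -independent), with
1000 length-matched random placements inside the mappable workspace.

Writes enrichment.tsv under results/benchmark/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chromdiff import enrichment, io as cio, synthetic as syn
from chromdiff.pipeline import stage_seed

BASE = Path(__file__).resolve().parents[1] / "results" / "benchmark"
SEED = 0


def main() -> None:
    bundle = syn.read_annotation(BASE / "annotation")
    domains_bed = cio.read_bed(BASE / "domains.bed").merge()
    genes = pd.read_csv(BASE / "genes.tsv", sep="\t")
    gene_sets = {
        name: cio.read_gene_set(BASE / "gene_sets" / f"{name}.txt")
        for name in ("up_60", "dependent", "independent")
    }
    gene_sets = {k: v for k, v in gene_sets.items() if v}

    cats = enrichment.build_categories(
        bundle, gene_sets, known_genes=set(genes["gene_id"])
    )
    table = enrichment.enrichment_table(
        domains_bed, cats, bundle.workspace,
        n_sim=1000, seed=stage_seed(SEED, "enrichment"),
    )
    table.to_csv(BASE / "enrichment.tsv", sep="\t", index=False)

    print("fold enrichment (observed / expected overlap, 1000 simulations):")
    for r in table.to_dict("records"):
        fold = "n/a" if r["fold"] is None else f"{r['fold']:.2f}"
        p = "n/a" if r["p_enrich"] is None else f"{r['p_enrich']:.3g}"
        print(f"  {r['category']:<28} fold {fold:>7}   p {p}")


if __name__ == "__main__":
    main()
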