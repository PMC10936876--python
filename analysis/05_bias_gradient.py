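#!/usr/bin/env python
"""Enhancer-bias fold gradient: the pipeline's end-to-end recovery check.

Re-runs the full chain (simulate -> call domains -> classify genes ->
enrichment) for planted enhancer biases 1, 2 and 4. With bias 1 domain
placement is uniform over the workspace and the fold at responsive-gene
enhancers should sit near 1; increasing the bias concentrates planted
domains at enhancers of responsive genes and the estimated fold must rise
with it, with the responsive-enhancer category outrunning the all-enhancer
category — the benchmark analogue of a fold gradient across progressively
more specific enhancer sets.

Writes results/gradient.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chromdiff import benchmarks as bm
from chromdiff.pipeline import stage_seed

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    table = bm.gradient_experiment(
        stage_seed(SEED, "gradient"), biases=(1.0, 2.0, 4.0), n_sim=1000
    )
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "gradient.tsv", sep="\t", index=False)
    print("enhancer bias -> enrichment fold (1000 simulations each):")
    for bias, grp in table.groupby("bias"):
        by_cat = {r["category"]: r["fold"] for r in grp.to_dict("records")}
        print(f"  bias {bias:.0f}: all enhancers {by_cat['all_enhancers']:.2f}, "
              f"responsive-gene enhancers "
              f"{by_cat['enhancers_of:responsive']:.2f}")


if __name__ == "__main__":
    main()
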