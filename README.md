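# chromdiff

Differential histone-mark **domain calling**, permutation-based
**interval enrichment**, and three-condition **knockdown-dependence
classification** — the computational chain used to connect a
stimulation-induced chromatin mark (e.g. growth-factor-induced
H3K9me2S10ph measured by CUT&RUN) to the enhancers of the genes that
respond to the stimulus, packaged as a tested pipeline that runs end to
end on synthetic data with known ground truth.

## Who this is for

Epigenomics analysts who have replicate coverage tracks for two
conditions (plus an IgG background control), genome annotation
(enhancers with linked genes, promoters, gene bodies, a denylist), and a
gene × sample count matrix across control / stimulated / stimulated +
kinase-knockdown conditions — and who want the standard
binned-coverage domain statistics and GAT-style enrichment with fully
reproducible seeds, plus a simulator to validate the whole chain.

## The statistics

**Domain calling.** The genome is tiled into 1-kb bins. Per sample:
counts-per-million scaling, subtraction of the matched IgG track,
removal of denylisted bins, per-sample z-transform
`z = (x − mean)/sd`, and a centered rolling mean over 10 bins (window
`[i−5, i+4]`, clipped at chromosome ends). Per bin, an equal-variance
two-sample t-test compares treated vs control replicates; p-values are
Benjamini–Hochberg corrected, bins with adjusted p < 0.005 (and the
requested sign) are kept, and book-ended significant bins are merged
into domains (maximum gap 0, as in `bedtools merge -d 0`).

**Enrichment.** For a query set Q and annotation A inside a mappable
workspace W, `observed = |Q ∩ A|` in base pairs. Each query segment is
repeatedly re-placed uniformly at random over all legal start positions
within W (length preserved, never crossing a workspace gap; a workspace
interval of length L offers `L − l + 1` starts for a segment of length
l). With n simulations, `expected` is the mean simulated overlap,
`fold = observed/expected`, and the enrichment p-value is
`(1 + #{sim ≥ observed})/(1 + n)` — so 1000 simulations bound p below at
1/1001 ≈ 0.001.

**Response classification.** Genes with CPM > 10 in at least two
samples are kept. Up-regulated genes satisfy `log2FC > 0.5` and
BH-adjusted p < 0.05 (default test: Welch's t on log2(CPM+1);
externally computed DE tables, e.g. from edgeR, plug in unchanged).
Their per-condition mean profiles (control, stimulated,
stimulated+knockdown) are row-scaled and clustered hierarchically
(Euclidean, complete linkage, k = 2); the cluster whose profiles drop
most under knockdown is re-tested (stimulated vs stimulated+knockdown,
BH within the cluster), and genes significantly lower under knockdown
form the **dependent** set; the remaining up-regulated genes are
**independent**.

## Worked example

The numbered scripts under `analysis/` run the full benchmark and write
their tables under `results/`:

```bash
python analysis/01_simulate_benchmark.py
python analysis/02_call_domains.py
python analysis/03_classify_genes.py
python analysis/04_enhancer_enrichment.py
python analysis/05_bias_gradient.py
```

Output of the run shipped with this README:

```
genome: 2 chromosomes, 50 Mb, bin size 1000 bp
annotation: 500 genes, 1000 enhancers, workspace 49.5 Mb
planted: 50 domains (effect x3, enhancer bias 4), 100 responsive genes (20 knockdown-dependent)

81 domains at adjusted p < 0.005 (mean 5.8 kb, 0.95% of the workspace)
recovery vs planted truth: sensitivity 1.00, precision 0.85

up-regulated at 60 min: 97 genes (planted responsive: 100)
knockdown-dependent: 20 (planted: 20); independent: 77
dependent-set recovery: sensitivity 1.00, specificity 1.00

fold enrichment (observed / expected overlap, 1000 simulations):
  all_enhancers                fold    2.73   p 0.000999
  enhancers_of:up_60           fold   11.92   p 0.000999
  enhancers_of:dependent       fold    9.15   p 0.000999
```

Reading this: the caller recovered every planted domain (a few extra
calls are smoothing-halo fragments flanking true domains — hence
precision 0.85); the classifier recovered the planted
knockdown-dependent genes exactly; and because domains were planted
with a 4× bias toward responsive-gene enhancers, the fold enrichment at
those enhancers (≈12) far exceeds the genome-wide enhancer fold (≈2.7),
with the permutation p at its 1000-simulation floor. Script 05 repeats
the whole chain at biases 1 → 2 → 4 and shows the fold rising from ≈1
(uniform placement) with the planted bias.

The same stages are available as a CLI
(`chromdiff simulate|bin|call-domains|enrich|classify|run`), each a thin
wrapper over the library; `chromdiff run --config cfg.yaml --seed N`
executes everything from one YAML config and writes a byte-reproducible
JSON report.

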