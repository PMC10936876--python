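# Methods

This note documents the model behind each stage, the defaults and why
they are set where they are, what the synthetic benchmark does and does
not emulate, and the numerical conventions.

## Problem setting

A stimulus (e.g. a growth factor) induces a combinatorial histone
modification at discrete genomic locations; the analysis asks (i) where
the mark increases significantly between conditions, (ii) whether those
locations coincide with annotated regulatory elements — in particular
enhancers of stimulus-responsive genes — more often than chance, and
(iii) which responsive genes depend on a specific kinase, as judged by a
knockdown condition. The three stages are deliberately modular: domains
feed the enrichment as a BED file, and the classifier's gene sets feed
the enrichment as category definitions, so any stage can be replaced by
external results.

## Domain calling

Coverage is reduced to 1-kb bins (terminal bins truncated; a bin's value
is its signal mass divided by its width, uncovered bases counting 0).
The per-sample chain is fixed and order-enforced:

| stage | operation | notes |
|---|---|---|
| raw → cpm | per-sample scaling to 1e6 | totals are bin sums over retained (non-denylisted) bins |
| cpm → ctrl_subtracted | subtract matched IgG column | negatives preserved |
| → zscore | per-sample `(x − mean)/sd`, ddof 1 | absorbs dynamic-range differences between libraries |
| → smoothed | centered rolling mean, window 10 | window `[i−5, i+4]` ("left" centering; `[i−4, i+5]` selectable), clipped per chromosome |

Denylisted bins are removed before CPM so library totals count mappable
signal only. Smoothing never crosses a chromosome boundary; bins made
non-adjacent by denylist removal remain index-adjacent within their
chromosome, which treats short masked gaps as if excised.

Per bin, an equal-variance two-sample t (df = n₁+n₂−2; Welch optional)
compares treated vs control replicate values of the smoothed scores;
two-sided p-values are BH-corrected over all retained bins. Two-sided
testing with a post-hoc direction filter reports gains and losses
symmetrically; the default output keeps the "up" direction. Significant
(adjusted p < 0.005) same-direction book-ended bins merge into domains;
domains are not re-tested after merging. The summary reports domain
count, mean length, and total length over workspace length.

Degenerate inputs: pooled variance is floored at 1e-12 (in smoothed-z
units); bins where both groups are constant and equal get t = 0, p = 1;
a zero-variance sample aborts z-scoring with the sample named.

## Permutation enrichment

The observed/expected statistic treats base-pair overlap as the test
quantity. Null placements are length-preserving and uniform over every
legal start in the workspace, with workspace intervals weighted by their
valid-start counts (`L − l + 1`), so the placement distribution is
exactly uniform over legal positions rather than approximately so under
interval-length weighting. Placements are mutually independent and may
overlap one another; at the query densities this pipeline produces
(≪ 1% of the workspace) the bias this introduces in the expected
overlap is negligible, and it keeps the sampler exact and fast. The
expectation uses the simulation mean; empirical p-values use the
(k+1)/(n+1) correction and are therefore never 0 — at the default 1000
simulations the floor is 1/1001. No G+C or isochore stratification is
applied; the workspace mask is the only conditioning.

Categories are merged interval sets clipped to the workspace:
`all_enhancers`, `promoters`, `gene_bodies`, and `enhancers_of:<set>`
for any named gene set (union of enhancers linked to any member; unknown
IDs are logged and skipped; an empty category is kept and flagged so
reports stay complete).

## Response classification

The expression filter (CPM > 10 in ≥ 2 samples) and the up-call
thresholds (lfc > 0.5, BH-adjusted p < 0.05) are applied to whatever
differential test is plugged in. The built-in default is Welch's t on
log2(CPM + 1): it is dispersion-agnostic, adequate at the replicate
counts the benchmark uses, and keeps the classification logic — the part
this package owns — independent of any negative-binomial machinery.
Count-model tests (edgeR and kin) can be supplied as external DE tables
(gene, lfc, adjusted p) and flow through identically. Bonferroni is
available in place of BH by flag.

Clustering distance, linkage and k are documented choices, not
inferences: Euclidean on row-scaled per-condition means, complete
linkage, k = 2. Flat profiles are scaled to zero and flagged. The
dependence call re-tests only the candidate cluster (the one with the
largest mean drop from stimulated to stimulated+knockdown in scaled
units); the BH adjustment for that secondary test spans the cluster's
genes, matching the construction of testing one cluster rather than the
transcriptome. Genes significant there with lower expression under
knockdown are dependent; all other up-regulated genes are independent,
so dependent ∪ independent always partitions the up-set. Down-regulated
genes (lfc < 0, adjusted p < 0.05) are reported but not classified.

## Synthetic benchmark: what it emulates and why its defaults are set

The generators produce a miniature genome whose analysis exercises every
stage at full statistical fidelity:

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 25 Mb, 1-kb bins (50,000 bins) | large enough that BH correction operates at realistic stringency; small enough for seconds-scale runs |
| genes / enhancers | 500 genes, 2 linked enhancers each (1 kb, within 50 kb of the TSS), promoters TSS −1000/+500 | enhancer bp ≈ 2% of the genome — sparse annotation, as in real genomes |
| denylist | 50 × 10 kb (≈ 1%) | sparse masked regions; workspace = complement |
| planted domains | 50, of 10–20 bins, effect ×3 | see below |
| coverage | Poisson (NB optional), 20 counts/bin target, 10 counts/bin IgG, 3 target replicates per condition, one shared IgG track | deep CUT&RUN-like per-bin counts; 3 replicates make the t-test well-posed |
| expression | NB, 4 replicates/condition, gene baselines log-normal around 200 (σ = 0.5), dispersion 0.05, induced fold 4 | typical bulk RNA-seq moments |
| responsive genes | 20% of genes (100), of which 20% (20) knockdown-dependent | induced genes are a minority, so CPM composition shifts stay small (< 0.4 log2 units), the regime a CPM-based lfc handles |

**Why domains of 10–20 bins at effect ×3.** The per-bin test has
n₁+n₂−2 = 4 degrees of freedom, and BH at adjusted p < 0.005 over
5×10⁴ bins only rejects at raw p ≲ 10⁻⁴ — t ≳ 15. A planted domain
shorter than the 10-bin smoothing window contributes only `len/10` of
its raw amplitude to any smoothed bin, so sub-window domains are
detectable only at raw amplitudes of tens of within-replicate SDs; at
those amplitudes the planted bins dominate each treated sample's
z-normalization (the variance share grows as `f·z²` for signal fraction
f), which both dampens the planted signal and degrades the
between-condition scale match. Domains at or above the window length
saturate the smoothing, so a moderate ×3 effect (≈ 4–5 combined-noise
SDs per bin) yields central-bin t ≈ 30 and near-complete recovery while
keeping the planted variance share ≈ 1%, preserving null calibration.
These defaults are the benchmark's study conditions; experiments state
any overrides explicitly.

**Placement bias model.** With enhancer bias r, each domain is
relocated to the bin containing a random responsive-gene enhancer's
midpoint with probability 1 − 1/r (0 when r ≤ 1), otherwise placed
uniformly over bin-aligned workspace positions — so r = 1 is exactly
uniform and the planted overlap fraction rises monotonically with r.
Placements are independent; coverage takes the maximum effect where
domains overlap.

**Why one shared IgG track.** An IgG library is far shallower than the
target, so after CPM scaling its per-bin noise is large. Subtracting a
*per-condition* IgG track adds that noise as a shift common to all
replicates of one condition — invisible to the replicate-variance
estimate and therefore a direct source of spurious between-condition
differences. A single track shared by both conditions cancels exactly
in the contrast. Real designs with per-condition IgG remain supported
(`igg_mode="per_condition"`), but the benchmark's default keeps the
caller's null calibrated by construction.

**What the generator does not emulate.** Real coverage has reproducible
biological background structure shared across replicates (which makes
real between-replicate noise much smaller than marginal bin variance),
mappability and GC trends, fragment-length effects, and overdispersion
that varies along the genome; the expression model has no
gene-correlation structure and CPM is used without composition
normalization (TMM and kin). Passing benchmarks therefore demonstrate
the statistics are implemented and calibrated as specified — not that
effect sizes detectable here are detectable in any particular real
dataset.

## Standard experiments (`chromdiff.benchmarks`)

All reported numbers come from these functions; the analysis scripts,
the test suite and `scripts/acceptance.py` share them. Problem sizes:
null calibration pools 20 independent 10,000-bin null simulations
(fraction of raw p < 0.05; count of runs with zero domains at adjusted
p < 0.005); recovery plants 50 domains at the default conditions and
scores ≥ 1 bp overlap both ways; enrichment calibration draws 500
queries from the placement sampler itself (199 simulations each, so
p = 0.05 is exactly attainable); the fold gradient runs the full chain
at biases 1/2/4 with 100 planted domains and 1000 simulations (100
domains keep the fold's sampling error well below the gradient spacing);
the classifier experiment uses the default 20 dependent / 80
independent planted genes. A single seed drives every experiment through
per-stage CRC-derived sub-seeds, so any stage reruns identically in
isolation.

## Known limitations

* With 3 replicates per condition the per-bin t-test has 4 degrees of
  freedom: genome-wide discovery at adjusted p < 0.005 requires
  per-window effects of several combined-noise SDs, and isolated 1–2-bin
  events of modest amplitude are beyond the design's power. This is a
  property of the published stage chain (smoothing window, test, and
  threshold), not of this implementation.
* The smoothing halo means called domains extend up to ~9 bins beyond a
  true signal edge, and flanking windows occasionally detach as
  separate short calls — recovery precision at the defaults is ≈ 0.85–0.9
  with sensitivity ≈ 1.0.
* The per-sample z-scoring reads "samples of each condition were
  converted to z-scores" in its per-sample sense; the per-condition
  alternative is not implemented. The t-test runs on the smoothed
  ("final") scores; testing unsmoothed z-scores is possible via the API
  but is not the default.
* Enrichment expectation ignores inter-segment exclusion (placements may
  overlap); with query densities approaching the workspace size the
  expectation would be biased upward.
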