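# betimed

Integrative screen analysis that nominates **mediator genes** of
BET-bromodomain-inhibitor (BETi) response in MYC-driven medulloblastoma — and
the synthetic-data machinery to exercise every stage against planted truth.

BETi (JQ1, IBET151) suppresses thousands of genes at once, so knowing *which*
suppressed genes actually drive the loss of viability requires intersecting
three independent lines of evidence. A mediator gene is one that is

1. **suppressed** by drug (differential expression),
2. **essential** for viability (pooled CRISPR knockout screen), and
3. **sufficient to rescue** the drug effect when re-expressed (pooled ORF
   overexpression screen under drug).

This package implements the scoring layer of each assay, the three-way
integration, and three auxiliary quantifications: gene-level ChIP-seq binding
Z-scores, clonal DNA-barcode sharing across replicate treatments
(predetermined drug tolerance), and Bliss-independence synergy of drug
combinations.

## The models at the core

**CRISPR dependency probability.** Guide log2 fold changes
(`LFC = log2(RPM_final + 1) − log2(RPM_early + 1)`) are collapsed to gene
scores by the median over guides. Each gene's posterior probability of being
a true dependency comes from a two-component empirical mixture

&nbsp;&nbsp;&nbsp;&nbsp;`P(dep | x) = π f_dep(x) / (π f_dep(x) + (1 − π) f_non(x))`

with `f_dep` a kernel density over the scores of *pan-essential* genes (genes
in the bottom 26% of scores in ≥ 90% of a reference line panel), `f_non` a
kernel density over the scores of genes not expressed in the line, and `π`
fitted by EM with the densities held fixed. Tail clamps force probability 1
below score −1.5 and 0 above 0.25, the probability-vs-score curve is smoothed
with a Gaussian kernel of sd 0.15, and genes are called essential at
probability > 0.35 with FDR < 0.2 (q at rank *i* of the descending ranking is
the running mean of `1 − p`).

**ORF rescue.** Per-ORF drug-arm LFCs versus the early time point; rescue
ORFs confer > 1.5 log2 enrichment with q < 0.25 (robust-z against the
cross-ORF null, Benjamini–Hochberg).

**Marker selection.** Signal-to-noise ratio
`SNR = (μ_A − μ_B)/(σ'_A + σ'_B)` with a variance floor
`σ' = max(σ, 0.2·|μ|)`, exact label-permutation p-values, and a
p < 0.05 & q < 0.1 call (Bonferroni < 0.1 in chromatin-profiling mode).

**Overlap statistics.** One-sided hypergeometric (Fisher) and Pearson
chi-square tests on gene-set overlaps within a declared universe.

**Auxiliary layers.** ChIP reads extended 200 bp, rpm/bp coverage integrated
over gene ± 500 kb and Z-transformed per sample; barcode survival/sharing
fractions after a minimum-3-read early-time-point filter; Bliss excess
`f_ab − (f_a + f_b − f_a·f_b)` per dose-matrix well.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
with planted truth (everything is seeded and deterministic):

```bash
python analysis/01_simulate_inputs.py --seed 1   # writes results/study/
python analysis/02_crispr_dependency.py
python analysis/03_orf_rescue.py
python analysis/04_expression_markers.py
python analysis/05_integrate_mediators.py
```

which prints, step by step:

```
simulated study written to results/study (seed 1)
  gene universe: 1000 genes
  planted essential: 130 (pan-essential anchors: 87)
  planted suppressed: 280; rescue: 20; mediators: 8
essential calls: 132 of 1000 genes (mixture weight pi = 0.128)
recovery vs planted truth: recall 0.908, false-positive rate 0.016
rescue genes called: 19 (19 of 20 planted recovered)
cross-drug concordance: R^2 = 0.556 (p = 6.6e-178, n = 1000 ORFs)
suppressed genes called: 273 (recall 0.921, empirical FDR 0.055 vs planted truth)
suppressed & essential: 57 genes, chi-square p = 1.1e-05
mediators (triple intersection): ['G00035', 'G00144', 'G00470', 'G00509',
 'G00752', 'G00823', 'G00947', 'G00949']
matches planted truth
```

The 132 essential calls are the genes whose mixture-model probability and
FDR clear the 0.35 / 0.2 thresholds; 57 of them are also suppressed
(chi-square confirms that is far more than the ~36 expected by chance), and
exactly the eight genes planted as strong hits in all three assays come out
as mediators. Scripts `06`–`08` run the ChIP, barcode and synergy layers,
and `09` the closed-form overlap tests at the full published screen
geometry. The same pipeline runs in one call via
`betimed.run_pipeline(RunConfig(seed=1))`, and on real data by pointing
`RunConfig.inputs` at count/BED/CSV files instead of the simulate stage.

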