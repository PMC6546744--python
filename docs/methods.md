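# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the design decisions behind `betimed`. It states no empirical
result that the test suite or `scripts/acceptance.py` do not themselves
compute.

## Dependency scoring and the two-component mixture

Guide-level depletion is measured as the difference of mean
`log2(RPM + pseudocount)` between final and early-time-point samples
(pseudocount 1; RPM = reads per million within each sample, which makes every
downstream quantity invariant to sequencing depth). Gene scores are the
median over a gene's guides — the median, rather than the mean, because a
single inefficacious or off-target guide should not move the gene score.
Copy-number/guide-activity modeling is deliberately out of scope; the median
collapse is the package's plain substitute for the full screen-calibration
machinery and is the main reason gene scores here should not be compared
numerically with published processed datasets.

The mixture model turns a gene score `x` into a probability of true
dependency:

* `f_dep` — Gaussian KDE (Silverman bandwidth) of the scores of
  **pan-essential anchor genes** in this screen. Pan-essentials are derived
  from a multi-line score panel as genes in the bottom `pan_quantile = 0.26`
  of each line's scores in at least `pan_fraction = 0.90` of lines; with
  fewer than two lines the caller must supply the anchor list explicitly
  (the single-line pipeline consumes such a reference list as an input,
  mirroring how an external panel would supply it).
* `f_non` — KDE of the scores of genes **not expressed** in the line.
  "Not expressed" defaults to mean log2 normalized expression < 0.2,
  configurable.
* `π` — mixing weight fitted by EM over all gene scores with both component
  densities fixed (closed-form E and M steps, tolerance 1e-8); a fixed `π`
  can be configured instead.

Both densities are evaluated on a shared 512-point grid spanning the
observed score range padded by 1 score unit (always containing both clamp
boundaries) and renormalized to integrate to one on that grid, so the
posterior is well defined at every grid point.

Post-processing, in this order: hard tail clamps (probability 1 below score
−1.5, 0 above 0.25), Gaussian smoothing of the probability-versus-score
curve with sd 0.15 **in score units** (implemented as a discrete Gaussian
filter with sigma = 0.15/grid-spacing, nearest-edge padding), re-clip to
[0, 1] with the clamps re-imposed exactly, and finally a monotone
non-increasing projection (running minimum along increasing score). The
projection is this package's own addition: the KDE posterior can wiggle in
sparse tails, and a dependency probability that *decreases* as a gene gets
more depleted is uninterpretable. With well-separated anchor sets the
projection is a no-op; it only ever binds where the raw posterior is
non-monotone. "Width 0.15" is interpreted as the standard deviation of the
smoothing kernel in score space; rank-space smoothing was the alternative
reading and would change behavior only where gene scores are locally dense.

Essential calls: q-value at rank *i* of the descending-probability ordering
is the cumulative mean of `(1 − p)` — the standard aggregation of a local
false-discovery quantity into a tail FDR. Ties in probability share the q of
their last tied rank, making the calls order-independent. A gene is
essential iff probability > 0.35 and q < 0.2.

## ORF rescue scoring

Per-replicate LFCs are computed against the mean log2 RPM of the
early-time-point samples, per the screen's design; an optional
vehicle-differenced mode is available for drift control but is not the
default. The published analysis reports q-values without defining the test,
so the q machinery here is a repository decision, echoed in output
provenance: a robust z per ORF against the cross-ORF null
(`z = (LFC − median)/(1.4826·MAD)`), one-sided upper-tail normal p, and
Benjamini–Hochberg adjustment. Rescue = mean LFC > 1.5 **and** q < 0.25;
ORFs passing only the q threshold are tracked separately ("q-only"), since
such near-miss genes are biologically interesting but never enter the
mediator intersection. Genes with several ORFs collapse to their best
(max-LFC) ORF; a gene rescues if any of its ORFs does. Cross-drug
concordance is the R² of an ordinary least-squares fit between the two drug
arms' per-ORF LFC vectors, with the slope's two-sided p.

## Marker selection

The SNR statistic floors each group's sample sd at
`0.2·|group mean|` (and 1e-8 absolutely), the variance-stabilization
convention of the comparative-marker-selection tool family; the floor makes
the statistic *scale*-invariant but deliberately not *shift*-invariant, so
inputs are expected on a log scale anchored at zero. Significance comes from
label permutations of the two-group design: all `C(n, n_A)` distinct
labelings are enumerated exactly whenever there are at most 10,000 of them
(p = fraction of labelings, including the observed one, with
`|SNR| ≥ |SNR_obs|`); otherwise a seeded sample of labelings with +1
smoothing. Expression mode calls significance at p < 0.05 and BH q < 0.1;
chromatin mode uses Bonferroni-adjusted values at 0.1. A rank-by-SNR top-N
selection is provided for the alternative "most suppressed N genes" usage.

## Overlap statistics and integration

Fisher overlap p is the exact hypergeometric upper tail `P(X ≥ k)` —
one-sided, matching the directional enrichment claims. The chi-square test
is Pearson's on the 2×2 membership table, 1 df, without continuity
correction, and refuses tables with any expected cell below 1 (advising
Fisher). Universes are explicit arguments everywhere: the ORF-library gene
space for rescue overlaps, the knockout-library gene space for
suppressed/essential overlaps, and the simulated universe in the synthetic
study; every output echoes the universe used.

## ChIP binding scores

Each aligned read is replaced by a 200-bp interval anchored at its 5′ end in
strand direction (strand "." treated as "+"); coverage is the sum of
`1e6 / total mapped reads` per bp over extended reads, i.e. rpm/bp, kept as
an exact step function. Genome-wide coverage mass is therefore
`200 · 1e6` rpm·bp for any library, up to boundary clipping — a conservation
law the tests assert. A gene's raw score integrates coverage over the
annotated gene body extended 500 kb in each direction (gene body, not TSS;
clipped at chromosome bounds when sizes are provided). Z-scores use the
sample sd (n−1) within each sample column; a constant column maps to all
zeros by policy. Gene-set contrasts use Welch's two-sided t-test per sample.

## Barcode clonality

Barcodes need ≥ 3 reads in the early time point to be eligible; presence in
a post-treatment sample means ≥ 1 read (only the ETP is filtered). The
"surviving fraction" denominator is ambiguous in prose descriptions of such
experiments, so both conventions are implemented: the default **union**
denominator (eligible barcodes detected in ≥ 1 sample of any condition) and
the stricter **eligible** denominator; the choice is echoed in the output.
The sharing profile counts, per treated replicate, how many *other* treated
replicates each of its barcodes appears in, plus the fraction of survivors
present in all treated replicates and the fraction absent from every
vehicle replicate.

## Bliss synergy

Viability is normalized to the vehicle-well mean, clipped to [0, 1.05] and
capped at 1 so inhibition stays in [0, 1]. For well (i, j), `fa` comes from
the dose-0 column of drug B, `fb` from the dose-0 row of drug A, expected
inhibition `e = fa + fb − fa·fb`, excess `= f_ab − e`. The synergy decision
rule is pinned to **mean excess over nonzero-dose wells > 0.05**
(configurable); the per-well excess matrix is always reported so stricter
per-well criteria can be applied downstream. Loewe-additivity deviation
testing is out of scope (delegated to published tooling in the original
analyses).

## Synthetic-data generators

All generators are deterministic given their seed and return the planted
truth alongside the data. Count-bearing assays share one sampling model:
log-normally skewed clone abundances (log sd 0.5), planted effects acting as
log2 fold changes on final-time-point abundance, competitive renormalization
of the final pool, and negative-binomial reads with variance
`m + dispersion·m²`.

Defaults mirror stated study conditions wherever those exist:

| quantity | default | origin |
|---|---|---|
| genes (scaled) | 1,000 | scaled from 18,454-gene library; full scale available |
| guides per gene / controls | 4 / 100 | 73,687-guide, 1,000-control library geometry, scaled |
| essential fraction | 0.13 | 2,455 of 18,454 called essential |
| pan-essential anchor fraction | 0.087 | 1,607 of 18,454 |
| unexpressed fraction | 0.25 | typical unexpressed share of a line's transcriptome |
| depletion effect | −1.0 (mean guide LFC) | stated working effect size |
| CRISPR count dispersion | 0.2 | screen-count model default |
| suppressed fraction | 0.28 | ~5,241 genes down of ~18,454 |
| expression effect / noise | 1.5 / 0.5 log2 (3σ) | stated calibration condition |
| replicates | 3 (CRISPR arms), 5 (expression), 2+2 ETP/arm (ORF) | replicate ranges of the profiled experiments |
| ORF rescue fraction / effect | 0.02 / +2.0 | scaled hit rate; stated working effect |
| ORF dispersion / drift / arm noise | 0.05 / 0.15 / 0.1 | high-representation screen (≥1,000 cells per ORF); see below |
| barcodes / replicates | 10,000 / 8 | scaled from 600,000; 8 replicates as performed |
| tolerant fraction / kill probability | 0.02 / 0.967 | back-solved from 25% surviving, 8% shared-across-all |
| Hill dose–response | EC50 0.5, slope 1.5, 7-point half-log-ish grid | typical in-vitro viability surface |

Guide efficacy is a multiplicative attenuation of the gene effect
(Normal(1, 0.1) clipped at 0), which is exactly why multiple guides per gene
are aggregated. Non-targeting guides carry no planted effect, but
**competitive renormalization induces a small positive composition bias**
(≈ −log2 of the surviving abundance mass, < 0.11 at the defaults) in their
measured LFCs — real pooled screens have the same property, and the
control-centering test budgets for it explicitly.

The **combined study scenario** (`simulate_study`) shares one gene universe
across CRISPR, ORF and expression, and plants the per-assay sets so that the
truth's triple intersection is *exactly* the designated mediators: pairwise
overlaps (e.g. suppressed-and-essential) remain realistic, but non-mediator
rescue genes are drawn from genes carrying no other planted effect.
Mediators are planted above every assay's detection margin (depletion −1.8,
suppression 2.0 log2 = 4σ, rescue +3.0): the genes this analysis design
nominates are by construction the strong, concordant hits, so exact recovery
of the planted mediators is the correct expected outcome of a correctly
wired pipeline, and the end-to-end test asserts exactly that. The ORF
generator's noise defaults model a high-representation screen for the same
reason: at the scaled library size, a noisy ORF layer would contaminate the
three-way intersection with its nominal-rate false calls and turn the
end-to-end check into a coin flip.

What the generators do **not** emulate: guide off-target structure and
copy-number artifacts, batch effects and normalization drift in expression,
overdispersed clone growth rates (barcode counts are NB around a fixed
surviving abundance), spatial read structure (ChIP reads fall uniformly in
gene bodies), and Loewe-type dose-equivalence interactions. Tests passing on
these generators therefore validate the *scoring and integration logic*, not
robustness to those real-data pathologies.

## Problem sizes and runtimes

The scaled defaults (1,000 genes, 4,100 guides, 1,000 ORFs, 10,000
barcodes, 200 ChIP genes) let the full pipeline run in about a second and
the whole test suite in a few seconds on one CPU; full-scale shapes are
available by overriding the size fields. The permutation layer enumerates
exactly up to 10,000 labelings (a 5v5 design has 252), which keeps exact
inference the common case.

## Degenerate inputs and numerical conventions

Zero-total samples, empty eligible barcode sets, zero-variance LFC vectors,
MAD = 0 nulls, singleton gene sets, overlapping target/background sets, and
sub-minimum anchor sets all raise early with actionable messages rather than
propagating NaNs. Probabilities are compared against thresholds strictly
(`> 0.35`, `< 0.2`), matching the stated call rules. All genomic coordinates
are 0-based half-open internally; BED and bedGraph are native to that
convention. Pipeline outputs are pure functions of (inputs, config, seed);
the provenance record echoes every threshold and the seed.

## Known limitations

* Gene scores are median-of-guides; no guide-efficacy or copy-number
  correction, so absolute score scales differ from fully calibrated screen
  pipelines even though the probability layer is anchor-based and largely
  self-calibrating.
* The ORF q-value construction is a cross-ORF null, not a replicate-based
  test; with few replicates and strong global drift its calibration degrades
  (the vehicle-differenced mode mitigates drift).
* The chi-square overlap test is two-sided by construction; for heavily
  unbalanced tables prefer the Fisher route (the implementation enforces
  this only for expected cells < 1).
* Barcode survival treats detection as binary presence; clone-size inference
  from read counts is out of scope.
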