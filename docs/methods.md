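# Methods

## Problem setting

Bulk RNA-seq of samples with variable pre-extraction delay raises the
question of whether measured abundance changes reflect biology or RNA
degradation. Because poly-A selection anchors library fragments at the
3' end, degradation leaves a specific footprint: per-base coverage that
decays toward the 5' end. `covdrift` tests for this footprint at the
single-gene level by comparing coverage *shape* between groups, using a
same-time technical contrast as the yardstick for how much shape
variation is normal.

## Coverage representation

Per-base depth is kept in transcript space, 0-based half-open, oriented
5'→3'. Base *i* of a length-*L* transcript maps to relative position
(i+1)/L — the last base maps to exactly 1.0; the anchor choice is a
convention and has no effect at transcript lengths of interest. Its
weight is depth_i / Σdepth ("relative coverage"). Within a sample group,
per-gene depth vectors are summed across samples before normalization;
pooling commutes with normalization in the sense that the pooled
distribution equals the depth-weighted mixture of per-sample
distributions (property-tested). Per-sample analysis is available by
passing single-sample groups.

Genes with zero total coverage in any group of a contrast are excluded
from the statistics and written to an exclusion report rather than
silently dropped, since silent dropping would bias gene counts.

## Weighted KS statistic

The two-sample statistic is D = sup_x |F_a(x) − F_b(x)| where F is the
right-continuous weighted ECDF: cumulative weight in position order,
with tied positions jumping by their summed weight. Because both ECDFs
are step functions, the supremum is attained at support points; it is
evaluated exactly over the union of both supports — no asymptotics, no
grids. A brute-force oracle (explicit indicator-matrix ECDF on a dense
evaluation grid) arbitrates correctness in the tests; with equal weights
1/n the statistic reduces to the classical two-sample D (also tested,
against `scipy.stats.ks_2samp`). D carries no p-value here: the analysis
uses it descriptively through the band classification below.

## Delta D and the band

For gene g, ΔD = D(test, reference) − D(reference, baseline-alt), where
test/reference differ in processing time and reference/baseline-alt
differ only in sampling source at the same time. ΔD ∈ [−1, 1]; values
near zero mean time added no coverage drift beyond technical variation.
Genes are classified by a closed band [−0.25, 0.25] (the `band`
parameter). The per-gene-set summary reports both in-band and
out-of-band counts and the delta range, leaving interpretation to the
analyst. Whether D should be computed on pooled or per-sample coverage
is not canonical; pooling is the default because the aggregate curves
are also pooled, and a flagged alternative covers the per-sample
reading.

## 3'/5' bias

bias = mass3 / (mass3 + mass5), with mass3/mass5 the summed depth in the
last/first ⌈window_fraction · L⌉ bases (default window_fraction = 0.1,
minimum one base). Uniform coverage gives exactly 0.5 by symmetry;
coverage concentrated in the terminal window gives 1.0. Fractional
windows were chosen over fixed-bp windows so the metric is
length-invariant; the window fraction is configurable. Profiles with no
coverage in either end window are flagged uncomputable.

## Expression metrics

CPM[g,s] = counts[g,s] / libsize[s] × 10⁶ with libsize the column sum;
FPKM additionally divides by length in kb. The low-expression filter
retains a gene iff the number of samples where *both* CPM > 1 and
FPKM > 1 (strict inequalities) is ≥ 5; both thresholds are parameters.
The filter is monotone in counts and invariant to row/column order
(property-tested). Biotype tallies use the vocabulary
protein_coding / lncRNA / pseudogene / other.

Between-source concordance is the per-subject Pearson r of
log2(CPM + 1) over retained genes. log2(CPM+1) was chosen over a
model-based variance-stabilizing transform to keep the module
self-contained; the property of interest — r near 1 for technical
replicates — is robust to the transform.

## Consensus differential-abundance calls

The DE model fits themselves are inputs (two external result tables with
log2FC and FDR). A gene is a consensus call iff FDR < 0.05 in both
tables and |log2FC| > 0.5 in the designated reference table (the first
argument); "Log fold-change" is interpreted as log2, the scale both
upstream tools report. Genes whose fold-change signs disagree between
algorithms are never consensus — sign conflicts are not adjudicated.
Which-algorithm-called-what is recorded for M-A-plot shape coding
(both / single algorithm / none). BH adjustment is the standard step-up
procedure (delegated to statsmodels, verified against a literal step-up
oracle).

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated.

*Coverage.* Fragments per transcript per sample ~ Poisson(mean_depth;
default 500). Each fragment has fixed length 150 nt (matching common
read lengths) and a relative position drawn from
p(x) ∝ exp(−λ(1−x)) on [0,1] (x = 1 is the 3' end) for degraded
gene/group combinations, uniform otherwise. The drawn position is
mapped onto the fragment's 5'-most base over the admissible start range
[0, L − 150], so the uniform model yields coverage symmetric about the
transcript midpoint (mean coverage-mass position 0.5) and mass is
conserved at fragments × fragment length; only transcripts shorter than
one fragment truncate it. Unconstrained right-extending starts were
rejected because they shift the uniform model's coverage mass ~0.07 of
a transcript length toward the 3' end, confounding the degradation
signal with an artifact of the fragment model. λ defaults: 0 (intact);
4 is used as the canonical "detectable degradation" condition, giving
an analytic positional mean of ≈ 0.77 versus 0.5.

*Counts.* Per-gene means are log-uniform over nb_mean_range (default
5–5000, the dynamic range of a filtered bulk matrix); counts are
negative binomial with variance μ + φμ² (φ default 0.1, typical bulk
biological dispersion; φ < 1e-10 switches to the exact Poisson limit).
A fraction de_fraction of genes (size round(de_fraction·n_genes)) gets
group-2 means multiplied by 2^(±de_log2fc), signs randomized.

*What it does not emulate.* Read-level error, positional biases of
priming/GC, multimapping, isoform mixtures, rRNA contamination, or
library-size variation beyond Poisson sampling. Passing tests therefore
establish the correctness and calibration of the statistics under the
stated model, not robustness to every artifact of real libraries.

*Synthetic DE tables.* To exercise the consensus module end to end the
pipeline derives two result tables from the simulated counts with a
Welch t-test and a Mann–Whitney U test on log2(CPM+1), each
BH-adjusted. These are deliberately simple synthetic stand-ins for the
external algorithms whose outputs the module consumes in real use.

## Numerical and design choices

- Determinism: one `numpy` Generator seeded from the config; identical
  config + seed gives byte-identical serialized output (tested).
- Weight normalization tolerance: 1e-6 on entry to the KS statistic;
  weights are constructed by exact division so are far tighter in
  practice.
- Band boundaries are inclusive; `band=0` degenerates to "any non-zero
  delta is out of band" (tested).
- Aggregate curves use 100 relative-position bins (percent bins); bases
  are assigned to bins by midpoint, bin-averaged within gene after
  rescaling by the gene's own mean depth, then averaged across genes.
  Whether per-gene mean-rescaling precedes averaging is a genuinely open
  convention for such plots; rescaling was chosen so every gene
  contributes shape, not magnitude.
- Report TSVs are written atomically (temp file + rename); the run log
  contains versions and row counts but no timestamps, so a whole run
  directory is byte-reproducible.

## Validation problem sizes

The test suite and acceptance script run the drift statistics on 100
genes × 3 groups × 3 replicates at 500 fragments/transcript, the KS
oracle on 100 random lattice-supported distributions against a
10⁴-point grid, BH on 1000 random vectors, and concordance on 100 genes
at ~10⁵ fragments/library with abundances in the post-filter regime
(expected counts 30–5000). These sizes give comfortable statistical
margins for every property checked while keeping a full run in seconds.

## Known limitations

- Transcript-space only: no exon projection from genome-space coverage.
- The weighted KS D is descriptive; no null-distribution calibration or
  p-values are provided for it.
- The concordance transform (log2(CPM+1)) differs from model-based VST;
  absolute r values on real data may differ slightly.
- The consensus caller takes effect size and direction from the
  designated reference table; it does not average the two estimates.
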