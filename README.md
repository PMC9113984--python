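# covdrift

Transcript-coverage drift analysis for bulk RNA-seq degradation QC.

When blood (or any tissue) sits before RNA extraction, partial RNA
degradation is a standing worry: poly-A-selected libraries built from
degraded RNA lose sequencing coverage toward the 5' end of transcripts
while retaining the 3' end. `covdrift` quantifies whether transcript
coverage has *drifted* between sample groups — e.g. samples processed
immediately versus after a day of cold storage — beyond what technical
variation between two simultaneous preparations explains. It is aimed at
anyone running RNA-seq on samples with variable pre-processing delay
(liquid biopsies, field sampling, biobanked material).

## The statistics

**Weighted KS D.** For one transcript of length *L*, each base *i*
(0-based, 5'→3') contributes its relative position *(i+1)/L* with weight
equal to its share of the transcript's total coverage. Two samples or
pooled groups are compared by the weighted two-sample Kolmogorov–Smirnov
statistic

&nbsp;&nbsp;&nbsp;&nbsp;D = sup<sub>x</sub> |F<sub>a</sub>(x) − F<sub>b</sub>(x)|,

where F is the coverage-weighted empirical CDF of relative position.
The supremum is evaluated exactly over the union of both support sets.

**Delta D.** For each gene, a *test* contrast (e.g. 24 h vs 1 h
processing, same vein) is compared against a *technical baseline*
contrast (two veins sampled at the same time):

&nbsp;&nbsp;&nbsp;&nbsp;ΔD = D<sub>test</sub> − D<sub>baseline</sub>.

If storage does not change coverage shape beyond technical variation,
ΔD ≈ 0; genes are classified by a ±0.25 band (configurable).

**Supporting metrics.** 3'/5' bias (fraction of end-window coverage mass
in the 3' window; 0.5 = balanced, →1 = degradation-like), CPM/FPKM with
the low-expression filter (FPKM > 1 **and** CPM > 1 in ≥ 5 samples),
per-sample detection counts, proportion of reads assigned to annotation,
per-subject between-source concordance (Pearson r of log2(CPM+1)), and
the dual-algorithm consensus rule for differential abundance (FDR < 0.05
in both external algorithms and |log2FC| > 0.5).

A synthetic-data generator produces per-base coverage with a tunable
3'-decay parameter λ (fragment positions ∝ exp(−λ(1−x))) and
negative-binomial count matrices with planted fold-changes, so the whole
pipeline is testable without sequencing data.

## Worked example

Simulate 100 transcripts in three groups (test / reference / technical
baseline), with 20% of genes 3'-degraded (λ = 4) in the test group only,
then compute the Delta-D table:

```python
import covdrift as cd

cfg = cd.SimulationConfig(seed=7, n_genes=100, mean_depth=500,
                          degradation_decay=4.0, n_samples_per_group=3)
ds = cd.simulate_dataset(cfg, degraded_fraction=0.2)

from covdrift.coverage import pool_by_group
groups = ('test', 'reference', 'baseline_alt')
group_of = {f'{g}_rep{r+1}': g for g in groups for r in range(3)}
pooled = pool_by_group(ds.coverage, ds.lengths, group_of)

degraded = set(ds.truth.loc[ds.truth.degraded, 'gene_id'])
records, summary, excluded = cd.delta_d_table(
    pooled, gene_sets={'degraded': degraded,
                       'intact': set(ds.truth.gene_id) - degraded})
print(summary[['gene_set', 'n_genes', 'n_in_band', 'n_out_of_band',
               'delta_median']].to_string(index=False))
```

```
gene_set  n_genes  n_in_band  n_out_of_band  delta_median
degraded       20          0             20      0.386084
  intact       80         80              0      0.001464
```

Every planted degraded gene falls outside the ±0.25 band (median
ΔD ≈ 0.39: the 24h-style contrast is far larger than the technical
baseline), while all intact genes sit at ΔD ≈ 0. The 3'/5' bias tells
the same story per library:

```python
from covdrift.degradation import bias_table
bias = bias_table([pooled[g]['test'] for g in sorted(pooled)])
```

mean bias is 0.976 for degraded genes (coverage mass piled on the 3'
end) versus 0.498 for intact genes (balanced extremities).

The same analyses are available from the shell:

```sh
covdrift simulate --seed 7 --n-genes 100 --degradation-decay 4 \
    --degraded-fraction 0.2 --out run/dataset
covdrift all --seed 7 --out run     # full pipeline, all report TSVs
covdrift delta-d --coverage cov.tsv --metadata genes.tsv --groups groups.tsv \
    --test t24h --reference t1h --baseline-alt coccygeal_1h --out-prefix dd
```

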