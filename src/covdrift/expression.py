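"""Abundance normalization, expression filtering and concordance metrics.

CPM is counts scaled to library size per million; FPKM additionally
divides by transcript length in kilobases.  The expression filter keeps
a gene when *both* FPKM > 1 and CPM > 1 (strict) in at least five
samples — the standard guard against noise-dominated low counts before
differential analysis.  Between-source concordance is the per-subject
Pearson correlation of log2(CPM + 1) over retained genes, the check that
two sampling routes from the same subject quantify the same
transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountsMatrix",
    "FilterResult",
    "cpm",
    "fpkm",
    "filter_low_expression",
    "detection_counts",
    "proportion_assigned",
    "source_concordance",
]

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


@dataclass
class CountsMatrix:
    """Gene x sample integer counts with per-gene length and biotype.

    ``counts`` rows are genes, columns samples; ``gene_meta`` is indexed
    by gene_id with columns ``length_nt`` and ``biotype``;
    ``sample_meta`` (optional) is indexed by sample_id with arbitrary
    grouping columns (subject, source, processing time...).
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = self.counts.index.difference(self.gene_meta.index)
        if len(missing):
            raise KeyError(f"genes missing from metadata: {list(missing[:5])}")
        lengths = self.gene_meta.loc[self.counts.index, "length_nt"]
        if (lengths <= 0).any():
            raise ValueError("non-positive transcript length in metadata")

    @property
    def lengths(self) -> pd.Series:
        return self.gene_meta.loc[self.counts.index, "length_nt"].astype(float)

    @property
    def biotypes(self) -> pd.Series:
        bt = self.gene_meta.loc[self.counts.index, "biotype"]
        return bt.where(bt.isin(BIOTYPES[:3]), "other")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        gene_meta_path: str | Path,
        sample_meta_path: str | Path | None = None,
    ) -> "CountsMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        gene_meta = pd.read_csv(gene_meta_path, sep="\t")
        key = "transcript_id" if "transcript_id" in gene_meta.columns else "gene_id"
        gene_meta = gene_meta.set_index(key)
        sample_meta = None
        if sample_meta_path is not None:
            sample_meta = pd.read_csv(sample_meta_path, sep="\t").set_index("sample_id")
        return cls(counts, gene_meta, sample_meta)


@dataclass
class FilterResult:
    retained: set[str]
    dropped: set[str]
    per_biotype_retained: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained & self.dropped:
            raise ValueError("retained and dropped overlap")


def _check_libsizes(lib: pd.Series) -> None:
    zero = lib.index[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero)}")


def cpm(matrix: CountsMatrix) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6``."""
    lib = matrix.library_sizes
    _check_libsizes(lib)
    return matrix.counts / lib * 1e6


def fpkm(matrix: CountsMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million: CPM divided by length in kb."""
    lib = matrix.library_sizes
    _check_libsizes(lib)
    length_kb = matrix.lengths / 1000.0
    return (matrix.counts / lib * 1e6).div(length_kb, axis=0)


def filter_low_expression(
    matrix: CountsMatrix, min_value: float = 1.0, min_samples: int = 5
) -> FilterResult:
    """Retain genes with FPKM > min_value AND CPM > min_value in >= min_samples.

    Both thresholds are strict; the sample count requirement is
    inclusive ("five or more").
    """
    if min_samples > matrix.counts.shape[1]:
        raise ValueError(
            f"min_samples {min_samples} exceeds sample count {matrix.counts.shape[1]}"
        )
    both = (cpm(matrix) > min_value) & (fpkm(matrix) > min_value)
    passing = both.sum(axis=1) >= min_samples
    retained = set(matrix.counts.index[passing])
    dropped = set(matrix.counts.index[~passing])
    tallies = (
        matrix.biotypes[passing.reindex(matrix.counts.index)]
        .value_counts()
        .reindex(BIOTYPES, fill_value=0)
        .to_dict()
    )
    return FilterResult(retained, dropped, tallies)


def detection_counts(matrix: CountsMatrix, filt: FilterResult) -> pd.DataFrame:
    """Per-sample genes detected (count > 0) before and after filtering."""
    detected = matrix.counts > 0
    pre = detected.sum(axis=0)
    retained_mask = matrix.counts.index.isin(filt.retained)
    post = detected.loc[retained_mask].sum(axis=0)
    return pd.DataFrame(
        {"sample_id": matrix.counts.columns, "detected_pre": pre.values,
         "detected_post": post.values}
    )


def proportion_assigned(
    assigned_reads: Mapping[str, int] | pd.Series,
    total_reads: Mapping[str, int] | pd.Series,
) -> pd.Series:
    """Fraction of sequenced reads assigned to the annotation, per sample."""
    assigned = pd.Series(assigned_reads, dtype=float)
    total = pd.Series(total_reads, dtype=float).reindex(assigned.index)
    if total.isna().any():
        raise KeyError("total_reads missing for some samples")
    if (total <= 0).any():
        raise ValueError("total reads must be positive")
    if (assigned < 0).any() or (assigned > total).any():
        bad = assigned.index[(assigned < 0) | (assigned > total)][0]
        raise ValueError(f"assigned reads outside [0, total] for sample {bad!r}")
    return assigned / total


def source_concordance(
    matrix: CountsMatrix,
    pairing: Mapping[str, tuple[str, str]],
    retained: set[str] | None = None,
) -> pd.Series:
    """Per-subject Pearson r of log2(CPM + 1) between two paired samples.

    ``pairing`` maps subject -> (sample_A, sample_B), e.g. the two
    sampling sources from the same animal.  Restricted to ``retained``
    genes when given.
    """
    log_cpm = np.log2(cpm(matrix) + 1.0)
    if retained is not None:
        log_cpm = log_cpm.loc[log_cpm.index.isin(retained)]
    out = {}
    for subject, (a, b) in pairing.items():
        for s in (a, b):
            if s not in log_cpm.columns:
                raise KeyError(f"sample {s!r} (subject {subject!r}) not in matrix")
        out[subject] = float(np.corrcoef(log_cpm[a], log_cpm[b])[0, 1])
    return pd.Series(out, name="pearson_r")
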