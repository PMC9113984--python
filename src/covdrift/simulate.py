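"""Synthetic RNA-seq data with a tunable 3'-degradation coverage signature.

The generator produces the two data structures the downstream analysis
consumes: per-transcript per-base coverage vectors (one per gene and
sample) and a gene x sample negative-binomial count matrix with planted
log2 fold-changes.

Degradation model
-----------------
Poly-A-selected libraries built from partially degraded RNA lose coverage
toward the 5' end of transcripts while retaining the 3' end.  We emulate
this by drawing fragment positions from the density

    p(x) proportional to exp(-lambda * (1 - x)),   x in [0, 1]

where ``x`` is the relative position along the transcript (1 = 3' end)
and ``lambda`` (``degradation_decay``) controls how strongly mass piles
up at the 3' end.  ``lambda = 0`` recovers the uniform model of intact
RNA.  Each drawn position places a fixed-length fragment (default 150 nt)
whose 5'-most base is mapped onto the admissible start range, so intact
transcripts show the symmetric ramp-up/ramp-down coverage shape of real
single-end pileups.

Counts are negative binomial with variance mu + phi * mu**2, the
mean/dispersion convention of the standard bulk DE tools.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_coverage",
    "simulate_counts",
    "simulate_dataset",
    "synthetic_de_tables",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic generator.

    Parameters
    ----------
    seed
        Root seed; identical config + seed gives bit-identical output.
    n_genes
        Number of transcripts to simulate.
    length_range
        ``(min_nt, max_nt)`` inclusive range of transcript lengths.
    n_samples_per_group
        Biological replicates per sample group.
    mean_depth
        Expected fragments per transcript per sample (Poisson).
    degradation_decay
        Exponential decay rate ``lambda >= 0`` of coverage toward the
        5' end for degraded genes; 0 means uniform (intact) coverage.
    nb_mean_range
        ``(min, max)`` of per-gene expected counts (log-uniform draw).
    nb_dispersion
        NB dispersion ``phi`` with variance ``mu + phi * mu**2``.
    de_fraction
        Proportion of genes with a planted abundance effect.
    de_log2fc
        Magnitude of planted log2 fold-changes (sign randomized).
    fragment_length
        Fixed fragment length in nt.
    """

    seed: int = 0
    n_genes: int = 100
    length_range: tuple[int, int] = (500, 2000)
    n_samples_per_group: int = 5
    mean_depth: float = 500.0
    degradation_decay: float = 0.0
    nb_mean_range: tuple[float, float] = (5.0, 5000.0)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    fragment_length: int = 150

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.degradation_decay < 0:
            raise ValueError("degradation_decay must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(f"de_fraction {self.de_fraction} outside [0, 1]")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be non-negative")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["length_range"] = list(d["length_range"])
        d["nb_mean_range"] = list(d["nb_mean_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["length_range"] = tuple(d["length_range"])
        d["nb_mean_range"] = tuple(d["nb_mean_range"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    """Container joining coverage, counts and the planted truth."""

    config: SimulationConfig
    lengths: pd.Series  # gene_id -> transcript length (nt)
    coverage: dict[str, dict[str, np.ndarray]]  # gene -> sample -> depth
    counts: pd.DataFrame  # genes x samples, integer
    truth: pd.DataFrame  # gene_id, degraded, log2fc
    metadata: pd.DataFrame = field(default=None)  # gene_id, length_nt, biotype

    def validate(self) -> None:
        for gene, per_sample in self.coverage.items():
            want = int(self.lengths[gene])
            for sample, depth in per_sample.items():
                if len(depth) != want:
                    raise ValueError(
                        f"coverage length {len(depth)} != transcript length "
                        f"{want} for {gene}/{sample}"
                    )
                if (depth < 0).any():
                    raise ValueError(f"negative coverage in {gene}/{sample}")
        if set(self.truth["gene_id"]) != set(self.counts.index):
            raise ValueError("truth table does not cover every gene exactly once")
        if self.truth["gene_id"].duplicated().any():
            raise ValueError("duplicate gene in truth table")


def _sample_positions(rng: np.random.Generator, n: int, decay: float) -> np.ndarray:
    """Draw relative positions on [0, 1] from p(x) ~ exp(-decay * (1 - x)).

    Inverse-CDF sampling of the truncated exponential; decay == 0 falls
    back to the uniform.
    """
    u = rng.random(n)
    if decay == 0.0:
        return u
    # CDF F(x) = (exp(-decay (1-x)) - exp(-decay)) / (1 - exp(-decay))
    e = np.exp(-decay)
    return 1.0 + np.log(u * (1.0 - e) + e) / decay


def _gene_coverage(
    rng: np.random.Generator,
    length: int,
    mean_depth: float,
    decay: float,
    fragment_length: int,
) -> np.ndarray:
    """Per-base coverage from Poisson(mean_depth) fixed-length fragments.

    The drawn relative position is mapped to the fragment's 5'-most base
    over the admissible start range [0, length - fragment_length]; only
    transcripts shorter than one fragment truncate it.
    """
    if length <= 0:
        raise ValueError(f"non-positive transcript length {length}")
    n_frag = rng.poisson(mean_depth)
    cover = np.zeros(length, dtype=np.int64)
    if n_frag == 0:
        return cover
    x = _sample_positions(rng, n_frag, decay)
    span = max(length - fragment_length, 0)
    starts = np.minimum((x * (span + 1)).astype(np.int64), span)
    ends = np.minimum(starts + fragment_length, length)
    # difference-array accumulation of interval pileup
    diff = np.zeros(length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    cover = np.cumsum(diff[:-1])
    return cover


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def _sample_ids(config: SimulationConfig, groups: tuple[str, ...]) -> dict[str, list[str]]:
    return {
        g: [f"{g}_rep{r + 1}" for r in range(config.n_samples_per_group)]
        for g in groups
    }


def simulate_coverage(
    config: SimulationConfig,
    degraded_genes: set[str] | frozenset[str],
    groups: tuple[str, ...] = ("test", "reference", "baseline_alt"),
    degraded_groups: tuple[str, ...] = ("test",),
    lengths: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.Series]:
    """Simulate per-base coverage for every gene in every sample.

    Genes in ``degraded_genes`` get the 3'-decayed positional density in
    samples belonging to ``degraded_groups``; all other gene/sample
    combinations are uniform.  Returns the coverage map and the transcript
    lengths used.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    if lengths is None:
        lo, hi = config.length_range
        lengths = pd.Series(
            rng.integers(lo, hi + 1, size=config.n_genes), index=genes, name="length_nt"
        )
    samples = _sample_ids(config, groups)
    coverage: dict[str, dict[str, np.ndarray]] = {}
    for gene in genes:
        length = int(lengths[gene])
        per_sample: dict[str, np.ndarray] = {}
        for group in groups:
            decay = (
                config.degradation_decay
                if (gene in degraded_genes and group in degraded_groups)
                else 0.0
            )
            for sample in samples[group]:
                per_sample[sample] = _gene_coverage(
                    rng, length, config.mean_depth, decay, config.fragment_length
                )
        coverage[gene] = per_sample
    return coverage, lengths


def simulate_counts(
    config: SimulationConfig,
    groups: tuple[str, str] = ("group1", "group2"),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted log2 fold-changes.

    Group-2 means are multiplied by ``2**log2fc`` for effect genes; the
    planted set has size ``round(de_fraction * n_genes)`` and random
    effect signs.  Returns ``(counts, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    lo, hi = config.nb_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    log2fc = np.zeros(config.n_genes)
    log2fc[de_idx] = config.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)

    samples = _sample_ids(config, groups)
    cols: dict[str, np.ndarray] = {}
    for group in groups:
        group_mu = mu * np.exp2(log2fc) if group == groups[1] else mu
        for sample in samples[group]:
            cols[sample] = _nb_draw(rng, group_mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame(
        {"gene_id": genes, "log2fc": log2fc, "is_de": log2fc != 0.0}
    )
    return counts, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, variance = mu + phi mu^2); Poisson limit for tiny phi."""
    if phi < 1e-10:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_dataset(
    config: SimulationConfig,
    degraded_fraction: float = 0.0,
    groups: tuple[str, ...] = ("test", "reference", "baseline_alt"),
) -> SimulatedDataset:
    """One-call generator: coverage + counts + truth, deterministically.

    ``degraded_fraction`` of genes get the 3'-decay signature in the
    ``test`` group (relevant only when ``degradation_decay > 0``).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_deg = int(round(degraded_fraction * config.n_genes))
    degraded = set(
        np.array(genes)[rng.choice(config.n_genes, size=n_deg, replace=False)]
    )
    coverage, lengths = simulate_coverage(config, degraded, groups=groups, rng=rng)
    counts, truth = simulate_counts(config, rng=rng)
    truth = truth.assign(degraded=truth["gene_id"].isin(degraded))
    biotypes = pd.Series(
        rng.choice(
            ["protein_coding", "lncRNA", "pseudogene"],
            p=[0.9, 0.07, 0.03],
            size=config.n_genes,
        ),
        index=genes,
    )
    metadata = pd.DataFrame(
        {"gene_id": genes, "length_nt": lengths.values, "biotype": biotypes.values}
    )
    ds = SimulatedDataset(
        config=config,
        lengths=lengths,
        coverage=coverage,
        counts=counts,
        truth=truth,
        metadata=metadata,
    )
    ds.validate()
    return ds


def synthetic_de_tables(
    counts: pd.DataFrame,
    group_of: Mapping[str, str],
    contrast: tuple[str, str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two synthetic differential-abundance result tables from one matrix.

    Stand-ins for the external DE algorithms whose outputs the consensus
    caller consumes: algorithm A is a Welch t-test and algorithm B a
    Mann-Whitney U test, both on log2(CPM + 1), each BH-adjusted.  They
    exist to exercise the consensus machinery on data with known planted
    effects, not to estimate abundance differences well.
    """
    from scipy import stats as sps

    from .consensus import bh_adjust

    a_samples = [s for s in counts.columns if group_of[s] == contrast[0]]
    b_samples = [s for s in counts.columns if group_of[s] == contrast[1]]
    lib = counts.sum(axis=0).astype(float)
    logcpm = np.log2(counts / lib * 1e6 + 1.0)
    xa = logcpm[a_samples].to_numpy()
    xb = logcpm[b_samples].to_numpy()
    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    mean_ab = logcpm.mean(axis=1).to_numpy()

    t_p = sps.ttest_ind(xb, xa, axis=1, equal_var=False).pvalue
    t_p = np.nan_to_num(t_p, nan=1.0)
    u_p = np.array(
        [
            sps.mannwhitneyu(xb[i], xa[i], alternative="two-sided").pvalue
            if not np.allclose(xb[i], xa[i])
            else 1.0
            for i in range(len(counts))
        ]
    )

    def table(alg: str, p: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": counts.index,
                "log2fc": log2fc,
                "mean_abundance": mean_ab,
                "pvalue": p,
                "fdr": bh_adjust(p),
                "algorithm": alg,
            }
        )

    return table("welch_t", t_p), table("mannwhitney_u", u_p)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write coverage/counts/truth/metadata TSVs plus the config YAML.

    Coverage rows list only non-zero positions; readers fill zeros from
    the metadata lengths.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coverage": outdir / "coverage.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "metadata": outdir / "gene_metadata.tsv",
        "config": outdir / "config.yaml",
    }
    buf = io.StringIO()
    buf.write("transcript_id\tsample_id\tposition\tdepth\n")
    for gene in sorted(ds.coverage):
        for sample in sorted(ds.coverage[gene]):
            depth = ds.coverage[gene][sample]
            for pos in np.nonzero(depth)[0]:
                buf.write(f"{gene}\t{sample}\t{pos}\t{depth[pos]}\n")
    paths["coverage"].write_text(buf.getvalue())
    ds.counts.to_csv(paths["counts"], sep="\t")
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    ds.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    paths["config"].write_text(ds.config.to_yaml())
    return paths
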