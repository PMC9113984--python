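"""Per-transcript coverage profiles and their relative-position representation.

A :class:`CoverageProfile` holds one transcript's per-base sequencing
depth, oriented 5'->3' in transcript space (0-based, half-open
coordinates).  For the drift statistics each profile is converted to a
:class:`WeightedPositionalDistribution`: every base contributes its
relative position ``(i + 1) / L`` weighted by its share of the
transcript's total coverage.  Aggregate curves average per-gene
mean-rescaled depth over relative-position bins, the standard way of
displaying global 3'/5' coverage trends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "WeightedPositionalDistribution",
    "AggregateProfile",
    "ZeroCoverageError",
    "read_coverage",
    "read_coverage_tsv",
    "read_bedgraph",
    "write_coverage_tsv",
    "pool_group",
    "pool_by_group",
    "to_weighted_distribution",
    "aggregate_profile",
]


class ZeroCoverageError(ValueError):
    """Raised when an operation needs coverage mass and the profile has none."""


@dataclass
class CoverageProfile:
    gene_id: str
    group_id: str
    depth: np.ndarray  # one value per base, 5'->3'
    length_nt: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if len(self.depth) != self.length_nt:
            raise ValueError(
                f"{self.gene_id}: depth vector length {len(self.depth)} != "
                f"transcript length {self.length_nt}"
            )
        if (self.depth < 0).any():
            raise ValueError(f"{self.gene_id}: negative depth")

    @property
    def total(self) -> float:
        return float(self.depth.sum())


@dataclass
class WeightedPositionalDistribution:
    """Relative positions in (0, 1] with coverage-share weights summing to 1."""

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.shape != self.weights.shape:
            raise ValueError("positions and weights differ in length")
        if len(self.positions) == 0:
            raise ValueError("empty distribution")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if (self.weights < 0).any():
            raise ValueError("negative weights")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")


@dataclass
class AggregateProfile:
    gene_set_label: str
    mean_relative_depth: np.ndarray
    n_bins: int
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.mean_relative_depth) != self.n_bins:
            raise ValueError("curve length != n_bins")


# ---------------------------------------------------------------------------
# I/O


def _lengths_from_metadata(metadata: pd.DataFrame) -> pd.Series:
    if "transcript_id" in metadata.columns:
        key = "transcript_id"
    elif "gene_id" in metadata.columns:
        key = "gene_id"
    else:
        raise ValueError("metadata needs a transcript_id or gene_id column")
    return metadata.set_index(key)["length_nt"]


def read_coverage_tsv(path: str | Path, metadata: pd.DataFrame) -> list[CoverageProfile]:
    """Read long-format coverage (transcript_id, sample_id, position, depth).

    Missing positions are filled with depth 0 up to the transcript length
    recorded in ``metadata``; positions at or beyond that length, unknown
    transcripts and negative depths are errors.
    """
    lengths = _lengths_from_metadata(metadata)
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "sample_id", "position", "depth"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["depth"] < 0).any():
        bad = df.loc[df["depth"] < 0].iloc[0]
        raise ValueError(f"{path}: negative depth for {bad['transcript_id']}")
    profiles: list[CoverageProfile] = []
    for (gene, sample), rows in df.groupby(["transcript_id", "sample_id"], sort=True):
        if gene not in lengths.index:
            raise KeyError(f"{path}: unknown transcript_id {gene!r}")
        length = int(lengths[gene])
        pos = rows["position"].to_numpy()
        if (pos < 0).any() or (pos >= length).any():
            raise ValueError(
                f"{path}: position out of range [0, {length}) for {gene!r}"
            )
        depth = np.zeros(length, dtype=np.int64)
        depth[pos] = rows["depth"].to_numpy()
        profiles.append(CoverageProfile(str(gene), str(sample), depth, length))
    return profiles


def read_bedgraph(
    path: str | Path, metadata: pd.DataFrame, sample_id: str
) -> list[CoverageProfile]:
    """Read a transcript-space BedGraph (0-based, half-open intervals)."""
    lengths = _lengths_from_metadata(metadata)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["transcript_id", "start", "end", "depth"],
        header=None,
    )
    if (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth")
    profiles = []
    for gene, rows in df.groupby("transcript_id", sort=True):
        if gene not in lengths.index:
            raise KeyError(f"{path}: unknown transcript_id {gene!r}")
        length = int(lengths[gene])
        if (rows["end"] > length).any() or (rows["start"] < 0).any():
            raise ValueError(f"{path}: interval out of range for {gene!r}")
        depth = np.zeros(length, dtype=np.int64)
        for start, end, d in rows[["start", "end", "depth"]].itertuples(index=False):
            depth[int(start) : int(end)] = d
        profiles.append(CoverageProfile(str(gene), sample_id, depth, length))
    return profiles


def read_coverage(
    path: str | Path,
    metadata: pd.DataFrame,
    fmt: str = "auto",
    sample_id: str | None = None,
) -> list[CoverageProfile]:
    """Dispatch to the TSV or BedGraph reader (``fmt='auto'`` by suffix)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "bedgraph" if path.suffix in {".bedgraph", ".bg"} else "tsv"
    if fmt == "tsv":
        return read_coverage_tsv(path, metadata)
    if fmt == "bedgraph":
        if sample_id is None:
            raise ValueError("BedGraph input needs an explicit sample_id")
        return read_bedgraph(path, metadata, sample_id)
    raise ValueError(f"unknown coverage format {fmt!r}")


def write_coverage_tsv(profiles: Iterable[CoverageProfile], path: str | Path) -> None:
    """Write profiles in the long TSV format (non-zero positions only)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tsample_id\tposition\tdepth\n")
        for p in sorted(profiles, key=lambda p: (p.gene_id, p.group_id)):
            for pos in np.nonzero(p.depth)[0]:
                fh.write(f"{p.gene_id}\t{p.group_id}\t{pos}\t{p.depth[pos]}\n")


# ---------------------------------------------------------------------------
# Transformations


def pool_group(profiles: Sequence[CoverageProfile], group_id: str | None = None) -> CoverageProfile:
    """Sum depth vectors of one gene's profiles into a pooled group profile."""
    if not profiles:
        raise ValueError("cannot pool an empty profile set")
    gene_ids = {p.gene_id for p in profiles}
    if len(gene_ids) != 1:
        raise ValueError(f"profiles span multiple genes: {sorted(gene_ids)}")
    lengths = {p.length_nt for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"length mismatch within gene: {sorted(lengths)}")
    depth = np.sum([p.depth for p in profiles], axis=0)
    return CoverageProfile(
        profiles[0].gene_id,
        group_id if group_id is not None else profiles[0].group_id,
        depth,
        profiles[0].length_nt,
    )


def pool_by_group(
    coverage: dict[str, dict[str, np.ndarray]],
    lengths: pd.Series,
    group_of: dict[str, str],
) -> dict[str, dict[str, CoverageProfile]]:
    """Pool a gene -> sample -> depth map into gene -> group -> profile."""
    pooled: dict[str, dict[str, CoverageProfile]] = {}
    for gene, per_sample in coverage.items():
        by_group: dict[str, list[CoverageProfile]] = {}
        for sample, depth in per_sample.items():
            g = group_of[sample]
            by_group.setdefault(g, []).append(
                CoverageProfile(gene, sample, depth, int(lengths[gene]))
            )
        pooled[gene] = {g: pool_group(ps, group_id=g) for g, ps in by_group.items()}
    return pooled


def to_weighted_distribution(profile: CoverageProfile) -> WeightedPositionalDistribution:
    """Relative position ``(i + 1) / L`` weighted by the base's coverage share."""
    total = profile.total
    if total <= 0:
        raise ZeroCoverageError(
            f"{profile.gene_id}/{profile.group_id}: zero total coverage"
        )
    L = profile.length_nt
    positions = (np.arange(L) + 1) / L
    weights = profile.depth / total
    return WeightedPositionalDistribution(positions, weights)


def aggregate_profile(
    profiles: Iterable[CoverageProfile],
    gene_set: set[str] | None = None,
    n_bins: int = 100,
    gene_set_label: str = "all",
) -> AggregateProfile:
    """Mean relative depth per relative-position bin, averaged across genes.

    Each gene's depth is rescaled by its own mean depth (so uniform
    coverage maps to a flat curve at 1.0), bases are assigned to bins by
    their midpoint relative position, bin-averaged within the gene, then
    averaged across genes.  Zero-coverage genes are excluded.
    """
    curves = []
    for p in profiles:
        if gene_set is not None and p.gene_id not in gene_set:
            continue
        if p.total <= 0:
            continue
        L = p.length_nt
        rel = (np.arange(L) + 0.5) / L
        bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        scaled = p.depth / p.depth.mean()
        sums = np.bincount(bins, weights=scaled, minlength=n_bins)
        counts = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            curve = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        curves.append(curve)
    if not curves:
        raise ValueError("no usable (non-zero coverage) genes in gene set")
    mean_curve = np.nanmean(np.vstack(curves), axis=0)
    return AggregateProfile(gene_set_label, mean_curve, n_bins, len(curves))
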