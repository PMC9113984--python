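"""Coverage-drift statistics: weighted KS D, Delta-D and 3'/5' bias.

The central statistic compares two transcripts' relative-coverage
distributions with a weighted two-sample Kolmogorov-Smirnov D: each
base's relative position enters the empirical CDF with weight equal to
its share of the transcript's total coverage, and

    D = sup_x | F_a(x) - F_b(x) |

is evaluated exactly over the union of both support sets (the ECDFs are
right-continuous step functions, so the supremum is attained there).
With equal weights 1/n this reduces to the classical two-sample D.

The Delta-D contrast subtracts a same-time technical-baseline D from a
time-separated test D for the same gene:

    Delta D = D_test - D_baseline

If coverage drift over storage time is no larger than technical
variation between two simultaneous preparations, Delta D sits near zero;
a band of +/-0.25 separates "no drift" from "drifted" genes.  D and
Delta D are used descriptively — no p-values are attached.

The 3'/5' bias is the fraction of end-window coverage mass lying in the
3' window: 0.5 means balanced extremities, values near 1 the 3'-skewed
coverage characteristic of degraded poly-A-selected RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import (
    CoverageProfile,
    WeightedPositionalDistribution,
    ZeroCoverageError,
    to_weighted_distribution,
)

__all__ = [
    "DStat",
    "DeltaDRecord",
    "BiasMetric",
    "weighted_ks_d",
    "delta_d",
    "delta_d_table",
    "three_five_bias",
    "bias_table",
]

DEFAULT_BAND = 0.25


@dataclass(frozen=True)
class DStat:
    gene_id: str
    contrast: str
    D: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0 + 1e-12:
            raise ValueError(f"D = {self.D} outside [0, 1]")


@dataclass(frozen=True)
class DeltaDRecord:
    gene_id: str
    D_test: float
    D_baseline: float
    delta: float
    in_band: bool


@dataclass(frozen=True)
class BiasMetric:
    gene_id: str
    three_five_bias: float
    window_fraction: float


def _weighted_ecdf(dist: WeightedPositionalDistribution, grid: np.ndarray) -> np.ndarray:
    """Right-continuous weighted ECDF evaluated at ``grid`` points."""
    cum = np.cumsum(dist.weights)
    idx = np.searchsorted(dist.positions, grid, side="right")
    return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)


def weighted_ks_d(
    a: WeightedPositionalDistribution,
    b: WeightedPositionalDistribution,
    gene_id: str = "",
    contrast: str = "",
) -> DStat:
    """Exact weighted two-sample KS D between two positional distributions.

    Evaluates |F_a - F_b| at the union of both support sets; tied
    positions jump by their summed weight.  Raises on unnormalized
    weights (tolerance 1e-6).
    """
    for name, dist in (("a", a), ("b", b)):
        if abs(dist.weights.sum() - 1.0) > 1e-6:
            raise ValueError(f"distribution {name}: weights sum != 1")
    grid = np.union1d(a.positions, b.positions)
    d = float(np.abs(_weighted_ecdf(a, grid) - _weighted_ecdf(b, grid)).max())
    return DStat(gene_id, contrast, min(d, 1.0))


def delta_d(d_test: DStat, d_baseline: DStat, band: float = DEFAULT_BAND) -> DeltaDRecord:
    """Delta D = D_test - D_baseline with closed-interval band classification."""
    if d_test.gene_id != d_baseline.gene_id:
        raise ValueError(
            f"gene mismatch: {d_test.gene_id!r} vs {d_baseline.gene_id!r}"
        )
    delta = d_test.D - d_baseline.D
    return DeltaDRecord(
        gene_id=d_test.gene_id,
        D_test=d_test.D,
        D_baseline=d_baseline.D,
        delta=delta,
        in_band=(-band <= delta <= band),
    )


def delta_d_table(
    pooled: Mapping[str, Mapping[str, CoverageProfile]],
    test_group: str = "test",
    reference_group: str = "reference",
    baseline_alt_group: str = "baseline_alt",
    gene_sets: Mapping[str, set[str]] | None = None,
    band: float = DEFAULT_BAND,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene Delta-D records over pooled group coverage.

    ``pooled`` maps gene -> group -> pooled profile.  For every gene with
    usable (non-zero) coverage in all three groups, D_test contrasts the
    test group against the reference and D_baseline contrasts the
    reference against the baseline-alternative (the same-time technical
    contrast).  Genes lacking usable coverage in any group are excluded
    and reported.

    Returns ``(records, summary, exclusions)``:
    records has one row per usable gene with its gene-set label; summary
    reports per gene set the in-band/out-of-band counts, fractions and
    delta range; exclusions lists dropped genes with the reason.
    """
    if gene_sets is None:
        gene_sets = {"all": set(pooled)}
    label_of: dict[str, str] = {}
    for label, genes in gene_sets.items():
        for g in genes:
            if g in label_of:
                raise ValueError(f"gene {g!r} appears in multiple gene sets")
            label_of[g] = label

    rows, excluded = [], []
    for gene in sorted(pooled):
        if gene not in label_of:
            continue
        groups = pooled[gene]
        missing = [
            g
            for g in (test_group, reference_group, baseline_alt_group)
            if g not in groups
        ]
        if missing:
            excluded.append((gene, f"missing group(s): {','.join(missing)}"))
            continue
        try:
            dists = {
                g: to_weighted_distribution(groups[g])
                for g in (test_group, reference_group, baseline_alt_group)
            }
        except ZeroCoverageError:
            excluded.append((gene, "zero coverage in at least one group"))
            continue
        d_test = weighted_ks_d(
            dists[test_group],
            dists[reference_group],
            gene,
            f"{test_group}_vs_{reference_group}",
        )
        d_base = weighted_ks_d(
            dists[reference_group],
            dists[baseline_alt_group],
            gene,
            f"{reference_group}_vs_{baseline_alt_group}",
        )
        rec = delta_d(d_test, d_base, band=band)
        rows.append(
            {
                "gene_id": gene,
                "gene_set": label_of[gene],
                "D_test": rec.D_test,
                "D_baseline": rec.D_baseline,
                "delta": rec.delta,
                "in_band": rec.in_band,
            }
        )

    records = pd.DataFrame(
        rows,
        columns=["gene_id", "gene_set", "D_test", "D_baseline", "delta", "in_band"],
    )
    if len(records):
        summary = (
            records.groupby("gene_set")
            .agg(
                n_genes=("gene_id", "size"),
                n_in_band=("in_band", "sum"),
                delta_min=("delta", "min"),
                delta_max=("delta", "max"),
                delta_median=("delta", "median"),
            )
            .reset_index()
        )
        summary["n_out_of_band"] = summary["n_genes"] - summary["n_in_band"]
        summary["frac_in_band"] = summary["n_in_band"] / summary["n_genes"]
    else:
        summary = pd.DataFrame(
            columns=[
                "gene_set",
                "n_genes",
                "n_in_band",
                "delta_min",
                "delta_max",
                "delta_median",
                "n_out_of_band",
                "frac_in_band",
            ]
        )
    exclusions = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return records, summary, exclusions


def three_five_bias(
    profile: CoverageProfile, window_fraction: float = 0.1
) -> BiasMetric:
    """Fraction of end-window coverage mass in the 3' window.

    Windows are the first and last ``ceil(window_fraction * L)`` bases
    (minimum one base).  Uniform coverage gives exactly 0.5; coverage
    concentrated at the 3' end approaches 1.
    """
    if not 0.0 < window_fraction <= 0.5:
        raise ValueError("window_fraction must be in (0, 0.5]")
    if profile.total <= 0:
        raise ZeroCoverageError(f"{profile.gene_id}: zero total coverage")
    w = max(int(np.ceil(window_fraction * profile.length_nt)), 1)
    mass5 = float(profile.depth[:w].sum())
    mass3 = float(profile.depth[-w:].sum())
    if mass5 + mass3 == 0:
        raise ZeroCoverageError(
            f"{profile.gene_id}: no coverage in either end window"
        )
    return BiasMetric(profile.gene_id, mass3 / (mass3 + mass5), window_fraction)


def bias_table(
    profiles: Iterable[CoverageProfile], window_fraction: float = 0.1
) -> pd.DataFrame:
    """3'/5' bias for every profile with usable end-window coverage."""
    rows = []
    for p in profiles:
        try:
            m = three_five_bias(p, window_fraction)
        except ZeroCoverageError:
            continue
        rows.append(
            {
                "gene_id": m.gene_id,
                "group_id": p.group_id,
                "three_five_bias": m.three_five_bias,
                "window_fraction": m.window_fraction,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "group_id", "three_five_bias", "window_fraction"]
    )
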