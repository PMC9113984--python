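"""Dual-algorithm consensus differential-abundance calling.

Two differential-abundance algorithms run on the same contrast rarely
agree perfectly; requiring FDR < 0.05 from *both*, plus an absolute
log2 fold-change above 0.5, yields calls robust to the biases of either
model.  The module consumes externally produced result tables (gene,
log2fc, mean abundance, FDR), classifies every gene by which
algorithm(s) called it — the shape coding of an M-A plot — and reports
cross-contrast overlaps of the consensus sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConsensusCall",
    "consensus_calls",
    "consensus_table",
    "bh_adjust",
    "overlap_report",
    "read_de_table",
]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "fdr")


@dataclass(frozen=True)
class ConsensusCall:
    gene_id: str
    called_by: frozenset[str]
    consensus: bool
    direction: str  # "up" | "down" | "none"


def read_de_table(path: str, algorithm: str | None = None) -> pd.DataFrame:
    """Read a TSV result table (gene_id, log2fc, mean_abundance, fdr...)."""
    df = pd.read_csv(path, sep="\t")
    if missing := set(REQUIRED_COLUMNS) - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if algorithm is not None:
        df = df.assign(algorithm=algorithm)
    elif "algorithm" not in df.columns:
        raise ValueError(f"{path}: no algorithm column and none given")
    return df


def _validate_de_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    if missing := set(REQUIRED_COLUMNS) - set(df.columns):
        raise ValueError(f"table {label}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"table {label}: duplicate gene rows (e.g. {dup!r})")
    bad = ~df["fdr"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(f"table {label}: FDR outside [0, 1]")
    return df.set_index("gene_id")


def consensus_calls(
    a: pd.DataFrame,
    b: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> list[ConsensusCall]:
    """Consensus = FDR < threshold in both tables AND |log2fc| > lfc_threshold.

    The effect size and direction come from table ``a`` (the designated
    reference); genes whose fold-change signs disagree between the two
    tables are never consensus.  Genes absent from one table count as
    not called by that algorithm.
    """
    ta = _validate_de_table(a, "a")
    tb = _validate_de_table(b, "b")
    name_a = str(a["algorithm"].iloc[0]) if "algorithm" in a.columns else "algo_A"
    name_b = str(b["algorithm"].iloc[0]) if "algorithm" in b.columns else "algo_B"
    universe = ta.index.union(tb.index)

    calls = []
    for gene in universe:
        hit_a = gene in ta.index and ta.at[gene, "fdr"] < fdr_threshold
        hit_b = gene in tb.index and tb.at[gene, "fdr"] < fdr_threshold
        called_by = frozenset(
            n for n, hit in ((name_a, hit_a), (name_b, hit_b)) if hit
        )
        lfc = float(ta.at[gene, "log2fc"]) if gene in ta.index else np.nan
        signs_agree = True
        if gene in ta.index and gene in tb.index:
            sa, sb = np.sign(ta.at[gene, "log2fc"]), np.sign(tb.at[gene, "log2fc"])
            signs_agree = not (sa * sb < 0)
        consensus = (
            hit_a
            and hit_b
            and signs_agree
            and np.isfinite(lfc)
            and abs(lfc) > lfc_threshold
        )
        direction = "none" if not consensus else ("up" if lfc > 0 else "down")
        calls.append(ConsensusCall(str(gene), called_by, consensus, direction))
    return calls


def consensus_table(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    """Tabulate calls with the M-A-plot shape class per gene.

    Shape classes: ``both`` (consensus candidates hit by both
    algorithms), the single algorithm's name, or ``none``.
    """
    rows = []
    for c in calls:
        if len(c.called_by) == 2:
            shape = "both"
        elif len(c.called_by) == 1:
            shape = next(iter(c.called_by))
        else:
            shape = "none"
        rows.append(
            {
                "gene_id": c.gene_id,
                "called_by": ";".join(sorted(c.called_by)),
                "shape_class": shape,
                "consensus": c.consensus,
                "direction": c.direction,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "called_by", "shape_class", "consensus", "direction"]
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_report(
    calls_by_contrast: Mapping[str, Sequence[ConsensusCall]],
) -> pd.DataFrame:
    """Pairwise consensus-set overlaps across contrasts.

    For each contrast pair: intersection size and membership, and how
    many shared genes agree in direction.
    """
    if len(calls_by_contrast) < 2:
        raise ValueError("need at least two contrasts")
    sets = {
        name: {c.gene_id: c.direction for c in calls if c.consensus}
        for name, calls in calls_by_contrast.items()
    }
    rows = []
    for x, y in combinations(sorted(sets), 2):
        shared = sorted(set(sets[x]) & set(sets[y]))
        concordant = sum(sets[x][g] == sets[y][g] for g in shared)
        rows.append(
            {
                "contrast_a": x,
                "contrast_b": y,
                "n_a": len(sets[x]),
                "n_b": len(sets[y]),
                "n_shared": len(shared),
                "n_direction_concordant": concordant,
                "shared_genes": ";".join(shared),
            }
        )
    return pd.DataFrame(rows)
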