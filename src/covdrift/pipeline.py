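"""End-to-end synthetic pipeline: simulate -> profiles -> statistics -> reports.

`run_pipeline` materializes a run directory with every report table the
analysis produces, deterministically for a given config + seed:

    dataset/            coverage/counts/truth/metadata TSVs + config echo
    delta_d.tsv         per-gene D_test, D_baseline, delta, band class
    delta_d_summary.tsv per-gene-set in/out-of-band tallies and delta range
    exclusions.tsv      genes dropped from the drift statistics and why
    bias.tsv            per-gene 3'/5' bias per pooled group
    aggregate_*.tsv     mean relative depth per position bin per group
    cpm.tsv fpkm.tsv    normalized abundance matrices
    filter_report.tsv   retained/dropped per gene with biotype
    detection.tsv       genes detected per sample pre/post filter
    de_*.tsv            synthetic DE tables and the consensus calls
    run_log.txt         config echo, versions, row counts (no timestamps)

All tables are written atomically (temp file + rename) so a failed run
never leaves a truncated report.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import consensus_calls, consensus_table
from .coverage import CoverageProfile, aggregate_profile, pool_by_group
from .degradation import bias_table, delta_d_table
from .expression import (
    CountsMatrix,
    cpm,
    detection_counts,
    filter_low_expression,
    fpkm,
)
from .simulate import SimulationConfig, simulate_dataset, synthetic_de_tables, write_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

COVERAGE_GROUPS = ("test", "reference", "baseline_alt")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible synthetic run needs.

    ``simulation`` parameterizes the generator; ``degraded_fraction`` is
    the share of genes given the 3'-decay signature in the test group;
    the remaining fields are the analysis thresholds.
    """

    simulation: SimulationConfig = SimulationConfig()
    degraded_fraction: float = 0.2
    band: float = 0.25
    window_fraction: float = 0.1
    filter_min_value: float = 1.0
    filter_min_samples: int = 5
    fdr_threshold: float = 0.05
    lfc_threshold: float = 0.5
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.degraded_fraction <= 1.0:
            raise ValueError("degraded_fraction outside [0, 1]")
        if self.band < 0:
            raise ValueError("band must be >= 0")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        sim = d.pop("simulation")
        sim["length_range"] = list(sim["length_range"])
        sim["nb_mean_range"] = list(sim["nb_mean_range"])
        d["simulation"] = sim
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        sim = d.pop("simulation", {})
        sim["length_range"] = tuple(sim.get("length_range", (500, 2000)))
        sim["nb_mean_range"] = tuple(sim.get("nb_mean_range", (5.0, 5000.0)))
        return cls(simulation=SimulationConfig(**sim), **d)


def _atomic_write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full synthetic analysis; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ds = simulate_dataset(
        config.simulation,
        degraded_fraction=config.degraded_fraction,
        groups=COVERAGE_GROUPS,
    )
    write_dataset(ds, outdir / "dataset")

    # coverage-drift statistics on group-pooled profiles
    group_of = {
        f"{g}_rep{r + 1}": g
        for g in COVERAGE_GROUPS
        for r in range(config.simulation.n_samples_per_group)
    }
    pooled = pool_by_group(ds.coverage, ds.lengths, group_of)
    degraded = set(ds.truth.loc[ds.truth["degraded"], "gene_id"])
    gene_sets = {
        "degraded": degraded,
        "intact": set(ds.truth["gene_id"]) - degraded,
    }
    records, summary, exclusions = delta_d_table(
        pooled, *COVERAGE_GROUPS, gene_sets=gene_sets, band=config.band
    )
    _atomic_write_tsv(records, outdir / "delta_d.tsv")
    _atomic_write_tsv(summary, outdir / "delta_d_summary.tsv")
    _atomic_write_tsv(exclusions, outdir / "exclusions.tsv")

    all_pooled: list[CoverageProfile] = [
        p for per_group in pooled.values() for p in per_group.values()
    ]
    _atomic_write_tsv(
        bias_table(all_pooled, config.window_fraction), outdir / "bias.tsv"
    )
    for group in COVERAGE_GROUPS:
        agg = aggregate_profile(
            [pooled[g][group] for g in sorted(pooled) if group in pooled[g]],
            n_bins=config.n_bins,
            gene_set_label=group,
        )
        _atomic_write_tsv(
            pd.DataFrame(
                {"bin": range(config.n_bins),
                 "mean_relative_depth": agg.mean_relative_depth}
            ),
            outdir / f"aggregate_{group}.tsv",
        )

    # expression metrics on the simulated count matrix
    matrix = CountsMatrix(ds.counts, ds.metadata.set_index("gene_id"))
    _atomic_write_tsv(cpm(matrix).round(6), outdir / "cpm.tsv", index=True)
    _atomic_write_tsv(fpkm(matrix).round(6), outdir / "fpkm.tsv", index=True)
    filt = filter_low_expression(
        matrix, config.filter_min_value, config.filter_min_samples
    )
    report = pd.DataFrame(
        {
            "gene_id": matrix.counts.index,
            "biotype": matrix.biotypes.values,
            "retained": matrix.counts.index.isin(sorted(filt.retained)),
        }
    )
    _atomic_write_tsv(report, outdir / "filter_report.tsv")
    _atomic_write_tsv(detection_counts(matrix, filt), outdir / "detection.tsv")

    # synthetic DE tables exercise the consensus caller end to end
    count_group_of = {s: ("group1" if s.startswith("group1") else "group2")
                      for s in ds.counts.columns}
    de_a, de_b = synthetic_de_tables(
        ds.counts, count_group_of, ("group1", "group2"), seed=config.simulation.seed
    )
    _atomic_write_tsv(de_a.round(8), outdir / "de_welch_t.tsv")
    _atomic_write_tsv(de_b.round(8), outdir / "de_mannwhitney_u.tsv")
    calls = consensus_calls(de_a, de_b, config.fdr_threshold, config.lfc_threshold)
    _atomic_write_tsv(consensus_table(calls), outdir / "consensus.tsv")

    n_consensus = sum(c.consensus for c in calls)
    log = [
        f"covdrift {__version__}",
        f"seed: {config.simulation.seed}",
        "config:",
        *("  " + line for line in config.to_yaml().splitlines()),
        f"genes simulated: {config.simulation.n_genes}",
        f"delta-d records: {len(records)} (excluded: {len(exclusions)})",
        f"genes retained by expression filter: {len(filt.retained)}",
        f"consensus DE calls: {n_consensus}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outdir
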