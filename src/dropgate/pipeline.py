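"""End-to-end orchestration: cohort -> dots -> gates -> null -> motifs.

This module wires the stages together for the CLI, the test suite and the
reproduction script; all science lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gating, motif, preprocess, recurrence_stats
from .gating import GateParams, GateSpec, RecurrenceTable
from .synthetic import CohortConfig, CohortData, simulate_cohort

__all__ = ["AnalysisParams", "AnalysisResult", "run_analysis", "run_motif_stage"]


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the downstream analysis (gating, null, motif search)."""

    gate_params: GateParams = GateParams()
    min_count: int = 2
    frequent_threshold: int = 20
    top_k: int = 15
    null_iterations: int = 100
    motif_widths: tuple[int, ...] = (8, 10, 12, 15)
    motif_n_starts: int = 3
    motif_n_iter: int = 25
    motif_tol: float = 1e-3
    motif_shuffles: int = 100
    motif_n_motifs: int = 2
    enrichment_k: int = 10
    tail_window: int = 350
    seed: int = 0


@dataclass
class AnalysisResult:
    dots: pd.DataFrame
    bulk_qn: pd.DataFrame
    pseudo: pd.DataFrame
    correlations: pd.DataFrame
    correlation_summary: dict
    gates: list[GateSpec]
    tables: dict[str, RecurrenceTable]
    recurrent: dict[str, set]
    frequent: dict[str, set]
    top: dict[str, list[tuple[str, int]]]
    null: recurrence_stats.NullSummary | None = None
    motifs: dict[str, list[motif.MotifModel]] = field(default_factory=dict)
    enrichment: dict[str, dict] = field(default_factory=dict)


def run_analysis(
    data: CohortData,
    params: AnalysisParams = AnalysisParams(),
    gates: list[GateSpec] | None = None,
    with_null: bool = True,
) -> AnalysisResult:
    """Preprocess, gate and (optionally) run the random-pairing null."""
    dots, bulk_qn, pseudo = preprocess.preprocess_cohort(
        data.bulk, data.sample_to_dataset, data.sc, data.manifest
    )
    correlations, summary = preprocess.pair_correlations(dots)
    if gates is None:
        gates = gating.auto_gates(dots, params.gate_params)
    tables = {g.name: gating.recurrence(dots, g) for g in gates}
    recurrent = {
        name: gating.recurrent_genes(t, params.min_count) for name, t in tables.items()
    }
    frequent = {
        name: set(t.counts.index[t.counts >= params.frequent_threshold])
        for name, t in tables.items()
    }
    top = {name: gating.top_frequent(t, params.top_k) for name, t in tables.items()}

    null = None
    if with_null:
        null = recurrence_stats.null_run(
            pseudo, bulk_qn, data.manifest, gates, frequent,
            n_iter=params.null_iterations,
            seed=int(np.random.default_rng([params.seed, 7]).integers(2**31)),
            min_count=params.min_count,
            frequent_threshold=params.frequent_threshold,
        )
    return AnalysisResult(
        dots=dots, bulk_qn=bulk_qn, pseudo=pseudo,
        correlations=correlations, correlation_summary=summary,
        gates=gates, tables=tables, recurrent=recurrent,
        frequent=frequent, top=top, null=null,
    )


def run_motif_stage(
    result: AnalysisResult,
    sequences: dict,
    params: AnalysisParams = AnalysisParams(),
    gate_names: tuple[str, ...] = ("upper_left", "upper_right"),
) -> AnalysisResult:
    """Motif discovery and poly(T)-run enrichment on gate-derived gene sets.

    For each requested gate, the 3' tails of its recurrent genes are scanned
    for motifs, and the tails are tested for long T-run enrichment against
    the tails of all non-recurrent genes.
    """
    all_tails = motif.extract_tails(sequences, window=params.tail_window)
    for gate_idx, name in enumerate(gate_names):
        genes = result.recurrent.get(name, set())
        if not genes:
            result.motifs[name] = []
            result.enrichment[name] = {}
            continue
        target = {g: all_tails.tails[g] for g in sorted(genes) if g in all_tails.tails}
        background = {
            g: s for g, s in all_tails.tails.items() if g not in genes
        }
        result.motifs[name] = motif.find_motifs(
            target,
            widths=params.motif_widths,
            n_motifs=params.motif_n_motifs,
            n_starts=params.motif_n_starts,
            n_iter=params.motif_n_iter,
            tol=params.motif_tol,
            n_shuffles=params.motif_shuffles,
            seed=int(np.random.default_rng([params.seed, 11, gate_idx]).integers(2**31)),
        )
        result.enrichment[name] = motif.run_enrichment(
            target, background, base="T", k=params.enrichment_k
        )
    return result
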