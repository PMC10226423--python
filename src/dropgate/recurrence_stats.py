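"""Null models and summary statistics for gate recurrence.

Two nulls are implemented.  The occupancy expectation
(:func:`expected_recurrent`) asks how many distinct genes would land in a
gate at least twice if the gate's dots were assigned to genes uniformly at
random; the closed form is exact for a multinomial occupancy model and is
cross-checked against a Monte-Carlo oracle.  The random-pairing null
(:func:`null_run`) re-pairs each bulk profile with the pseudo-bulk of a
*different* sample — a uniform derangement — and re-runs the gating with the
gate polygons frozen from the observed analysis, quantifying how much of the
observed recurrence survives when the biological pairing is destroyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import GateSpec

logger = logging.getLogger(__name__)

__all__ = [
    "expected_recurrent",
    "monte_carlo_recurrent",
    "sample_derangement",
    "percent_frequent",
    "iou",
    "null_run",
    "NullSummary",
]


def expected_recurrent(n_genes: int, n_dots: int) -> float:
    """Expected number of genes hit >= 2 times by uniform random dots.

    With D dots over N genes, each gene's hit count is Binomial(D, 1/N);
    E[#genes with >= 2 hits] = N * [1 - (1-1/N)^D - (D/N)(1-1/N)^(D-1)].
    """
    N, D = int(n_genes), int(n_dots)
    if N < 1:
        raise ValueError("n_genes must be >= 1")
    if D < 0:
        raise ValueError("n_dots must be >= 0")
    if D < 2:
        return 0.0
    if N == 1:
        return 1.0
    q = 1.0 - 1.0 / N
    return N * (1.0 - q**D - (D / N) * q ** (D - 1))


def monte_carlo_recurrent(n_genes: int, n_dots: int, n_reps: int = 200,
                          rng=None) -> tuple[float, float]:
    """Monte-Carlo oracle for :func:`expected_recurrent`.

    Assigns ``n_dots`` dots uniformly to ``n_genes`` genes and counts genes
    hit at least twice; returns (mean, standard error) over ``n_reps``.
    """
    rng = np.random.default_rng(rng)
    stats = np.empty(n_reps)
    for r in range(n_reps):
        hits = np.bincount(rng.integers(0, n_genes, size=n_dots), minlength=n_genes)
        stats[r] = np.count_nonzero(hits >= 2)
    return float(stats.mean()), float(stats.std(ddof=1) / np.sqrt(n_reps))


def sample_derangement(n: int, rng) -> np.ndarray:
    """Uniform fixed-point-free permutation of range(n) by rejection sampling."""
    if n < 2:
        raise ValueError("a derangement requires n >= 2")
    rng = np.random.default_rng(rng)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def percent_frequent(table, threshold: int = 20) -> float:
    """100 * |genes with count >= threshold| / |genes with count >= 1|.

    ``table`` is a RecurrenceTable or a gene -> count Series/mapping.
    """
    counts = table.counts if hasattr(table, "counts") else pd.Series(table)
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = counts[counts >= 1]
    if len(counts) == 0:
        raise ValueError("empty recurrence table")
    return 100.0 * float((counts >= threshold).sum()) / float(len(counts))


def iou(set_a, set_b) -> float:
    """Intersection-over-union of two gene sets; two empty sets give 1.0."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        logger.info("iou: both sets empty, returning 1.0")
        return 1.0
    return len(a & b) / len(a | b)


def _membership_counts(X: np.ndarray, Y: np.ndarray, gate: GateSpec) -> np.ndarray:
    """Per-gene number of pairs inside ``gate`` for aligned (genes x pairs)
    pseudo-bulk (X) and bulk (Y) value matrices."""
    inside = gate.contains(X.ravel(), Y.ravel()).reshape(X.shape)
    return inside.sum(axis=1)


def _pearson_columns(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (Yc**2).sum(axis=0))
    return (Xc * Yc).sum(axis=0) / denom


@dataclass
class NullSummary:
    """Per-iteration random-pairing statistics plus their aggregates.

    ``per_iteration`` has one row per derangement with, per gate, the number
    of unique recurrent genes, the percent of unique genes occurring at or
    above the frequent threshold, and the IoU of the frequent set against
    the observed frequent set; plus the iteration's mean per-pair Pearson r.
    ``aggregate`` maps each of those columns to (mean, sd).
    """

    per_iteration: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    n_iterations: int
    seed: int
    child_seeds: list[int]


def null_run(
    pseudo: pd.DataFrame,
    bulk_qn: pd.DataFrame,
    manifest: pd.DataFrame,
    gates: list[GateSpec],
    observed_frequent: dict[str, set],
    n_iter: int = 100,
    seed: int = 0,
    min_count: int = 2,
    frequent_threshold: int = 20,
) -> NullSummary:
    """Random-pairing null: derangements of the sample pairing.

    The preprocessed matrices are re-joined under a fresh uniform derangement
    per iteration (bulk sample i vs pseudo-bulk of sample pi(i), pi(i) != i);
    gate polygons are frozen from the observed analysis.  No re-normalization
    is needed: size factors, log transform and quantile normalization do not
    depend on the pairing.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not bulk_qn.index.equals(pseudo.index):
        raise ValueError("matrices must share the gene axis")
    Y = bulk_qn[manifest["bulk_sample"]].to_numpy()
    X_all = pseudo[manifest["sc_sample"]].to_numpy()
    n_pairs = Y.shape[1]
    genes = bulk_qn.index.to_numpy()

    master = np.random.default_rng(seed)
    child_seeds = [int(s) for s in master.integers(0, 2**31, size=n_iter)]

    rows = []
    for it, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        perm = sample_derangement(n_pairs, rng)
        X = X_all[:, perm]
        row = {"iteration": it, "seed": child,
               "pearson_mean": float(_pearson_columns(X, Y).mean())}
        for gate in gates:
            counts = _membership_counts(X, Y, gate)
            occurring = counts >= 1
            n_occ = int(occurring.sum())
            n_freq = int((counts >= frequent_threshold).sum())
            freq_set = set(genes[counts >= frequent_threshold])
            row[f"{gate.name}_recurrent"] = int((counts >= min_count).sum())
            row[f"{gate.name}_percent_frequent"] = (
                100.0 * n_freq / n_occ if n_occ else 0.0
            )
            row[f"{gate.name}_iou"] = iou(freq_set, observed_frequent.get(gate.name, set()))
        rows.append(row)

    per_iter = pd.DataFrame(rows)
    aggregate = {
        col: (float(per_iter[col].mean()), float(per_iter[col].std(ddof=1)))
        for col in per_iter.columns
        if col not in ("iteration", "seed")
    }
    return NullSummary(
        per_iteration=per_iter,
        aggregate=aggregate,
        n_iterations=n_iter,
        seed=seed,
        child_seeds=child_seeds,
    )
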