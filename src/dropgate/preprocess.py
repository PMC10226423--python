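"""Normalization of bulk and single-cell counts into the paired dot table.

Bulk counts are normalized per dataset with median-of-ratios size factors,
log-transformed (natural log, +1 offset), restricted to the genes shared by
every modality and sample, and quantile-normalized jointly across all
samples.  Single-cell counts are library-size normalized (scale factor 1e4),
log-transformed, and averaged across cells into a pseudo-bulk profile per
sample.  Joining the two on the pairing manifest yields one dot per
(gene, sample pair): x = pseudo-bulk log expression, y = quantile-normalized
bulk log expression.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "lognorm_bulk",
    "pseudo_bulk",
    "intersect_genes",
    "quantile_normalize",
    "build_dots",
    "pair_correlations",
    "preprocess_cohort",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    Reference genes are the rows with no zero count; for each sample the
    factor is the median over reference genes of count / geometric-mean
    across samples.  Raises if no gene is positive in every sample.
    """
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative counts")
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "filter genes or samples before computing size factors"
        )
    logs = np.log(vals[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def lognorm_bulk(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """ln(1 + count / size_factor), per sample."""
    if np.any(factors.to_numpy() <= 0):
        raise ValueError("size factors must be positive")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative counts")
    out = np.log1p(vals / factors.reindex(counts.columns).to_numpy()[None, :])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def pseudo_bulk(cell_counts: pd.DataFrame, scale: float = 1e4) -> pd.Series:
    """Average library-size-normalized log expression across cells.

    Per cell c: v(g, c) = ln(1 + scale * count(g, c) / libsize(c)); the
    pseudo-bulk value of gene g is the mean of v(g, .) over cells.  Cells
    with zero total count are dropped with a warning.
    """
    if cell_counts.size == 0:
        raise ValueError("empty cell count matrix")
    vals = cell_counts.to_numpy(dtype=float)
    lib = vals.sum(axis=0)
    keep = lib > 0
    if not keep.any():
        raise ValueError("all cells have zero library size")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} cells with zero library size",
            stacklevel=2,
        )
        vals, lib = vals[:, keep], lib[keep]
    v = np.log1p(scale * vals / lib[None, :])
    return pd.Series(v.mean(axis=1), index=cell_counts.index, name="pseudo_bulk")


def intersect_genes(bulk: pd.DataFrame, pseudo: pd.DataFrame):
    """Restrict both matrices to their common genes, in a common order."""
    common = bulk.index.intersection(pseudo.index).sort_values()
    if len(common) == 0:
        raise ValueError("no genes shared between bulk and pseudo-bulk")
    dropped = (len(bulk.index) - len(common)) + (len(pseudo.index) - len(common))
    if dropped:
        logger.info("intersect_genes: dropped %d non-shared gene rows", dropped)
    return bulk.loc[common], pseudo.loc[common]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference.

    After normalization each column's sorted values equal the across-column
    mean of sorted columns; ties within a column receive the mean of the
    reference values over their rank span.  The map is deterministic, and
    idempotent whenever columns are tie-free (tied spans keep their group
    mean, which can differ across columns).  A single-column input is
    returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returning unchanged",
                      stacklevel=2)
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        sv = sorted_vals[:, j]
        starts = np.r_[0, np.nonzero(np.diff(sv))[0] + 1]
        lens = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(ref, starts) / lens
        out[order[:, j], j] = np.repeat(group_means, lens)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def build_dots(bulk_qn: pd.DataFrame, pseudo_all: pd.DataFrame,
               manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per (gene, sample pair): gene_id, pair_id, x, y.

    ``bulk_qn`` and ``pseudo_all`` must share the same gene axis; every bulk
    and single-cell sample referenced by the manifest must be present, and
    every column of both matrices must be paired.
    """
    if not bulk_qn.index.equals(pseudo_all.index):
        raise ValueError("bulk and pseudo-bulk matrices must share the gene axis")
    unpaired = (set(bulk_qn.columns) - set(manifest["bulk_sample"])) | (
        set(pseudo_all.columns) - set(manifest["sc_sample"])
    )
    if unpaired:
        raise ValueError(f"unpaired samples: {sorted(unpaired)}")
    missing = (set(manifest["bulk_sample"]) - set(bulk_qn.columns)) | (
        set(manifest["sc_sample"]) - set(pseudo_all.columns)
    )
    if missing:
        raise ValueError(f"manifest references absent samples: {sorted(missing)}")

    frames = []
    for _, row in manifest.iterrows():
        pair_id = f"{row['bulk_sample']}|{row['sc_sample']}"
        frames.append(pd.DataFrame({
            "gene_id": bulk_qn.index,
            "pair_id": pair_id,
            "x": pseudo_all[row["sc_sample"]].to_numpy(),
            "y": bulk_qn[row["bulk_sample"]].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def pair_correlations(dots: pd.DataFrame):
    """Per-pair Pearson r and Spearman rho, plus mean +/- sd across pairs.

    Pairs with a zero-variance axis are flagged and excluded from the
    summary with a warning.
    """
    from scipy.stats import pearsonr, spearmanr

    rows, flagged = [], []
    for pair_id, grp in dots.groupby("pair_id", sort=True):
        x, y = grp["x"].to_numpy(), grp["y"].to_numpy()
        if len(x) < 3:
            raise ValueError(f"pair {pair_id} has fewer than 3 genes")
        if np.std(x) == 0 or np.std(y) == 0:
            flagged.append(pair_id)
            continue
        rows.append({
            "pair_id": pair_id,
            "pearson_r": pearsonr(x, y).statistic,
            "spearman_rho": spearmanr(x, y).statistic,
        })
    if flagged:
        warnings.warn(
            f"excluded zero-variance pairs from summary: {flagged}", stacklevel=2
        )
    per_pair = pd.DataFrame(rows)
    summary = {
        "pearson_mean": float(per_pair["pearson_r"].mean()),
        "pearson_sd": float(per_pair["pearson_r"].std(ddof=1)),
        "spearman_mean": float(per_pair["spearman_rho"].mean()),
        "spearman_sd": float(per_pair["spearman_rho"].std(ddof=1)),
        "n_pairs": len(per_pair),
        "flagged_pairs": flagged,
    }
    return per_pair, summary


def preprocess_cohort(bulk: pd.DataFrame, sample_to_dataset: dict,
                      sc: dict, manifest: pd.DataFrame, scale: float = 1e4):
    """Full preprocessing of one cohort into the paired dot table.

    Size factors are computed within each bulk dataset, the gene axis is the
    joint intersection across bulk and every single-cell sample, and quantile
    normalization is applied to the bulk matrix across all samples jointly.
    Returns (dots, bulk_qn, pseudo_matrix).
    """
    pieces = []
    by_dataset: dict[str, list[str]] = {}
    for s in bulk.columns:
        ds = sample_to_dataset.get(s)
        if ds is None:
            raise ValueError(f"bulk sample {s!r} has no dataset assignment")
        by_dataset.setdefault(ds, []).append(s)
    for ds, samples in by_dataset.items():
        sub = bulk[samples]
        pieces.append(lognorm_bulk(sub, size_factors(sub)))
    bulk_log = pd.concat(pieces, axis=1)[bulk.columns]

    pseudo = pd.DataFrame({sid: pseudo_bulk(mat, scale=scale) for sid, mat in sc.items()})

    bulk_log, pseudo = intersect_genes(bulk_log, pseudo)
    bulk_qn = quantile_normalize(bulk_log)
    dots = build_dots(bulk_qn, pseudo, manifest)
    return dots, bulk_qn, pseudo
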