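"""Readers for the on-disk cohort bundle (TSV / MatrixMarket / FASTA)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_bulk_tsv(path) -> pd.DataFrame:
    """Bulk count table: genes x samples, first column gene_id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty bulk count table: {path}")
    return df


def read_mtx_sample(sample_dir) -> pd.DataFrame:
    """One sample's gene x cell counts from matrix.mtx + genes.tsv + barcodes.tsv."""
    from scipy.io import mmread

    d = Path(sample_dir)
    mat = mmread(str(d / "matrix.mtx")).toarray()
    genes = (d / "genes.tsv").read_text().splitlines()
    cells = (d / "barcodes.tsv").read_text().splitlines()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(f"label/matrix shape mismatch in {d}")
    return pd.DataFrame(mat, index=genes, columns=cells)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"bulk_sample", "sc_sample", "dataset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def read_transcripts_fasta(path) -> dict[str, list[tuple[str, str]]]:
    """FASTA with ``gene_id|transcript_id`` headers -> gene -> [(tx, seq)]."""
    from Bio import SeqIO

    out: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, _, tx_id = rec.id.partition("|")
        out.setdefault(gene_id, []).append((tx_id or rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no records in FASTA: {path}")
    return out


def read_cohort(cohort_dir):
    """Load a written cohort bundle back into memory.

    Returns (bulk DataFrame, sc dict sample->DataFrame, manifest DataFrame,
    sequences dict).  The single-cell samples are discovered from the
    manifest's ``sc_sample`` column.
    """
    d = Path(cohort_dir)
    manifest = read_manifest(d / "manifest.tsv")
    bulk = read_bulk_tsv(d / "bulk_counts.tsv")
    sc = {sid: read_mtx_sample(d / "sc" / sid) for sid in manifest["sc_sample"]}
    seqs = read_transcripts_fasta(d / "transcripts.fasta")
    return bulk, sc, manifest, seqs
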