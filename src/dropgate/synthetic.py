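"""Synthetic paired bulk / single-cell cohorts with a planted capture defect.

The generator emulates the structure of a multi-study compendium of paired
bulk RNA-seq and scRNA-seq samples: several bulk "datasets" (batches) with
dataset-level sequencing-scale effects, one scRNA-seq count matrix per
sample, and per-gene transcript sequences.  A configurable fraction of genes
carries a contiguous poly(T) run within the terminal window of its longest
transcript; those genes are given a reduced single-cell capture efficiency

    capture(g) = exp(-beta * max(0, max_T_run_tail(g) - r0))

so the cohort contains a known ground-truth set of genes under-detected in
the single-cell modality but not in bulk.  Every stage of the downstream
analysis (normalization, gating, recurrence statistics, motif discovery)
can therefore be validated against the planted truth without any external
download.

Counts are Poisson by design so closed-form expectations stay exact, and
every random draw flows from one master seed through per-(stage, sample)
streams, so adding samples never shifts earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motif import max_run

_BASES = np.array(list("ACGT"))

# RNG stream tags (stage component of the per-(stage, sample) stream key)
_SEQ, _BASEEXPR, _SCALE, _EFFECT, _BULK, _SC = range(6)

#: Uneven per-dataset sample counts typical of a multi-study compendium
#: (used when n_datasets=8 and n_samples=53; otherwise samples are split
#: round-robin).
DEFAULT_DATASET_SIZES = (15, 3, 24, 4, 2, 1, 2, 2)

__all__ = [
    "CohortConfig",
    "GeneRecord",
    "CohortTruth",
    "gen_transcriptome",
    "build_truth",
    "gen_bulk_counts",
    "gen_sc_counts",
    "gen_cohort",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a compendium of 53 paired samples drawn from 8 bulk
    datasets.  ``capture_beta`` and ``planted_run_length_range`` together
    set the strength of the planted under-detection (see module docstring);
    ``sample_effect_sigma`` is the per-(gene, sample) lognormal biology
    shared between a sample's bulk and single-cell rates, which is what
    makes true pairings more correlated than random re-pairings.
    """

    n_genes: int = 2000
    n_datasets: int = 8
    n_samples: int = 53
    cells_per_sample: int = 200
    frac_planted: float = 0.05
    tail_window: int = 350
    planted_run_length_range: tuple[int, int] = (15, 30)
    capture_beta: float = 0.4
    capture_run_offset: int = 8
    bulk_depth: float = 1e6
    sc_depth_per_cell: float = 5000.0
    base_log_mean: float = 0.0
    base_log_sigma: float = 1.5
    dataset_scale_sigma: float = 0.4
    sample_effect_sigma: float = 0.5
    transcript_length_range: tuple[int, int] = (500, 3000)
    max_transcripts_per_gene: int = 3
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_genes", self.n_genes >= 1),
            ("n_datasets", self.n_datasets >= 1),
            ("n_samples", self.n_samples >= 2),
            ("cells_per_sample", self.cells_per_sample >= 1),
            ("frac_planted", 0.0 <= self.frac_planted <= 1.0),
            ("tail_window", self.tail_window >= 1),
            ("planted_run_length_range",
             2 <= self.planted_run_length_range[0] <= self.planted_run_length_range[1]),
            ("capture_beta", self.capture_beta >= 0.0),
            ("capture_run_offset", self.capture_run_offset >= 0),
            ("bulk_depth", self.bulk_depth > 0),
            ("sc_depth_per_cell", self.sc_depth_per_cell > 0),
            ("base_log_sigma", self.base_log_sigma >= 0),
            ("dataset_scale_sigma", self.dataset_scale_sigma >= 0),
            ("sample_effect_sigma", self.sample_effect_sigma >= 0),
            ("transcript_length_range",
             60 <= self.transcript_length_range[0] <= self.transcript_length_range[1]),
            ("max_transcripts_per_gene", self.max_transcripts_per_gene >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid CohortConfig field: {name}")
        if self.planted_run_length_range[1] > self.tail_window:
            raise ValueError("invalid CohortConfig field: planted_run_length_range")

    @property
    def n_planted(self) -> int:
        return round(self.frac_planted * self.n_genes)

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def dataset_sizes(self) -> list[int]:
        if (self.n_datasets, self.n_samples) == (8, 53):
            return list(DEFAULT_DATASET_SIZES)
        base, extra = divmod(self.n_samples, self.n_datasets)
        return [base + (1 if i < extra else 0) for i in range(self.n_datasets)]

    def sample_to_dataset(self) -> dict[str, str]:
        mapping, i = {}, 0
        for d, size in enumerate(self.dataset_sizes()):
            for _ in range(size):
                mapping[self.sample_ids()[i]] = f"DS{d + 1}"
                i += 1
        return mapping


@dataclass
class GeneRecord:
    """One gene's transcripts plus its planted-defect annotation."""

    gene_id: str
    transcripts: list[tuple[str, str]]
    planted_flag: bool
    max_t_run_tail: int


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort, for parameter-recovery testing."""

    under_detected_genes: set[str]
    capture_efficiency: dict[str, float]
    dataset_scale: dict[str, float]
    base_expression: dict[str, float]
    seed: int

    def to_json(self, path):
        payload = {
            "under_detected_genes": sorted(self.under_detected_genes),
            "capture_efficiency": self.capture_efficiency,
            "dataset_scale": self.dataset_scale,
            "base_expression": self.base_expression,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(
            under_detected_genes=set(d["under_detected_genes"]),
            capture_efficiency=d["capture_efficiency"],
            dataset_scale=d["dataset_scale"],
            base_expression=d["base_expression"],
            seed=d["seed"],
        )


def gen_transcriptome(config: CohortConfig):
    """Generate transcripts with poly(T) runs planted in a random gene subset.

    Background composition is i.i.d. uniform over ACGT.  Exactly
    ``round(frac_planted * n_genes)`` genes get a contiguous T-run (length
    uniform in ``planted_run_length_range``) written into the last
    ``tail_window`` nt of their longest transcript.  Deterministic given the
    config seed.  Returns (records, planted_gene_ids).
    """
    rng = _rng(config.seed, _SEQ)
    lo, hi = config.transcript_length_range
    run_lo, run_hi = config.planted_run_length_range
    planted_idx = set(
        rng.choice(config.n_genes, size=config.n_planted, replace=False).tolist()
    )

    records: list[GeneRecord] = []
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:05d}"
        n_tx = int(rng.integers(1, config.max_transcripts_per_gene + 1))
        txs = []
        for t in range(n_tx):
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(_BASES[rng.integers(0, 4, size=L)])
            txs.append([f"{gene_id}.t{t + 1}", seq])
        # longest transcript carries the planted run; ties by transcript id
        longest = max(range(n_tx), key=lambda j: (len(txs[j][1]), txs[j][0]))
        planted = i in planted_idx
        if planted:
            tid, seq = txs[longest]
            L = len(seq)
            run_len = int(rng.integers(run_lo, run_hi + 1))
            win_start = max(0, L - config.tail_window)
            start = int(rng.integers(win_start, L - run_len + 1))
            seq = seq[:start] + "T" * run_len + seq[start + run_len:]
            txs[longest] = [tid, seq]
        tid, seq = txs[longest]
        tail = seq[-min(config.tail_window, len(seq)):]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                transcripts=[tuple(t) for t in txs],
                planted_flag=planted,
                max_t_run_tail=max_run(tail, "T"),
            )
        )
    planted_ids = {r.gene_id for r in records if r.planted_flag}
    return records, planted_ids


def build_truth(records: list[GeneRecord], config: CohortConfig) -> CohortTruth:
    """Sample base expression and dataset scales; derive capture efficiencies."""
    rng_e = _rng(config.seed, _BASEEXPR)
    base = rng_e.lognormal(config.base_log_mean, config.base_log_sigma,
                           size=len(records))
    rng_s = _rng(config.seed, _SCALE)
    scales = rng_s.lognormal(0.0, config.dataset_scale_sigma,
                             size=config.n_datasets)
    capture = {
        r.gene_id: float(
            np.exp(-config.capture_beta
                   * max(0, r.max_t_run_tail - config.capture_run_offset))
        )
        for r in records
    }
    return CohortTruth(
        under_detected_genes={r.gene_id for r in records if r.planted_flag},
        capture_efficiency=capture,
        dataset_scale={f"DS{d + 1}": float(scales[d]) for d in range(config.n_datasets)},
        base_expression={r.gene_id: float(base[i]) for i, r in enumerate(records)},
        seed=config.seed,
    )


def _sample_effects(config: CohortConfig, sample_index: int, n_genes: int) -> np.ndarray:
    """Per-gene lognormal expression effect of one sample, shared between the
    sample's bulk and single-cell rates (the matched-pair biological signal)."""
    eps = _rng(config.seed, _EFFECT, sample_index).standard_normal(n_genes)
    return np.exp(config.sample_effect_sigma * eps)


def _expression(records, truth, config, sample_index):
    try:
        base = np.array([truth.base_expression[r.gene_id] for r in records])
    except KeyError as e:
        raise ValueError(f"missing base expression for gene {e.args[0]}") from None
    return base * _sample_effects(config, sample_index, len(records))


def gen_bulk_counts(records, truth: CohortTruth, config: CohortConfig):
    """Poisson bulk counts, genes x samples, plus the sample->dataset map.

    count(g, s) ~ Poisson(bulk_depth * dataset_scale[d(s)] * expr(g, s) / sum_g expr).
    Capture efficiency plays no role in bulk.
    """
    sample_ids = config.sample_ids()
    s2d = config.sample_to_dataset()
    cols = {}
    for s, sid in enumerate(sample_ids):
        expr = _expression(records, truth, config, s)
        rate = config.bulk_depth * truth.dataset_scale[s2d[sid]] * expr / expr.sum()
        cols[sid] = _rng(config.seed, _BULK, s).poisson(rate)
    counts = pd.DataFrame(cols, index=[r.gene_id for r in records])
    return counts, s2d


def gen_sc_counts(records, truth: CohortTruth, config: CohortConfig, sample_id: str):
    """Poisson single-cell counts (genes x cells) for one sample.

    count(g, c) ~ Poisson(sc_depth_per_cell * capture(g) * expr(g, s) / sum_g capture * expr),
    so genes carrying long 3' poly(T) runs are depleted relative to bulk.
    """
    sample_ids = config.sample_ids()
    if sample_id not in sample_ids:
        raise ValueError(f"unknown sample_id: {sample_id!r}")
    s = sample_ids.index(sample_id)
    expr = _expression(records, truth, config, s)
    capture = np.array([truth.capture_efficiency[r.gene_id] for r in records])
    weighted = capture * expr
    q = weighted / weighted.sum()
    rng = _rng(config.seed, _SC, s)
    counts = rng.poisson(
        config.sc_depth_per_cell * q[:, None],
        size=(len(records), config.cells_per_sample),
    )
    cells = [f"{sample_id}_c{j + 1:04d}" for j in range(config.cells_per_sample)]
    return pd.DataFrame(counts, index=[r.gene_id for r in records], columns=cells)


def build_manifest(config: CohortConfig) -> pd.DataFrame:
    s2d = config.sample_to_dataset()
    return pd.DataFrame(
        {
            "bulk_sample": config.sample_ids(),
            "sc_sample": config.sample_ids(),
            "dataset": [s2d[s] for s in config.sample_ids()],
        }
    )


@dataclass
class CohortData:
    """An in-memory cohort: the bundle gen_cohort writes, minus the files."""

    config: CohortConfig
    records: list[GeneRecord]
    truth: CohortTruth
    bulk: pd.DataFrame
    sample_to_dataset: dict[str, str]
    sc: dict[str, pd.DataFrame]
    manifest: pd.DataFrame

    @property
    def sequences(self) -> dict[str, list[tuple[str, str]]]:
        return {r.gene_id: list(r.transcripts) for r in self.records}


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate a full cohort in memory (transcriptome, truth, bulk, sc)."""
    records, _ = gen_transcriptome(config)
    truth = build_truth(records, config)
    bulk, s2d = gen_bulk_counts(records, truth, config)
    sc = {sid: gen_sc_counts(records, truth, config, sid) for sid in config.sample_ids()}
    return CohortData(
        config=config,
        records=records,
        truth=truth,
        bulk=bulk,
        sample_to_dataset=s2d,
        sc=sc,
        manifest=build_manifest(config),
    )


def gen_cohort(config: CohortConfig, outdir) -> dict[str, Path]:
    """Write a cohort bundle to ``outdir``.

    Layout: transcripts.fasta (headers ``gene|transcript``), bulk_counts.tsv
    (genes x samples), sc/<sample>/{matrix.mtx,genes.tsv,barcodes.tsv},
    manifest.tsv (bulk_sample, sc_sample, dataset), truth.json.  Files
    round-trip through :mod:`dropgate.io`.
    """
    from scipy import sparse
    from scipy.io import mmwrite

    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e

    data = simulate_cohort(config)
    paths = {}

    fasta = out / "transcripts.fasta"
    with fasta.open("w") as fh:
        for r in data.records:
            for tid, seq in r.transcripts:
                fh.write(f">{r.gene_id}|{tid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    paths["fasta"] = fasta

    bulk_path = out / "bulk_counts.tsv"
    data.bulk.rename_axis("gene_id").to_csv(bulk_path, sep="\t")
    paths["bulk"] = bulk_path

    sc_root = out / "sc"
    for sid, mat in data.sc.items():
        d = sc_root / sid
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(str(d / "matrix.mtx"), sparse.csr_matrix(mat.to_numpy()))
        (d / "genes.tsv").write_text("\n".join(mat.index) + "\n")
        (d / "barcodes.tsv").write_text("\n".join(mat.columns) + "\n")
    paths["sc"] = sc_root

    manifest_path = out / "manifest.tsv"
    data.manifest.to_csv(manifest_path, sep="\t", index=False)
    paths["manifest"] = manifest_path

    truth_path = out / "truth.json"
    data.truth.to_json(truth_path)
    paths["truth"] = truth_path

    config_path = out / "cohort_config.json"
    config_path.write_text(json.dumps(asdict(config), indent=1))
    paths["config"] = config_path
    return paths
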