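"""3' transcript-tail motif analysis.

Genes flagged as consistently under-detected in scRNA-seq are tested for
shared sequence features near the transcript 3' end, where oligo-dT capture
acts.  Two complementary routes are provided:

* homopolymer-run statistics (:func:`max_run`, :func:`run_enrichment`): a
  direct hypergeometric test for an excess of long poly(T) (or other base)
  runs in a target tail set versus a background tail set;
* a simplified motif finder (:func:`em_motif`, :func:`find_motifs`): EM on
  the ZOOPS likelihood ("zero or one occurrence per sequence") with a
  0-order background estimated from the input, per-position information
  content in bits, and an empirical significance value calibrated by
  refitting on per-sequence shuffles (composition- and length-preserving).

The significance value plays the role of a motif E-value: an empirical
shuffle p-value Bonferroni-adjusted across the motif widths scanned, to be
compared against 0.05.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

__all__ = [
    "TailSet",
    "MotifModel",
    "extract_tails",
    "max_run",
    "run_enrichment",
    "em_motif",
    "find_motifs",
    "motif_significance",
    "pwm_bits",
    "conserved_block",
]


# ---------------------------------------------------------------------------
# tail extraction and run statistics
# ---------------------------------------------------------------------------


@dataclass
class TailSet:
    """Terminal 3' windows of the longest transcript per gene.

    ``tails`` maps gene_id -> uppercase ACGTN string of length <= window;
    ``provenance`` maps gene_id -> (transcript_id, original_length);
    ``skipped`` lists requested genes with no sequence available.
    """

    tails: dict[str, str]
    provenance: dict[str, tuple[str, int]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    window: int = 350

    def __len__(self) -> int:
        return len(self.tails)


def _iter_fasta(path):
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            gene_id, tx_id = rec.id.split("|", 1)
        else:
            gene_id, tx_id = rec.id, rec.id
        yield gene_id, tx_id, str(rec.seq).upper()


def extract_tails(source, gene_set=None, window: int = 350) -> TailSet:
    """Extract the last ``window`` nt of each gene's longest transcript.

    ``source`` is either a FASTA path (headers ``gene_id|transcript_id``) or a
    mapping gene_id -> list of (transcript_id, sequence).  Ties on transcript
    length are broken by lexicographically smallest transcript_id.  Genes in
    ``gene_set`` with no sequence are recorded in ``skipped`` rather than
    raising.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if isinstance(source, dict):
        records = (
            (g, t, s.upper()) for g, txs in source.items() for t, s in txs
        )
    else:
        records = _iter_fasta(source)

    best: dict[str, tuple[int, str, str]] = {}
    for gene_id, tx_id, seq in records:
        if gene_set is not None and gene_id not in gene_set:
            continue
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"transcript {tx_id} has characters outside ACGTN")
        cur = best.get(gene_id)
        key = (len(seq), tx_id)
        # longest wins; on equal length the smaller transcript_id wins
        if cur is None or len(seq) > cur[0] or (len(seq) == cur[0] and tx_id < cur[1]):
            best[gene_id] = (len(seq), tx_id, seq)

    tails, prov = {}, {}
    for gene_id, (length, tx_id, seq) in best.items():
        tails[gene_id] = seq[-min(window, length):]
        prov[gene_id] = (tx_id, length)
    skipped = sorted(set(gene_set) - set(tails)) if gene_set is not None else []
    if skipped:
        logger.warning("extract_tails: %d requested genes had no sequence", len(skipped))
    return TailSet(tails=tails, provenance=prov, skipped=skipped, window=window)


def max_run(seq: str, base: str) -> int:
    """Length of the longest contiguous run of ``base`` in ``seq`` (0 if none)."""
    if not seq:
        return 0
    return max((m.end() - m.start() for m in re.finditer(f"{re.escape(base)}+", seq)), default=0)


def run_enrichment(target, background, base: str = "T", k: int = 10):
    """One-sided hypergeometric test for long ``base`` runs in target tails.

    ``target`` and ``background`` map gene_id -> tail sequence and must be
    disjoint (background = the non-target genes).  A gene is a "hit" when its
    tail carries a run of ``base`` of length >= ``k``.  Returns a dict with
    the 2x2 table, hit fractions, a Haldane-corrected odds ratio and the
    upper-tail hypergeometric p-value.
    """
    from scipy.stats import hypergeom

    if isinstance(target, TailSet):
        target = target.tails
    if isinstance(background, TailSet):
        background = background.tails
    if not target:
        raise ValueError("empty target tail set")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    overlap = set(target) & set(background)
    if overlap:
        raise ValueError(f"target and background overlap ({len(overlap)} genes)")

    t_hit = sum(max_run(s, base) >= k for s in target.values())
    b_hit = sum(max_run(s, base) >= k for s in background.values())
    n_t, n_b = len(target), len(background)
    M, K = n_t + n_b, t_hit + b_hit
    p = float(hypergeom.sf(t_hit - 1, M, K, n_t))
    a, b_, c, d = t_hit, n_t - t_hit, b_hit, n_b - b_hit
    if min(a, b_, c, d) == 0:
        a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
    return {
        "base": base,
        "k": k,
        "table": ((t_hit, n_t - t_hit), (b_hit, n_b - b_hit)),
        "target_fraction": t_hit / n_t,
        "background_fraction": b_hit / n_b if n_b else float("nan"),
        "odds_ratio": (a * d) / (b_ * c),
        "pvalue": p,
    }


# ---------------------------------------------------------------------------
# ZOOPS EM motif finder
# ---------------------------------------------------------------------------


@dataclass
class MotifModel:
    """A fitted ZOOPS motif.

    ``pwm`` is a (width x 4) row-stochastic matrix over ACGT; ``lam`` the
    fitted prior probability that a sequence carries a site; ``llr`` the
    log-likelihood ratio of the ZOOPS model over background-only; ``sites``
    lists (name, start, end) with 0-based half-open coordinates within each
    tail for sequences whose posterior site probability exceeds 0.5.
    ``significance`` (set by :func:`motif_significance` / :func:`find_motifs`)
    is the shuffle-calibrated value compared against 0.05.
    """

    width: int
    pwm: np.ndarray
    lam: float
    llr: float
    sites: list[tuple[str, int, int]]
    consensus: str
    background: np.ndarray
    n_widths_scanned: int = 1
    significance: float | None = None
    objective_history: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def bits(self) -> np.ndarray:
        return pwm_bits(self.pwm)


def _encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode sequences (A,C,G,T,N -> 0..4), right-padded with 4."""
    lengths = np.array([len(s) for s in seqs])
    L = int(lengths.max())
    X = np.full((len(seqs), L), 4, dtype=np.int8)
    for i, s in enumerate(seqs):
        X[i, : len(s)] = [_CODE[c] for c in s]
    return X, lengths


def _background_freqs(X: np.ndarray) -> np.ndarray:
    counts = np.bincount(X[X < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("sequences contain no A/C/G/T characters")
    freqs = counts / counts.sum()
    return np.clip(freqs, 1e-6, None) / np.clip(freqs, 1e-6, None).sum()


def _window_design(X: np.ndarray, lengths: np.ndarray, w: int):
    """One-hot window design matrix W (n*P, 4w) and valid-position mask (n, P).

    Ambiguous/padding positions (N) one-hot to all-zero rows, so they
    contribute nothing to either the motif or the background window score
    (missing data).  A position p is valid when the window fits inside the
    true sequence, p + w <= length.
    """
    n, L = X.shape
    P = L - w + 1
    onehot = np.zeros((n, L, 4))
    r, c = np.nonzero(X < 4)
    onehot[r, c, X[r, c]] = 1.0
    win = sliding_window_view(onehot, w, axis=1)  # (n, P, 4, w)
    W = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * P, 4 * w)
    valid = np.arange(P)[None, :] + w <= lengths[:, None]
    return W, valid


def _seed_pwms(X, lengths, w, n_starts, rng):
    """Initial PWMs built from randomly chosen data windows (MEME-style)."""
    n = X.shape[0]
    pwms = np.empty((n_starts, w, 4))
    for s in range(n_starts):
        i = int(rng.integers(0, n))
        p = int(rng.integers(0, lengths[i] - w + 1))
        pwm = np.full((w, 4), 0.15)
        window = X[i, p : p + w]
        for j, b in enumerate(window):
            if b < 4:
                pwm[j, b] = 0.55
            else:
                pwm[j] = 0.25
        pwms[s] = pwm / pwm.sum(axis=1, keepdims=True)
    return pwms


def _zoops_em(
    W, valid, bg, pwms, *, lam0=0.5, n_iter=100, tol=1e-6, alpha=1e-3
):
    """Batched ZOOPS EM over ``n_starts`` initial PWMs.

    Maximizes the penalized objective  LLR + alpha * sum(log pwm)  (EM for a
    Dirichlet(alpha+1) MAP estimate of the PWM rows), which is guaranteed
    non-decreasing across iterations.  Returns the best start's parameters,
    its unpenalized LLR, the site posteriors, and the objective history.
    """
    S, w, _ = pwms.shape
    n, P = valid.shape
    Pi = valid.sum(axis=1)
    if np.any(Pi < 1):
        raise ValueError("a sequence admits no valid motif window")
    lam = np.full(S, lam0)
    invalid = ~valid
    history = []
    prev = None
    log_bg = np.log(bg)

    for _ in range(n_iter):
        V = (np.log(pwms) - log_bg[None, None, :]).reshape(S, w * 4).T
        Sc = (W @ V).reshape(n, P, S)
        Sc[invalid] = -np.inf
        m = Sc.max(axis=1)  # (n, S); finite (valid windows score finitely)
        T = np.exp(Sc - m[:, None, :]).sum(axis=1)
        log_site = np.log(lam)[None, :] - np.log(Pi)[:, None] + m + np.log(T)
        tot = np.logaddexp(np.log1p(-lam)[None, :], log_site)
        obj = tot.sum(axis=0) + alpha * np.log(pwms).sum(axis=(1, 2))
        history.append(obj.copy())
        Q = np.exp(log_site - tot)  # (n, S) posterior P(site present)
        z = np.exp(Sc - m[:, None, :]) / T[:, None, :] * Q[:, None, :]
        counts = (W.T @ z.reshape(n * P, S)).T.reshape(S, w, 4)
        pwms = (counts + alpha) / (counts.sum(axis=2, keepdims=True) + 4 * alpha)
        lam = np.clip(Q.mean(axis=0), 1e-4, 1 - 1e-4)
        if prev is not None and np.max(obj - prev) < tol * max(1.0, np.max(np.abs(obj))):
            prev = obj
            break
        prev = obj

    # final scores/posteriors under the last parameters
    V = (np.log(pwms) - log_bg[None, None, :]).reshape(S, w * 4).T
    Sc = (W @ V).reshape(n, P, S)
    Sc[invalid] = -np.inf
    m = Sc.max(axis=1)
    T = np.exp(Sc - m[:, None, :]).sum(axis=1)
    log_site = np.log(lam)[None, :] - np.log(Pi)[:, None] + m + np.log(T)
    tot = np.logaddexp(np.log1p(-lam)[None, :], log_site)
    llr = tot.sum(axis=0)
    obj = llr + alpha * np.log(pwms).sum(axis=(1, 2))
    history.append(obj.copy())

    best = int(np.argmax(obj))
    Q = np.exp(log_site[:, best] - tot[:, best])
    pos = np.argmax(Sc[:, :, best], axis=1)
    hist = np.array([h[best] for h in history])
    return pwms[best], float(lam[best]), float(llr[best]), Q, pos, hist


def _consensus(pwm: np.ndarray) -> str:
    return "".join(ALPHABET[b] for b in pwm.argmax(axis=1))


def em_motif(
    seqs,
    w: int,
    n_starts: int = 50,
    n_iter: int = 100,
    seed: int = 0,
    lam0: float = 0.5,
    tol: float = 1e-6,
    rng=None,
) -> MotifModel:
    """Fit one ZOOPS motif of width ``w`` to a set of sequences.

    ``seqs`` is a mapping name -> sequence (or a list, auto-named).  EM is
    restarted from ``n_starts`` data-derived seeds and the start with the
    highest log-likelihood ratio wins; ties break to the earliest start, so
    results are deterministic given ``seed``.
    """
    if isinstance(seqs, dict):
        names, strings = list(seqs.keys()), [s.upper() for s in seqs.values()]
    else:
        strings = [s.upper() for s in seqs]
        names = [f"seq{i}" for i in range(len(strings))]
    if w < 4:
        raise ValueError(f"motif width must be >= 4, got {w}")
    for name, s in zip(names, strings):
        if len(s) < w:
            raise ValueError(f"sequence {name!r} is shorter than width {w}")
    if not strings:
        raise ValueError("no sequences supplied")

    rng = np.random.default_rng(seed) if rng is None else rng
    X, lengths = _encode(strings)
    bg = _background_freqs(X)
    W, valid = _window_design(X, lengths, w)
    pwms = _seed_pwms(X, lengths, w, n_starts, rng)
    pwm, lam, llr, Q, pos, hist = _zoops_em(
        W, valid, bg, pwms, lam0=lam0, n_iter=n_iter, tol=tol
    )
    sites = [
        (names[i], int(pos[i]), int(pos[i]) + w)
        for i in range(len(names))
        if Q[i] > 0.5
    ]
    return MotifModel(
        width=w,
        pwm=pwm,
        lam=lam,
        llr=llr,
        sites=sites,
        consensus=_consensus(pwm),
        background=bg,
        objective_history=hist,
    )


def motif_significance(
    model: MotifModel,
    seqs,
    n_shuffles: int = 100,
    seed: int = 0,
    n_starts: int = 50,
    n_iter: int = 100,
    tol: float = 1e-6,
) -> float:
    """Empirical significance of a fitted motif via per-sequence shuffling.

    Each shuffled dataset permutes the letters within every sequence
    (preserving its length and mononucleotide composition exactly) and the
    finder is re-run at the model's width with the same number of restarts.
    p = (1 + #{shuffled best LLR >= observed LLR}) / (n_shuffles + 1), then
    multiplied by the number of widths scanned when the model came from a
    width scan (Bonferroni).  Compared against 0.05 by callers.
    """
    if isinstance(seqs, dict):
        strings = [s.upper() for s in seqs.values()]
    else:
        strings = [s.upper() for s in seqs]
    if n_shuffles < 20:
        warnings.warn(
            f"n_shuffles={n_shuffles} gives coarse p-value resolution", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = ["".join(rng.permutation(list(s))) for s in strings]
        fit = em_motif(
            shuffled, model.width, n_starts=n_starts, n_iter=n_iter, tol=tol, rng=rng
        )
        if fit.llr >= model.llr:
            exceed += 1
    p = (1 + exceed) / (n_shuffles + 1) * model.n_widths_scanned
    return float(min(p, 1.0))


def find_motifs(
    seqs,
    widths=(8, 10, 12, 15),
    n_motifs: int = 2,
    n_starts: int = 50,
    n_iter: int = 100,
    n_shuffles: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
) -> list[MotifModel]:
    """Width-scanned motif discovery with iterative masking.

    For each motif round the finder is run at every width and the fit with
    the highest LLR is kept; its significance is calibrated by shuffling at
    that width (Bonferroni-corrected across the widths scanned).  Reported
    sites are then masked to N and the next motif is sought, approximating
    a multi-occurrence search with a single-site model.  Tails shorter than
    the largest width are excluded with a logged count.
    """
    if isinstance(seqs, TailSet):
        seqs = seqs.tails
    if not isinstance(seqs, dict):
        seqs = {f"seq{i}": s for i, s in enumerate(seqs)}
    wmax = max(widths)
    usable = {k: v.upper() for k, v in seqs.items() if len(v) >= wmax}
    if len(usable) < len(seqs):
        logger.warning(
            "find_motifs: excluded %d tails shorter than %d nt",
            len(seqs) - len(usable), wmax,
        )
    if not usable:
        raise ValueError(f"no sequences of length >= {wmax}")

    current = dict(usable)
    models: list[MotifModel] = []
    for round_idx in range(n_motifs):
        fits = []
        for wi, w in enumerate(widths):
            fit = em_motif(
                current, w, n_starts=n_starts, n_iter=n_iter, tol=tol,
                seed=int(np.random.default_rng([seed, round_idx, wi]).integers(2**31)),
            )
            fits.append(fit)
        best = max(range(len(fits)), key=lambda i: fits[i].llr)
        model = fits[best]
        model.n_widths_scanned = len(widths)
        model.significance = motif_significance(
            model, current, n_shuffles=n_shuffles,
            seed=int(np.random.default_rng([seed, round_idx, 99]).integers(2**31)),
            n_starts=n_starts, n_iter=n_iter, tol=tol,
        )
        models.append(model)
        # mask reported sites so the next round finds a different signal
        masked = dict(current)
        for name, start, end in model.sites:
            s = masked[name]
            masked[name] = s[:start] + "N" * (end - start) + s[end:]
        current = masked
    return models


# ---------------------------------------------------------------------------
# PWM information content
# ---------------------------------------------------------------------------


def pwm_bits(pwm: np.ndarray) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p log2 p (0..2)."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must be (width, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return 2.0 + plogp.sum(axis=1)


def conserved_block(pwm: np.ndarray, base: str = "T", min_percent: float = 50.0) -> int:
    """Longest run of positions whose modal base is ``base`` with information
    content at or above ``min_percent`` of the 2-bit ceiling."""
    b = ALPHABET.index(base)
    percent = pwm_bits(pwm) / 2.0 * 100.0
    good = (np.asarray(pwm).argmax(axis=1) == b) & (percent >= min_percent)
    best = run = 0
    for g in good:
        run = run + 1 if g else 0
        best = max(best, run)
    return best
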