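"""Tail extraction, run statistics and the ZOOPS EM motif finder."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dropgate as dg


class TestExtractTails:
    def test_short_transcript_returned_whole(self):
        ts = dg.extract_tails({"g": [("t1", "ACGT" * 25)]}, window=350)
        assert ts.tails["g"] == "ACGT" * 25

    def test_longest_transcript_chosen(self):
        ts = dg.extract_tails(
            {"g": [("t1", "A" * 400), ("t2", "C" * 500)]}, window=350
        )
        assert ts.tails["g"] == "C" * 350
        assert ts.provenance["g"] == ("t2", 500)

    def test_tail_is_terminal_window(self):
        ts = dg.extract_tails({"g": [("t1", "A" * 400 + "T" * 350)]}, window=350)
        assert ts.tails["g"] == "T" * 350

    def test_missing_genes_reported_not_fatal(self):
        ts = dg.extract_tails({"g": [("t1", "ACGTACGT")]}, gene_set={"g", "h"})
        assert ts.skipped == ["h"]

    def test_length_tie_breaks_by_transcript_id(self):
        ts = dg.extract_tails({"g": [("t2", "A" * 100), ("t1", "C" * 100)]})
        assert ts.provenance["g"][0] == "t1"


class TestMaxRun:
    @pytest.mark.parametrize(
        "seq, base, expected",
        [("TTATTT", "T", 3), ("ACGC", "T", 0), ("", "T", 0), ("TTTT", "T", 4)],
    )
    def test_hand_cases(self, seq, base, expected):
        assert dg.max_run(seq, base) == expected

    def test_against_all_substring_oracle(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            brute = max(
                (j - i for i, j in itertools.combinations(range(len(seq) + 1), 2)
                 if set(seq[i:j]) == {"T"}),
                default=0,
            )
            assert dg.max_run(seq, "T") == brute

    def test_against_groupby_oracle_long(self, rng):
        from itertools import groupby

        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=350, p=[0.2, 0.2, 0.2, 0.4]))
            oracle = max((len(list(g)) for b, g in groupby(seq) if b == "T"), default=0)
            assert dg.max_run(seq, "T") == oracle


class TestRunEnrichment:
    def test_exhaustive_hypergeometric_toy(self):
        # 3/4 target hits vs 1/4 background hits; enumerate all 4-subsets
        target = {f"t{i}": ("T" * 12 if i < 3 else "ACGT" * 3) for i in range(4)}
        background = {f"b{i}": ("T" * 12 if i < 1 else "ACGT" * 3) for i in range(4)}
        res = dg.run_enrichment(target, background, k=10)
        hits, n, N = 4, 4, 8
        universe = list(range(N))
        hit_ids = set(range(hits))
        count = sum(
            1 for comb in itertools.combinations(universe, n)
            if len(set(comb) & hit_ids) >= 3
        )
        expected_p = count / math.comb(N, n)
        assert res["pvalue"] == pytest.approx(expected_p, rel=1e-9)

    def test_extreme_separation(self):
        target = {f"t{i}": "T" * 15 for i in range(4)}
        background = {f"b{i}": "ACGT" * 10 for i in range(4)}
        res = dg.run_enrichment(target, background, k=10)
        assert res["pvalue"] == pytest.approx(1 / math.comb(8, 4), rel=1e-9)
        assert np.isfinite(res["odds_ratio"]) and res["odds_ratio"] > 1

    def test_type_one_error_controlled_under_null(self):
        # same composition in target and background: p should be ~uniform
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(500):
            pool = ["".join(rng.choice(list("ACGT"), 80, p=[.2, .2, .2, .4]))
                    for _ in range(30)]
            target = {f"t{i}": s for i, s in enumerate(pool[:10])}
            background = {f"b{i}": s for i, s in enumerate(pool[10:])}
            if dg.run_enrichment(target, background, k=5)["pvalue"] < 0.05:
                rejections += 1
        assert rejections / 500 <= 0.07

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            dg.run_enrichment({"a": "TTTT"}, {"a": "TTTT"}, k=2)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dg.run_enrichment({}, {"a": "TTTT"}, k=2)


def planted_dataset(n=50, length=100, frac=0.8, motif="T" * 10, seed=7):
    rng = np.random.default_rng(seed)
    seqs, offsets = {}, {}
    n_planted = int(frac * n)
    for i in range(n):
        s = "".join(rng.choice(list("ACGT"), length))
        if i < n_planted:
            p = int(rng.integers(0, length - len(motif) + 1))
            s = s[:p] + motif + s[p + len(motif):]
            offsets[f"g{i}"] = p
        seqs[f"g{i}"] = s
    return seqs, offsets


class TestEmMotif:
    def test_recovers_planted_polyt(self):
        seqs, offsets = planted_dataset()
        model = dg.em_motif(seqs, w=10, n_starts=50, n_iter=100, seed=0)
        assert model.consensus == "T" * 10
        # site overlaps the planted run substantially in >= 90% of carriers
        recovered = sum(
            1 for (name, start, end) in model.sites
            if name in offsets and min(end, offsets[name] + 10) - max(start, offsets[name]) >= 8
        )
        assert recovered >= 0.9 * len(offsets)
        assert model.lam == pytest.approx(0.8, abs=0.1)

    def test_objective_monotone(self):
        seqs, _ = planted_dataset(n=20, seed=3)
        model = dg.em_motif(seqs, w=10, n_starts=5, n_iter=50, seed=1)
        hist = np.asarray(model.objective_history)
        assert np.all(np.diff(hist) >= -1e-8 * np.maximum(1.0, np.abs(hist[:-1])))

    def test_degenerate_identical_sequences(self):
        model = dg.em_motif(["ACGTACGT"] * 10, w=8, n_starts=3, n_iter=30, seed=0)
        bits = model.bits()
        assert np.all(bits > 1.8)
        assert model.consensus == "ACGTACGT"

    def test_short_sequence_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            dg.em_motif({"ok": "ACGTACGTAC", "tiny": "ACG"}, w=8)

    def test_width_floor(self):
        with pytest.raises(ValueError, match="width"):
            dg.em_motif(["ACGTACGT"], w=3)

    def test_deterministic(self):
        seqs, _ = planted_dataset(n=15, seed=5)
        a = dg.em_motif(seqs, w=8, n_starts=5, n_iter=30, seed=2)
        b = dg.em_motif(seqs, w=8, n_starts=5, n_iter=30, seed=2)
        np.testing.assert_array_equal(a.pwm, b.pwm)
        assert a.llr == b.llr


class TestSignificance:
    def test_planted_motif_significant(self):
        seqs, _ = planted_dataset(n=30, length=80)
        model = dg.em_motif(seqs, w=10, n_starts=5, n_iter=30, seed=0)
        p = dg.motif_significance(model, seqs, n_shuffles=99, seed=0,
                                  n_starts=5, n_iter=30, tol=1e-3)
        assert p < 0.05

    def test_shuffle_preserves_composition(self):
        # indirectly: a composition-only signal (T-rich but runless vs not)
        # cannot be distinguished from its own shuffles
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60, p=[.1, .1, .1, .7]))
                for _ in range(12)]
        model = dg.em_motif(seqs, w=8, n_starts=3, n_iter=25, seed=1, tol=1e-3)
        p = dg.motif_significance(model, seqs, n_shuffles=49, seed=1,
                                  n_starts=3, n_iter=25, tol=1e-3)
        assert p > 0.05

    def test_low_shuffle_count_warns(self):
        seqs, _ = planted_dataset(n=8, length=40)
        model = dg.em_motif(seqs, w=8, n_starts=2, n_iter=10, seed=0)
        with pytest.warns(UserWarning, match="resolution"):
            dg.motif_significance(model, seqs, n_shuffles=5, seed=0,
                                  n_starts=2, n_iter=10)


class TestPwmBits:
    @pytest.mark.parametrize(
        "row, expected",
        [([0.25, 0.25, 0.25, 0.25], 0.0),
         ([1.0, 0.0, 0.0, 0.0], 2.0),
         ([0.5, 0.5, 0.0, 0.0], 1.0)],
    )
    def test_closed_forms(self, row, expected):
        assert dg.pwm_bits(np.array([row]))[0] == pytest.approx(expected)

    def test_conserved_block(self):
        pwm = np.array(
            [[0.25, 0.25, 0.25, 0.25]]       # uninformative
            + [[0.0, 0.0, 0.0, 1.0]] * 3     # strong T block
            + [[0.1, 0.1, 0.1, 0.7]]         # T but weak (< 50%)
        )
        assert dg.conserved_block(pwm, "T") == 3

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            dg.pwm_bits(np.array([[0.5, 0.5, 0.5, 0.5]]))


class TestFindMotifs:
    def test_masking_yields_second_motif(self):
        # two planted motifs; the second is found after masking the first
        rng = np.random.default_rng(9)
        seqs = {}
        for i in range(30):
            s = "".join(rng.choice(list("ACGT"), 90))
            s = s[:10] + "T" * 12 + s[22:]
            s = s[:60] + "GGGGGGGGGG" + s[70:]
            seqs[f"g{i}"] = s
        models = dg.find_motifs(seqs, widths=(10,), n_motifs=2, n_starts=20,
                                n_iter=40, n_shuffles=29, seed=0, tol=1e-3)
        consensi = {m.consensus for m in models}
        assert any("TTTTTT" in c for c in consensi)
        assert any("GGGGGG" in c for c in consensi)

    def test_short_tails_excluded_with_log(self, caplog):
        seqs = {"long": "ACGTACGTACGTACGT", "short": "ACGT"}
        with caplog.at_level("WARNING"):
            dg.find_motifs(seqs, widths=(8,), n_motifs=1, n_starts=2,
                           n_iter=10, n_shuffles=20, seed=0)
        assert "excluded 1 tails" in caplog.text
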