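"""Pair classification, scoring, empirical site rules and the local aligner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirforest import (
    AlignConfig,
    PairCategory,
    RNASequence,
    Role,
    align_duplex,
    check_empirical_rules,
    classify_column,
    score_alignment,
)
from mirforest.duplex import (
    RULE_I,
    RULE_II,
    RULE_III,
    RULE_IV,
    RULE_TOO_SHORT,
    DuplexAlignment,
    _gotoh_local,
    infer_categories,
)

from conftest import make_alignment

GC = PairCategory.GC_MATCH
AU = PairCategory.AU_MATCH
GU = PairCategory.GU_WOBBLE
MM = PairCategory.MISMATCH
GAP = PairCategory.GAP

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def quartic_oracle(mirna: str, rtarget: str, cfg: AlignConfig) -> float:
    """Independent best-local-score: direct recursion over matched-pair sets.

    f(i, j) is the best score of a local alignment whose last paired column
    is (i, j); unpaired residues between consecutive paired columns form one
    gap run per row with closed-form affine cost.
    """

    def gap(g: int) -> float:
        return 0.0 if g == 0 else cfg.gap_open + cfg.gap_extend * (g - 1)

    m, n = len(mirna), len(rtarget)
    f = {}
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            prev = 0.0
            for i2 in range(1, i):
                for j2 in range(1, j):
                    prev = max(prev, f[(i2, j2)] + gap(i - i2 - 1) + gap(j - j2 - 1))
            f[(i, j)] = cfg.pair_score(mirna[i - 1], rtarget[j - 1]) + prev
            best = max(best, f[(i, j)])
    return best


class TestClassifyColumn:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("G", "C", GC), ("C", "G", GC),
            ("A", "U", AU), ("U", "A", AU),
            ("G", "U", GU), ("U", "G", GU),
            ("A", "C", MM), ("A", "A", MM), ("C", "U", MM),
            ("-", "A", GAP), ("G", "-", GAP),
        ],
    )
    def test_category(self, a, b, expected):
        assert classify_column(a, b) is expected

    def test_double_gap_rejected(self):
        with pytest.raises(ValueError):
            classify_column("-", "-")

    @given(st.sampled_from("ACGU"), st.sampled_from("ACGU"))
    @settings(deadline=None)
    def test_symmetric(self, a, b):
        assert classify_column(a, b) is classify_column(b, a)


class TestScoreAlignment:
    def test_all_gc(self, align_cfg):
        assert score_alignment(make_alignment([GC] * 7), align_cfg) == 35

    def test_gc_plus_wobble(self, align_cfg):
        assert score_alignment(make_alignment([GC] * 6 + [GU]), align_cfg) == 32

    def test_empty(self, align_cfg):
        aln = DuplexAlignment("", "", 0.0, 1, 0)
        assert score_alignment(aln, align_cfg) == 0

    def test_affine_gap_run(self, align_cfg):
        # two-column gap run in the miRNA row: open + extend, charged once
        aln = DuplexAlignment(
            mirna_row="GG--GG",
            target_row="CCAACC",
            score=0.0,
            target_start=1,
            target_end=6,
        )
        assert score_alignment(aln, align_cfg) == 4 * 5 + (-8) + (-2)


class TestEmpiricalRules:
    def test_seed_mismatch_violates_rule_i(self):
        cats = [GC] * 22
        cats[2] = MM  # column 3
        ok, violated = check_empirical_rules(make_alignment(cats))
        assert not ok and RULE_I in violated

    def test_perfect_duplex_violates_rule_iii(self):
        ok, violated = check_empirical_rules(make_alignment([GC, AU] * 11))
        assert not ok and violated == [RULE_III]

    def test_single_central_mismatch_accepted(self):
        cats = [GC] * 22
        cats[9] = MM  # column 10 lies in 9..L-5
        ok, violated = check_empirical_rules(make_alignment(cats))
        assert ok and violated == []

    def test_five_core_mismatches_violate_rule_ii(self):
        cats = [GC] * 22
        for col in (5, 6, 7, 8, 10):  # all within 3..12, none in 2..4
            cats[col - 1] = MM
        ok, violated = check_empirical_rules(make_alignment(cats))
        assert not ok and RULE_II in violated

    def test_two_tail_mismatches_violate_rule_iv(self):
        cats = [GC] * 22
        cats[9] = MM
        cats[18] = MM
        cats[20] = MM  # columns 19 and 21 in the last five
        ok, violated = check_empirical_rules(make_alignment(cats))
        assert not ok and RULE_IV in violated

    def test_wobble_counts_as_pairing(self):
        cats = [GC] * 22
        cats[1] = GU  # wobble in the seed anchor does not violate rule i
        cats[9] = MM
        ok, violated = check_empirical_rules(make_alignment(cats))
        assert ok

    def test_short_alignment_distinct_code(self):
        ok, violated = check_empirical_rules(make_alignment([GC] * 13))
        assert not ok and violated == [RULE_TOO_SHORT]


class TestGotohDP:
    def test_matches_exhaustive_oracle(self, align_cfg):
        rng = np.random.default_rng(42)
        for _ in range(60):
            mirna = "".join(rng.choice(list("ACGU"), rng.integers(4, 9)))
            rtarget = "".join(rng.choice(list("ACGU"), rng.integers(6, 13)))
            got, _ = _gotoh_local(mirna, rtarget, align_cfg, frozenset())
            assert got == quartic_oracle(mirna, rtarget, align_cfg)

    def test_score_additivity(self, align_cfg):
        # the DP-reported score must equal the column-wise recomputation
        rng = np.random.default_rng(7)
        for _ in range(30):
            mirna = "".join(rng.choice(list("ACGU"), 18))
            rtarget = "".join(rng.choice(list("ACGU"), 60))
            score, hit = _gotoh_local(mirna, rtarget, align_cfg, frozenset())
            if hit is None:
                continue
            mrow, trow, j0, j1 = hit
            aln = DuplexAlignment(mrow, trow, score, 1, j1 - j0 + 1)
            assert score_alignment(aln, align_cfg) == pytest.approx(score)

    def test_masked_columns_not_consumed(self, align_cfg):
        mirna = "GGGG"
        rtarget = "GGGGCCCC"
        masked = frozenset(range(4, 8))  # forbid the complementary block
        score, hit = _gotoh_local(mirna, rtarget, align_cfg, masked)
        if hit is not None:
            _, _, j0, j1 = hit
            assert j1 <= 4


def _embed_site(mirna: str, mismatch_at: int, flank5: str, flank3: str) -> str:
    """Target (5'->3') carrying the reverse complement of ``mirna`` with one
    mismatched column against miRNA position ``mismatch_at`` (1-based)."""
    partners = []
    for k, ch in enumerate(mirna, start=1):
        if k == mismatch_at:
            partners.append(ch)  # same residue never pairs with itself
        else:
            partners.append(WC[ch])
    return flank5 + "".join(reversed(partners)) + flank3


class TestAlignDuplex:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"

    def test_perfect_complement_rejected_by_central_bulge_rule(self):
        mirna = RNASequence("m", "GCGCAUAUGCGCAUAUGCGC", Role.MIRNA)
        target = RNASequence("t", _embed_site(mirna.residues, 0, "AAGGG" * 4, "CCUUU" * 4))
        assert align_duplex(mirna, target) == []

    def test_single_central_mismatch_site_found_with_coordinates(self):
        mirna = RNASequence("m", self.MIRNA, Role.MIRNA)
        flank5, flank3 = "GGAAG" * 4, "CUUCC" * 4
        target = RNASequence("t", _embed_site(self.MIRNA, 12, flank5, flank3))
        sites = align_duplex(mirna, target)
        assert len(sites) == 1
        aln = sites[0]
        # coordinate soundness: displayed 3'->5' residues equal the reversed
        # target slice
        assert aln.ungapped_target() == target.residues[
            aln.target_start - 1 : aln.target_end
        ][::-1]
        assert aln.target_start >= len(flank5) - 2
        assert check_empirical_rules(aln)[0]

    def test_random_target_rarely_passes_high_threshold(self):
        rng = np.random.default_rng(11)
        cfg = AlignConfig(score_threshold=50.0)
        hits = 0
        for _ in range(10):
            mirna = RNASequence("m", "".join(rng.choice(list("ACGU"), 22)), Role.MIRNA)
            target = RNASequence("t", "".join(rng.choice(list("ACGU"), 60)))
            hits += bool(align_duplex(mirna, target, cfg))
        assert hits <= 2  # chance sites are rare on unrelated sequence

    def test_empty_sequence_rejected(self):
        from mirforest.seqs import SequenceError

        with pytest.raises(SequenceError):
            RNASequence("t", "")

    def test_multiple_nonoverlapping_sites(self):
        site_target = _embed_site(self.MIRNA, 12, "", "")
        target = RNASequence(
            "t", "AAGGA" * 3 + site_target + "CGUUC" * 3 + site_target + "AAGGA" * 3
        )
        mirna = RNASequence("m", self.MIRNA, Role.MIRNA)
        sites = align_duplex(mirna, target)
        assert len(sites) == 2
        a, b = sites
        assert a.target_end < b.target_start or b.target_end < a.target_start
        assert a.score >= b.score

    def test_category_rows_consistent(self):
        mirna = RNASequence("m", self.MIRNA, Role.MIRNA)
        target = RNASequence("t", _embed_site(self.MIRNA, 12, "GGAAG" * 4, "CUUCC" * 4))
        for aln in align_duplex(mirna, target):
            assert aln.categories == infer_categories(aln.mirna_row, aln.target_row)
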