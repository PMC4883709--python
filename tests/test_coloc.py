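import numpy as np
import pytest
from scipy import stats

from mama.coloc import (
    PairCounts,
    PairStats,
    SharedMemberError,
    chi_square_pair,
    enrichment_EN,
    evaluate_all_pairs,
    pair_counts,
    select_enriched_pairs,
    separation_histogram,
)
from mama.grouping import MotifGroup, build_pcm
from mama.sequence_io import PromoterSet

MOTIF_A = "ACGTAGGC"
MOTIF_B = "TTGACCAT"


def make_group(*members):
    g = MotifGroup(members[0], list(members), 1.0, np.zeros((4, len(members[0])), dtype=int))
    g.pcm = build_pcm(g)
    return g


def promoter_with(motifs_at, width=650, region=(-500, 150)):
    seq = list("T" * width)
    for motif, offset in motifs_at:
        i = offset - region[0]
        seq[i : i + len(motif)] = motif
    return "".join(seq)


class TestPairCounts:
    def test_construction_case(self):
        # A in all UP genes, B in none
        records, labels = {}, {}
        for i in range(4):
            records[f"u{i}"] = promoter_with([(MOTIF_A, -300)])
            labels[f"u{i}"] = True
        for i in range(6):
            records[f"n{i}"] = promoter_with([])
            labels[f"n{i}"] = False
        ps = PromoterSet(region=(-500, 150), records=records)
        c = pair_counts(make_group(MOTIF_A), make_group(MOTIF_B), ps, labels)
        assert c.ab_up == 0 and c.anb_up == 4 and c.n_up == 4 and c.n_nup == 6

    def test_hand_tabulated_ten_gene_fixture(self):
        # brute-force tabulation of a mixed fixture
        spec = [  # (has_a, has_b, up)
            (1, 1, 1), (1, 0, 1), (0, 1, 1), (0, 0, 1), (1, 1, 1),
            (1, 1, 0), (0, 0, 0), (0, 1, 0), (1, 0, 0), (0, 0, 0),
        ]
        records, labels = {}, {}
        for i, (a, b, up) in enumerate(spec):
            motifs = ([(MOTIF_A, -400)] if a else []) + ([(MOTIF_B, -100)] if b else [])
            records[f"g{i}"] = promoter_with(motifs)
            labels[f"g{i}"] = bool(up)
        ps = PromoterSet(region=(-500, 150), records=records)
        c = pair_counts(make_group(MOTIF_A), make_group(MOTIF_B), ps, labels)
        expect = {
            (1, 1, 1): 2, (0, 1, 1): 1, (1, 0, 1): 1, (0, 0, 1): 1,
            (1, 1, 0): 1, (0, 1, 0): 1, (1, 0, 0): 1, (0, 0, 0): 2,
        }
        assert (c.ab_up, c.nab_up, c.anb_up, c.nanb_up) == (
            expect[1, 1, 1], expect[0, 1, 1], expect[1, 0, 1], expect[0, 0, 1]
        )
        assert (c.ab_nup, c.nab_nup, c.anb_nup, c.nanb_nup) == (
            expect[1, 1, 0], expect[0, 1, 0], expect[1, 0, 0], expect[0, 0, 0]
        )

    def test_shared_member_rejected(self):
        ps = PromoterSet(region=(-500, 150), records={"g": promoter_with([])})
        shared = make_group(MOTIF_A, "CCCCGGGG")
        other = make_group("CCCCGGGG")
        with pytest.raises(SharedMemberError):
            pair_counts(shared, other, ps, {"g": True})


class TestChiSquare:
    def test_proportional_tables_give_zero(self):
        c = PairCounts(10, 20, 30, 40, 1, 2, 3, 4)
        chi2, p = chi_square_pair(c)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_example_21(self):
        # Oi = (30,20,10,40); !UP cells (15,25,20,40) scale to Ei with
        # N(UP)=100 = N(!UP): X^2 = 15 + 1 + 5 + 0 = 21
        c = PairCounts(30, 20, 10, 40, 15, 25, 20, 40)
        chi2, p = chi_square_pair(c)
        assert chi2 == pytest.approx(21.0, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(21.0, 3)), rel=1e-12)

    def test_doubling_counts_doubles_chi2(self, rng):
        for _ in range(50):
            cells = rng.integers(1, 50, size=8)
            c1 = PairCounts(*cells)
            c2 = PairCounts(*(2 * cells))
            assert chi_square_pair(c2)[0] == pytest.approx(
                2 * chi_square_pair(c1)[0], rel=1e-9
            )

    def test_matches_general_chi2_oracle(self, rng):
        """Same Oi/Ei fed to an independently computed tail (df=3)."""
        for _ in range(100):
            cells = rng.integers(1, 80, size=8)
            c = PairCounts(*cells)
            chi2, p = chi_square_pair(c)
            obs = np.array(cells[:4], dtype=float)
            exp = obs.sum() / cells[4:].sum() * np.array(cells[4:], dtype=float)
            oracle_chi2 = float(((obs - exp) ** 2 / exp).sum())
            assert chi2 == pytest.approx(oracle_chi2, rel=1e-10)
            assert p == pytest.approx(float(stats.chi2.sf(oracle_chi2, 3)), rel=1e-10)

    def test_p_monotone_in_chi2(self):
        chis = [chi_square_pair(PairCounts(k, 20, 10, 40, 15, 25, 20, 40)) for k in (15, 30, 60)]
        ps = [p for _, p in chis]
        assert ps[0] > ps[1] > ps[2]

    def test_zero_expected_flags_untestable(self):
        with pytest.raises(ValueError):
            chi_square_pair(PairCounts(5, 5, 5, 5, 0, 5, 5, 5))

    def test_no_nup_genes_errors(self):
        with pytest.raises(ValueError):
            chi_square_pair(PairCounts(5, 5, 5, 5, 0, 0, 0, 0))


class TestEnrichment:
    def test_worked_example(self):
        # N(A|B|UP)=40 of N(B|UP)=50 vs N(A|!B|UP)=20 of N(!B|UP)=50 -> EN1=2
        c = PairCounts(40, 10, 20, 30, 20, 30, 20, 30)
        en1, en2 = enrichment_EN(c)
        assert en1 == pytest.approx((40 / 50) / (20 / 50))
        assert en2 == pytest.approx((40 / 50) / (20 / 50))

    def test_independence_gives_one(self):
        c = PairCounts(10, 10, 10, 10, 10, 10, 10, 10)
        en1, en2 = enrichment_EN(c)
        assert en1 == pytest.approx(1.0) and en2 == pytest.approx(1.0)

    def test_zero_denominator_flags(self):
        with pytest.raises(ValueError):
            enrichment_EN(PairCounts(0, 0, 5, 5, 5, 5, 5, 5))


class TestSelection:
    def _pair(self, name, p, en1, en2, testable=True):
        return PairStats(
            name, "X", PairCounts(1, 1, 1, 1, 1, 1, 1, 1),
            chi2=1.0, p_value=p, en1=en1, en2=en2, testable=testable,
        )

    def test_zero_nmp(self):
        sel = select_enriched_pairs([self._pair("a", 0.01, 2, 2)], 0)
        assert sel.pairs == [] and sel.n_mp == 0

    def test_low_en_excluded_despite_low_p(self):
        pairs = [self._pair("a", 1e-9, 0.5, 3), self._pair("b", 0.5, 2, 2)]
        sel = select_enriched_pairs(pairs, 5)
        assert [p.motif_a for p in sel.pairs] == ["b"]

    def test_fewer_survivors_than_nmp(self):
        pairs = [self._pair(n, 0.1, 2, 2) for n in "abc"]
        sel = select_enriched_pairs(pairs, 5)
        assert len(sel.pairs) == 3

    def test_sorted_by_p(self):
        pairs = [self._pair("a", 0.3, 2, 2), self._pair("b", 0.1, 2, 2)]
        sel = select_enriched_pairs(pairs, 2)
        assert [p.motif_a for p in sel.pairs] == ["b", "a"]

    def test_untestable_excluded(self):
        sel = select_enriched_pairs([self._pair("a", 0.1, 2, 2, testable=False)], 2)
        assert sel.pairs == []


class TestSeparationHistogram:
    def test_fixed_separation_single_bin(self):
        records = {
            f"g{i}": promoter_with([(MOTIF_A, -400), (MOTIF_B, -250)]) for i in range(5)
        }
        ps = PromoterSet(region=(-500, 150), records=records)
        hist = separation_histogram(
            make_group(MOTIF_A), make_group(MOTIF_B), ps, list(records)
        )
        occupied = hist["bin_center"][hist["count"] > 0]
        assert list(occupied) == [-150]
        assert hist["count"].sum() == 5
        assert hist["normalized"].sum() == pytest.approx(1.0)

    def test_no_cooccurrence_empty(self):
        records = {"g1": promoter_with([(MOTIF_A, -400)]), "g2": promoter_with([(MOTIF_B, -250)])}
        ps = PromoterSet(region=(-500, 150), records=records)
        hist = separation_histogram(make_group(MOTIF_A), make_group(MOTIF_B), ps, list(records))
        assert hist["count"].sum() == 0

    def test_reversing_mirrors(self):
        records = {f"g{i}": promoter_with([(MOTIF_A, -390 - 7 * i), (MOTIF_B, -180)]) for i in range(6)}
        ps = PromoterSet(region=(-500, 150), records=records)
        ga, gb = make_group(MOTIF_A), make_group(MOTIF_B)
        ab = separation_histogram(ga, gb, ps, list(records))
        ba = separation_histogram(gb, ga, ps, list(records))
        assert np.array_equal(ab["count"], ba["count"][::-1])

    def test_total_equals_cooccurrence_pairs(self):
        records = {"g": promoter_with([(MOTIF_A, -400), (MOTIF_A, -300), (MOTIF_B, -100)])}
        ps = PromoterSet(region=(-500, 150), records=records)
        hist = separation_histogram(make_group(MOTIF_A), make_group(MOTIF_B), ps, ["g"])
        assert hist["count"].sum() == 2  # 2 A hits x 1 B hit

    def test_empty_subset_errors(self):
        ps = PromoterSet(region=(-500, 150), records={"g": promoter_with([])})
        with pytest.raises(ValueError):
            separation_histogram(make_group(MOTIF_A), make_group(MOTIF_B), ps, [])


class TestEvaluateAllPairs:
    def test_shared_member_pairs_skipped(self):
        records = {f"g{i}": promoter_with([(MOTIF_A, -300)]) for i in range(6)}
        ps = PromoterSet(region=(-500, 150), records=records)
        labels = {g: i % 2 == 0 for i, g in enumerate(records)}
        g1 = make_group(MOTIF_A)
        g2 = make_group(MOTIF_A[:-1] + "T", MOTIF_A)  # shares MOTIF_A
        g3 = make_group(MOTIF_B)
        results = evaluate_all_pairs([g1, g2, g3], ps, labels)
        names = {(r.motif_a, r.motif_b) for r in results}
        assert (g1.name, g2.name) not in names
        assert len(results) == 2
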