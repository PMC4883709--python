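"""Unit and property tests of the window/gene/candidate scoring stack."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mama.dna import reverse_complement
from mama.scoring import (
    MatchDecomposition,
    ScoringParams,
    h_score_gene,
    h_score_window,
    mama_score,
    match_runs,
    r_score,
    score_candidates,
)
from mama.sequence_io import ExpressionTable, PromoterSet

from conftest import random_expression, random_promoters

DEFAULTS = ScoringParams()


# --- independent oracle -------------------------------------------------------

def oracle_decompose(candidate, window):
    """Literal char-by-char run/gap decomposition, coded independently."""
    flags = [a == b and a != "N" and b != "N" for a, b in zip(candidate, window)]
    runs, gaps = [], []
    i = 0
    while i < len(flags):
        j = i
        while j < len(flags) and flags[j] == flags[i]:
            j += 1
        if flags[i]:
            runs.append(j - i)
        elif runs:  # only gaps BETWEEN runs count
            gaps.append(j - i)
        i = j
    if not flags or not flags[-1]:
        if gaps and runs and len(gaps) >= len(runs):
            gaps.pop()  # trailing mismatch block is not a gap
    return runs, gaps


def oracle_h(runs, gaps, a_hat, nu):
    """Term-by-term literal evaluation of the similarity formula."""
    total = float(sum(math.factorial(h) for h in runs))
    for x in range(len(runs)):
        for y in range(x + 1, len(runs)):
            term = float(runs[x] * runs[y])
            for k in range(x, y):
                term /= a_hat * gaps[k] + 1.0
            total += term
    return total**nu


class TestMatchRuns:
    def test_identity(self):
        d = match_runs("ACGTACGT", "ACGTACGT")
        assert d.run_lengths == (8,) and d.gaps == ()

    def test_single_mismatch(self):
        d = match_runs("ACGTACGT", "ACGAACGT")
        assert d.run_lengths == (3, 4) and d.gaps == (1,)

    def test_no_match(self):
        d = match_runs("AAAAAAAA", "CCCCCCCC")
        assert d.run_lengths == () and d.gaps == ()

    def test_n_matches_nothing(self):
        d = match_runs("ACGTACGT", "ACNTACGT")
        assert d.run_lengths == (2, 5) and d.gaps == (1,)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            match_runs("ACGT", "ACGTA")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=12), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_decomposition(self, candidate, data):
        window = data.draw(
            st.text(alphabet="ACGTN", min_size=len(candidate), max_size=len(candidate))
        )
        d = match_runs(candidate, window)
        runs, gaps = oracle_decompose(candidate, window)
        assert list(d.run_lengths) == runs
        assert list(d.gaps) == gaps


class TestHScoreWindow:
    def test_perfect_match_is_40320(self):
        assert h_score_window(MatchDecomposition((8,), ()), DEFAULTS) == 40320.0

    def test_perfect_match_nu2(self):
        assert h_score_window(MatchDecomposition((8,), ()), ScoringParams(nu=2)) == 40320.0**2

    def test_worked_two_run_example(self):
        # 3! + 4! + 3*4/(1*1+1) = 36
        assert h_score_window(MatchDecomposition((3, 4), (1,)), DEFAULTS) == 36.0

    def test_worked_three_run_example(self):
        # 2!*3 + 4/2 + 4/(2*2) + 4/2 = 11, incl. the h1*h3 double-gap term
        assert h_score_window(MatchDecomposition((2, 2, 2), (1, 1)), DEFAULTS) == 11.0

    def test_power_rule(self):
        assert h_score_window(MatchDecomposition((3, 4), (1,)), ScoringParams(nu=2)) == 36.0**2

    def test_empty_decomposition_scores_zero(self):
        assert h_score_window(MatchDecomposition((), ()), DEFAULTS) == 0.0

    @pytest.mark.parametrize("a_hat", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("nu", [1, 2, 3])
    def test_oracle_equivalence_random_pairs(self, rng, a_hat, nu):
        params = ScoringParams(nu=nu, a_hat=a_hat)
        for _ in range(200):
            cand = "".join(rng.choice(list("ACGT"), size=8))
            window = "".join(rng.choice(list("ACGTN"), p=[0.23] * 4 + [0.08], size=8))
            d = match_runs(cand, window)
            runs, gaps = oracle_decompose(cand, window)
            assert h_score_window(d, params) == oracle_h(runs, gaps, a_hat, nu)

    @given(
        st.lists(st.integers(1, 8), min_size=1, max_size=4),
        st.data(),
        st.integers(1, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_nu_scaling_property(self, runs, data, nu):
        gaps = tuple(data.draw(st.integers(1, 6)) for _ in range(len(runs) - 1))
        d = MatchDecomposition(tuple(runs), gaps)
        base = h_score_window(d, ScoringParams(nu=1))
        powered = h_score_window(d, ScoringParams(nu=nu))
        assert powered == pytest.approx(base**nu, rel=1e-12)


class TestHScoreGene:
    def test_verbatim_hit_dominates(self):
        assert h_score_gene("ACGTACGT", "TTACGTACGTTT", DEFAULTS) == 40320.0

    def test_reverse_complement_hit(self):
        promoter = "TT" + reverse_complement("ACGTACGT") + "GG"
        assert h_score_gene("ACGTACGT", promoter, DEFAULTS) == 40320.0

    def test_all_n_promoter_scores_zero(self):
        assert h_score_gene("ACGTACGT", "N" * 30, DEFAULTS) == 0.0

    def test_short_promoter_scores_zero(self):
        assert h_score_gene("ACGTACGT", "ACGTACG", DEFAULTS) == 0.0

    def test_is_max_over_windows_and_strands(self, rng):
        params = ScoringParams(a_hat=0.5)
        for _ in range(20):
            cand = "".join(rng.choice(list("ACGT"), size=8))
            prom = "".join(rng.choice(list("ACGT"), size=40))
            expected = 0.0
            for seq in (prom, reverse_complement(prom)):
                for i in range(len(seq) - 7):
                    expected = max(
                        expected, h_score_window(match_runs(cand, seq[i : i + 8]), params)
                    )
            assert h_score_gene(cand, prom, params) == expected

    def test_extra_mismatch_never_increases(self, rng):
        # single-gene promoter equal to the candidate; mutating any one
        # base of the best window cannot raise the similarity
        for _ in range(20):
            cand = "".join(rng.choice(list("ACGT"), size=8))
            base = h_score_gene(cand, cand, DEFAULTS)
            pos = int(rng.integers(8))
            other = rng.choice([b for b in "ACGT" if b != cand[pos]])
            mutated = cand[:pos] + other + cand[pos + 1 :]
            assert h_score_gene(cand, mutated, DEFAULTS) <= base


class TestRScore:
    def test_cap(self):
        assert r_score(25.0, DEFAULTS) == 10.0

    def test_downregulated_set_to_one(self):
        assert r_score(0.3, DEFAULTS) == 1.0

    def test_reciprocal_policy(self):
        assert r_score(0.25, ScoringParams(downregulated_policy="reciprocal")) == 4.0

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            r_score(0.0, DEFAULTS)

    def test_remove_policy_is_an_upstream_contract(self):
        with pytest.raises(ValueError):
            r_score(0.5, ScoringParams(downregulated_policy="remove"))


class TestMamaScore:
    def test_constant_ratio_gives_ratio_to_tau(self, rng):
        promoters = random_promoters(rng, n_genes=10, length=40)
        expr = ExpressionTable({g: 3.0 for g in promoters.gene_ids})
        params = ScoringParams(tau=2.0)
        score = mama_score("ACGTACGT", promoters, expr, params)
        assert score.mama_score == pytest.approx(3.0**2, rel=1e-12)

    def test_two_gene_weighted_average(self):
        promoters = PromoterSet(
            region=(-12, 0),
            records={"g1": "TTACGTACGTTT", "g2": "GGACGTACGTGG"},
        )
        expr = ExpressionTable({"g1": 25.0, "g2": 0.5})  # capped 10, floored 1
        score = mama_score("ACGTACGT", promoters, expr, DEFAULTS)
        assert score.mama_score == pytest.approx(5.5, rel=1e-12)
        assert score.n_contributing == 2

    def test_absent_candidate_scores_zero(self):
        promoters = PromoterSet(region=(-10, 0), records={"g1": "A" * 10})
        expr = ExpressionTable({"g1": 5.0})
        score = mama_score("CGCGCGCG", promoters, expr, DEFAULTS)
        assert score.mama_score == 0.0 and score.n_contributing == 0

    def test_strand_symmetry(self, rng):
        promoters = random_promoters(rng, n_genes=15, length=60)
        expr = random_expression(rng, promoters.gene_ids)
        for _ in range(25):
            cand = "".join(rng.choice(list("ACGT"), size=8))
            fwd = mama_score(cand, promoters, expr, DEFAULTS).mama_score
            rev = mama_score(reverse_complement(cand), promoters, expr, DEFAULTS).mama_score
            assert fwd == pytest.approx(rev, rel=0, abs=0)

    def test_bounds_with_defaults(self, rng):
        promoters = random_promoters(rng, n_genes=30, length=60)
        expr = random_expression(rng, promoters.gene_ids, low=0.2, high=30.0)
        params = ScoringParams(tau=2.0)
        cands = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(50)]
        for s in score_candidates(cands, promoters, expr, params):
            if s.mama_score > 0:
                assert 1.0 - 1e-12 <= s.mama_score <= 10.0**2 + 1e-9

    def test_remove_policy_excludes_genes_from_both_sums(self):
        promoters = PromoterSet(
            region=(-12, 0),
            records={"g1": "TTACGTACGTTT", "g2": "GGACGTACGTGG"},
        )
        expr = ExpressionTable({"g1": 4.0, "g2": 0.5})
        score = mama_score(
            "ACGTACGT", promoters, expr, ScoringParams(downregulated_policy="remove")
        )
        assert score.mama_score == pytest.approx(4.0)
        assert score.n_contributing == 1

    def test_empty_gene_set_errors(self):
        promoters = PromoterSet(region=(-10, 0), records={"g1": "ACGTACGTAC"})
        expr = ExpressionTable({"other": 2.0})
        with pytest.raises(ValueError):
            mama_score("ACGTACGT", promoters, expr, DEFAULTS)

    def test_batch_matches_per_gene_composition(self, rng):
        """Vectorized scores equal a from-parts recomputation (dual route)."""
        promoters = random_promoters(rng, n_genes=12, length=50, n_prob=0.03)
        expr = random_expression(rng, promoters.gene_ids)
        params = ScoringParams(nu=2, tau=1.5, a_hat=0.5)
        cands = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(20)]
        batch = score_candidates(cands, promoters, expr, params)
        for cs in batch:
            num = den = 0.0
            for g, seq in promoters.records.items():
                h = h_score_gene(cs.sequence, seq, params)
                num += h * r_score(expr.ratios[g], params) ** params.tau
                den += h
            expected = num / den if den else 0.0
            assert cs.mama_score == pytest.approx(expected, rel=1e-12)
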