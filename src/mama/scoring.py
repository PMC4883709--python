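"""Similarity-weighted expression scoring of candidate 8-mers.

A candidate sequence is compared ungapped against every equal-length window
of a promoter (both strands).  Each comparison decomposes into maximal
exact-match runs ``h_1..h_x`` separated by mismatch gaps ``d_{k,k+1}``; the
window similarity is

    h = { sum_x h_x!  +  sum_{x<y} h_x*h_y / prod_{k=x..y-1} (a_hat*d_{k,k+1} + 1) } ** nu

The per-gene similarity is the maximum over windows and strands.  The
candidate's score is then the similarity-weighted average of transformed
expression ratios over ALL genes:

    score = sum_n h(n) * r(n)**tau / sum_n h(n)

where r(n) is the gene's ratio after the down-regulation policy and the
``highest_r_score`` cap.  Because a window comparison of a k-bp candidate
has only 2**k possible match patterns, window similarities are computed
through a precomputed pattern lookup table, which makes scoring thousands
of candidates against thousands of promoters a handful of vectorized
passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .dna import encode, reverse_complement
from .sequence_io import ExpressionTable, PromoterSet

__all__ = [
    "ScoringParams",
    "MatchDecomposition",
    "CandidateScore",
    "match_runs",
    "h_score_window",
    "h_score_gene",
    "r_score",
    "mama_score",
    "score_candidates",
]

_FACTORIALS = [math.factorial(i) for i in range(9)]


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the scoring function.

    nu: sensitivity to sequence similarity (window similarity is raised to
        this power); tau: sensitivity to the expression ratio (applied to
        the capped ratio inside the weighted average); a_hat: mismatch-gap
        penalty in the cross-term denominators; highest_r_score: cap on the
        ratio; downregulated_policy: how ratios < 1 enter the average.
    """

    nu: int = 1
    tau: float = 1.0
    a_hat: float = 1.0
    highest_r_score: float = 10.0
    downregulated_policy: str = "set_to_one"

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError(f"nu must be >= 1, got {self.nu}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.a_hat < 0:
            raise ValueError(f"a_hat must be >= 0, got {self.a_hat}")
        if self.highest_r_score < 1:
            raise ValueError(f"highest_r_score must be >= 1, got {self.highest_r_score}")
        if self.downregulated_policy not in ("set_to_one", "remove", "reciprocal"):
            raise ValueError(f"unknown downregulated_policy {self.downregulated_policy!r}")


@dataclass(frozen=True)
class MatchDecomposition:
    """Maximal exact-match runs and the mismatch gaps between them."""

    run_lengths: tuple[int, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.gaps) != max(0, len(self.run_lengths) - 1):
            raise ValueError("need exactly one gap between consecutive runs")
        if any(h < 1 for h in self.run_lengths) or any(d < 1 for d in self.gaps):
            raise ValueError("run lengths and gaps must be positive")


@dataclass(frozen=True)
class CandidateScore:
    sequence: str
    mama_score: float
    n_contributing: int


def match_runs(candidate: str, window: str) -> MatchDecomposition:
    """Decompose an equal-length ungapped comparison into runs and gaps.

    'N' never matches anything (in either string).
    """
    if len(candidate) != len(window):
        raise ValueError(
            f"candidate ({len(candidate)}) and window ({len(window)}) lengths differ"
        )
    runs: list[int] = []
    gaps: list[int] = []
    run = gap = 0
    for a, b in zip(candidate, window):
        if a == b and a != "N":
            if run == 0 and runs:
                gaps.append(gap)
            gap = 0
            run += 1
        else:
            if run:
                runs.append(run)
                run = 0
            gap += 1
    if run:
        runs.append(run)
    return MatchDecomposition(tuple(runs), tuple(gaps))


def h_score_window(decomp: MatchDecomposition, params: ScoringParams) -> float:
    """Window similarity from a match decomposition (0 for no matches)."""
    runs, gaps = decomp.run_lengths, decomp.gaps
    if not runs:
        return 0.0
    total = float(sum(_FACTORIALS[h] if h < 9 else math.factorial(h) for h in runs))
    for x in range(len(runs)):
        for y in range(x + 1, len(runs)):
            term = float(runs[x] * runs[y])
            for k in range(x, y):  # cross terms divide by every gap factor between
                term /= params.a_hat * gaps[k] + 1.0
            total += term
    return total**params.nu


# --- pattern lookup machinery -------------------------------------------------
#
# A word-length ungapped comparison has only 2**word match patterns, and for
# word <= 8 both sequences pack into 16-bit two-bit codes whose XOR fully
# determines the pattern; window scores then come from one XOR pass and one
# 65536-entry table gather.

@lru_cache(maxsize=32)
def _pattern_table(word: int, a_hat: float) -> np.ndarray:
    """nu=1 window similarity for every 2**word match/mismatch pattern.

    Bit ``word-1-j`` of the pattern index is 1 iff position ``j`` matches.
    """
    params = ScoringParams(nu=1, a_hat=a_hat)
    table = np.empty(1 << word, dtype=np.float64)
    for pattern in range(1 << word):
        runs: list[int] = []
        gaps: list[int] = []
        run = gap = 0
        for j in range(word):
            if pattern & (1 << (word - 1 - j)):
                if run == 0 and runs:
                    gaps.append(gap)
                gap = 0
                run += 1
            else:
                if run:
                    runs.append(run)
                    run = 0
                gap += 1
        if run:
            runs.append(run)
        table[pattern] = h_score_window(
            MatchDecomposition(tuple(runs), tuple(gaps)), params
        )
    return table


@lru_cache(maxsize=32)
def _xor_score_table(word: int, a_hat: float) -> np.ndarray:
    """nu=1 window similarity indexed by XOR of packed two-bit encodings."""
    if word > 8:
        raise ValueError("packed scan supports word lengths up to 8")
    pattern_scores = _pattern_table(word, a_hat)
    xors = np.arange(1 << (2 * word), dtype=np.uint32)
    patterns = np.zeros(len(xors), dtype=np.uint16)
    for j in range(word):
        digit = (xors >> np.uint32(2 * (word - 1 - j))) & np.uint32(3)
        patterns |= (digit == 0).astype(np.uint16) << np.uint16(word - 1 - j)
    return pattern_scores[patterns]


def _pack_windows(codes: np.ndarray, word: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-bit-packed value of every window, plus an N-free validity mask.

    N positions are packed as 0 (aliasing A); windows touching an N are
    reported invalid so callers can zero them out.
    """
    n_win = len(codes) - word + 1
    is_n = codes >= 4
    packed = np.zeros(n_win, dtype=np.uint16)
    has_n = np.zeros(n_win, dtype=bool)
    safe = np.where(is_n, 0, codes).astype(np.uint16)
    for j in range(word):
        packed |= safe[j : j + n_win] << np.uint16(2 * (word - 1 - j))
        has_n |= is_n[j : j + n_win]
    return packed, ~has_n


def _pack_kmers(cand_codes: np.ndarray) -> np.ndarray:
    word = cand_codes.shape[1]
    weights = (4 ** np.arange(word - 1, -1, -1)).astype(np.uint16)
    return (cand_codes.astype(np.uint16) * weights).sum(axis=1, dtype=np.uint16)


def _window_patterns(cand_codes: np.ndarray, seq_codes: np.ndarray) -> np.ndarray:
    """Match-pattern index of every candidate against every window.

    cand_codes: (n_cand, word) uint8; seq_codes: 1-D uint8.
    Returns (n_cand, n_windows) uint16 (word <= 16).
    """
    word = cand_codes.shape[1]
    n_win = len(seq_codes) - word + 1
    if n_win <= 0:
        return np.empty((cand_codes.shape[0], 0), dtype=np.uint16)
    patterns = np.zeros((cand_codes.shape[0], n_win), dtype=np.uint16)
    for j in range(word):
        cand_col = cand_codes[:, j : j + 1]
        # N (code 4) on either side never matches
        match = (cand_col == seq_codes[np.newaxis, j : j + n_win]) & (cand_col < 4)
        patterns |= match.astype(np.uint16) << (word - 1 - j)
    return patterns


def h_score_gene(candidate: str, promoter: str, params: ScoringParams) -> float:
    """Best window similarity of *candidate* over both strands of *promoter*."""
    word = len(candidate)
    if word == 0:
        raise ValueError("empty candidate")
    if len(promoter) < word:
        return 0.0
    table = _pattern_table(word, params.a_hat)
    cand = encode(candidate)[np.newaxis, :]
    best = 0.0
    for seq in (promoter, reverse_complement(promoter)):
        patterns = _window_patterns(cand, encode(seq))
        if patterns.size:
            best = max(best, float(table[patterns].max()))
    return best**params.nu


def r_score(ratio: float, params: ScoringParams) -> float:
    """Policy-adjusted, capped expression ratio (tau is NOT applied here)."""
    if ratio <= 0:
        raise ValueError(f"expression ratio must be > 0, got {ratio}")
    if ratio < 1.0:
        if params.downregulated_policy == "set_to_one":
            ratio = 1.0
        elif params.downregulated_policy == "reciprocal":
            ratio = 1.0 / ratio
        else:  # "remove": the gene should have been excluded upstream
            raise ValueError(
                "r_score called for a downregulated gene under policy 'remove'"
            )
    return min(ratio, params.highest_r_score)


def _active_genes(
    promoters: PromoterSet, expr: ExpressionTable, params: ScoringParams
) -> list[str]:
    genes = [g for g in promoters.records if g in expr.ratios]
    if params.downregulated_policy == "remove":
        genes = [g for g in genes if expr.ratios[g] >= 1.0]
    if not genes:
        raise ValueError("no genes left to score")
    return genes


def _gene_h_matrix(
    cand_codes: np.ndarray,
    sequences: Sequence[str],
    params: ScoringParams,
) -> np.ndarray:
    """(n_cand, n_genes) matrix of per-gene similarities h**nu.

    Promoters are concatenated with 'N' separators so the whole scan is a
    few array passes; per-gene maxima come from segment reductions over the
    forward and reverse-complement concatenations.
    """
    word = cand_codes.shape[1]
    if (cand_codes > 3).any():
        raise ValueError("candidates must be N-free A/C/G/T strings")
    table = _pattern_table(word, params.a_hat)
    lut = _xor_score_table(word, params.a_hat)
    packed_cands = _pack_kmers(cand_codes)
    n_cand = cand_codes.shape[0]
    best = np.zeros((n_cand, len(sequences)), dtype=np.float64)
    keep = [i for i, s in enumerate(sequences) if len(s) >= word]
    if not keep:
        return best
    for rc in (False, True):
        strand_seqs = [
            reverse_complement(sequences[i]) if rc else sequences[i] for i in keep
        ]
        concat = ("N" * word).join(strand_seqs)
        codes = encode(concat)
        n_win = len(codes) - word + 1
        # only windows fully inside a single promoter count; windows that
        # reach into a separator or the next gene contain an N and are
        # masked out together with the out-of-gene starts
        starts = np.empty(len(keep), dtype=np.intp)
        inside = np.zeros(n_win, dtype=bool)
        pos = 0
        for k, s in enumerate(strand_seqs):
            starts[k] = pos
            inside[pos : pos + len(s) - word + 1] = True
            pos += len(s) + word
        packed, n_free = _pack_windows(codes, word)
        fast_valid = inside & n_free
        # interior windows touching a real N still score their non-N
        # matches; handle those few columns through the generic path
        slow_cols = np.nonzero(inside & ~n_free)[0]
        slow_codes = (
            np.stack([codes[c : c + word] for c in slow_cols]) if len(slow_cols) else None
        )
        # chunk candidates to bound the score matrix at ~256 MB
        chunk = max(1, (256 << 20) // max(1, 10 * n_win))
        for i in range(0, n_cand, chunk):
            xors = packed_cands[i : i + chunk, np.newaxis] ^ packed[np.newaxis, :]
            scores = lut[xors]
            scores *= fast_valid
            if slow_codes is not None:
                sub_cands = cand_codes[i : i + chunk]
                match = sub_cands[:, np.newaxis, :] == slow_codes[np.newaxis, :, :]
                weights = 1 << np.arange(word - 1, -1, -1)
                patterns = (match * weights).sum(axis=2)
                scores[:, slow_cols] = table[patterns]
            gene_max = np.maximum.reduceat(scores, starts, axis=1)
            sub = best[i : i + chunk, keep]
            best[i : i + chunk, keep] = np.maximum(sub, gene_max)
    if params.nu != 1:
        best **= params.nu
    return best


def score_candidates(
    candidates: Sequence[str],
    promoters: PromoterSet,
    expr: ExpressionTable,
    params: ScoringParams = ScoringParams(),
) -> list[CandidateScore]:
    """Score many candidates at once (vectorized); order preserved."""
    if not len(promoters.records):
        raise ValueError("empty promoter set")
    word_lengths = {len(c) for c in candidates}
    if len(word_lengths) > 1:
        raise ValueError("all candidates must share one length")
    if not candidates:
        return []
    genes = _active_genes(promoters, expr, params)
    r = np.array([r_score(expr.ratios[g], params) for g in genes])
    r_tau = r**params.tau
    cand_codes = np.vstack([encode(c) for c in candidates])
    h = _gene_h_matrix(cand_codes, [promoters.records[g] for g in genes], params)
    denom = h.sum(axis=1)
    numer = h @ r_tau
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    n_contrib = (h > 0).sum(axis=1)
    return [
        CandidateScore(c, float(s), int(n))
        for c, s, n in zip(candidates, scores, n_contrib)
    ]


def mama_score(
    candidate: str,
    promoters: PromoterSet,
    expr: ExpressionTable,
    params: ScoringParams = ScoringParams(),
) -> CandidateScore:
    """Similarity-weighted average expression score of one candidate."""
    return score_candidates([candidate], promoters, expr, params)[0]
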