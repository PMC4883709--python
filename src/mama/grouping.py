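"""Candidate enumeration, ranking, and grouping of similar 8-mers.

Candidates are every N-free 8-bp substring of the most up-regulated genes'
promoters.  After scoring, the top fraction of the ranking seed motif
groups; lower-ranked candidates within the mismatch budget of a seed join
that seed's group (highest-ranked eligible seed wins, each candidate in at
most one group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dna import BASES, encode, reverse_complement
from .scoring import CandidateScore
from .sequence_io import ExpressionTable, PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "MotifGroup",
    "enumerate_candidates",
    "rank_candidates",
    "group_motifs",
    "build_pcm",
    "write_groups_tsv",
    "write_meme_motifs",
]


@dataclass
class MotifGroup:
    """A seed 8-mer plus the lower-scoring candidates grouped under it."""

    seed: str
    members: list[str]
    seed_score: float
    pcm: np.ndarray  # 4 x word counts over members, rows A,C,G,T

    @property
    def name(self) -> str:
        return self.seed

    @property
    def word(self) -> int:
        return len(self.seed)

    def frequencies(self) -> np.ndarray:
        """Per-position base frequencies (logo heights)."""
        return self.pcm / self.pcm.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pcm.argmax(axis=0))


def enumerate_candidates(
    promoters: PromoterSet,
    expr: ExpressionTable,
    top_k: int = 50,
    word: int = 8,
) -> set[str]:
    """All distinct N-free *word*-mers from the top_k most up-regulated genes.

    Genes are ranked by descending expression ratio, ties broken by gene ID;
    substrings are taken from the stored (forward) strand.
    """
    genes = [g for g in promoters.records if g in expr.ratios]
    if top_k > len(genes):
        raise ValueError(f"top_k={top_k} exceeds the {len(genes)} paired genes")
    genes.sort(key=lambda g: (-expr.ratios[g], g))
    candidates: set[str] = set()
    for g in genes[:top_k]:
        seq = promoters.records[g]
        for i in range(len(seq) - word + 1):
            kmer = seq[i : i + word]
            if "N" not in kmer:
                candidates.add(kmer)
    if not candidates:
        raise ValueError(f"no promoter of the top {top_k} genes is >= {word} bp")
    return candidates


def rank_candidates(scores: Iterable[CandidateScore]) -> list[CandidateScore]:
    """Descending score; ties broken lexicographically by sequence."""
    return sorted(scores, key=lambda s: (-s.mama_score, s.sequence))


def group_motifs(
    ranked: Sequence[CandidateScore],
    top_fraction: float = 0.05,
    max_mismatch: int = 2,
) -> list[MotifGroup]:
    """Greedy grouping of a ranked candidate list.

    Walking the ranking top-down, an ungrouped candidate in the top
    *top_fraction* becomes a seed and absorbs every strictly lower-ranked,
    still ungrouped candidate within Hamming distance *max_mismatch*
    (forward orientation, equal length).
    """
    if not ranked:
        raise ValueError("ranked candidate list is empty")
    n_seedable = int(len(ranked) * top_fraction)
    if n_seedable == 0:
        logger.warning("top_fraction %.3g yields no seedable candidates", top_fraction)
        return []
    seqs = np.vstack([encode(c.sequence) for c in ranked])
    grouped = np.zeros(len(ranked), dtype=bool)
    groups: list[MotifGroup] = []
    for i in range(n_seedable):
        if grouped[i]:
            continue
        grouped[i] = True
        dist = (seqs[i + 1 :] != seqs[i]).sum(axis=1)
        member_idx = np.nonzero((dist <= max_mismatch) & ~grouped[i + 1 :])[0] + i + 1
        grouped[member_idx] = True
        members = [ranked[i].sequence] + [ranked[j].sequence for j in member_idx]
        group = MotifGroup(
            seed=ranked[i].sequence,
            members=members,
            seed_score=ranked[i].mama_score,
            pcm=np.zeros((4, seqs.shape[1]), dtype=np.int64),
        )
        group.pcm = build_pcm(group)
        groups.append(group)
    _log_revcomp_pairs(groups)
    return groups


def _log_revcomp_pairs(groups: list[MotifGroup]) -> None:
    """Strand-symmetric scoring surfaces both orientations; note the pairs."""
    seeds = {g.seed for g in groups}
    for g in groups:
        rc = reverse_complement(g.seed)
        if rc in seeds and rc > g.seed:
            logger.info("seeds %s and %s are reverse complements", g.seed, rc)


def build_pcm(group: MotifGroup) -> np.ndarray:
    """4 x word position-count matrix (rows A, C, G, T) over group members."""
    if not group.members:
        raise ValueError("cannot build a count matrix from zero members")
    word = len(group.seed)
    pcm = np.zeros((4, word), dtype=np.int64)
    for m in group.members:
        if len(m) != word:
            raise ValueError(f"member {m!r} length differs from seed {group.seed!r}")
        codes = encode(m)
        if (codes > 3).any():
            raise ValueError(f"member {m!r} contains non-ACGT characters")
        pcm[codes, np.arange(word)] += 1
    return pcm


def write_groups_tsv(path: str | Path, groups: Sequence[MotifGroup]) -> None:
    with open(path, "w") as fh:
        fh.write("seed\tscore\tn_members\tmembers\n")
        for g in groups:
            fh.write(f"{g.seed}\t{g.seed_score:.6g}\t{len(g.members)}\t{','.join(g.members)}\n")


def write_meme_motifs(path: str | Path, groups: Sequence[MotifGroup]) -> None:
    """Minimal MEME-format frequency matrices for external scanners."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for g in groups:
            freq = g.frequencies()
            fh.write(f"MOTIF {g.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {g.word} "
                f"nsites= {len(g.members)} E= 0\n"
            )
            for col in range(g.word):
                fh.write(" ".join(f"{freq[row, col]:.6f}" for row in range(4)) + "\n")
            fh.write("\n")
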