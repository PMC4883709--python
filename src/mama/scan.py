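"""Locating motif occurrences relative to the TSS.

A "hit" is an exact match of any group member on either strand; it is
anchored at the leftmost (stored-strand 5'-most) base of the matched
window, and region membership is decided by that anchor under half-open
``[start, end)`` accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dna import reverse_complement
from .grouping import MotifGroup
from .sequence_io import PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "GeneSetCounts",
    "scan_motif",
    "genes_with_hit",
    "cover_ratio",
    "positional_distribution",
    "binomial_enrichment_pvalue",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    position: int  # TSS-relative offset of the leftmost base of the match
    strand: str
    member: str


@dataclass(frozen=True)
class GeneSetCounts:
    """Bookkeeping for enrichment summaries."""

    N: int
    N_A: int
    N_UP: int

    def __post_init__(self) -> None:
        if not (0 <= self.N_A <= self.N and 0 <= self.N_UP <= self.N):
            raise ValueError("inconsistent gene-set counts")


def _member_lookup(group: MotifGroup) -> dict[str, tuple[str, str]]:
    """Map searchable k-mer -> (member, strand on the stored sequence)."""
    lookup: dict[str, tuple[str, str]] = {}
    for m in group.members:
        lookup.setdefault(m, (m, "+"))
        rc = reverse_complement(m)
        lookup.setdefault(rc, (m, "-"))
    return lookup


def scan_motif(
    group: MotifGroup,
    promoters: PromoterSet,
    region: tuple[int, int] | None = None,
    gene_subset: Iterable[str] | None = None,
) -> list[MotifHit]:
    """Exact-match occurrences of any group member, both strands.

    Overlapping hits are all reported.  A hit counts when its anchor lies
    in ``[region.start, region.end)``.
    """
    if region is None:
        region = promoters.region
    lookup = _member_lookup(group)
    word = group.word
    genes = promoters.gene_ids if gene_subset is None else list(gene_subset)
    hits: list[MotifHit] = []
    for gid in genes:
        seq = promoters.records[gid]
        offset0 = promoters.start_offsets[gid]
        for i in range(len(seq) - word + 1):
            kmer = seq[i : i + word]
            entry = lookup.get(kmer)
            if entry is None:
                continue
            pos = offset0 + i
            if region[0] <= pos < region[1]:
                hits.append(MotifHit(gid, pos, entry[1], entry[0]))
    return hits


def genes_with_hit(
    group: MotifGroup,
    promoters: PromoterSet,
    region: tuple[int, int],
    gene_subset: Iterable[str] | None = None,
) -> set[str]:
    """Genes whose region contains at least one hit."""
    return {h.gene_id for h in scan_motif(group, promoters, region, gene_subset)}


def cover_ratio(
    group: MotifGroup,
    promoters: PromoterSet,
    gene_subset: Iterable[str],
    region: tuple[int, int],
) -> float:
    """Fraction of the gene subset whose region contains the motif."""
    subset = list(gene_subset)
    if not subset:
        raise ValueError("empty gene subset")
    carriers = genes_with_hit(group, promoters, region, subset)
    return len(carriers) / len(subset)


def positional_distribution(
    group: MotifGroup,
    promoters: PromoterSet,
    gene_subset: Iterable[str],
    window_bp: int = 50,
    span: tuple[int, int] = (-3000, 2000),
    reference: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Hit frequency per fixed-width position window, raw and normalized.

    Raw series: hit count per window divided by the subset size.  The
    normalized series divides by the mean per-window frequency of the
    reference set (default: all genes in the promoter set) over the span.
    """
    subset = list(gene_subset)
    if not subset:
        raise ValueError("empty gene subset")
    ref = promoters.gene_ids if reference is None else list(reference)
    edges = np.arange(span[0], span[1] + window_bp, window_bp)
    edges = edges[edges <= span[1]]
    if edges[-1] < span[1]:
        edges = np.append(edges, span[1])

    def per_gene_freq(genes: list[str]) -> np.ndarray:
        positions = [h.position for h in scan_motif(group, promoters, span, genes)]
        counts, _ = np.histogram(positions, bins=edges)
        return counts / len(genes)

    raw = per_gene_freq(subset)
    ref_freq = per_gene_freq(ref)
    baseline = ref_freq.mean()
    normalized = raw / baseline if baseline > 0 else np.full_like(raw, np.nan)
    return {
        "window_start": edges[:-1],
        "raw": raw,
        "normalized": normalized,
        "reference_raw": ref_freq,
    }


def _region_window_count(
    promoters: PromoterSet, genes: Iterable[str], region: tuple[int, int], word: int
) -> int:
    """Number of word-length windows (both strands) in the genes' regions."""
    total = 0
    for gid in genes:
        gs = promoters.start_offsets[gid]
        ge = gs + len(promoters.records[gid])
        lo, hi = max(region[0], gs), min(region[1], ge)
        if hi - lo >= word:
            total += 2 * (hi - lo - word + 1)
    return total


def binomial_enrichment_pvalue(
    group: MotifGroup,
    regulated: Iterable[str],
    all_genes: Iterable[str],
    promoters: PromoterSet,
    region: tuple[int, int] = (-500, 0),
) -> float:
    """Upper-tail binomial P for motif-occurrence excess in regulated genes.

    k = occurrences (per hit, both strands) in regulated genes' regions,
    n = number of 8-bp windows there, p = the occurrence rate in all genes.
    Reported descriptively; never used for ranking.
    """
    regulated = list(regulated)
    all_genes = list(all_genes)
    word = group.word
    # count hits on both strands; a palindromic member matches both strands
    # at one locus but scan_motif reports one hit per locus, so double-count
    # palindromes explicitly for window-rate consistency
    def occurrences(genes: list[str]) -> int:
        hits = scan_motif(group, promoters, region, genes)
        return sum(
            2 if h.member == reverse_complement(h.member) else 1 for h in hits
        )

    k = occurrences(regulated)
    n = _region_window_count(promoters, regulated, region, word)
    k_all = occurrences(all_genes)
    n_all = _region_window_count(promoters, all_genes, region, word)
    if n_all == 0 or n == 0:
        raise ValueError("no scannable windows in the requested region")
    p = k_all / n_all
    if p == 0:
        if k > 0:
            logger.warning("degenerate enrichment test: p=0 with k=%d", k)
            return 0.0
        return 1.0
    if set(regulated) == set(all_genes):
        logger.info("regulated set equals reference set; P-value non-informative")
    return float(stats.binom.sf(k - 1, n, min(p, 1.0)))


def write_hits_tsv(path: str | Path, hits: Sequence[MotifHit], word: int) -> None:
    """BED-like TSV of hits in TSS-relative coordinates."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tmember\tstrand\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.position}\t{h.position + word}\t{h.member}\t{h.strand}\n")
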