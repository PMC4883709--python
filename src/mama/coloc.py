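"""Pairwise motif co-occurrence statistics in a TSS-anchored region.

For motifs A and B, genes are cross-tabulated by presence of A, presence
of B and up-regulation into eight cells.  The four up-regulated cells are
tested against expectations derived from the non-up-regulated cells:

    E[cell|UP] = N(UP) * cell|!UP / N(!UP),   X^2 = sum (O - E)^2 / E

with the chi-square upper tail at 3 degrees of freedom.  Two conditional
enrichments accompany the test:

    EN1 = [N(A|B|UP)/N(B|UP)]  / [N(A|!B|UP)/N(!B|UP)]
    EN2 = [N(A|B|UP)/N(B|UP)]  / [N(A|B|!UP)/N(B|!UP)]

Pairs whose groups share a member sequence are never evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .grouping import MotifGroup
from .scan import genes_with_hit, scan_motif
from .sequence_io import PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "PairCounts",
    "PairStats",
    "PairSelection",
    "SharedMemberError",
    "pair_counts",
    "chi_square_pair",
    "enrichment_EN",
    "separation_histogram",
    "evaluate_pair",
    "evaluate_all_pairs",
    "select_enriched_pairs",
    "write_pair_table",
]

PAIR_REGION = (-500, 150)


class SharedMemberError(ValueError):
    """Raised when two groups share a member sequence (pair not evaluable)."""


@dataclass(frozen=True)
class PairCounts:
    """The eight observed cells N(A?|B?|UP?) of a motif pair."""

    ab_up: int
    nab_up: int    # !A, B
    anb_up: int    # A, !B
    nanb_up: int
    ab_nup: int
    nab_nup: int
    anb_nup: int
    nanb_nup: int

    @property
    def n_up(self) -> int:
        return self.ab_up + self.nab_up + self.anb_up + self.nanb_up

    @property
    def n_nup(self) -> int:
        return self.ab_nup + self.nab_nup + self.anb_nup + self.nanb_nup

    def up_cells(self) -> np.ndarray:
        return np.array([self.ab_up, self.nab_up, self.anb_up, self.nanb_up], dtype=float)

    def nup_cells(self) -> np.ndarray:
        return np.array([self.ab_nup, self.nab_nup, self.anb_nup, self.nanb_nup], dtype=float)


@dataclass
class PairStats:
    motif_a: str
    motif_b: str
    counts: PairCounts
    chi2: float = np.nan
    p_value: float = np.nan
    en1: float = np.nan
    en2: float = np.nan
    testable: bool = False
    separations: dict | None = field(default=None, repr=False)

    @property
    def name(self) -> str:
        return f"{self.motif_a}~{self.motif_b}"


@dataclass
class PairSelection:
    pairs: list[PairStats]
    n_mp: int


def pair_counts(
    a: MotifGroup,
    b: MotifGroup,
    promoters: PromoterSet,
    up_labels: Mapping[str, bool],
    region: tuple[int, int] = PAIR_REGION,
) -> PairCounts:
    """Cross-tabulate per-gene presence of A and B split by the UP label."""
    if set(a.members) & set(b.members):
        raise SharedMemberError(
            f"groups {a.name} and {b.name} share member sequences; pair skipped"
        )
    genes = [g for g in promoters.records if g in up_labels]
    has_a = genes_with_hit(a, promoters, region, genes)
    has_b = genes_with_hit(b, promoters, region, genes)
    return _tabulate(genes, has_a, has_b, up_labels)


def _tabulate(genes, has_a, has_b, up_labels) -> PairCounts:
    cells = np.zeros((2, 2, 2), dtype=int)  # [A][B][UP]
    for g in genes:
        cells[int(g in has_a), int(g in has_b), int(bool(up_labels[g]))] += 1
    return PairCounts(
        ab_up=cells[1, 1, 1], nab_up=cells[0, 1, 1],
        anb_up=cells[1, 0, 1], nanb_up=cells[0, 0, 1],
        ab_nup=cells[1, 1, 0], nab_nup=cells[0, 1, 0],
        anb_nup=cells[1, 0, 0], nanb_nup=cells[0, 0, 0],
    )


def chi_square_pair(counts: PairCounts) -> tuple[float, float]:
    """Chi-square statistic and upper-tail P for the four UP cells (df=3)."""
    if counts.n_nup == 0:
        raise ValueError("no non-up-regulated genes; expectations undefined")
    observed = counts.up_cells()
    expected = counts.n_up * counts.nup_cells() / counts.n_nup
    if (expected == 0).any():
        raise ValueError("zero expected cell; pair untestable")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=3))
    return chi2, p


def enrichment_EN(counts: PairCounts) -> tuple[float, float]:
    """Conditional enrichments of A given B (EN1: vs !B; EN2: vs !UP)."""
    n_b_up = counts.ab_up + counts.nab_up
    n_nb_up = counts.anb_up + counts.nanb_up
    n_b_nup = counts.ab_nup + counts.nab_nup
    if n_b_up == 0 or n_nb_up == 0 or n_b_nup == 0:
        raise ValueError("zero denominator; pair untestable")
    rate_ab_up = counts.ab_up / n_b_up

    def _ratio(num: float, ref: float) -> float:
        if ref == 0:
            if num == 0:
                raise ValueError("0/0 enrichment; pair untestable")
            return float("inf")
        return num / ref

    en1 = _ratio(rate_ab_up, counts.anb_up / n_nb_up)
    en2 = _ratio(rate_ab_up, counts.ab_nup / n_b_nup)
    return en1, en2


def evaluate_pair(
    a: MotifGroup,
    b: MotifGroup,
    promoters: PromoterSet,
    up_labels: Mapping[str, bool],
    region: tuple[int, int] = PAIR_REGION,
) -> PairStats:
    """Counts + chi-square + enrichments for one pair; flags untestables."""
    counts = pair_counts(a, b, promoters, up_labels, region)
    result = PairStats(a.name, b.name, counts)
    try:
        result.chi2, result.p_value = chi_square_pair(counts)
        result.en1, result.en2 = enrichment_EN(counts)
        result.testable = True
    except ValueError as exc:
        logger.info("pair %s untestable: %s", result.name, exc)
    return result


def evaluate_all_pairs(
    groups: Sequence[MotifGroup],
    promoters: PromoterSet,
    up_labels: Mapping[str, bool],
    region: tuple[int, int] = PAIR_REGION,
) -> list[PairStats]:
    """All unordered group pairs; pairs sharing members are skipped.

    Per-group gene presence is computed once and reused across pairs.
    """
    genes = [g for g in promoters.records if g in up_labels]
    presence = {
        g.name: genes_with_hit(g, promoters, region, genes) for g in groups
    }
    members = {g.name: set(g.members) for g in groups}
    results: list[PairStats] = []
    for a, b in combinations(groups, 2):
        if members[a.name] & members[b.name]:
            logger.info("groups %s and %s share members; pair skipped", a.name, b.name)
            continue
        counts = _tabulate(genes, presence[a.name], presence[b.name], up_labels)
        result = PairStats(a.name, b.name, counts)
        try:
            result.chi2, result.p_value = chi_square_pair(counts)
            result.en1, result.en2 = enrichment_EN(counts)
            result.testable = True
        except ValueError as exc:
            logger.info("pair %s untestable: %s", result.name, exc)
        results.append(result)
    return results


def select_enriched_pairs(all_pairs: Iterable[PairStats], n_mp: int) -> PairSelection:
    """Testable pairs with EN1 > 1 and EN2 > 1, lowest P first, top n_mp."""
    if n_mp < 0:
        raise ValueError("n_mp must be >= 0")
    eligible = [
        p for p in all_pairs if p.testable and p.en1 > 1.0 and p.en2 > 1.0
    ]
    eligible.sort(key=lambda p: (p.p_value, p.name))
    if len(eligible) < n_mp:
        logger.warning("only %d eligible pairs for n_mp=%d", len(eligible), n_mp)
    return PairSelection(pairs=eligible[:n_mp], n_mp=n_mp)


def separation_histogram(
    a: MotifGroup,
    b: MotifGroup,
    promoters: PromoterSet,
    gene_subset: Iterable[str],
    region: tuple[int, int] = PAIR_REGION,
    bin_bp: int = 50,
) -> dict[str, np.ndarray]:
    """Signed offsets position(A) - position(B) over all co-occurring hits.

    Bins are *bin_bp* wide and centered on multiples of *bin_bp* (for the
    default 50 bp: [-25, 25), [25, 75), ...).  Counts are normalized by the
    subset size.
    """
    subset = list(gene_subset)
    if not subset:
        raise ValueError("empty gene subset")
    hits_a: dict[str, list[int]] = {}
    for h in scan_motif(a, promoters, region, subset):
        hits_a.setdefault(h.gene_id, []).append(h.position)
    seps: list[int] = []
    for h in scan_motif(b, promoters, region, subset):
        for pa in hits_a.get(h.gene_id, ()):
            seps.append(pa - h.position)
    width = region[1] - region[0]
    max_center = (width // bin_bp + 1) * bin_bp
    centers = np.arange(-max_center, max_center + bin_bp, bin_bp)
    edges = np.append(centers - bin_bp / 2, centers[-1] + bin_bp / 2)
    counts, _ = np.histogram(seps, bins=edges)
    return {
        "bin_center": centers,
        "count": counts,
        "normalized": counts / len(subset),
        "n_pairs": np.array(len(seps)),
    }


def write_pair_table(path: str | Path, pairs: Sequence[PairStats]) -> None:
    cols = [
        "motif_a", "motif_b",
        "n_ab_up", "n_nab_up", "n_anb_up", "n_nanb_up",
        "n_ab_nup", "n_nab_nup", "n_anb_nup", "n_nanb_nup",
        "chi2", "p_value", "en1", "en2", "testable",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in pairs:
            c = p.counts
            fh.write(
                f"{p.motif_a}\t{p.motif_b}\t"
                f"{c.ab_up}\t{c.nab_up}\t{c.anb_up}\t{c.nanb_up}\t"
                f"{c.ab_nup}\t{c.nab_nup}\t{c.anb_nup}\t{c.nanb_nup}\t"
                f"{p.chi2:.6g}\t{p.p_value:.6g}\t{p.en1:.6g}\t{p.en2:.6g}\t"
                f"{int(p.testable)}\n"
            )
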