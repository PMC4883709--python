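"""Sequence, annotation and expression-table I/O plus promoter assembly.

Coordinate convention used throughout: the transcription start site (TSS)
is 0, upstream offsets are negative, and promoter windows are half-open
``[start_offset, end_offset)`` intervals so that window length equals
``end_offset - start_offset``.  Promoters are always returned 5'->3' on the
coding strand (i.e. reading toward/through the TSS), so minus-strand genes
yield the reverse complement of the mirrored genomic window.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .dna import reverse_complement, validate_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "PromoterSet",
    "ExpressionTable",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "read_expression_table",
    "extract_promoters",
    "merge_identical_promoters",
    "pair_promoters_expression",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS location: one TSS per gene ID is taken as given."""

    gene_id: str
    chromosome: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class PromoterSet:
    """TSS-anchored sequences per gene with a shared coordinate window.

    ``region`` is ``(start_offset, end_offset)`` relative to the TSS.
    Sequences may be shorter than the window (chromosome-end truncation);
    truncated sequences are right-anchored at ``end_offset`` when the
    truncation removed the upstream end, which is recorded per gene in
    ``start_offsets``.
    """

    region: tuple[int, int]
    records: dict[str, str]
    #: actual start offset per gene (== region[0] unless truncated upstream)
    start_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        start, end = self.region
        if start >= end:
            raise ValueError(f"empty region {self.region}")
        width = end - start
        for gid, seq in self.records.items():
            if len(seq) > width:
                raise ValueError(
                    f"{gid}: sequence length {len(seq)} exceeds window {width}"
                )
            self.start_offsets.setdefault(gid, end - len(seq))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def subregion(self, region: tuple[int, int]) -> "PromoterSet":
        """Restrict every promoter to *region* (clipped to this set's window)."""
        start, end = region
        s0, e0 = self.region
        start, end = max(start, s0), min(end, e0)
        if start >= end:
            raise ValueError(f"subregion {region} does not overlap {self.region}")
        records: dict[str, str] = {}
        offsets: dict[str, int] = {}
        for gid, seq in self.records.items():
            gs = self.start_offsets[gid]
            lo = max(start, gs)
            sub = seq[lo - gs : end - gs]
            if sub:
                records[gid] = sub
                offsets[gid] = lo
        return PromoterSet(region=(start, end), records=records, start_offsets=offsets)


@dataclass
class ExpressionTable:
    """Per-gene treatment/control signal ratios (strictly positive)."""

    ratios: dict[str, float]

    def __post_init__(self) -> None:
        for gid, r in self.ratios.items():
            if not (r > 0) or not math.isfinite(r):
                raise ValueError(f"{gid}: ratio must be a positive finite number, got {r}")

    def __len__(self) -> int:
        return len(self.ratios)

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionTable":
        return ExpressionTable({g: self.ratios[g] for g in gene_ids})


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{gene_id: uppercase sequence}``.

    The gene ID is the first whitespace-delimited token of the header.
    Duplicate IDs and characters outside A/C/G/T/N are rejected.
    """
    path = Path(path)
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is not None:
            records[current] = validate_sequence("".join(chunks), context=current)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise ValueError(f"{path}: empty FASTA header")
                if current in records:
                    raise ValueError(f"{path}: duplicate sequence ID {current!r}")
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    _flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for gid, seq in records.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or 6-column BED (by extension).

    BED is 0-based half-open: TSS = start for '+', end-1 for '-'.
    GFF3 is 1-based closed: TSS = start-1 for '+', end-1 for '-'
    (converted to 0-based coordinates).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if suffix == ".bed":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED needs 6 columns")
                chrom, start, end, gid, _score, strand = fields[:6]
                tss = int(start) if strand == "+" else int(end) - 1
            else:  # GFF3
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
                if ftype not in ("gene", "mRNA", "transcript"):
                    continue
                gid = _gff3_id(attrs, path, lineno)
                tss = int(start) - 1 if strand == "+" else int(end) - 1
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            annotations.append(GeneAnnotation(gid, chrom, tss, strand))
    if not annotations:
        raise ValueError(f"{path}: no annotations found")
    return annotations


def _gff3_id(attrs: str, path: Path, lineno: int) -> str:
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith("ID="):
            return kv[3:]
    raise ValueError(f"{path}:{lineno}: GFF3 attributes lack an ID= tag")


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV/CSV with header columns ``gene_id`` and ``ratio``."""
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    ratios: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        cols = reader.fieldnames or []
        missing = [c for c in ("gene_id", "ratio") if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for rownum, row in enumerate(reader, 2):
            gid = row["gene_id"]
            if gid in ratios:
                raise ValueError(f"{path}: row {rownum}: duplicate gene_id {gid!r}")
            try:
                ratio = float(row["ratio"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {rownum}: non-numeric ratio {row['ratio']!r}"
                ) from None
            if not (ratio > 0) or not math.isfinite(ratio):
                raise ValueError(f"{path}: row {rownum}: ratio must be > 0, got {ratio}")
            ratios[gid] = ratio
    if not ratios:
        raise ValueError(f"{path}: no expression rows found")
    return ExpressionTable(ratios)


def extract_promoters(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    region: tuple[int, int],
) -> PromoterSet:
    """Cut TSS-anchored windows out of a genome.

    For '+' strand genes the window is ``genome[tss+start : tss+end)``; for
    '-' strand genes the mirrored window is cut and reverse complemented so
    that all returned sequences read 5'->3' toward/through the TSS.  Windows
    are truncated at chromosome ends (logged); genes whose window is empty
    after truncation are dropped with a warning.
    """
    start_off, end_off = region
    if start_off >= end_off:
        raise ValueError(f"invalid region {region}")
    records: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for ann in annotations:
        if ann.chromosome not in genome:
            raise KeyError(f"{ann.gene_id}: chromosome {ann.chromosome!r} not in genome")
        chrom_seq = genome[ann.chromosome]
        L = len(chrom_seq)
        if ann.strand == "+":
            lo, hi = ann.tss + start_off, ann.tss + end_off
        else:
            # mirror: offset o maps to genomic coordinate tss - o
            lo, hi = ann.tss - end_off + 1, ann.tss - start_off + 1
        clo, chi = max(lo, 0), min(hi, L)
        if clo >= chi:
            logger.warning("%s: promoter window empty after truncation; dropped", ann.gene_id)
            continue
        seq = chrom_seq[clo:chi].upper()
        if ann.strand == "-":
            seq = reverse_complement(seq)
        if len(seq) < end_off - start_off:
            logger.info(
                "%s: promoter truncated to %d bp at chromosome end", ann.gene_id, len(seq)
            )
        # actual start offset in TSS coordinates after truncation
        if ann.strand == "+":
            actual_start = clo - ann.tss
            actual_end = chi - ann.tss
        else:
            actual_start = ann.tss - chi + 1
            actual_end = ann.tss - clo + 1
        assert actual_end - actual_start == len(seq)
        records[ann.gene_id] = seq
        offsets[ann.gene_id] = actual_start
    return PromoterSet(region=region, records=records, start_offsets=offsets)


def pair_promoters_expression(
    promoters: PromoterSet, expr: ExpressionTable
) -> tuple[PromoterSet, ExpressionTable]:
    """Intersect a promoter set and an expression table on gene IDs.

    Genes present in only one of the two are dropped; the dropped count is
    logged.
    """
    common = [g for g in promoters.records if g in expr.ratios]
    dropped = (len(promoters) - len(common)) + (len(expr) - len(common))
    if dropped:
        logger.info("pairing dropped %d unmatched gene records", dropped)
    if not common:
        raise ValueError("no genes shared between promoters and expression table")
    sub = PromoterSet(
        region=promoters.region,
        records={g: promoters.records[g] for g in common},
        start_offsets={g: promoters.start_offsets[g] for g in common},
    )
    return sub, expr.subset(common)


def merge_identical_promoters(
    promoters: PromoterSet,
    expr: ExpressionTable,
    mapping_path: str | Path | None = None,
) -> tuple[PromoterSet, ExpressionTable]:
    """Collapse genes with byte-identical promoters into single records.

    The surviving ID is the lexicographically smallest member; the merged
    expression ratio is the geometric mean of the member ratios.  An
    optional JSON sidecar records the merge mapping.
    """
    by_seq: dict[str, list[str]] = {}
    for gid, seq in promoters.records.items():
        if gid not in expr.ratios:
            raise ValueError(f"{gid}: promoter present but no expression ratio")
        by_seq.setdefault(seq, []).append(gid)

    records: dict[str, str] = {}
    offsets: dict[str, int] = {}
    ratios: dict[str, float] = {}
    mapping: dict[str, list[str]] = {}
    for seq, members in by_seq.items():
        members.sort()
        rep = members[0]
        records[rep] = seq
        offsets[rep] = promoters.start_offsets[rep]
        if len(members) == 1:
            ratios[rep] = expr.ratios[rep]
        else:
            log_mean = sum(math.log(expr.ratios[m]) for m in members) / len(members)
            ratios[rep] = math.exp(log_mean)
        if len(members) > 1:
            mapping[rep] = members
            logger.info("merged identical promoters %s -> %s", members, rep)
    if mapping_path is not None:
        with open(mapping_path, "w") as fh:
            json.dump(mapping, fh, indent=2, sort_keys=True)
    merged = PromoterSet(region=promoters.region, records=records, start_offsets=offsets)
    return merged, ExpressionTable(ratios)
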