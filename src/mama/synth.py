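"""Synthetic promoter/expression generator with planted ground truth.

Backgrounds are i.i.d. draws over A/C/G/T; motifs (optionally mutated, and
optionally with a partner at a fixed separation) overwrite the background
at sampled positions in a controlled fraction of up-regulated and
background genes.  Expression ratios for designated up-regulated genes are
drawn uniformly above the up threshold; the rest are log-normal around 1.
Every insertion is recorded in a truth record so downstream stages can be
validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .dna import BASES
from .sequence_io import ExpressionTable, PromoterSet

__all__ = ["PlantSpec", "SynthConfig", "Insertion", "TruthRecord", "generate", "benchmark_scenario"]


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant, with carrier rates, placement, and mutation."""

    motif: str
    carrier_fraction_up: float = 0.8
    carrier_fraction_bg: float = 0.05
    position_mode: Literal["uniform", "fixed", "windowed"] = "uniform"
    position_args: tuple[int, ...] = ()  # fixed: (offset,); windowed: (lo, hi)
    per_base_mutation_prob: float = 0.0
    partner: tuple[str, int, int] | None = None  # (motif, separation_bp, jitter_bp)

    def __post_init__(self) -> None:
        for frac in (self.carrier_fraction_up, self.carrier_fraction_bg):
            if not 0 <= frac <= 1:
                raise ValueError(f"carrier fraction {frac} outside [0, 1]")
        if not 0 <= self.per_base_mutation_prob <= 1:
            raise ValueError("per_base_mutation_prob outside [0, 1]")
        if self.position_mode == "fixed" and len(self.position_args) != 1:
            raise ValueError("fixed placement needs (offset,)")
        if self.position_mode == "windowed" and len(self.position_args) != 2:
            raise ValueError("windowed placement needs (lo, hi)")


@dataclass
class SynthConfig:
    n_genes: int = 400
    region: tuple[int, int] = (-500, 150)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_up: int = 60
    up_ratio_range: tuple[float, float] = (3.0, 10.0)
    background_ratio_sigma: float = 0.25
    planted: list[PlantSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.n_up > self.n_genes:
            raise ValueError("n_up exceeds n_genes")


@dataclass(frozen=True)
class Insertion:
    gene_id: str
    motif: str           # the spec's motif (pre-mutation)
    inserted: str        # what actually went into the sequence
    position: int        # TSS-relative offset of the leftmost base


@dataclass
class TruthRecord:
    up_genes: list[str]
    insertions: list[Insertion]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "up_genes": self.up_genes,
                    "insertions": [asdict(i) for i in self.insertions],
                },
                fh,
                indent=2,
            )


def _sample_position(
    spec: PlantSpec, region: tuple[int, int], width: int, rng: np.random.Generator
) -> int:
    lo, hi = region
    if spec.position_mode == "fixed":
        return spec.position_args[0]
    if spec.position_mode == "windowed":
        lo, hi = spec.position_args
    # leftmost base offset such that the motif fits inside [lo, hi)
    last = hi - width
    if last < lo:
        raise ValueError(f"motif of width {width} cannot fit in [{lo}, {hi})")
    return int(rng.integers(lo, last + 1))


def _mutate(motif: str, prob: float, rng: np.random.Generator) -> str:
    if prob == 0:
        return motif
    out = []
    for b in motif:
        if rng.random() < prob:
            out.append(rng.choice([c for c in BASES if c != b]))
        else:
            out.append(b)
    return "".join(out)


def generate(config: SynthConfig) -> tuple[PromoterSet, ExpressionTable, TruthRecord]:
    """Generate promoters, ratios and the ground-truth insertion list."""
    rng = np.random.default_rng(config.seed)
    width = config.region[1] - config.region[0]
    n = config.n_genes
    digits = len(str(max(n - 1, 1)))
    gene_ids = [f"g{i:0{digits}d}" for i in range(n)]

    base_idx = rng.choice(4, size=(n, width), p=config.base_probs)
    seq_matrix = np.array(list(BASES), dtype="S1")[base_idx]
    gene_row = {g: i for i, g in enumerate(gene_ids)}

    up_genes = sorted(rng.choice(gene_ids, size=config.n_up, replace=False))
    up_set = set(up_genes)
    ratios: dict[str, float] = {}
    lo, hi = config.up_ratio_range
    for g in gene_ids:
        if g in up_set:
            ratios[g] = float(rng.uniform(lo, hi))
        else:
            ratios[g] = float(np.exp(rng.normal(0.0, config.background_ratio_sigma)))

    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    insertions: list[Insertion] = []

    def _overlaps(span: tuple[int, int], others: list[tuple[int, int]]) -> bool:
        return any(span[0] < oe and os_ < span[1] for os_, oe in others)

    def place(gene: str, motif_spec: PlantSpec) -> None:
        w = len(motif_spec.motif)
        partner = motif_spec.partner
        for attempt in range(100):
            pos = _sample_position(motif_spec, config.region, w, rng)
            spans = [(pos, pos + w)]
            motifs = [motif_spec.motif]
            if partner is not None:
                pm, sep, jitter = partner
                offset = sep + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
                ppos = pos + offset
                if not (config.region[0] <= ppos and ppos + len(pm) <= config.region[1]):
                    continue
                spans.append((ppos, ppos + len(pm)))
                motifs.append(pm)
            taken = list(occupied[gene])
            if not any(_overlaps(s, taken + spans[:i]) for i, s in enumerate(spans)):
                break
        else:
            raise RuntimeError(f"{gene}: could not place motif after 100 attempts")
        seq = seq_matrix[gene_row[gene]]
        for (s, _e), motif in zip(spans, motifs):
            inserted = _mutate(motif, motif_spec.per_base_mutation_prob, rng)
            i0 = s - config.region[0]
            seq[i0 : i0 + len(inserted)] = np.frombuffer(inserted.encode(), dtype="S1")
            occupied[gene].append((s, s + len(inserted)))
            insertions.append(Insertion(gene, motif, inserted, s))

    for spec in config.planted:
        bg_genes = [g for g in gene_ids if g not in up_set]
        n_carrier_up = round(spec.carrier_fraction_up * len(up_genes))
        n_carrier_bg = round(spec.carrier_fraction_bg * len(bg_genes))
        carriers = list(rng.choice(up_genes, size=n_carrier_up, replace=False)) + list(
            rng.choice(bg_genes, size=n_carrier_bg, replace=False)
        )
        for gene in carriers:
            place(gene, spec)

    records = {g: seq_matrix[gene_row[g]].tobytes().decode() for g in gene_ids}
    promoters = PromoterSet(region=config.region, records=records)
    return promoters, ExpressionTable(ratios), TruthRecord(up_genes, insertions)


def benchmark_scenario(name: str, seed: int = 0) -> SynthConfig:
    """Frozen named configurations used by the acceptance suite."""
    if name == "null":
        return SynthConfig(n_genes=400, n_up=60, planted=[], seed=seed)
    if name == "single_motif":
        return SynthConfig(
            n_genes=400,
            n_up=60,
            up_ratio_range=(3.0, 10.0),
            planted=[
                PlantSpec(
                    motif="ACGTACGT",
                    carrier_fraction_up=0.8,
                    carrier_fraction_bg=0.05,
                    position_mode="windowed",
                    position_args=(-500, 0),
                )
            ],
            seed=seed,
        )
    if name == "pair_coloc":
        return SynthConfig(
            n_genes=400,
            n_up=60,
            up_ratio_range=(3.0, 10.0),
            planted=[
                PlantSpec(
                    motif="ACGTACGT",
                    carrier_fraction_up=0.8,
                    carrier_fraction_bg=0.05,
                    position_mode="windowed",
                    position_args=(-480, -100),
                    partner=("TTGACCAT", 150, 10),
                ),
            ],
            seed=seed,
        )
    raise ValueError(f"unknown benchmark scenario {name!r}")
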