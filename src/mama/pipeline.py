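"""End-to-end composition of the discovery -> co-localization -> simulation
stages, shared by the CLI and the hyperparameter optimizer."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .coloc import PairSelection, evaluate_all_pairs, select_enriched_pairs
from .grouping import MotifGroup, enumerate_candidates, group_motifs, rank_candidates
from .scan import binomial_enrichment_pvalue
from .scoring import CandidateScore, ScoringParams, score_candidates
from .sequence_io import ExpressionTable, PromoterSet, pair_promoters_expression
from .simulate import (
    NEAR_TSS_REGION,
    PAIR_REGION,
    UPSTREAM_REGION,
    SimConfig,
    SimResult,
    build_features,
    make_labels,
    run_simulation,
)

logger = logging.getLogger(__name__)

__all__ = ["DiscoveryConfig", "DiscoveryResult", "discover", "simulate_once", "make_runner"]


@dataclass
class DiscoveryConfig:
    top_k: int = 50
    word: int = 8
    top_fraction: float = 0.05
    max_mismatch: int = 2
    region: tuple[int, int] = UPSTREAM_REGION
    #: cap on groups carried forward as classifier features
    max_motifs: int = 30


@dataclass
class DiscoveryResult:
    region: tuple[int, int]
    ranked: list[CandidateScore]
    groups: list[MotifGroup]

    def top_groups(self, n: int) -> list[MotifGroup]:
        return self.groups[:n]


def discover(
    promoters: PromoterSet,
    expr: ExpressionTable,
    params: ScoringParams = ScoringParams(),
    config: DiscoveryConfig = DiscoveryConfig(),
) -> DiscoveryResult:
    """Enumerate, score, rank and group candidates within one region."""
    promoters, expr = pair_promoters_expression(promoters, expr)
    scoped = promoters.subregion(config.region)
    candidates = sorted(
        enumerate_candidates(scoped, expr, top_k=config.top_k, word=config.word)
    )
    logger.info(
        "scoring %d candidates over %d genes in region %s",
        len(candidates), len(scoped), config.region,
    )
    scores = score_candidates(candidates, scoped, expr, params)
    ranked = rank_candidates(scores)
    groups = group_motifs(ranked, config.top_fraction, config.max_mismatch)
    logger.info("grouped into %d motifs", len(groups))
    return DiscoveryResult(region=config.region, ranked=ranked, groups=groups)


def enrichment_table(
    result: DiscoveryResult,
    promoters: PromoterSet,
    expr: ExpressionTable,
    up_threshold: float = 2.0,
    region: tuple[int, int] = (-500, 0),
) -> list[tuple[str, float, float]]:
    """(seed, score, binomial P) per group, for the ranked motif report."""
    labels = make_labels(expr, up_threshold)
    regulated = [g for g in promoters.records if labels.get(g) == 1]
    rows = []
    for g in result.groups:
        try:
            p = binomial_enrichment_pvalue(g, regulated, promoters.gene_ids, promoters, region)
        except ValueError:
            p = float("nan")
        rows.append((g.seed, g.seed_score, p))
    return rows


def simulate_once(
    promoters: PromoterSet,
    expr: ExpressionTable,
    scoring: ScoringParams,
    sim: SimConfig,
    n_mp: int = 0,
    discovery: DiscoveryConfig = DiscoveryConfig(),
    include_neartss: bool = True,
) -> SimResult:
    """One full pipeline pass: discovery (both regions), pairs, simulation."""
    promoters, expr = pair_promoters_expression(promoters, expr)
    upstream = discover(promoters, expr, scoring, replace(discovery, region=UPSTREAM_REGION))
    up_groups = upstream.top_groups(discovery.max_motifs)
    tss_groups: list[MotifGroup] = []
    if include_neartss:
        neartss = discover(promoters, expr, scoring, replace(discovery, region=NEAR_TSS_REGION))
        seen = {g.seed for g in up_groups}
        tss_groups = [g for g in neartss.top_groups(discovery.max_motifs) if g.seed not in seen]
    pairs: PairSelection | None = None
    if n_mp > 0:
        labels = make_labels(expr, sim.up_threshold)
        up_labels = {g: lab == 1 for g, lab in labels.items()}
        stats = evaluate_all_pairs(up_groups + tss_groups, promoters, up_labels, PAIR_REGION)
        pairs = select_enriched_pairs(stats, n_mp)
    features = build_features(promoters, up_groups, tss_groups, pairs)
    return run_simulation(features, expr, sim)


def make_runner(
    promoters: PromoterSet,
    expr: ExpressionTable,
    base_scoring: ScoringParams = ScoringParams(),
    base_sim: SimConfig = SimConfig(),
    discovery: DiscoveryConfig = DiscoveryConfig(),
    include_neartss: bool = True,
):
    """Adapt the pipeline to the optimizer's (nu, tau, n_mp, seed) callable."""

    def runner(nu: int, tau: float, n_mp: int, seed: int) -> float:
        scoring = replace(base_scoring, nu=int(nu), tau=float(tau))
        sim = replace(base_sim, seed=int(seed))
        result = simulate_once(
            promoters, expr, scoring, sim, n_mp=n_mp,
            discovery=discovery, include_neartss=include_neartss,
        )
        return result.auc_roc

    return runner
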