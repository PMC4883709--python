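"""Expression simulation: motif-presence features -> margin classifier.

Genes become binary feature vectors (motif present / absent in the
relevant region, plus selected co-localized pairs).  Genes up-regulated
more than the threshold are the positive class.  After a stratified 50/50
split, negatives in the training half are undersampled, an RBF-kernel SVM
is tuned by cross-validated grid search on AUC-ROC, and the model is
scored on the untouched test half.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .coloc import PairSelection
from .grouping import MotifGroup
from .scan import genes_with_hit
from .sequence_io import ExpressionTable, PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "SimConfig",
    "SimResult",
    "UPSTREAM_REGION",
    "NEAR_TSS_REGION",
    "PAIR_REGION",
    "build_features",
    "make_labels",
    "split_train_test",
    "undersample_negatives",
    "grid_search_train",
    "evaluate",
    "run_simulation",
]

UPSTREAM_REGION = (-500, 0)
NEAR_TSS_REGION = (-50, 150)
PAIR_REGION = (-500, 150)

DEFAULT_C_GRID = [2.0**k for k in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-15, 4, 2)]


@dataclass
class SimConfig:
    up_threshold: float = 2.0
    split_fraction: float = 0.5
    ru: float = 1 / 16
    c_grid: list[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    gamma_grid: list[float] = field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 < self.ru <= 1:
            raise ValueError("ru must be in (0, 1]")
        if self.up_threshold <= 1:
            raise ValueError("up_threshold must be > 1")


@dataclass
class FeatureMatrix:
    genes: list[str]
    columns: list[str]
    values: np.ndarray  # (n_genes, n_columns) in {0, 1}

    def __post_init__(self) -> None:
        if len(self.columns) != len(set(self.columns)):
            raise ValueError("duplicate feature names")
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError("feature matrix shape mismatch")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.columns) + "\n")
            for g, row in zip(self.genes, self.values):
                fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclass
class SimResult:
    auc_roc: float
    accuracy: float
    n_test: int
    n_correct: int
    best_c: float
    best_gamma: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def build_features(
    promoters: PromoterSet,
    upstream_motifs: Sequence[MotifGroup],
    neartss_motifs: Sequence[MotifGroup] = (),
    pairs: PairSelection | None = None,
) -> FeatureMatrix:
    """One binary column per motif (region-specific) and selected pair.

    Upstream motifs are scored in (-500, 0), near-TSS motifs in (-50, +150),
    and a pair column is the AND of both motifs' presence in (-500, +150).
    """
    if not upstream_motifs and not neartss_motifs:
        raise ValueError("no motifs supplied; feature space would be empty")
    genes = promoters.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    columns: list[str] = []
    data: list[np.ndarray] = []
    presence_by_name: dict[str, set[str]] = {}

    def add_column(name: str, carrier_genes: set[str]) -> None:
        if name in set(columns):
            raise ValueError(f"duplicate feature name {name!r}")
        col = np.zeros(len(genes), dtype=np.int8)
        for g in carrier_genes:
            col[gene_index[g]] = 1
        columns.append(name)
        data.append(col)

    for group in upstream_motifs:
        add_column(f"up:{group.name}", genes_with_hit(group, promoters, UPSTREAM_REGION))
    for group in neartss_motifs:
        add_column(f"tss:{group.name}", genes_with_hit(group, promoters, NEAR_TSS_REGION))
    if pairs is not None and pairs.pairs:
        all_groups = {g.name: g for g in list(upstream_motifs) + list(neartss_motifs)}
        for ps in pairs.pairs:
            for name in (ps.motif_a, ps.motif_b):
                if name not in presence_by_name:
                    group = all_groups[name]
                    presence_by_name[name] = genes_with_hit(group, promoters, PAIR_REGION)
            both = presence_by_name[ps.motif_a] & presence_by_name[ps.motif_b]
            add_column(f"pair:{ps.motif_a}+{ps.motif_b}", both)
    return FeatureMatrix(genes=list(genes), columns=columns, values=np.column_stack(data))


def make_labels(expr: ExpressionTable, threshold: float = 2.0) -> dict[str, int]:
    """+1 for genes with ratio strictly above the threshold, else -1."""
    return {g: (1 if r > threshold else -1) for g, r in expr.ratios.items()}


def split_train_test(
    genes: Sequence[str],
    labels: Mapping[str, int],
    config: SimConfig,
) -> tuple[list[str], list[str]]:
    """Stratified random split; both classes guaranteed in both halves."""
    y = np.array([labels[g] for g in genes])
    for cls in (1, -1):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 members; cannot split")
    train, test = train_test_split(
        list(genes),
        test_size=1 - config.split_fraction,
        stratify=y,
        random_state=config.seed,
    )
    return list(train), list(test)


def undersample_negatives(
    train: Sequence[str],
    labels: Mapping[str, int],
    ru: float = 1 / 16,
    seed: int = 0,
) -> list[str]:
    """Keep all positives and a uniform random *ru* fraction of negatives."""
    if not 0 < ru <= 1:
        raise ValueError("ru must be in (0, 1]")
    positives = [g for g in train if labels[g] == 1]
    negatives = [g for g in train if labels[g] == -1]
    if ru == 1:
        return list(train)
    # floor of 2 (when available) keeps stratified CV feasible at small n
    floor = min(len(negatives), 2)
    n_keep = max(floor, round(ru * len(negatives)))
    rng = np.random.default_rng(seed)
    kept = list(rng.choice(negatives, size=n_keep, replace=False))
    out = positives + kept
    rng.shuffle(out)
    return out


def _cv_auc(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float, folds: int, seed: int
) -> float:
    """Mean cross-validated AUC; re-draws folds on degenerate splits."""
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        aucs = []
        try:
            for tr, va in skf.split(X, y):
                if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                    raise ValueError("degenerate fold")
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[va], clf.decision_function(X[va])))
            return float(np.mean(aucs))
        except ValueError:
            continue
    raise ValueError("could not draw non-degenerate CV folds in 5 attempts")


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    config: SimConfig,
) -> tuple[SVC, float, float]:
    """Grid-search (C, gamma) by cross-validated AUC, refit the best pair."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    folds = min(config.cv_folds, int((y == 1).sum()), int((y == -1).sum()))
    folds = max(folds, 2)
    best: tuple[float, float, float] | None = None  # (auc, c, gamma)
    for c in config.c_grid:
        for gamma in config.gamma_grid:
            auc = _cv_auc(X, y, c, gamma, folds, config.seed)
            if best is None or auc > best[0]:
                best = (auc, c, gamma)
    assert best is not None
    _, best_c, best_gamma = best
    clf = SVC(C=best_c, gamma=best_gamma, kernel="rbf")
    clf.fit(X, y)
    return clf, best_c, best_gamma


def evaluate(
    classifier: SVC,
    X_test: np.ndarray,
    y_test: np.ndarray,
    best_c: float,
    best_gamma: float,
    seed: int,
) -> SimResult:
    """AUC-ROC from decision values and sign-threshold accuracy on test."""
    if len(np.unique(y_test)) < 2:
        raise ValueError("test data contains a single class")
    decision = classifier.decision_function(X_test)
    auc = float(roc_auc_score(y_test, decision))
    predicted = np.where(decision > 0, 1, -1)
    n_correct = int((predicted == y_test).sum())
    return SimResult(
        auc_roc=auc,
        accuracy=n_correct / len(y_test),
        n_test=len(y_test),
        n_correct=n_correct,
        best_c=best_c,
        best_gamma=best_gamma,
        seed=seed,
    )


def run_simulation(
    features: FeatureMatrix,
    expr: ExpressionTable,
    config: SimConfig,
) -> SimResult:
    """split -> undersample -> grid search -> evaluate, under one seed."""
    labels = make_labels(expr, config.up_threshold)
    genes = features.genes
    train, test = split_train_test(genes, labels, config)
    train = undersample_negatives(train, labels, config.ru, config.seed)
    index = {g: i for i, g in enumerate(genes)}
    Xtr = features.values[[index[g] for g in train]].astype(float)
    ytr = np.array([labels[g] for g in train])
    Xte = features.values[[index[g] for g in test]].astype(float)
    yte = np.array([labels[g] for g in test])
    clf, best_c, best_gamma = grid_search_train(Xtr, ytr, config)
    return evaluate(clf, Xte, yte, best_c, best_gamma, config.seed)
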