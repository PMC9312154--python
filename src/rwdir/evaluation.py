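"""Leave-one-out evaluation with negative sampling, ROC curves and AUC.

Each known related vertex is relabeled unlabeled in turn and the chosen
algorithm must re-rank it highly; an equal number of negatives sampled
from the irrelevant pool is relabeled unlabeled in every fold and scored
as the mean over folds.  Scores are the final m1 for RW-DIR and the
stationary Pt for the baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, Label, LabelAssignment
from .walk import (
    RankedResult,
    WalkConfig,
    run_rwdir,
    run_rwdir_no_entropy,
    run_trwr_on_network,
)

__all__ = [
    "ALGORITHMS",
    "CVResult",
    "ROCResult",
    "run_algorithm",
    "sample_negatives",
    "loo_cv",
    "roc_curve",
    "compare_methods",
]

ALGORITHMS = ("rwdir", "trwr", "rwdir-no-entropy")

_RUNNERS = {
    "rwdir": run_rwdir,
    "trwr": run_trwr_on_network,
    "rwdir-no-entropy": run_rwdir_no_entropy,
}


def run_algorithm(
    net: HeteroNetwork,
    labels,
    config: WalkConfig,
    algorithm: str,
) -> RankedResult:
    """Dispatch to one of rwdir, trwr, rwdir-no-entropy."""
    try:
        runner = _RUNNERS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return runner(net, labels, config)


@dataclass(frozen=True)
class CVResult:
    """Held-out positive scores and matched negative scores for one method."""

    positive_scores: tuple[tuple[str, float], ...]
    negative_scores: tuple[tuple[str, float], ...]
    algorithm: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.positive_scores) != len(self.negative_scores):
            raise ValueError("positive and negative score lists must have equal length")


@dataclass(frozen=True)
class ROCResult:
    """ROC points at every distinct score plus the trapezoidal AUC."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def sample_negatives(
    labels: LabelAssignment | dict[str, Label],
    count: int,
    rng_seed: int,
) -> list[str]:
    """Uniform sample without replacement from the irrelevant-labeled pool."""
    mapping = labels.labels if isinstance(labels, LabelAssignment) else labels
    pool = sorted(vid for vid, lab in mapping.items() if lab is Label.IRRELEVANT)
    if count > len(pool):
        raise ValueError(f"requested {count} negatives but the irrelevant pool has {len(pool)}")
    rng = np.random.default_rng(rng_seed)
    picked = rng.choice(len(pool), size=count, replace=False)
    return [pool[i] for i in sorted(picked)]


def loo_cv(
    net: HeteroNetwork,
    labels: LabelAssignment,
    config: WalkConfig,
    algorithm: str,
    negatives: list[str] | None = None,
) -> CVResult:
    """Leave-one-out over the related vertices.

    Fold r relabels the held-out related vertex r *and* the whole sampled
    negative set as unlabeled, runs the algorithm, and records r's score.
    Each negative's score is its mean across all folds (it is unlabeled in
    every one), so no single fold's seed choice dominates it.
    """
    resolved = dict(zip(net.ids, labels.resolve(net)))
    related = sorted(vid for vid, lab in resolved.items() if lab is Label.RELATED)
    if len(related) < 2:
        raise ValueError("leave-one-out needs at least 2 related vertices")
    if negatives is None:
        negatives = sample_negatives(resolved, len(related), config.seed)

    neg_sums = {vid: 0.0 for vid in negatives}
    positive_scores: list[tuple[str, float]] = []
    for held_out in related:
        fold = dict(resolved)
        fold[held_out] = Label.UNLABELED
        for vid in negatives:
            fold[vid] = Label.UNLABELED
        result = run_algorithm(net, [fold[vid] for vid in net.ids], config, algorithm)
        positive_scores.append((held_out, result.scores[held_out]))
        for vid in negatives:
            neg_sums[vid] += result.scores[vid]

    n_folds = len(related)
    negative_scores = [(vid, neg_sums[vid] / n_folds) for vid in negatives]
    return CVResult(
        positive_scores=tuple(positive_scores),
        negative_scores=tuple(negative_scores),
        algorithm=algorithm,
        seed=config.seed,
    )


def roc_curve(
    positive_scores,
    negative_scores,
) -> ROCResult:
    """ROC by threshold sweep over every distinct score; trapezoidal AUC.

    Tied positive/negative scores step diagonally (the curve point moves in
    tpr and fpr simultaneously), which makes the trapezoidal area equal to
    the Mann-Whitney statistic U / (n_pos * n_neg) with half-credit ties.
    The AUC is accumulated with integer tp/fp counts so the equality is
    exact in floating point.
    """
    pos = np.asarray([s for _, s in positive_scores] if _is_pairs(positive_scores) else positive_scores, dtype=float)
    neg = np.asarray([s for _, s in negative_scores] if _is_pairs(negative_scores) else negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    n_pos, n_neg = pos.size, neg.size

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tp = np.array([0] + [int((pos >= th).sum()) for th in thresholds], dtype=np.int64)
    fp = np.array([0] + [int((neg >= th).sum()) for th in thresholds], dtype=np.int64)

    # integer trapezoid numerator: sum (fp_i+1 - fp_i) * (tp_i + tp_i+1)
    num = int(np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1])))
    auc = num / (2 * n_pos * n_neg)
    return ROCResult(
        thresholds=tuple(float(t) for t in thresholds),
        fpr=tuple(fp / n_neg),
        tpr=tuple(tp / n_pos),
        auc=float(auc),
    )


def _is_pairs(scores) -> bool:
    scores = list(scores)
    return bool(scores) and isinstance(scores[0], tuple)


def compare_methods(
    net: HeteroNetwork,
    labels: LabelAssignment,
    config: WalkConfig,
    algorithms=ALGORITHMS,
) -> tuple[pd.DataFrame, dict[str, tuple[CVResult, ROCResult]]]:
    """LOO-CV AUC for each algorithm with a shared negative sample.

    Returns a summary table (algorithm, auc, n_pos, n_neg) and per-method
    (CVResult, ROCResult) details.
    """
    resolved = dict(zip(net.ids, labels.resolve(net)))
    n_related = sum(1 for lab in resolved.values() if lab is Label.RELATED)
    negatives = sample_negatives(resolved, n_related, config.seed)
    rows = []
    details: dict[str, tuple[CVResult, ROCResult]] = {}
    for alg in algorithms:
        cv = loo_cv(net, labels, config, alg, negatives=negatives)
        roc = roc_curve(cv.positive_scores, cv.negative_scores)
        details[alg] = (cv, roc)
        rows.append(
            {
                "algorithm": alg,
                "auc": roc.auc,
                "n_pos": len(cv.positive_scores),
                "n_neg": len(cv.negative_scores),
            }
        )
    return pd.DataFrame(rows), details
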