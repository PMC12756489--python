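"""Held-out predictive evaluation and agreement statistics.

Discrimination is summarized by the rank-based (Mann-Whitney) ROC-AUC with
midranks for ties, which equals the trapezoidal area under the empirical ROC
curve.  Thresholded performance uses precision, recall and the F-beta family
(F2 weights recall over precision).  Label reliability between human raters
is summarized by Cohen's kappa; for more than two raters the default
reduction is the mean of all pairwise kappas, with Fleiss' kappa available
as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .corpus import ChatSession
from .features import FeatureOptions, build_design
from .lexicon import SRFLexicon
from .risk_model import fit_logistic, predict_proba

__all__ = [
    "SplitSpec",
    "ClassificationMetrics",
    "split",
    "fbeta_score",
    "precision_recall_fbeta",
    "roc_auc",
    "cohen_kappa",
    "mean_pairwise_kappa",
    "fleiss_kappa",
    "evaluate_holdout",
]


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0
    stratify_by_outcome: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class ClassificationMetrics:
    precision: float
    recall: float
    f1: float
    f2: float
    roc_auc: float
    threshold: float
    n_test: int


def split(sessions: Sequence[ChatSession],
          spec: SplitSpec) -> tuple[list[ChatSession], list[ChatSession]]:
    """Deterministic train/test partition, optionally outcome-stratified."""
    if len(sessions) < 10:
        raise ValueError("need at least 10 sessions to split")
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(len(sessions))
    labels = np.array([s.sr_label for s in sessions])
    test_idx: list[int] = []
    if spec.stratify_by_outcome:
        for cls in np.unique(labels):
            cls_idx = idx[labels == cls]
            n_test = round(len(cls_idx) * spec.test_fraction)
            test_idx.extend(rng.permutation(cls_idx)[:n_test].tolist())
    else:
        n_test = round(len(idx) * spec.test_fraction)
        test_idx = rng.permutation(idx)[:n_test].tolist()
    test_set = set(test_idx)
    train = [sessions[i] for i in idx if i not in test_set]
    test = [sessions[i] for i in sorted(test_set)]
    if len({s.sr_label for s in test}) < 2:
        warnings.warn("test split contains a single outcome class",
                      RuntimeWarning, stacklevel=2)
    return train, test


def fbeta_score(precision: float, recall: float, beta: float = 1.0) -> float:
    """F_beta = (1 + beta^2) P R / (beta^2 P + R); 0 when both P and R are 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def precision_recall_fbeta(y_true: Sequence[int], y_pred: Sequence[int],
                           beta: float = 1.0) -> tuple[float, float, float]:
    """(precision, recall, F_beta) with zero-denominator -> 0 plus a warning."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0",
                      RuntimeWarning, stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall set to 0",
                      RuntimeWarning, stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return precision, recall, fbeta_score(precision, recall, beta)


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC with midranks for tied scores."""
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise ValueError("length mismatch between labels and scores")
    n1 = int(np.sum(yt == 1))
    n0 = int(np.sum(yt == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC-AUC requires both outcome classes")
    ranks = stats.rankdata(sc, method="average")
    return float((np.sum(ranks[yt == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def cohen_kappa(rater_a: Sequence[int], rater_b: Sequence[int]) -> float:
    """Chance-corrected two-rater agreement over paired binary labels."""
    a = np.asarray(rater_a, dtype=int)
    b = np.asarray(rater_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("raters must give equal-length, non-empty label lists")
    if not (set(np.unique(a)) <= {0, 1} and set(np.unique(b)) <= {0, 1}):
        raise ValueError("labels must be binary")
    n = a.size
    p_o = float(np.mean(a == b))
    p_a1, p_b1 = float(np.mean(a)), float(np.mean(b))
    p_e = p_a1 * p_b1 + (1.0 - p_a1) * (1.0 - p_b1)
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement is 1 "
                         "(both raters constant with identical marginals)")
    return (p_o - p_e) / (1.0 - p_e)


def mean_pairwise_kappa(ratings: np.ndarray) -> float:
    """Default multi-rater reduction: mean Cohen's kappa over rater pairs.

    ``ratings`` is items x raters.  Reported agreement from more than two
    reviewers is reduced this way unless Fleiss' kappa is requested
    explicitly.
    """
    ratings = np.asarray(ratings, dtype=int)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be items x raters with >= 2 raters")
    kappas = [cohen_kappa(ratings[:, i], ratings[:, j])
              for i, j in combinations(range(ratings.shape[1]), 2)]
    return float(np.mean(kappas))


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for binary labels from a fixed panel of raters."""
    ratings = np.asarray(ratings, dtype=int)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be items x raters with >= 2 raters")
    n, r = ratings.shape
    n1 = ratings.sum(axis=1)
    n0 = r - n1
    p_i = (n1 * (n1 - 1) + n0 * (n0 - 1)) / (r * (r - 1))
    p_bar = float(np.mean(p_i))
    pj1 = float(np.mean(n1) / r)
    p_e = pj1 ** 2 + (1.0 - pj1) ** 2
    if p_e >= 1.0 - 1e-15:
        raise ValueError("Fleiss' kappa undefined: no marginal variation")
    return (p_bar - p_e) / (1.0 - p_e)


def evaluate_holdout(sessions: Sequence[ChatSession], lexicon: SRFLexicon,
                     spec: SplitSpec | None = None, threshold: float = 0.5,
                     options: FeatureOptions | None = None) -> ClassificationMetrics:
    """Train on the split's train side, score the test side, summarize.

    The classification threshold on the predicted probability defaults to
    0.5 and is configurable.
    """
    spec = spec or SplitSpec()
    train, test = split(sessions, spec)
    train_design = build_design(train, lexicon, options=options,
                                stratum_name="train")
    fit = fit_logistic(train_design)
    test_design = build_design(test, lexicon, options=options,
                               stratum_name="test")
    p = predict_proba(fit, test_design)
    y = test_design.y
    precision, recall, f1 = precision_recall_fbeta(y, (p >= threshold).astype(int))
    f2 = fbeta_score(precision, recall, beta=2.0)
    return ClassificationMetrics(
        precision=precision, recall=recall, f1=f1, f2=f2,
        roc_auc=roc_auc(y, p), threshold=threshold, n_test=len(test),
    )
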