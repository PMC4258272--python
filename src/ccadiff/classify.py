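"""Automatic sample classification from one-dimensional ordination scores.

Procedure: build a one-vs-rest differentiation variable for the programme
of interest, score every test sample by the single constrained axis it
induces, split the scores with deterministic two-group k-means, and call
the higher-scoring group positive.  Sensitivity and accuracy are attached
with leave-one-out jackknife confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cca_core import cca
from .diffvar import DifferentiationVariable, one_vs_rest_variable
from .io_preprocess import ExpressionMatrix

__all__ = [
    "ClassificationResult",
    "cca_score_1d",
    "kmeans_classify",
    "confusion_metrics",
    "jackknife_ci",
    "classify_samples",
]


@dataclass(frozen=True)
class ClassificationResult:
    """Per-sample predictions plus confusion-matrix summary statistics."""

    predicted_positive: np.ndarray
    truth: np.ndarray | None = None
    scores: np.ndarray | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: float | None = None  # TP/(TP+FN); None when no positives
    accuracy: float | None = None
    ci95_sensitivity: tuple[float, float] | None = None
    ci95_accuracy: tuple[float, float] | None = None


def cca_score_1d(test: ExpressionMatrix, d: DifferentiationVariable) -> np.ndarray:
    """Principal sample scores on the single axis constrained by ``d``.

    The axis is oriented so that the biplot coefficient of the contrast is
    positive: a higher score means closer alignment with the ``to_class``
    programme.  Negating ``d`` therefore changes nothing.
    """
    fold_t = [g.casefold() for g in test.gene_ids]
    fold_d = [g.casefold() for g in d.gene_ids]
    if fold_t != fold_d:
        raise ValueError("test matrix and differentiation variable gene universes differ")
    name = f"{d.from_class}->{d.to_class}"
    result = cca(test, d.d, programme_names=(name,))
    if result.m == 0:
        raise ValueError("constrained axis is numerically null for this contrast")
    return result.sample_scores_principal[:, 0]


def kmeans_classify(scores: np.ndarray) -> np.ndarray:
    """Two-group k-means partition of 1-D scores; higher-mean group positive.

    In one dimension the k=2 solution is a threshold partition, so the
    global minimum-within-SS split is found exactly by scanning every cut of
    the sorted scores (prefix-sum evaluation of both cluster SS).  This is
    fully deterministic — no seed or initialisation enters.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples to partition")
    if np.ptp(s) == 0:
        raise ValueError("all scores identical; cannot partition into 2 groups")
    order = np.argsort(s, kind="stable")
    v = s[order]
    n = len(v)
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    cuts = np.arange(1, n)  # lower cluster = v[:cut]
    lo_ss = csq[cuts - 1] - csum[cuts - 1] ** 2 / cuts
    hi_n = n - cuts
    hi_sum = csum[-1] - csum[cuts - 1]
    hi_ss = (csq[-1] - csq[cuts - 1]) - hi_sum**2 / hi_n
    best_cut = int(cuts[np.argmin(lo_ss + hi_ss)])
    positive = np.zeros(n, dtype=bool)
    positive[order[best_cut:]] = True
    return positive


def confusion_metrics(
    predicted: np.ndarray,
    truth: np.ndarray,
    scores: np.ndarray | None = None,
) -> ClassificationResult:
    """Confusion counts, sensitivity TP/(TP+FN), accuracy (TP+TN)/total.

    Sensitivity is reported as None (not 0) when there are no condition
    positives in the truth labels.
    """
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int((pred & tru).sum())
    fp = int((pred & ~tru).sum())
    tn = int((~pred & ~tru).sum())
    fn = int((~pred & tru).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    acc = (tp + tn) / len(tru) if len(tru) else None
    return ClassificationResult(
        predicted_positive=pred, truth=tru, scores=scores,
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, accuracy=acc,
    )


def jackknife_ci(evaluate, samples) -> tuple[float, tuple[float, float]]:
    """Leave-one-out jackknife mean and 95% normal interval of a metric.

    ``evaluate`` maps a list of retained samples to a scalar metric (or
    None/NaN when undefined, in which case that replicate is dropped with a
    warning).  The interval is theta_bar +/- 1.96*SE with
    SE^2 = ((m-1)/m) * sum_i (theta_i - theta_bar)^2.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("jackknife needs at least 3 samples")
    thetas = []
    for i in range(len(samples)):
        subset = samples[:i] + samples[i + 1:]
        t = evaluate(subset)
        if t is None or (isinstance(t, float) and math.isnan(t)):
            warnings.warn(f"metric undefined on leave-one-out replicate {i}; dropped")
            continue
        thetas.append(float(t))
    if not thetas:
        raise ValueError("metric undefined on every replicate")
    th = np.asarray(thetas)
    m = len(th)
    theta_bar = th.mean()
    se = math.sqrt((m - 1) / m * ((th - theta_bar) ** 2).sum())
    return float(theta_bar), (float(theta_bar - 1.96 * se), float(theta_bar + 1.96 * se))


def classify_samples(
    test: ExpressionMatrix,
    resource: ExpressionMatrix,
    target_class: str,
    n_features: int | None = None,
    *,
    jackknife: bool = False,
) -> ClassificationResult:
    """End-to-end one-vs-rest classification of test samples.

    Builds the one-vs-rest differentiation variable for ``target_class``
    (optionally restricted to the ``n_features`` genes with the largest
    contrast), scores the test samples on the induced axis, partitions the
    scores by two-group k-means, and — when the test matrix carries class
    labels — evaluates against truth ``sample_class == target_class``, with
    leave-one-out jackknife intervals on request.
    """
    from .diffvar import select_top_features  # local import avoids cycle noise
    from .io_preprocess import intersect_genes

    test, resource = intersect_genes(test, resource)
    if n_features is not None:
        feats = set(g.casefold() for g in select_top_features(resource, target_class, n_features))
        rows = [i for i, g in enumerate(resource.gene_ids) if g.casefold() in feats]
        resource = ExpressionMatrix(
            resource.values[rows],
            tuple(resource.gene_ids[i] for i in rows),
            resource.sample_ids, resource.sample_class,
        )
        test = ExpressionMatrix(
            test.values[rows],
            tuple(test.gene_ids[i] for i in rows),
            test.sample_ids, test.sample_class,
        )
    d = one_vs_rest_variable(resource, target_class)
    scores = cca_score_1d(test, d)
    predicted = kmeans_classify(scores)
    if test.sample_class is None:
        return ClassificationResult(predicted_positive=predicted, scores=scores)
    truth = np.array([c == target_class for c in test.sample_class])
    result = confusion_metrics(predicted, truth, scores)
    if not jackknife:
        return result

    def _metric(attr):
        def ev(kept_indices):
            sub = test.subset_samples(kept_indices)
            sc = cca_score_1d(sub, d)
            pred = kmeans_classify(sc)
            tru = np.array([c == target_class for c in sub.sample_class])
            return getattr(confusion_metrics(pred, tru), attr)
        return ev

    idx = list(range(test.n_samples))
    _, ci_sens = jackknife_ci(_metric("sensitivity"), idx)
    _, ci_acc = jackknife_ci(_metric("accuracy"), idx)
    return ClassificationResult(
        predicted_positive=result.predicted_positive, truth=result.truth,
        scores=result.scores, tp=result.tp, fp=result.fp, tn=result.tn,
        fn=result.fn, sensitivity=result.sensitivity, accuracy=result.accuracy,
        ci95_sensitivity=ci_sens, ci95_accuracy=ci_acc,
    )
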