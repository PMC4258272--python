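"""Explanatory variables built from a resource dataset of defined cell subsets.

A differentiation variable is the gene-wise contrast between two
differentiation programmes, d = mu_y - mu_x, where mu are per-class mean
expression profiles of the resource dataset (replicate variation within a
class is deliberately ignored: the method assumes large between-class and
small within-class variance).  This module also houses the gene-filtering
rules used to pick features: Welch-t/Benjamini-Hochberg differential
expression with a fold-change percentile cut, a linear-scale
lineage-specificity filter, and top-|d| feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentiationVariable",
    "class_means",
    "differentiation_variable",
    "one_vs_rest_variable",
    "select_de_genes",
    "lineage_specific_genes",
    "select_top_features",
]


@dataclass(frozen=True)
class DifferentiationVariable:
    """A single gene-indexed contrast d = mu_to - mu_from."""

    d: np.ndarray
    from_class: str
    to_class: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.ndim != 1 or len(d) != len(self.gene_ids):
            raise ValueError("d must be a vector matching gene_ids")
        if not np.any(d):
            raise ValueError(
                f"degenerate differentiation variable: {self.from_class} and "
                f"{self.to_class} have identical mean profiles"
            )

    def __neg__(self) -> "DifferentiationVariable":
        return DifferentiationVariable(-self.d, self.to_class, self.from_class, self.gene_ids)


def class_means(resource: ExpressionMatrix) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-class mean expression profiles (k genes x n_classes).

    Column order follows first appearance of each class among the samples.
    Samples labelled ``"unknown"`` are excluded with a warning.
    """
    if resource.sample_class is None:
        raise ValueError("resource matrix has no sample class labels")
    labels = resource.classes()
    if not labels:
        raise ValueError("no labelled samples in resource matrix")
    n_unknown = sum(1 for c in resource.sample_class if c == "unknown")
    if n_unknown:
        warnings.warn(f"excluding {n_unknown} unlabelled sample(s) from class means")
    cols = np.empty((resource.n_genes, len(labels)))
    for j, lab in enumerate(labels):
        idx = [i for i, c in enumerate(resource.sample_class) if c == lab]
        cols[:, j] = resource.values[:, idx].mean(axis=1)
    return cols, labels


def _class_mean(resource: ExpressionMatrix, label: str) -> np.ndarray:
    idx = [i for i, c in enumerate(resource.sample_class or ()) if c == label]
    if not idx:
        raise ValueError(f"class {label!r} not present in resource matrix")
    return resource.values[:, idx].mean(axis=1)


def differentiation_variable(
    resource: ExpressionMatrix, from_class: str, to_class: str
) -> DifferentiationVariable:
    """d = mu_{to_class} - mu_{from_class} over the resource gene universe."""
    if from_class == to_class:
        raise ValueError("from_class and to_class must differ")
    mu_x = _class_mean(resource, from_class)
    mu_y = _class_mean(resource, to_class)
    return DifferentiationVariable(mu_y - mu_x, from_class, to_class, resource.gene_ids)


def one_vs_rest_variable(
    resource: ExpressionMatrix, target_class: str
) -> DifferentiationVariable:
    """Contrast of the target programme against the average of all others.

    The "rest" profile is the unweighted mean of the other classes' mean
    profiles (mean of class means, not a pooled-sample mean), so classes
    with more replicates do not dominate the contrast.
    """
    means, labels = class_means(resource)
    if target_class not in labels:
        raise ValueError(f"class {target_class!r} not present in resource matrix")
    if len(labels) < 2:
        raise ValueError("one-vs-rest contrast needs at least 2 classes")
    t = labels.index(target_class)
    rest = np.delete(means, t, axis=1).mean(axis=1)
    return DifferentiationVariable(means[:, t] - rest, "rest", target_class, resource.gene_ids)


def select_de_genes(
    resource: ExpressionMatrix,
    class_a: str,
    class_b: str,
    fdr: float = 0.01,
    fc_percentile: float = 1.0,
) -> list[str]:
    """Differentially expressed genes between two classes.

    A gene is selected when it passes BOTH filters: (i) Benjamini-Hochberg
    adjusted p-value below ``fdr`` under a two-sample Welch t-test, and
    (ii) mean difference in the top or bottom ``fc_percentile`` percent of
    all genes.  Requires at least 2 replicates per class for the test.
    """
    if not 0 < fc_percentile <= 50:
        raise ValueError("fc_percentile must be in (0, 50]")
    ia = [i for i, c in enumerate(resource.sample_class or ()) if c == class_a]
    ib = [i for i, c in enumerate(resource.sample_class or ()) if c == class_b]
    if not ia or not ib:
        raise ValueError(f"classes {class_a!r}/{class_b!r} not both present")
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            "Welch t-test needs >=2 replicates per class; with single replicates "
            "use the fold-change-only filters (select_top_features or "
            "lineage_specific_genes)"
        )
    a = resource.values[:, ia]
    b = resource.values[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance, zero-diff genes
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")

    diff = a.mean(axis=1) - b.mean(axis=1)
    lo = np.percentile(diff, fc_percentile)
    hi = np.percentile(diff, 100.0 - fc_percentile)
    extreme = (diff <= lo) | (diff >= hi)

    keep = reject & extreme
    out = [g for g, k in zip(resource.gene_ids, keep) if k]
    logger.info(
        "select_de_genes %s vs %s: %d of %d genes (fdr<%g, top/bottom %g%%)",
        class_a, class_b, len(out), resource.n_genes, fdr, fc_percentile,
    )
    return out


def lineage_specific_genes(
    resource: ExpressionMatrix,
    target_class: str,
    min_expression: float = 5.0,
    fold: float = 2.0,
) -> list[str]:
    """Linear-scale lineage-specificity filter for RNA-seq resource data.

    A gene is lineage-specific when its mean expression (RPKM scale) in the
    target class is at least ``min_expression`` and at least ``fold`` times
    the mean of every other class.
    """
    means, labels = class_means(resource)
    if target_class not in labels:
        raise ValueError(f"class {target_class!r} not present")
    t = labels.index(target_class)
    others = np.delete(means, t, axis=1)
    ok = (means[:, t] >= min_expression) & (means[:, t][:, None] >= fold * others).all(axis=1)
    return [g for g, k in zip(resource.gene_ids, ok) if k]


def select_top_features(
    resource: ExpressionMatrix, target_class: str, n: int
) -> list[str]:
    """The n genes with the largest |one-vs-rest contrast| for a class.

    Ties broken lexicographically by gene id, so the result for n is always
    a prefix of the result for n+1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > resource.n_genes:
        raise ValueError(f"n={n} exceeds {resource.n_genes} genes")
    dv = one_vs_rest_variable(resource, target_class)
    mag = np.abs(dv.d)
    ids = np.array(resource.gene_ids)
    # descending |d|, ascending gene id on ties
    order = np.lexsort((ids, -mag))
    return list(ids[order[:n]])
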