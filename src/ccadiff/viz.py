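"""Ordination graphics: triplots, 1-D score plots, axis-ordered heatmaps.

Every figure is paired with a TSV of the numbers it draws; the plots are
views, the tables are the data of record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
matplotlib.rcParams["svg.hashsalt"] = "ccadiff"  # byte-stable SVG output

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

from .cca_core import CCAResult
from .io_preprocess import ExpressionMatrix

__all__ = ["triplot", "score_plot_1d", "heatmap_by_axis"]

#: longest programme arrow spans this fraction of the sample-score range
ARROW_SPAN = 0.8


def _axis_label(result: CCAResult, axis: int) -> str:
    pct = 100.0 * result.axis_inertia_fraction(axis)
    return f"Axis {axis + 1} ({pct:.1f}% of constrained inertia)"


def _data_path(fig_path: str | Path) -> Path:
    p = Path(fig_path)
    return p.with_suffix(".tsv")


def triplot(
    result: CCAResult,
    path: str | Path,
    axes: tuple[int, int] = (0, 1),
    highlight_genes: list[str] | None = None,
) -> Path:
    """Samples + genes + programme arrows on two constrained axes.

    Gene positions are WA principal scores, sample positions principal
    sample scores, programmes the biplot correlations rescaled so the
    longest arrow spans 80% of the sample-score range.  With
    ``highlight_genes`` only that subset of genes is drawn (gene-plot
    variant).
    """
    ax1, ax2 = axes
    if result.m < 2 or max(axes) >= result.m:
        raise ValueError(
            f"result has {result.m} axis/axes; need both requested axes "
            "(for a one-dimensional solution use score_plot_1d)"
        )
    if result.biplot_scores is None:
        raise ValueError("triplot needs a constrained result with programme arrows")

    genes = result.gene_scores_wa_principal[:, [ax1, ax2]]
    samples = result.sample_scores_principal[:, [ax1, ax2]]
    gene_ids = np.array(result.gene_ids)
    if highlight_genes is not None:
        want = {g.casefold() for g in highlight_genes}
        keep = np.array([g.casefold() in want for g in gene_ids])
        genes, gene_ids = genes[keep], gene_ids[keep]

    arrows = result.biplot_scores[:, [ax1, ax2]]
    span = np.abs(samples).max() if samples.size else 1.0
    longest = np.linalg.norm(arrows, axis=1).max() if arrows.size else 1.0
    scale = ARROW_SPAN * span / longest if longest > 0 else 1.0

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(genes[:, 0], genes[:, 1], s=6, c="grey", alpha=0.5, label="genes", zorder=1)
    classes = result.sample_class or tuple("sample" for _ in result.sample_ids)
    for cls in dict.fromkeys(classes):
        idx = [i for i, c in enumerate(classes) if c == cls]
        ax.scatter(samples[idx, 0], samples[idx, 1], s=40, label=cls, zorder=3)
    for name, (bx, by) in zip(result.programme_names or (), arrows):
        ax.annotate(
            "", xy=(bx * scale, by * scale), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:blue", lw=1.5), zorder=4,
        )
        ax.text(bx * scale * 1.05, by * scale * 1.05, name, color="tab:blue", fontsize=9)
    ax.axhline(0, color="k", lw=0.3)
    ax.axvline(0, color="k", lw=0.3)
    ax.set_xlabel(_axis_label(result, ax1))
    ax.set_ylabel(_axis_label(result, ax2))
    ax.legend(fontsize=7, loc="best")
    ax.set_title(f"arrow scale x{scale:.3g}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    rows = []
    for gid, (gx, gy) in zip(gene_ids, genes):
        rows.append(("gene", gid, gx, gy))
    for sid, cls, (sx, sy) in zip(result.sample_ids, classes, samples):
        rows.append(("sample", f"{sid}|{cls}", sx, sy))
    for name, (bx, by) in zip(result.programme_names or (), arrows):
        rows.append(("programme", name, bx, by))
    pd.DataFrame(rows, columns=["layer", "id", f"axis{ax1 + 1}", f"axis{ax2 + 1}"]).to_csv(
        _data_path(path), sep="\t", index=False
    )
    return Path(path)


def score_plot_1d(
    result: CCAResult,
    path: str | Path,
    group_labels: list[str] | tuple[str, ...] | None = None,
) -> Path:
    """Strip plot of 1-D sample scores, grouped by label."""
    if result.m < 1:
        raise ValueError("result has no axes")
    scores = result.sample_scores_principal[:, 0]
    if group_labels is None or len(group_labels) == 0:
        group_labels = list(result.sample_class or ("all",) * len(scores))
    groups = list(dict.fromkeys(group_labels))

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(groups)), 4))
    for gi, g in enumerate(groups):
        idx = [i for i, lab in enumerate(group_labels) if lab == g]
        ax.scatter(np.full(len(idx), gi), scores[idx], s=35)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=45, ha="right", fontsize=8)
    pct = 100.0 * result.percent_explained
    ax.set_ylabel("sample score (axis 1)")
    ax.set_title(f"{pct:.2f}% of total inertia explained", fontsize=9)
    ax.axhline(0, color="k", lw=0.3)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    pd.DataFrame(
        {"sample_id": list(result.sample_ids), "group": list(group_labels), "score": scores}
    ).to_csv(_data_path(path), sep="\t", index=False)
    return Path(path)


def heatmap_by_axis(
    result: CCAResult,
    x: ExpressionMatrix,
    path: str | Path,
    axis: int = 0,
    top_fraction: float = 0.02,
) -> Path:
    """Expression heatmap of the genes most extreme on one ordination axis.

    Rows are the ``top_fraction`` of genes ranked by |WA score| on the
    axis, ordered by their score; columns (samples) are clustered by
    complete-linkage on Euclidean distance.  Returns the figure path; the
    reordered matrix is written alongside as TSV.
    """
    if axis >= result.m:
        raise ValueError(f"axis {axis} not present ({result.m} axes)")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    wa = result.gene_scores_wa_principal[:, axis]
    n_top = int(round(top_fraction * len(wa)))
    if n_top == 0:
        raise ValueError("top_fraction selects 0 genes")
    top = np.argsort(-np.abs(wa))[:n_top]
    order = top[np.argsort(-wa[top])]  # descending score, extremes at the top

    fold_res = {g.casefold(): i for i, g in enumerate(x.gene_ids)}
    rows = [fold_res[result.gene_ids[i].casefold()] for i in order]
    sub = x.values[rows]

    if x.n_samples > 2:
        link = complete(pdist(sub.T, metric="euclidean"))
        col_order = leaves_list(link)
    else:
        col_order = np.arange(x.n_samples)
    sub = sub[:, col_order]
    col_ids = [x.sample_ids[j] for j in col_order]

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(col_ids)), max(3, 0.08 * n_top)))
    im = ax.imshow(sub, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(col_ids)))
    ax.set_xticklabels(col_ids, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"top {n_top} genes by |axis-{axis + 1} score| (score-ordered)")
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    out = pd.DataFrame(sub, index=[x.gene_ids[i] for i in rows], columns=col_ids)
    out.index.name = "gene_id"
    out.to_csv(_data_path(path), sep="\t")
    return Path(path)
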