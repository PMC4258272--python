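"""Loading, validation and cross-platform harmonisation of expression matrices.

The ordination machinery downstream works in the chi-square metric, which
requires a strictly non-negative gene x sample matrix with positive row and
column margins.  Everything in this module exists to get real-world inputs
(TSV exports, GEO series-matrix files, log-scale microarray values that dip
below zero) into that state, and to put two independently produced datasets
onto an identical, ordered gene universe so they can be cross-analysed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "load_expression_matrix",
    "write_expression_matrix",
    "log2_rpkm_transform",
    "intersect_genes",
    "rank_normalize",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as an expression matrix."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene x sample expression values with identifiers.

    Rows are genes ("sites" at which transcripts are measured), columns are
    samples (cellular phenotypes).  ``sample_class`` carries the phenotype
    label of each sample; ``"unknown"`` marks unlabelled samples.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    sample_class: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.sample_class is not None:
            object.__setattr__(self, "sample_class", tuple(str(c) for c in self.sample_class))
        if v.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        k, p = v.shape
        if len(self.gene_ids) != k:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {k} rows")
        if len(self.sample_ids) != p:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {p} columns")
        if self.sample_class is not None and len(self.sample_class) != p:
            raise ValueError("sample_class length must match number of samples")
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite (drop NA rows first)")
        if (v < 0).any():
            raise ValueError("expression values must be non-negative (see clip_negative)")
        folded = [g.casefold() for g in self.gene_ids]
        if len(set(folded)) != len(folded):
            raise ValueError("gene ids must be unique after case-folding")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if k == 0 or p == 0:
            raise ValueError("empty expression matrix")
        if (v.sum(axis=1) <= 0).any():
            raise ValueError("zero-sum gene rows present; drop them before construction")
        if (v.sum(axis=0) <= 0).any():
            raise ValueError("zero-sum sample columns present; drop them before construction")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    def classes(self) -> tuple[str, ...]:
        """Distinct class labels in order of first appearance ('unknown' excluded)."""
        if self.sample_class is None:
            return ()
        seen: dict[str, None] = {}
        for c in self.sample_class:
            if c != "unknown":
                seen.setdefault(c, None)
        return tuple(seen)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices)
        cls = None if self.sample_class is None else tuple(self.sample_class[i] for i in idx)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            tuple(self.sample_ids[i] for i in idx),
            cls,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=values)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        sample_class: dict[str, str] | None = None,
        *,
        clip_negative: bool = True,
    ) -> "ExpressionMatrix":
        """Build a valid matrix from a raw gene x sample DataFrame.

        Cleaning steps, in order: rows with any NA dropped; duplicate gene
        rows (case-folded id) collapsed by mean, keeping the first-seen
        spelling and position; negative values clipped at zero (or rejected
        when ``clip_negative`` is false); zero-margin rows and columns
        dropped with a logged count.
        """
        df = df.apply(pd.to_numeric, errors="coerce")
        n_na = int(df.isna().any(axis=1).sum())
        if n_na:
            logger.info("dropping %d gene rows containing NA values", n_na)
            df = df.dropna(axis=0)
        if df.shape[1] == 0:
            raise ValueError("expression table has zero sample columns")

        folded = pd.Index([str(g).casefold() for g in df.index])
        if folded.has_duplicates:
            spelling = {}
            for raw, key in zip(df.index, folded):
                spelling.setdefault(key, str(raw))
            order = folded.drop_duplicates()
            collapsed = df.groupby(folded, sort=False).mean()
            df = collapsed.loc[order]
            df.index = [spelling[k] for k in df.index]
            logger.info("collapsed duplicate gene rows to %d unique genes", df.shape[0])

        vals = df.to_numpy(dtype=float)
        if (vals < 0).any():
            n_neg = int((vals < 0).sum())
            if not clip_negative:
                raise ValueError(f"{n_neg} negative values present and clip_negative=False")
            logger.info("clipping %d negative values to 0", n_neg)
            vals = np.clip(vals, 0.0, None)

        row_ok = vals.sum(axis=1) > 0
        if not row_ok.all():
            logger.info("dropping %d zero-sum gene rows", int((~row_ok).sum()))
            vals = vals[row_ok]
            df = df.loc[row_ok]
        col_ok = vals.sum(axis=0) > 0
        if not col_ok.all():
            logger.warning("dropping %d zero-sum sample columns", int((~col_ok).sum()))
            vals = vals[:, col_ok]
            df = df.loc[:, col_ok]
        if vals.size == 0:
            raise ValueError("no usable rows/columns after cleaning")

        classes = None
        if sample_class is not None:
            classes = tuple(sample_class.get(s, "unknown") for s in df.columns)
        return cls(vals, tuple(str(g) for g in df.index), tuple(str(s) for s in df.columns), classes)


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    """Read the data table of a GEO series-matrix flat file.

    Metadata lines start with '!'; the expression table sits between the
    table-begin/-end markers (which themselves start with '!').
    """
    lines = [ln for ln in path.read_text().splitlines() if ln and not ln.startswith("!")]
    if not lines:
        raise FormatError(f"{path}: no data table found in series-matrix file")
    buf = io.StringIO("\n".join(lines))
    df = pd.read_csv(buf, sep="\t", index_col=0)
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = [str(g).strip('"') for g in df.index]
    return df


def load_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    class_path: str | Path | None = None,
    clip_negative: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        TSV with gene ids in the first column and one numeric column per
        sample, or a GEO series-matrix flat file.
    format
        ``"tsv"`` or ``"geo_series_matrix"``.
    class_path
        Optional two-column TSV (``sample_id<TAB>class``) assigning a class
        label to each sample; unlisted samples get ``"unknown"``.
    clip_negative
        Clip negative values (log-scale microarray artefacts) to zero rather
        than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "tsv":
            df = pd.read_csv(path, sep="\t", index_col=0)
        elif format == "geo_series_matrix":
            df = _read_geo_series_matrix(path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: zero sample columns")

    classes = None
    if class_path is not None:
        cmap = pd.read_csv(class_path, sep="\t", index_col=0).iloc[:, 0]
        classes = {str(k): str(v) for k, v in cmap.items()}
    return ExpressionMatrix.from_frame(df, classes, clip_negative=clip_negative)


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that :func:`load_expression_matrix` reads back identically."""
    df = x.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def log2_rpkm_transform(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """log2(RPKM + pseudocount).

    The pseudocount must be at least 1: smaller values would map small RPKM
    to negative numbers, which the chi-square metric cannot accommodate.
    """
    if pseudocount < 1:
        raise ValueError("pseudocount must be >= 1 to keep transformed values non-negative")
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("RPKM values must be non-negative")
    return np.log2(v + pseudocount)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in identical order.

    Matching is by case-folded gene symbol (microarray and RNA-seq exports
    disagree on capitalisation).  Order follows the first matrix.
    """
    fold_a = [g.casefold() for g in a.gene_ids]
    fold_b = {g.casefold(): i for i, g in enumerate(b.gene_ids)}
    keep_a = [i for i, g in enumerate(fold_a) if g in fold_b]
    if not keep_a:
        raise ValueError(
            "no shared genes between matrices "
            f"(first ids: {a.gene_ids[:3]} vs {b.gene_ids[:3]}); "
            "check that both use the same identifier style"
        )
    keep_b = [fold_b[fold_a[i]] for i in keep_a]
    logger.info("gene intersection: %d shared of %d / %d", len(keep_a), a.n_genes, b.n_genes)

    def _take(x: ExpressionMatrix, rows: list[int]) -> ExpressionMatrix:
        return ExpressionMatrix(
            x.values[rows],
            tuple(x.gene_ids[i] for i in rows),
            x.sample_ids,
            x.sample_class,
        )

    return _take(a, keep_a), _take(b, keep_b)


def rank_normalize(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Map every sample column onto a common reference distribution by rank.

    The reference is the mean sorted profile over all columns of both
    datasets (quantile-normalisation style).  Each column is replaced by the
    reference values at its within-column ranks, with ties resolved by
    average rank (averaged reference values).  Because only ranks enter, the
    output is invariant under any strictly increasing transform of a column
    — the property that makes microarray and RNA-seq columns comparable.
    """
    fa = [g.casefold() for g in a.gene_ids]
    fb = [g.casefold() for g in b.gene_ids]
    if fa != fb:
        raise ValueError("gene universes differ; run intersect_genes first")
    k = a.n_genes
    pooled = np.concatenate([a.values, b.values], axis=1)
    reference = np.sort(pooled, axis=0).mean(axis=1)  # mean sorted profile, ascending

    def _normalize(values: np.ndarray) -> np.ndarray:
        out = np.empty_like(values, dtype=float)
        for j in range(values.shape[1]):
            col = values[:, j]
            if np.ptp(col) == 0:
                raise ValueError(f"constant sample column (index {j}); cannot rank-normalize")
            ranks = rankdata(col, method="average")  # in [1, k]
            out[:, j] = np.interp(ranks, np.arange(1, k + 1), reference)
        return out

    return a.with_values(_normalize(a.values)), b.with_values(_normalize(b.values))
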