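"""Canonical correspondence analysis in the chi-square metric.

The model: a non-negative gene x sample matrix X is standardised to

    S = D_r^{-1/2} (X/n - r c^T) D_c^{-1/2}

where n is the grand total and r, c the row/column masses (margins of X/n).
The squared Frobenius norm of S is the total inertia, Pearson chi-square of
X divided by n.  Explanatory gene-level profiles Z (differentiation
programmes) constrain the solution through the weighted least-squares
projector

    Q = D_r^{1/2} Z (Z^T D_r Z)^{-1} Z^T D_r^{1/2},

and the SVD of the constrained matrix S* = Q S = U D_alpha V^T yields gene
and sample ordination scores.  With Z spanning everything (or absent) the
procedure reduces to plain correspondence analysis, which serves as an
internal oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExplanatoryMatrix",
    "CCAResult",
    "chi_square_standardize",
    "standardize_explanatory",
    "projection_matrix",
    "constrained_projection",
    "cca",
    "correspondence_analysis",
    "pca",
]

#: relative singular-value cutoff below which constrained axes are dropped
SV_RTOL = 1e-10


class CollinearityError(ValueError):
    """Explanatory variables are linearly dependent after standardization."""


class DegenerateVariableError(ValueError):
    """An explanatory column is constant (zero variance)."""


@dataclass(frozen=True)
class ExplanatoryMatrix:
    """Standardized explanatory profiles Z (k genes x q programmes).

    Columns have weighted mean 0 and weighted variance 1 in the row-mass
    metric used for the projection, so that regression and correlation are
    computed in a single geometry.
    """

    z: np.ndarray
    programme_names: tuple[str, ...]
    standardized: bool = True

    @property
    def q(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class CCAResult:
    """Full ordination output: singular values, all score types, inertia.

    Score naming: LC scores are the fitted (constrained) gene coordinates
    D_r^{-1/2} U (standard) and D_r^{-1/2} U D_alpha (principal); WA scores
    are weighted averages obtained by projecting S onto the sample scores,
    D_r^{-1/2} S V (standard) and D_r^{-1/2} S V D_alpha (principal), so
    that in the unconstrained limit WA-standard coincides with the
    principal gene coordinates of correspondence analysis.  Sample scores
    are D_c^{-1/2} V (standard) and D_c^{-1/2} V D_alpha (principal).
    """

    singular_values: np.ndarray            # (m,) descending
    gene_scores_lc_standard: np.ndarray    # (k, m)
    gene_scores_lc_principal: np.ndarray   # (k, m)
    gene_scores_wa_standard: np.ndarray    # (k, m)
    gene_scores_wa_principal: np.ndarray   # (k, m)
    sample_scores_standard: np.ndarray     # (p, m)
    sample_scores_principal: np.ndarray    # (p, m)
    biplot_scores: np.ndarray | None       # (q, m) weighted correlations, or None (CA)
    inertia_total: float
    inertia_constrained: float
    row_masses: np.ndarray                 # (k,) sums to 1
    col_masses: np.ndarray                 # (p,) sums to 1
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    programme_names: tuple[str, ...] | None = None
    sample_class: tuple[str, ...] | None = None

    @property
    def m(self) -> int:
        return len(self.singular_values)

    @property
    def inertia_unconstrained(self) -> float:
        return self.inertia_total - self.inertia_constrained

    @property
    def percent_explained(self) -> float:
        """I_C / I_T; NaN for a matrix with zero total inertia."""
        if self.inertia_total == 0:
            return float("nan")
        return self.inertia_constrained / self.inertia_total

    def axis_inertia_fraction(self, axis: int) -> float:
        """alpha_axis^2 / I_C — share of the constrained inertia on one axis."""
        return float(self.singular_values[axis] ** 2 / self.inertia_constrained)

    def save(self, out_dir: str | Path) -> None:
        """Serialize as a directory of TSVs plus a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        axes = [f"axis{i + 1}" for i in range(self.m)]
        pd.DataFrame(
            {"singular_value": self.singular_values, "inertia": self.singular_values**2}
        ).to_csv(out / "singular_values.tsv", sep="\t", index=False)
        gene = pd.DataFrame(index=list(self.gene_ids))
        gene.index.name = "gene_id"
        for name, arr in [
            ("lc_standard", self.gene_scores_lc_standard),
            ("lc_principal", self.gene_scores_lc_principal),
            ("wa_standard", self.gene_scores_wa_standard),
            ("wa_principal", self.gene_scores_wa_principal),
        ]:
            for j, ax in enumerate(axes):
                gene[f"{name}_{ax}"] = arr[:, j]
        gene.to_csv(out / "gene_scores.tsv", sep="\t")
        samp = pd.DataFrame(index=list(self.sample_ids))
        samp.index.name = "sample_id"
        if self.sample_class is not None:
            samp["class"] = list(self.sample_class)
        for name, arr in [
            ("standard", self.sample_scores_standard),
            ("principal", self.sample_scores_principal),
        ]:
            for j, ax in enumerate(axes):
                samp[f"{name}_{ax}"] = arr[:, j]
        samp.to_csv(out / "sample_scores.tsv", sep="\t")
        if self.biplot_scores is not None:
            bp = pd.DataFrame(
                self.biplot_scores, index=list(self.programme_names or ()), columns=axes
            )
            bp.index.name = "programme"
            bp.to_csv(out / "biplot_scores.tsv", sep="\t")
        pd.DataFrame(
            {
                "quantity": ["total", "constrained", "unconstrained"],
                "inertia": [
                    self.inertia_total,
                    self.inertia_constrained,
                    self.inertia_unconstrained,
                ],
            }
        ).to_csv(out / "inertia.tsv", sep="\t", index=False)
        summary = {
            "n_axes": self.m,
            "inertia_total": self.inertia_total,
            "inertia_constrained": self.inertia_constrained,
            "percent_explained": self.percent_explained,
            "programmes": list(self.programme_names or ()),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))


# ---------------------------------------------------------------------------
# building blocks


def chi_square_standardize(
    x: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Standardize X in the chi-square metric.

    Returns ``(S, r, c, n)`` with S_ij = (x_ij/n - r_i c_j) / sqrt(r_i c_j).
    Scale-invariant: X and 2X give the same S.
    """
    X = x.values
    n = float(X.sum())
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("zero row or column margin; invalid ExpressionMatrix")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return S, r, c, n


def _weighted_standardize_columns(
    z: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to weighted mean 0, variance 1; returns (z_std, sd)."""
    w = weights / weights.sum()
    mean = w @ z
    centered = z - mean
    var = w @ centered**2
    return centered, np.sqrt(var)


def standardize_explanatory(
    z_raw: np.ndarray,
    r: np.ndarray,
    programme_names: tuple[str, ...] | None = None,
    *,
    weighted: bool = True,
) -> ExplanatoryMatrix:
    """Standardize explanatory columns to mean 0, variance 1.

    By default the row masses r weight both moments, so Z lives in the same
    D_r metric as the projection; ``weighted=False`` gives the plain
    unweighted standardization for sensitivity checks.
    """
    z = np.atleast_2d(np.asarray(z_raw, dtype=float))
    if z.ndim == 2 and z.shape[0] == 1 and len(r) != 1:
        z = z.T
    k, q = z.shape
    if k != len(r):
        raise ValueError(f"Z has {k} rows but {len(r)} row masses")
    names = tuple(programme_names) if programme_names else tuple(f"Z{j + 1}" for j in range(q))
    if len(names) != q:
        raise ValueError("programme_names length mismatch")
    weights = r if weighted else np.full(k, 1.0 / k)
    centered, sd = _weighted_standardize_columns(z, weights)
    if (sd == 0).any():
        culprits = [names[j] for j in np.flatnonzero(sd == 0)]
        raise DegenerateVariableError(f"constant explanatory column(s): {culprits}")
    z_std = centered / sd
    _check_rank(z_std, r, names)
    return ExplanatoryMatrix(z_std, names, standardized=True)


def _check_rank(z_std: np.ndarray, r: np.ndarray, names: tuple[str, ...]) -> int:
    """Effective rank of D_r^{1/2} Z_std, raising on genuine collinearity.

    Weighted centering removes the direction of sqrt(r) from the column
    space, so q columns can span at most min(q, k-1) dimensions; a rank
    below that bound means the variables themselves are linearly dependent.
    """
    k, q = z_std.shape
    W = np.sqrt(r)[:, None] * z_std
    s = np.linalg.svd(W, compute_uv=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    structural = min(q, k - 1) if k > 1 else min(q, 1)
    if rank < structural:
        # pivoted QR orders columns by how much new span they add
        _, _, piv = scipy_qr(W, pivoting=True)
        culprits = [names[j] for j in piv[rank:]]
        raise CollinearityError(
            f"explanatory columns are collinear (rank {rank} < {structural}); "
            f"dependent column(s): {culprits}"
        )
    return rank


def projection_matrix(z: ExplanatoryMatrix, r: np.ndarray) -> np.ndarray:
    """The symmetric idempotent projector Q onto span(D_r^{1/2} Z).

    Computed from an orthonormal basis of the column space rather than the
    Gram inverse, which stays well-defined in the full-span limit where
    weighted centering makes the Gram matrix singular by construction.
    """
    W = np.sqrt(r)[:, None] * z.z
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    B = U[:, :rank]
    return B @ B.T


def constrained_projection(S: np.ndarray, z: ExplanatoryMatrix, r: np.ndarray) -> np.ndarray:
    """Project the standardized matrix onto the explanatory span: S* = Q S."""
    if not z.standardized:
        raise ValueError("explanatory matrix must be standardized first")
    _check_rank(z.z, r, z.programme_names)
    return projection_matrix(z, r) @ S


# ---------------------------------------------------------------------------
# main entry points


def _svd_scores(S_star: np.ndarray, m_cap: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated SVD of the (constrained) matrix: returns (U, alpha, V)."""
    U, alpha, Vt = np.linalg.svd(S_star, full_matrices=False)
    m = min(m_cap, len(alpha))
    U, alpha, V = U[:, :m], alpha[:m], Vt[:m].T
    if alpha.size and alpha[0] > 0:
        keep = alpha >= SV_RTOL * alpha[0]
        U, alpha, V = U[:, keep], alpha[keep], V[:, keep]
    else:
        U, alpha, V = U[:, :0], alpha[:0], V[:, :0]
    return U, alpha, V


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    am = a - w @ a
    bm = b - w @ b
    cov = w @ (am * bm)
    denom = np.sqrt((w @ am**2) * (w @ bm**2))
    if denom == 0:
        return 0.0
    return float(cov / denom)


def _assemble(
    U: np.ndarray,
    alpha: np.ndarray,
    V: np.ndarray,
    S: np.ndarray,
    r: np.ndarray,
    c: np.ndarray,
    I_T: float,
    I_C: float,
    z: ExplanatoryMatrix | None,
    x: ExpressionMatrix,
) -> CCAResult:
    # fix the arbitrary SVD signs: largest-|biplot| programme positive per
    # axis (largest-|sample score| when there is no Z)
    lc_standard = U / np.sqrt(r)[:, None]
    if z is not None:
        biplot = np.empty((z.q, len(alpha)))
        for jq in range(z.q):
            for ja in range(len(alpha)):
                biplot[jq, ja] = _weighted_corr(z.z[:, jq], lc_standard[:, ja], r)
        ref = biplot
    else:
        biplot = None
        ref = V / np.sqrt(c)[:, None]  # standard sample scores
    for j in range(len(alpha)):
        col = ref[:, j] if biplot is None else biplot[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
            if biplot is not None:
                biplot[:, j] *= -1

    lc_standard = U / np.sqrt(r)[:, None]
    lc_principal = lc_standard * alpha
    wa_standard = (S @ V) / np.sqrt(r)[:, None]
    wa_principal = wa_standard * alpha
    samp_standard = V / np.sqrt(c)[:, None]
    samp_principal = samp_standard * alpha
    return CCAResult(
        singular_values=alpha,
        gene_scores_lc_standard=lc_standard,
        gene_scores_lc_principal=lc_principal,
        gene_scores_wa_standard=wa_standard,
        gene_scores_wa_principal=wa_principal,
        sample_scores_standard=samp_standard,
        sample_scores_principal=samp_principal,
        biplot_scores=biplot,
        inertia_total=I_T,
        inertia_constrained=I_C,
        row_masses=r,
        col_masses=c,
        gene_ids=x.gene_ids,
        sample_ids=x.sample_ids,
        programme_names=None if z is None else z.programme_names,
        sample_class=x.sample_class,
    )


def cca(
    x: ExpressionMatrix,
    z_raw: np.ndarray,
    programme_names: tuple[str, ...] | list[str] | None = None,
    *,
    weighted_z: bool = True,
) -> CCAResult:
    """Constrained ordination of ``x`` by explanatory profiles ``z_raw``.

    ``z_raw`` is a k x q matrix sharing the gene order of ``x`` (a single
    differentiation variable may be passed as a 1-D vector, giving the
    one-dimensional scoring solution).  Composes chi-square standardization,
    weighted projection and SVD; at most min(q, p-1, k) axes are returned,
    with numerically null axes dropped.
    """
    S, r, c, _ = chi_square_standardize(x)
    z = standardize_explanatory(z_raw, r, tuple(programme_names) if programme_names else None,
                                weighted=weighted_z)
    S_star = constrained_projection(S, z, r)
    I_T = float((S**2).sum())
    I_C = float((S_star**2).sum())
    k, p = S.shape
    U, alpha, V = _svd_scores(S_star, m_cap=min(z.q, p - 1, k))
    res = _assemble(U, alpha, V, S, r, c, I_T, I_C, z, x)
    logger.info(
        "cca: %d axes, I_C/I_T = %.4f", res.m, res.percent_explained
    )
    return res


def correspondence_analysis(x: ExpressionMatrix) -> CCAResult:
    """Unconstrained correspondence analysis: SVD of S itself.

    Equivalent to ``cca`` with explanatory variables spanning the whole
    space; the full total inertia is "constrained".  Used throughout as the
    oracle for the full-span limit of the constrained analysis.
    """
    S, r, c, _ = chi_square_standardize(x)
    I_T = float((S**2).sum())
    k, p = S.shape
    U, alpha, V = _svd_scores(S, m_cap=min(p - 1, k - 1) if min(k, p) > 1 else 1)
    return _assemble(U, alpha, V, S, r, c, I_T, I_T, None, x)


def pca(
    x: np.ndarray | ExpressionMatrix,
    center: bool = True,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA of a gene x sample matrix, columns as variables.

    Returns ``(scores, loadings, eigenvalues, percent_variance)`` where the
    row (gene) scores are directly usable as explanatory profiles for
    :func:`cca`.  Eigenvalues use the 1/(k-1) sample-covariance convention.
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    k, p = X.shape
    if p < 2:
        raise ValueError("PCA requires at least 2 columns")
    Xc = X - X.mean(axis=0) if center else X.copy()
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column with scale=True")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = int((s > (s[0] * 1e-12 if s.size and s[0] > 0 else 1)).sum())
    U, s, V = U[:, :m], s[:m], Vt[:m].T
    # deterministic orientation: largest-|loading| positive on each axis
    for j in range(m):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    eigenvalues = s**2 / (k - 1)
    total_var = (Xc**2).sum() / (k - 1)
    percent = 100.0 * eigenvalues / total_var
    scores = U * s
    return scores, V, eigenvalues, percent
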