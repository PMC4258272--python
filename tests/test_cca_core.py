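import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from oracles import brute_force_standardize

from ccadiff import (
    ExpressionMatrix,
    cca,
    chi_square_standardize,
    constrained_projection,
    correspondence_analysis,
    pca,
    standardize_explanatory,
)
from ccadiff.cca_core import (
    CollinearityError,
    DegenerateVariableError,
    projection_matrix,
)


class TestChiSquareStandardize:
    def test_matches_entrywise_formula(self, toy_matrix):
        S, r, c, n = chi_square_standardize(toy_matrix)
        assert n == 21.0
        np.testing.assert_allclose(S, brute_force_standardize(toy_matrix.values), atol=1e-12)
        assert r.sum() == pytest.approx(1.0)
        assert c.sum() == pytest.approx(1.0)

    def test_independence_gives_zero_matrix(self):
        x = ExpressionMatrix(np.full((3, 2), 4.0), ("a", "b", "c"), ("s", "t"))
        S, _, _, _ = chi_square_standardize(x)
        np.testing.assert_allclose(S, 0.0, atol=1e-15)

    def test_scale_invariance(self, toy_matrix):
        S1, *_ = chi_square_standardize(toy_matrix)
        S2, *_ = chi_square_standardize(toy_matrix.with_values(2.0 * toy_matrix.values))
        np.testing.assert_allclose(S1, S2, atol=1e-14)

    def test_frobenius_norm_is_total_inertia(self, toy_matrix):
        # Pearson chi-square of the table, divided by n
        S, r, c, n = chi_square_standardize(toy_matrix)
        X = toy_matrix.values
        expected = n * np.outer(r, c)
        chi2 = ((X - expected) ** 2 / expected).sum()
        assert (S**2).sum() == pytest.approx(chi2 / n, rel=1e-12)


class TestStandardizeExplanatory:
    def test_hand_computed_uniform_masses(self):
        r = np.full(3, 1 / 3)
        z = standardize_explanatory(np.array([1.0, 2.0, 3.0]), r)
        # weighted mean 2, centered (-1,0,1), weighted sd sqrt(2/3)
        np.testing.assert_allclose(z.z[:, 0], np.array([-1, 0, 1]) / np.sqrt(2 / 3))
        w_mean = r @ z.z[:, 0]
        w_var = r @ z.z[:, 0] ** 2
        assert w_mean == pytest.approx(0.0, abs=1e-14)
        assert w_var == pytest.approx(1.0)

    def test_idempotent_on_already_standardized(self):
        rng = np.random.default_rng(3)
        r = rng.dirichlet(np.ones(6))
        z1 = standardize_explanatory(rng.normal(size=(6, 2)), r)
        z2 = standardize_explanatory(z1.z, r)
        np.testing.assert_allclose(z1.z, z2.z, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateVariableError):
            standardize_explanatory(np.ones((4, 1)), np.full(4, 0.25))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=6)
        z = np.column_stack([a, 2 * a + 1])
        with pytest.raises(CollinearityError, match="Z2|Z1"):
            standardize_explanatory(z, np.full(6, 1 / 6), ("Z1", "Z2"))


class TestProjection:
    def test_projector_idempotent_and_symmetric(self):
        rng = np.random.default_rng(5)
        r = rng.dirichlet(np.ones(5))
        z = standardize_explanatory(rng.normal(size=(5, 1)), r)
        Q = projection_matrix(z, r)
        np.testing.assert_allclose(Q @ Q, Q, atol=1e-10)
        np.testing.assert_allclose(Q, Q.T, atol=1e-10)

    def test_projection_shrinks_norm(self, random_matrix_factory):
        x = random_matrix_factory(7, 4, seed=6)
        S, r, _, _ = chi_square_standardize(x)
        z = standardize_explanatory(np.random.default_rng(1).normal(size=(7, 2)), r)
        S_star = constrained_projection(S, z, r)
        assert (S_star**2).sum() <= (S**2).sum() + 1e-12

    def test_full_span_limit_is_identity_on_S(self, random_matrix_factory):
        x = random_matrix_factory(6, 4, seed=8)
        S, r, _, _ = chi_square_standardize(x)
        z = standardize_explanatory(np.random.default_rng(2).normal(size=(6, 6)), r)
        np.testing.assert_allclose(constrained_projection(S, z, r), S, atol=1e-12)


class TestCCA:
    def test_full_rank_z_reproduces_correspondence_analysis(self, random_matrix_factory):
        x = random_matrix_factory(6, 4, seed=9)
        Z = np.random.default_rng(10).normal(size=(6, 6))
        np.testing.assert_allclose(
            cca(x, Z).singular_values,
            correspondence_analysis(x).singular_values,
            atol=1e-10,
        )

    def test_single_variable_gives_one_axis(self, random_matrix_factory):
        x = random_matrix_factory(8, 5, seed=11)
        res = cca(x, np.random.default_rng(3).normal(size=8))
        assert res.m == 1
        assert res.sample_scores_principal.shape == (5, 1)

    def test_single_component_closed_form(self, random_matrix_factory):
        # Z spanning one direction: alpha_1^2 equals the squared norm of the
        # projection of S onto that direction, computed by hand.
        x = random_matrix_factory(4, 3, seed=12)
        S, r, _, _ = chi_square_standardize(x)
        z_raw = np.random.default_rng(4).normal(size=4)
        z = standardize_explanatory(z_raw, r)
        w = np.sqrt(r) * z.z[:, 0]
        w = w / np.linalg.norm(w)
        expected = (np.outer(w, w @ S) ** 2).sum()
        res = cca(x, z_raw)
        assert res.singular_values[0] ** 2 == pytest.approx(expected, rel=1e-10)
        assert res.inertia_constrained == pytest.approx(expected, rel=1e-10)

    def test_result_invariants(self, random_matrix_factory):
        x = random_matrix_factory(10, 6, seed=13)
        Z = np.random.default_rng(5).normal(size=(10, 3))
        res = cca(x, Z)
        assert res.m <= min(3, 5, 10)
        assert 0 <= res.inertia_constrained <= res.inertia_total
        assert 0 <= res.percent_explained <= 1
        assert np.all(np.abs(res.biplot_scores) <= 1 + 1e-12)
        assert res.row_masses.sum() == pytest.approx(1.0)
        assert res.col_masses.sum() == pytest.approx(1.0)
        assert np.sum(res.singular_values**2) == pytest.approx(res.inertia_constrained)
        # U, V orthonormal: reconstruct them from the stored scores
        U = res.gene_scores_lc_standard * np.sqrt(res.row_masses)[:, None]
        V = res.sample_scores_standard * np.sqrt(res.col_masses)[:, None]
        np.testing.assert_allclose(U.T @ U, np.eye(res.m), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(res.m), atol=1e-10)

    def test_monotone_inertia_in_nested_models(self, random_matrix_factory):
        x = random_matrix_factory(12, 5, seed=14)
        Z = np.random.default_rng(6).normal(size=(12, 4))
        prev = 0.0
        for q in range(1, 5):
            ic = cca(x, Z[:, :q]).inertia_constrained
            assert ic >= prev - 1e-12
            prev = ic

    def test_gene_permutation_equivariance(self, random_matrix_factory):
        x = random_matrix_factory(9, 4, seed=15)
        Z = np.random.default_rng(7).normal(size=(9, 2))
        res = cca(x, Z)
        perm = np.random.default_rng(8).permutation(9)
        xp = ExpressionMatrix(
            x.values[perm], tuple(x.gene_ids[i] for i in perm), x.sample_ids
        )
        resp = cca(xp, Z[perm])
        np.testing.assert_allclose(res.singular_values, resp.singular_values, atol=1e-10)
        np.testing.assert_allclose(
            res.sample_scores_principal, resp.sample_scores_principal, atol=1e-10
        )
        np.testing.assert_allclose(res.biplot_scores, resp.biplot_scores, atol=1e-10)
        np.testing.assert_allclose(
            res.gene_scores_wa_principal[perm], resp.gene_scores_wa_principal, atol=1e-10
        )

    def test_save_roundtrip(self, tmp_path, random_matrix_factory):
        x = random_matrix_factory(6, 4, seed=16)
        res = cca(x, np.random.default_rng(9).normal(size=(6, 2)))
        res.save(tmp_path / "out")
        for f in ["singular_values.tsv", "gene_scores.tsv", "sample_scores.tsv",
                  "biplot_scores.tsv", "inertia.tsv", "summary.json"]:
            assert (tmp_path / "out" / f).exists()


class TestCorrespondenceAnalysis:
    def test_all_equal_matrix_has_no_axes(self):
        x = ExpressionMatrix(np.full((4, 3), 2.0), tuple("abcd"), ("s", "t", "u"))
        res = correspondence_analysis(x)
        assert res.m == 0
        assert res.inertia_total == pytest.approx(0.0, abs=1e-15)

    def test_perfect_association_2x2(self):
        x = ExpressionMatrix(np.array([[10.0, 0.0], [0.0, 10.0]]), ("a", "b"), ("s", "t"))
        res = correspondence_analysis(x)
        assert res.m == 1
        assert res.singular_values[0] == pytest.approx(1.0, abs=1e-12)

    def test_conservation(self, random_matrix_factory):
        x = random_matrix_factory(7, 5, seed=17)
        res = correspondence_analysis(x)
        assert np.sum(res.singular_values**2) == pytest.approx(res.inertia_total, rel=1e-10)

    def test_wa_standard_equals_principal_gene_scores(self, random_matrix_factory):
        # transition formula in the unconstrained limit
        x = random_matrix_factory(8, 4, seed=18)
        res = correspondence_analysis(x)
        np.testing.assert_allclose(
            res.gene_scores_wa_standard, res.gene_scores_lc_principal, atol=1e-10
        )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_constrained_eigenvalues_match_vegan(tmp_path, random_matrix_factory):
    """Independent oracle: vegan::cca on the same matrix and constraints."""
    x = random_matrix_factory(8, 5, seed=19)
    Z = np.random.default_rng(20).normal(size=(8, 2))
    np.savetxt(tmp_path / "X.txt", x.values)
    np.savetxt(tmp_path / "Z.txt", Z)
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        X <- as.matrix(read.table("X.txt"))
        Z <- as.data.frame(as.matrix(read.table("Z.txt")))
        m <- cca(X ~ ., data = Z)
        cat(sprintf("%.15g\\n", m$CCA$eig), sep = "")
        """
    )
    (tmp_path / "oracle.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    vegan_eig = np.array([float(v) for v in out.stdout.split()])
    ours = cca(x, Z).singular_values ** 2
    np.testing.assert_allclose(np.sort(ours)[::-1], np.sort(vegan_eig)[::-1], rtol=1e-8)


class TestPCA:
    def test_collinear_data_explains_everything_on_pc1(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t, -t])
        _, _, _, pct = pca(X)
        assert pct[0] == pytest.approx(100.0)

    def test_eigenvalues_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 3))
        _, _, eig, _ = pca(X)
        cov_eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(eig, cov_eig[: len(eig)], rtol=1e-10)

    def test_constant_column_with_scale_rejected(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            pca(X, scale=True)

    def test_gene_scores_usable_as_explanatory(self, random_matrix_factory):
        x = random_matrix_factory(20, 4, seed=22)
        scores, _, _, _ = pca(x)
        res = cca(x, scores[:, :2])
        assert res.m == 2
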