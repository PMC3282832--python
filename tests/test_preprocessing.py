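"""Standardization, whitening, projection lengths and sigmoid weighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glfd import (
    ExpressionMatrix,
    delta_threshold,
    f_statistic,
    projection_length,
    residualize,
    sigmoid_weights,
    standardize_genes,
    weight_residuals,
    weighted_residual_matrix,
    whiten_clinical,
)

from conftest import random_expression


class TestStandardizeGenes:
    def test_center_and_scale_by_definition(self):
        expr = ExpressionMatrix([[1.0, 2.0, 3.0]], ["g"], ["a", "b", "c"])
        out = standardize_genes(expr)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)
        assert out.standardized

    def test_idempotent_on_standardized_rows(self, rng):
        expr = standardize_genes(random_expression(rng))
        again = standardize_genes(expr)
        np.testing.assert_array_equal(expr.values, again.values)

    def test_output_moments(self, rng):
        out = standardize_genes(random_expression(rng, p=10, n=6))
        assert np.max(np.abs(out.values.mean(axis=1))) < 1e-12
        assert np.max(np.abs(np.linalg.norm(out.values, axis=1) - 1)) < 1e-12

    def test_constant_row_dropped_with_warning(self, rng, caplog):
        values = rng.standard_normal((3, 5))
        values[1] = 7.0
        expr = ExpressionMatrix(values, ["g0", "gconst", "g2"], list("abcde"))
        with caplog.at_level("WARNING", logger="glfd"):
            out = standardize_genes(expr)
        assert out.gene_ids == ["g0", "g2"]
        assert "gconst" in caplog.text

    def test_constant_row_strict_errors_with_gene_id(self, rng):
        values = rng.standard_normal((2, 5))
        values[0] = 0.0
        expr = ExpressionMatrix(values, ["flat", "g1"], list("abcde"))
        with pytest.raises(ValueError, match="flat"):
            standardize_genes(expr, constant_policy="error")

    def test_non_finite_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix([[1.0, np.nan, 2.0]], ["g"], list("abc"))


class TestWhitenClinical:
    def test_single_column_is_centered_normalization(self, rng):
        b = rng.standard_normal(12)
        clin = whiten_clinical(b[:, None])
        centered = b - b.mean()
        np.testing.assert_allclose(
            np.abs(clin.whitened[:, 0]),
            np.abs(centered / np.linalg.norm(centered)),
            atol=1e-10,
        )

    def test_orthonormal_centered_columns_stay_orthonormal(self, rng):
        raw = np.linalg.qr(rng.standard_normal((15, 4)))[0][:, :2]
        raw -= raw.mean(axis=0)
        raw /= np.linalg.norm(raw, axis=0)
        # re-orthonormalize after centering so input is exactly orthonormal
        raw = np.linalg.qr(raw)[0]
        clin = whiten_clinical(raw)
        np.testing.assert_allclose(
            clin.whitened.T @ clin.whitened, np.eye(2), atol=1e-10
        )

    def test_random_matrix_orthonormal_and_span_preserved(self, rng):
        raw = rng.standard_normal((20, 3))
        clin = whiten_clinical(raw)
        W = clin.whitened
        np.testing.assert_allclose(W.T @ W, np.eye(3), atol=1e-8)
        # independent orthonormalization of the centered columns
        Q = np.linalg.qr(raw - raw.mean(axis=0))[0]
        principal_cosines = np.linalg.svd(Q.T @ W, compute_uv=False)
        assert np.min(principal_cosines) > 1 - 1e-8

    def test_rank_deficient_reports_numerical_rank(self, rng):
        col = rng.standard_normal(10)
        raw = np.column_stack([col, 2 * col, rng.standard_normal(10)])
        with pytest.raises(ValueError, match="rank 2"):
            whiten_clinical(raw)

    def test_too_many_factors_rejected(self, rng):
        with pytest.raises(ValueError, match="n > m"):
            whiten_clinical(rng.standard_normal((5, 4)))


class TestProjectionLength:
    def test_vector_inside_subspace(self, rng):
        basis = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        assert projection_length(basis[:, 0], basis) == pytest.approx(1.0)

    def test_vector_orthogonal_to_subspace(self, rng):
        Q = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        assert projection_length(Q[:, 2], Q[:, :2]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_projection_matrix_oracle(self, rng):
        basis = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        g = rng.standard_normal(10)
        g /= np.linalg.norm(g)
        P = basis @ basis.T
        assert projection_length(g, basis) == pytest.approx(
            np.linalg.norm(P @ g), abs=1e-12
        )

    def test_rejects_non_unit_vector(self, rng):
        basis = np.linalg.qr(rng.standard_normal((6, 1)))[0]
        with pytest.raises(ValueError, match="unit length"):
            projection_length(np.ones(6), basis)

    def test_rejects_non_orthonormal_basis(self, rng):
        g = np.zeros(6)
        g[0] = 1.0
        with pytest.raises(ValueError, match="orthonormal"):
            projection_length(g, np.ones((6, 2)))


class TestResidualize:
    @staticmethod
    def _setup(rng, p=12, n=10, m=2):
        expr = standardize_genes(random_expression(rng, p=p, n=n))
        clin = whiten_clinical(
            rng.standard_normal((n, m)), sample_ids=expr.sample_ids
        )
        return expr, clin

    def test_gene_in_clinical_span_has_zero_residual(self, rng):
        _, clin = self._setup(rng)
        g = clin.whitened[:, 0]
        expr = ExpressionMatrix(
            g[None, :], ["g"], clin.sample_ids, standardized=True
        )
        wr = residualize(expr, clin)
        assert np.linalg.norm(wr.residuals[0]) < 1e-10
        assert wr.projection_lengths[0] == pytest.approx(1.0)

    def test_orthogonal_gene_passes_through(self, rng):
        expr, clin = self._setup(rng)
        B = clin.whitened
        g = expr.values[0] - B @ (B.T @ expr.values[0])
        g -= g.mean()
        g /= np.linalg.norm(g)
        e = ExpressionMatrix(g[None, :], ["g"], clin.sample_ids, standardized=True)
        wr = residualize(e, clin)
        np.testing.assert_allclose(wr.residuals[0], g, atol=1e-10)

    def test_matches_projection_matrix_oracle(self, rng):
        expr, clin = self._setup(rng)
        B = clin.whitened
        P = np.eye(len(clin.sample_ids)) - B @ B.T
        wr = residualize(expr, clin)
        np.testing.assert_allclose(wr.residuals, expr.values @ P.T, atol=1e-10)

    def test_pythagoras(self, rng):
        expr, clin = self._setup(rng, p=30)
        wr = residualize(expr, clin)
        np.testing.assert_allclose(
            wr.projection_lengths**2 + np.linalg.norm(wr.residuals, axis=1) ** 2,
            np.ones(30),
            atol=1e-10,
        )

    def test_orthogonality_to_clinical_basis(self, rng):
        expr, clin = self._setup(rng, p=30)
        wr = residualize(expr, clin)
        assert np.max(np.abs(wr.residuals @ clin.whitened)) < 1e-8

    def test_sample_mismatch_rejected(self, rng):
        expr, clin = self._setup(rng)
        shuffled = list(reversed(clin.sample_ids))
        clin2 = whiten_clinical(clin.raw, sample_ids=shuffled)
        with pytest.raises(ValueError, match="sample identifiers"):
            residualize(expr, clin2)


class TestDeltaThreshold:
    def test_limit_behavior(self):
        assert delta_threshold(1 - 1e-12, 1, 100) < 1e-5
        assert delta_threshold(1e-300, 1, 100) > 0.99

    @pytest.mark.parametrize("alpha", [0.001, 0.01, 0.05])
    @pytest.mark.parametrize("m", [1, 2, 5])
    @pytest.mark.parametrize("n", [20, 100])
    def test_round_trip_with_f_statistic(self, alpha, m, n):
        """delta is the exact inverse of the projection-length F test."""
        delta = delta_threshold(alpha, m, n)
        fq = stats.f.ppf(1 - alpha, m, n - m - 1)
        assert f_statistic(delta, m, n) == pytest.approx(fq, abs=1e-10 * fq)

    def test_monotone_decreasing_in_alpha(self):
        alphas = [0.001, 0.01, 0.05, 0.2]
        deltas = [delta_threshold(a, 2, 50) for a in alphas]
        assert all(d1 > d2 for d1, d2 in zip(deltas, deltas[1:]))

    def test_null_exceedance_probability(self):
        """Fraction of null genes beyond delta matches the alpha level."""
        rng = np.random.default_rng(5)
        n, alpha = 100, 0.05
        delta = delta_threshold(alpha, 1, n)
        basis = whiten_clinical(
            rng.standard_normal((n, 1))
        ).whitened
        G = rng.standard_normal((50_000, n))
        G -= G.mean(axis=1, keepdims=True)
        G /= np.linalg.norm(G, axis=1, keepdims=True)
        frac = np.mean(np.abs(G @ basis[:, 0]) > delta)
        assert frac == pytest.approx(alpha, abs=0.01)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError):
            delta_threshold(0.01, 5, 6)


class TestSigmoidWeights:
    def test_midpoint_is_half(self):
        assert sigmoid_weights(np.array([0.3]), 100.0, 0.3)[0] == pytest.approx(0.5)

    def test_direct_substitution(self):
        w = sigmoid_weights(np.array([0.4]), 100.0, 0.3)[0]
        assert w == pytest.approx(1 - 1 / (1 + np.exp(10.0)))

    def test_vector_matches_scalar_loop(self, rng):
        lengths = rng.uniform(0, 1, 50)
        w = sigmoid_weights(lengths, 100.0, 0.32)
        loop = [1 - 1 / (1 + np.exp(100.0 * (l - 0.32))) for l in lengths]
        np.testing.assert_allclose(w, loop, atol=1e-12)

    def test_extreme_arguments_saturate_finitely(self):
        w = sigmoid_weights(np.array([0.0, 1.0]), 1e6, 0.5)
        assert np.all(np.isfinite(w))
        assert w[0] == pytest.approx(0.0, abs=1e-300)
        assert w[1] == pytest.approx(1.0)

    def test_strictly_increasing(self, rng):
        lengths = np.sort(rng.uniform(0.25, 0.4, 20))
        w = sigmoid_weights(lengths, 100.0, 0.32)
        assert np.all(np.diff(w) > 0)


class TestWeightResiduals:
    @staticmethod
    def _wr(rng, lengths):
        """Build a residual container with prescribed projection lengths."""
        n = 20
        p = len(lengths)
        residuals = rng.standard_normal((p, n))
        residuals /= np.linalg.norm(residuals, axis=1, keepdims=True)
        residuals *= np.sqrt(1 - np.asarray(lengths)[:, None] ** 2)
        from glfd.preprocessing import WeightedResidualMatrix

        return WeightedResidualMatrix(
            residuals=residuals,
            projection_lengths=np.asarray(lengths, dtype=float),
            gene_ids=[f"g{i}" for i in range(p)],
            sample_ids=[f"s{j}" for j in range(n)],
        )

    def test_all_below_threshold_zeroes_matrix(self, rng):
        wr = weight_residuals(self._wr(rng, [0.1, 0.2]), delta=0.7, phi=100.0)
        assert np.max(np.abs(wr.weighted)) < 1e-10

    def test_all_above_threshold_keeps_residuals(self, rng):
        wr = weight_residuals(self._wr(rng, [0.9, 0.95]), delta=0.3, phi=100.0)
        np.testing.assert_allclose(wr.weighted, wr.residuals, atol=1e-10)

    def test_mixed_rows_match_elementwise_product(self, rng):
        wr = weight_residuals(
            self._wr(rng, [0.1, 0.31, 0.33, 0.9]), delta=0.32, phi=100.0
        )
        expected = wr.weights[:, None] * wr.residuals
        np.testing.assert_array_equal(wr.weighted, expected)


class TestNullCalibration:
    def test_projection_statistic_follows_f_distribution(self):
        """Null genes give Eq.-7-style statistics distributed as F(m, n-m-1)."""
        rng = np.random.default_rng(11)
        m, n = 2, 50
        clin = whiten_clinical(rng.standard_normal((n, m)))
        G = rng.standard_normal((20_000, n))
        G -= G.mean(axis=1, keepdims=True)
        G /= np.linalg.norm(G, axis=1, keepdims=True)
        lengths = np.linalg.norm(G @ clin.whitened, axis=1)
        fstats = f_statistic(lengths, m, n)
        _, pval = stats.kstest(fstats, stats.f(m, n - m - 1).cdf)
        assert pval > 0.001


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    p=st.integers(2, 12),
    n=st.integers(8, 20),
    m=st.integers(1, 3),
    seed=st.integers(0, 2**31 - 1),
)
def test_weighted_residual_matrix_invariants(p, n, m, seed):
    """Orthogonality and Pythagoras hold for arbitrary inputs."""
    if n <= m + 1:
        n = m + 3
    rng = np.random.default_rng(seed)
    expr = standardize_genes(random_expression(rng, p=p, n=n))
    if expr.n_genes == 0:
        return
    clin = whiten_clinical(rng.standard_normal((n, m)), sample_ids=expr.sample_ids)
    wr = weighted_residual_matrix(expr, clin)
    assert np.max(np.abs(wr.residuals @ clin.whitened)) < 1e-8
    np.testing.assert_allclose(
        wr.projection_lengths**2 + np.linalg.norm(wr.residuals, axis=1) ** 2,
        1.0,
        atol=1e-10,
    )
    np.testing.assert_array_equal(wr.weighted, wr.weights[:, None] * wr.residuals)
    order = np.argsort(wr.projection_lengths)
    assert np.all(np.diff(wr.weights[order]) >= -1e-15)
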