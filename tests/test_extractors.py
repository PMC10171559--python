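"""The four extractors: fitted-state contracts, oracles, recovery tests."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fcfingerprint import (
    CohortError,
    CobeExtractor,
    ConvergenceError,
    KsvdExtractor,
    PcaExtractor,
    RawExtractor,
    RpcaExtractor,
    cobe_fit,
    make_extractor,
    principal_component_pursuit,
)
from fcfingerprint.extractors import learn_sparse_dictionary
from fcfingerprint.ksvd import ksvd
from conftest import cohort_from_columns


def sparse_dictionary_data(n_features, k, s0, n_cols, seed, scale=1.0):
    """Y = D0 X0 with unit-norm atoms and exactly s0-sparse columns."""
    rng = np.random.default_rng(seed)
    d0 = rng.standard_normal((n_features, k))
    d0 /= np.linalg.norm(d0, axis=0)
    x0 = np.zeros((k, n_cols))
    for j in range(n_cols):
        idx = rng.choice(k, s0, replace=False)
        x0[idx, j] = (rng.random(s0) + 0.5) * rng.choice([-1, 1], s0) * scale
    return d0, x0, d0 @ x0


class TestPca:
    def test_rank_one_explains_all_variance(self, rng):
        u = rng.standard_normal(50)
        coeffs = rng.standard_normal(8)
        cohort = cohort_from_columns([c * u for c in coeffs], p=4, s=2)
        model = PcaExtractor(1).fit(cohort)
        # centering keeps the data rank 1
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_full_rank_reconstructs_centered_input(self, fc_cohort):
        rank = np.linalg.matrix_rank(
            fc_cohort.values - fc_cohort.values.mean(axis=1, keepdims=True)
        )
        model = PcaExtractor(rank).fit(fc_cohort)
        sub = model.transform(fc_cohort)
        centered = fc_cohort.values - model.mean_[:, None]
        np.testing.assert_allclose(sub.values, centered, atol=1e-8)

    def test_explained_variance_non_increasing(self, fc_cohort):
        model = PcaExtractor(3).fit(fc_cohort)
        assert np.all(np.diff(model.explained_variance_ratio_) <= 1e-12)

    def test_column_centered_orthogonal_to_basis_maps_to_zero(self, rng):
        basis_data = rng.standard_normal((40, 8))
        cohort = cohort_from_columns(list(basis_data.T), p=4, s=2)
        model = PcaExtractor(2).fit(cohort)
        v = rng.standard_normal(40)
        v -= model.basis_ @ (model.basis_.T @ v)
        # column whose training-mean-centered version is orthogonal to the basis
        test = cohort_from_columns([model.mean_ + v] * 4, p=2, s=2)
        sub = model.transform(test)
        np.testing.assert_allclose(sub.values, 0.0, atol=1e-8)

    def test_projection_idempotent(self, fc_cohort):
        model = PcaExtractor(4).fit(fc_cohort)
        once = model.transform(fc_cohort)
        again = model.transform(once.with_values(once.values + model.mean_[:, None]))
        np.testing.assert_allclose(once.values, again.values, atol=1e-10)

    def test_components_beyond_rank_rejected(self, rng):
        u, v = rng.standard_normal(30), rng.standard_normal(30)
        cohort = cohort_from_columns([u, v, u + v, u - v], p=2, s=2)
        with pytest.raises(CohortError, match="rank"):
            PcaExtractor(4).fit(cohort)

    def test_transform_is_linear(self, fc_cohort, rng):
        model = PcaExtractor(3).fit(fc_cohort)
        x = rng.standard_normal(fc_cohort.values.shape)
        z = rng.standard_normal(fc_cohort.values.shape)
        # remove the mean term to expose the linear projector
        px = model.transform(fc_cohort.with_values(x + model.mean_[:, None])).values
        pz = model.transform(fc_cohort.with_values(z + model.mean_[:, None])).values
        pxz = model.transform(
            fc_cohort.with_values(2 * x + 3 * z + model.mean_[:, None])
        ).values
        np.testing.assert_allclose(pxz, 2 * px + 3 * pz, atol=1e-8)


class TestPcp:
    def test_clean_low_rank_has_no_sparse_part(self, rng):
        y = rng.standard_normal((400, 2)) @ rng.standard_normal((2, 60))
        res = principal_component_pursuit(y, tol=1e-9)
        assert np.linalg.norm(res.sparse) / np.linalg.norm(y) < 1e-4

    def test_planted_low_rank_recovered(self, rng):
        l0 = rng.standard_normal((400, 2)) @ rng.standard_normal((2, 60))
        s0 = np.zeros_like(l0)
        mask = rng.random(l0.shape) < 0.01
        s0[mask] = 10 * l0.std() * rng.choice([-1.0, 1.0], size=int(mask.sum()))
        res = principal_component_pursuit(l0 + s0, tol=1e-9)
        rel = np.linalg.norm(res.low_rank - l0) / np.linalg.norm(l0)
        assert rel < 1e-3

    def test_huge_weight_forces_sparse_to_zero(self, rng):
        y = rng.standard_normal((50, 20))
        res = principal_component_pursuit(y, lam=1e6)
        np.testing.assert_allclose(res.sparse, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.low_rank, y, atol=1e-6)

    def test_budget_exhaustion_carries_residual(self, rng):
        y = rng.standard_normal((60, 40))
        with pytest.raises(ConvergenceError) as err:
            principal_component_pursuit(y, tol=1e-12, max_iter=3)
        assert err.value.residual > 0


class TestRpca:
    def test_dictionary_atoms_recover_planted_basis(self):
        """The l1 dictionary stage on S = D0 a0 matches D0 up to sign/permutation."""
        d0, _, s = sparse_dictionary_data(100, 10, 3, 200, seed=3, scale=3.0)
        d, _, _ = learn_sparse_dictionary(s, k=10, lam=0.1, n_iter=200, seed=0)
        corr = np.abs(np.corrcoef(d0.T, d.T)[:10, 10:])
        rows, cols = linear_sum_assignment(-corr)
        assert corr[rows, cols].min() > 0.9

    def test_huge_penalty_zeroes_all_codes(self):
        _, _, s = sparse_dictionary_data(40, 4, 2, 30, seed=5)
        _, codes, errors = learn_sparse_dictionary(s, k=4, lam=1e6, n_iter=5, seed=0)
        np.testing.assert_allclose(codes, 0.0)
        # objective collapses to 0.5*||S||_F^2 when nothing is coded
        assert errors[-1] == pytest.approx(0.5 * np.linalg.norm(s) ** 2, rel=1e-6)

    def test_objective_history_non_increasing(self, fc_cohort):
        model = RpcaExtractor(k=5, lam=0.2, n_iter=30, seed=0).fit(fc_cohort)
        hist = np.asarray(model.objective_history_)
        assert np.all(np.diff(hist) <= 1e-8)

    def test_pcp_split_reconstructs_training_matrix(self, fc_cohort):
        model = RpcaExtractor(k=5, lam=0.2, seed=0).fit(fc_cohort)
        np.testing.assert_allclose(
            model.low_rank_ + model.sparse_, fc_cohort.values, atol=1e-5
        )

    def test_transform_is_projection_onto_dictionary_span(self, fc_cohort, rng):
        model = RpcaExtractor(k=5, lam=0.2, seed=0).fit(fc_cohort)
        sub = model.transform(fc_cohort)
        residual = fc_cohort.values - sub.values
        np.testing.assert_allclose(
            model.dictionary_.T @ residual, 0.0, atol=1e-8
        )

    def test_column_in_span_reproduced(self, fc_cohort, rng):
        model = RpcaExtractor(k=5, lam=0.2, seed=0).fit(fc_cohort)
        coeffs = rng.standard_normal((5, fc_cohort.n_scans))
        inside = fc_cohort.with_values(model.dictionary_ @ coeffs)
        sub = model.transform(inside)
        np.testing.assert_allclose(sub.values, inside.values, atol=1e-8)

    def test_column_orthogonal_to_span_maps_to_zero(self, fc_cohort, rng):
        model = RpcaExtractor(k=5, lam=0.2, seed=0).fit(fc_cohort)
        v = rng.standard_normal(fc_cohort.n_features)
        v -= model.dictionary_ @ np.linalg.lstsq(model.dictionary_, v, rcond=None)[0]
        ortho = fc_cohort.with_values(np.tile(v[:, None], fc_cohort.n_scans))
        np.testing.assert_allclose(model.transform(ortho).values, 0.0, atol=1e-8)

    def test_invalid_hyperparameters_rejected(self, fc_cohort):
        with pytest.raises(ValueError, match="lam"):
            RpcaExtractor(k=5, lam=0.0)
        with pytest.raises(CohortError, match="smaller than the feature"):
            RpcaExtractor(k=fc_cohort.n_features, lam=0.1).fit(fc_cohort)


class TestKsvd:
    def test_exact_recovery_on_sparse_data(self):
        """Residual vanishes on exactly representable data (s0 << k)."""
        _, _, y = sparse_dictionary_data(50, 6, 2, 150, seed=0)
        res = ksvd(y, k=6, s0=2, n_iter=30, seed=0)
        assert res.objective[-1] / np.linalg.norm(y) < 1e-3

    def test_single_atom_rank_one_exact(self, rng):
        atom = rng.standard_normal(30)
        scales = rng.random(10) + 0.5  # nonnegative scale pattern
        y = np.outer(atom, scales)
        res = ksvd(y, k=1, s0=1, n_iter=5, seed=0)
        assert res.objective[-1] / np.linalg.norm(y) < 1e-10

    def test_objective_non_increasing(self):
        _, _, y = sparse_dictionary_data(50, 6, 2, 150, seed=1)
        res = ksvd(y, k=6, s0=2, n_iter=20, seed=0)
        diffs = np.diff(res.objective)
        assert np.all(diffs <= 1e-8 * np.linalg.norm(y))

    def test_atoms_unit_norm(self):
        _, _, y = sparse_dictionary_data(40, 5, 2, 80, seed=2)
        res = ksvd(y, k=5, s0=2, n_iter=10, seed=0)
        np.testing.assert_allclose(
            np.linalg.norm(res.dictionary, axis=0), 1.0, atol=1e-10
        )

    def test_sparsity_budget_respected(self):
        _, _, y = sparse_dictionary_data(40, 5, 2, 80, seed=2)
        res = ksvd(y, k=5, s0=2, n_iter=10, seed=0)
        assert np.max(np.count_nonzero(res.codes, axis=0)) <= 2

    def test_oversized_sparsity_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            KsvdExtractor(k=2, s0=3)

    def test_transform_subtracts_shared_reconstruction(self, fc_cohort):
        model = KsvdExtractor(k=3, s0=2, n_iter=10, seed=0).fit(fc_cohort)
        sub = model.transform(fc_cohort)
        codes, *_ = np.linalg.lstsq(model.dictionary_, fc_cohort.values, rcond=None)
        np.testing.assert_allclose(
            sub.values + model.dictionary_ @ codes, fc_cohort.values, atol=1e-9
        )

    def test_residual_matches_explicit_projector(self, rng):
        """With k full-rank atoms, Sub = (I - P) Y for the span projector P."""
        cols = [rng.standard_normal(30) for _ in range(8)]
        cohort = cohort_from_columns(cols, p=4, s=2)
        model = KsvdExtractor(k=4, s0=2, n_iter=10, seed=0).fit(cohort)
        d = model.dictionary_
        projector = d @ np.linalg.pinv(d)
        expected = (np.eye(30) - projector) @ cohort.values
        np.testing.assert_allclose(
            model.transform(cohort).values, expected, atol=1e-8
        )

    def test_fully_spanned_test_matrix_maps_to_zero(self, fc_cohort, rng):
        model = KsvdExtractor(k=4, s0=2, n_iter=10, seed=0).fit(fc_cohort)
        inside = fc_cohort.with_values(
            model.dictionary_ @ rng.standard_normal((4, fc_cohort.n_scans))
        )
        np.testing.assert_allclose(model.transform(inside).values, 0.0, atol=1e-8)


class TestCobe:
    def test_identical_blocks_fully_removed(self, rng):
        v = rng.standard_normal((50, 3))
        block = v @ rng.standard_normal((3, 4))
        model = cobe_fit([block, block, block], n_components=3)
        residual = block - model.basis @ (model.basis.T @ block)
        np.testing.assert_allclose(residual, 0.0, atol=1e-8)

    def test_planted_shared_vector_recovered(self, rng):
        g = rng.standard_normal(200)
        g /= np.linalg.norm(g)
        blocks = [
            np.outer(g, rng.standard_normal(5) + 1.0)
            + 0.05 * rng.standard_normal((200, 5))
            for _ in range(8)
        ]
        model = cobe_fit(blocks, n_components=2)
        assert abs(np.corrcoef(model.basis[:, 0], g)[0, 1]) > 0.99

    def test_orthogonal_blocks_have_no_common_direction(self, rng):
        q = np.linalg.qr(rng.standard_normal((40, 12)))[0]
        blocks = [q[:, 4 * i : 4 * (i + 1)] for i in range(3)]
        model = cobe_fit(blocks, n_components=2)
        assert model.commonality[0] <= 1.0 + 1e-8

    def test_basis_orthonormal(self, fc_cohort):
        model = CobeExtractor(2).fit(fc_cohort)
        gram = model.model_.basis.T @ model.model_.basis
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)

    def test_residual_orthogonal_to_shared_atoms(self, fc_cohort):
        model = CobeExtractor(2).fit(fc_cohort)
        sub = model.transform(fc_cohort)
        np.testing.assert_allclose(
            model.model_.basis.T @ sub.values, 0.0, atol=1e-10
        )

    def test_spanned_input_maps_to_zero(self, fc_cohort, rng):
        model = CobeExtractor(2).fit(fc_cohort)
        inside = fc_cohort.with_values(
            model.model_.basis @ rng.standard_normal((2, fc_cohort.n_scans))
        )
        np.testing.assert_allclose(model.transform(inside).values, 0.0, atol=1e-10)

    def test_orthogonal_input_passes_through(self, fc_cohort, rng):
        model = CobeExtractor(2).fit(fc_cohort)
        v = rng.standard_normal(fc_cohort.n_features)
        d = model.model_.basis
        v -= d @ (d.T @ v)
        outside = fc_cohort.with_values(np.tile(v[:, None], fc_cohort.n_scans))
        np.testing.assert_allclose(
            model.transform(outside).values, outside.values, atol=1e-10
        )

    def test_transform_is_linear(self, fc_cohort, rng):
        model = CobeExtractor(2).fit(fc_cohort)
        x = rng.standard_normal(fc_cohort.values.shape)
        z = rng.standard_normal(fc_cohort.values.shape)
        lhs = model.transform(fc_cohort.with_values(2 * x + 3 * z)).values
        rhs = (
            2 * model.transform(fc_cohort.with_values(x)).values
            + 3 * model.transform(fc_cohort.with_values(z)).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_too_many_components_rejected(self, fc_cohort):
        with pytest.raises(CohortError, match="n_components"):
            CobeExtractor(fc_cohort.s + 1).fit(fc_cohort)

    def test_zero_block_rejected(self, rng):
        with pytest.raises(CohortError, match="zero"):
            cobe_fit([rng.standard_normal((10, 3)), np.zeros((10, 3))], 1)


class TestUniformContract:
    @pytest.mark.parametrize(
        "name,params",
        [
            ("none", {}),
            ("pca", {"n_components": 3}),
            ("rpca", {"k": 4, "lam": 0.2, "seed": 0}),
            ("ksvd", {"k": 3, "s0": 2, "seed": 0}),
            ("cobe", {"n_components": 2}),
        ],
    )
    def test_shape_index_preserved_and_fit_deterministic(self, name, params, fc_cohort):
        train = fc_cohort.select_sessions(fc_cohort.sessions[:2])
        test = fc_cohort.select_sessions(fc_cohort.sessions[2:])
        ex1 = make_extractor(name, **params).fit(train)
        ex2 = make_extractor(name, **params).fit(train)
        sub = ex1.transform(test)
        assert sub.values.shape == test.values.shape
        assert sub.index == test.index
        assert sub.extractor == name
        # fitting never touches test columns and is deterministic
        for attr in ("basis_", "dictionary_", "mean_"):
            if hasattr(ex1, attr):
                np.testing.assert_array_equal(getattr(ex1, attr), getattr(ex2, attr))

    def test_feature_dimension_mismatch_rejected(self, fc_cohort, rng):
        model = PcaExtractor(2).fit(fc_cohort)
        other = cohort_from_columns([rng.standard_normal(7) for _ in range(4)], 2, 2)
        with pytest.raises(CohortError, match="dimension mismatch"):
            model.transform(other)
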