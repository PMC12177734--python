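"""Core SGCCA engine: oracles, constraints, deflation, projection, AVE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset, random_dataset
from sgccapipe import (
    SGCCAModel,
    SparsityConfig,
    compute_ave,
    fit_sgcca,
    inner_ave,
    transform,
    uniform_design,
)
from sgccapipe.sgcca import project_l1l2


class TestProjection:
    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 4.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_result_satisfies_both_constraints(self, seed, s):
        a = np.random.default_rng(seed).standard_normal(16)
        w = project_l1l2(a, s)
        assert np.linalg.norm(w) <= 1 + 1e-10
        assert np.abs(w).sum() <= s + 1e-8

    def test_large_budget_reduces_to_l2_normalization(self):
        a = np.random.default_rng(0).standard_normal(9)
        w = project_l1l2(a, s=3.0)  # sqrt(9) = 3 disables the L1 constraint
        np.testing.assert_allclose(w, a / np.linalg.norm(a), atol=1e-12)

    def test_unit_budget_keeps_single_coordinate(self):
        a = np.array([0.5, -2.0, 1.0])
        w = project_l1l2(a, s=1.0)
        np.testing.assert_allclose(w, [0.0, -1.0, 0.0], atol=1e-8)

    def test_zero_vector_returns_none(self):
        assert project_l1l2(np.zeros(4), 1.5) is None


class TestFitOracles:
    def test_duplicated_single_column_views_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 1))
        ds = make_dataset([x, x.copy()])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        scores = transform(model, ds)
        r = np.corrcoef(scores.values[0][:, 0], scores.values[1][:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_two_view_unconstrained_fit_matches_cross_covariance_svd(self):
        ds = random_dataset(0, 100, [5, 4])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1, scheme="horst", tol=1e-12)
        x1, x2 = ds.matrices()
        c = x1.T @ x2 / (ds.n - 1)
        u, sv, vt = np.linalg.svd(c)
        scores = transform(model, ds)
        y1, y2 = scores.values[0][:, 0], scores.values[1][:, 0]
        cov = (y1 - y1.mean()) @ (y2 - y2.mean()) / (ds.n - 1)
        assert cov == pytest.approx(sv[0], abs=1e-6)
        w1 = model.weights[0][:, 0]
        assert min(np.linalg.norm(w1 - u[:, 0]), np.linalg.norm(w1 + u[:, 0])) < 1e-4

    def test_sparse_limit_selects_best_coordinate_by_enumeration(self):
        ds = random_dataset(3, 100, [5, 4])
        lam = 1 / np.sqrt(5)
        model = fit_sgcca(ds, sparsity=SparsityConfig((lam, 1.0)), n_components=1, scheme="horst")
        w1 = model.weights[0][:, 0]
        nnz = np.flatnonzero(np.abs(w1) > 1e-9)
        assert nnz.size == 1
        # the fitted coordinate maximizes |cov(x_1i, y_2)| over all coordinates
        y2 = transform(model, ds).values[1][:, 0]
        covs = np.abs(ds.matrices()[0].T @ y2)
        assert nnz[0] == np.argmax(covs)


class TestInvariants:
    @pytest.mark.parametrize("scheme", ["horst", "centroid", "factorial"])
    def test_objective_trace_nondecreasing_and_constraints_hold(self, scheme):
        for seed in range(6):
            ds = random_dataset(100 + seed, 60, [7, 5, 6])
            lam = 0.5
            sparsity = SparsityConfig(
                tuple(max(lam, 1 / np.sqrt(p)) for p in (7, 5, 6))
            )
            model = fit_sgcca(ds, sparsity=sparsity, n_components=2, scheme=scheme)
            for trace in model.convergence_trace:
                assert (np.diff(trace) >= -1e-10).all()
            for j, w in enumerate(model.weights):
                s_j = sparsity.lambda_per_view[j] * np.sqrt(w.shape[0])
                assert (np.linalg.norm(w, axis=0) <= 1 + 1e-8).all()
                assert (np.abs(w).sum(axis=0) <= s_j + 1e-8).all()

    def test_converged_objective_nondecreasing_in_lambda(self):
        from sgccapipe import lambda_objective_path

        ladder = [0.4, 0.55, 0.7, 0.85, 1.0]
        for seed in range(10):
            ds = random_dataset(200 + seed, 80, [8, 6, 7])
            objectives = lambda_objective_path(ds, ladder)
            assert (np.diff(objectives) >= -1e-6).all()

    def test_within_view_scores_are_orthogonal_after_deflation(self):
        ds = random_dataset(5, 120, [10, 9, 8])
        model = fit_sgcca(ds, sparsity=1.0, n_components=5)
        scores = transform(model, ds)
        for y in scores.values:
            corr = np.corrcoef(y.T)
            off = np.abs(corr - np.diag(np.diag(corr))).max()
            assert off < 1e-6

    def test_variable_permutation_within_view_permutes_weights(self):
        ds = random_dataset(9, 80, [8, 6])
        perm = np.random.default_rng(1).permutation(8)
        x1, x2 = ds.matrices()
        ds_perm = make_dataset([x1[:, perm], x2], standardized=False)
        m1 = fit_sgcca(ds, sparsity=0.6, n_components=2)
        m2 = fit_sgcca(ds_perm, sparsity=0.6, n_components=2)
        np.testing.assert_allclose(m2.weights[0], m1.weights[0][perm], atol=1e-12)
        s1 = transform(m1, ds)
        s2 = transform(m2, ds_perm)
        np.testing.assert_allclose(s1.values[0], s2.values[0], atol=1e-12)

    def test_infeasible_budget_and_bad_design_are_errors(self):
        ds = random_dataset(2, 50, [5, 4])
        with pytest.raises(ValueError, match="infeasible"):
            fit_sgcca(ds, sparsity=0.1, n_components=1)
        design = np.zeros((2, 2))
        with pytest.raises(ValueError, match="positive off-diagonal"):
            fit_sgcca(ds, design=design, sparsity=1.0, n_components=1)


class TestTransform:
    def test_training_data_transform_reproduces_training_scores(self):
        ds = random_dataset(11, 90, [7, 6, 5])
        model = fit_sgcca(ds, sparsity=0.7, n_components=3)
        s1 = transform(model, ds)
        s2 = transform(model, ds)
        for a, b in zip(s1.values, s2.values):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_all_zero_view_yields_all_zero_scores(self):
        ds = random_dataset(12, 40, [5, 4])
        model = fit_sgcca(ds, sparsity=1.0, n_components=2)
        zeroed = ds.with_values([np.zeros((40, 5)), np.zeros((40, 4))])
        scores = transform(model, zeroed)
        for y in scores.values:
            np.testing.assert_array_equal(y, 0)

    def test_variable_mismatch_is_an_error_listing_names(self):
        ds = random_dataset(13, 40, [5, 4])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        shrunk = ds.subset_variables({"view0": ["view0_0", "view0_1"]})
        with pytest.raises(ValueError, match="view0_2"):
            transform(model, shrunk)

    def test_heldout_planted_signal_beats_permutation_null(self):
        from sgccapipe import SyntheticSpec, ViewSpec, generate_multiview, standardize

        spec = SyntheticSpec(
            n_participants=300,
            view_specs=(ViewSpec("a", 10), ViewSpec("b", 8)),
            n_true_components=1,
            support_fraction=0.3,
            loading_scale=3.0,
            noise_sd=1.0,
            seed=21,
        )
        dataset, _ = generate_multiview(spec)
        dataset = standardize(dataset)
        half = dataset.n // 2
        ids = dataset.participant_ids
        train = dataset.subset_participants(ids[:half])
        test = dataset.subset_participants(ids[half:])
        model = fit_sgcca(train, sparsity=1.0, n_components=1)
        observed = inner_ave(transform(model, test), model.design)[0]
        rng = np.random.default_rng(0)
        nulls = []
        for _ in range(200):
            perm_test = test.with_values([v.values[rng.permutation(test.n)] for v in test.views])
            nulls.append(inner_ave(transform(model, perm_test), model.design)[0])
        assert observed > np.quantile(nulls, 0.95)


class TestAVE:
    def test_identical_scores_across_views_give_inner_ave_one(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        from sgccapipe import Scores

        scores = Scores(
            values=[y[:, None], y[:, None], y[:, None]],
            view_names=["a", "b", "c"],
            participant_ids=[str(i) for i in range(30)],
        )
        np.testing.assert_allclose(inner_ave(scores, uniform_design(3)), [1.0])

    def test_two_views_with_half_correlation_give_quarter_inner_ave(self):
        rng = np.random.default_rng(1)
        y1 = rng.standard_normal(4000)
        y2 = 0.5 * y1 + np.sqrt(1 - 0.25) * rng.standard_normal(4000)
        # rescale to achieve exactly corr = 0.5 via Gram-Schmidt construction
        e = y2 - (y1 @ y2 / (y1 @ y1)) * y1
        y2 = 0.5 * y1 / np.linalg.norm(y1) + np.sqrt(0.75) * e / np.linalg.norm(e)
        y1c = y1 - y1.mean()
        y2c = y2 - y2.mean()
        r = y1c @ y2c / np.linalg.norm(y1c) / np.linalg.norm(y2c)
        from sgccapipe import Scores

        scores = Scores(
            values=[y1[:, None], y2[:, None]],
            view_names=["a", "b"],
            participant_ids=[str(i) for i in range(4000)],
        )
        np.testing.assert_allclose(inner_ave(scores, uniform_design(2)), [r**2])

    def test_rank_one_view_fully_explained_by_its_component(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(60)
        x1 = np.outer(z, [1.0, -2.0, 0.5])
        x2 = np.outer(z, [1.0, 1.0])
        ds = make_dataset([x1, x2], standardized=False)
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        scores = transform(model, ds)
        report = compute_ave(scores, ds, model.design)
        np.testing.assert_allclose(report.outer_ave_per_view[:, 0], 1.0, atol=1e-10)
        np.testing.assert_allclose(report.inner_ave, [1.0], atol=1e-10)

    def test_cumulative_outer_ave_is_nondecreasing_and_bounded(self):
        ds = random_dataset(30, 80, [8, 7, 6])
        model = fit_sgcca(ds, sparsity=1.0, n_components=4)
        report = compute_ave(transform(model, ds), ds, model.design)
        assert (np.diff(report.cumulative_outer_ave) >= -1e-12).all()
        assert (report.inner_ave >= 0).all() and (report.inner_ave <= 1).all()
        assert (report.outer_ave_per_view >= 0).all()
        assert (report.outer_ave_per_view <= 1 + 1e-12).all()


class TestSerialization:
    def test_model_json_round_trip_reproduces_scores(self, tmp_path):
        ds = random_dataset(31, 60, [6, 5])
        model = fit_sgcca(ds, sparsity=0.8, n_components=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = SGCCAModel.from_json(path)
        s1 = transform(model, ds)
        s2 = transform(loaded, ds)
        for a, b in zip(s1.values, s2.values):
            np.testing.assert_array_equal(a, b)
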