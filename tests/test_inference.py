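"""Permutation significance, score regression, structural coefficients."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, random_dataset
from sgccapipe import (
    Scores,
    SyntheticSpec,
    ViewSpec,
    aggregated_loadings,
    component_regression,
    fit_sgcca,
    generate_multiview,
    permutation_significance,
    preprocess_train_test,
    structural_coefficients,
    top_items,
    transform,
)
from sgccapipe.inference import _rank_against_null


def make_scores(arrays, names=None):
    names = names or [f"v{j}" for j in range(len(arrays))]
    n = arrays[0].shape[0]
    return Scores(
        values=[np.asarray(a, dtype=float) for a in arrays],
        view_names=names,
        participant_ids=[f"s{i}" for i in range(n)],
    )


class TestPermutationSignificance:
    def test_p_value_is_one_when_observed_ties_every_null(self):
        observed = np.array([0.3])
        nulls = np.full((50, 1), 0.3)
        res = _rank_against_null(observed, nulls, "train")
        assert res.p_perm[0] == 1.0

    def test_p_value_floor_is_one_over_b_plus_one(self):
        observed = np.array([0.9])
        nulls = np.random.default_rng(0).uniform(0, 0.1, (200, 1))
        res = _rank_against_null(observed, nulls, "test")
        assert res.p_perm[0] == pytest.approx(1 / 201)

    def test_strong_planted_signal_saturates_rank_in_both_contexts(self):
        spec = SyntheticSpec(
            n_participants=300,
            view_specs=(ViewSpec("clinical", 10), ViewSpec("imgA", 8), ViewSpec("imgB", 6)),
            n_true_components=1,
            support_fraction=0.3,
            loading_scale=5.0,
            noise_sd=1.0,
            seed=33,
        )
        dataset, _ = generate_multiview(spec)
        train, test = preprocess_train_test(dataset, 0.7, seed=0)
        model = fit_sgcca(train, sparsity=1.0, n_components=1)
        res = permutation_significance(model, train, test, n_perm=200, seed=0)
        assert res["train"].p_perm[0] == pytest.approx(1 / 201)
        assert res["test"].p_perm[0] == pytest.approx(1 / 201)
        assert res["train"].z[0] > 3
        assert res["test"].z[0] > 3

    def test_deterministic_and_parallel_invariant(self):
        ds = random_dataset(3, 80, [6, 5])
        train = ds.subset_participants(ds.participant_ids[:60])
        test = ds.subset_participants(ds.participant_ids[60:])
        model = fit_sgcca(train, sparsity=1.0, n_components=1)
        r1 = permutation_significance(model, train, test, n_perm=20, seed=9, n_jobs=1)
        r2 = permutation_significance(model, train, test, n_perm=20, seed=9, n_jobs=2)
        np.testing.assert_array_equal(r1["test"].null_draws, r2["test"].null_draws)

    def test_invalid_b_is_an_error(self):
        ds = random_dataset(4, 40, [5, 4])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(model, ds, ds, n_perm=0, seed=0)


class TestComponentRegression:
    def test_perfect_predictor_gives_r_one_and_ci_excluding_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(200)
        imaging = [y.copy()] + [rng.standard_normal(200) for _ in range(3)]
        clinical = make_scores([y[:, None]], names=["clinical"])
        img = make_scores([a[:, None] for a in imaging], names=["i1", "i2", "i3", "i4"])
        res = component_regression(clinical, img, component=1, n_boot=200, seed=1)
        assert res.r > 0.999
        lo, hi = res.coef_ci[0]
        assert lo > 0 or hi < 0

    def test_regression_r_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(150)
        x1 = 0.5 * y + rng.standard_normal(150)
        x2 = rng.standard_normal(150)
        clinical = make_scores([y[:, None]], names=["clinical"])
        img_a = make_scores([x1[:, None], x2[:, None]], names=["i1", "i2"])
        img_b = make_scores([(3.0 * x1)[:, None], (0.1 * x2 + 5 * 0)[:, None]], names=["i1", "i2"])
        r_a = component_regression(clinical, img_a, 1, n_boot=50, seed=0).r
        r_b = component_regression(clinical, img_b, 1, n_boot=50, seed=0).r
        assert r_a == pytest.approx(r_b, abs=1e-12)

    def test_null_predictors_keep_coefficient_cis_covering_zero(self):
        rng = np.random.default_rng(2)
        covered = 0
        total = 0
        for rep in range(20):
            y = rng.standard_normal(250)
            imaging = [rng.standard_normal(250) for _ in range(7)]
            clinical = make_scores([y[:, None]], names=["clinical"])
            img = make_scores(
                [a[:, None] for a in imaging], names=[f"i{j}" for j in range(7)]
            )
            res = component_regression(clinical, img, 1, n_boot=200, seed=rep)
            for lo, hi in res.coef_ci:
                covered += lo <= 0 <= hi
                total += 1
        assert covered / total > 0.85

    def test_collinear_predictors_raise_error_naming_views(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(100)
        x = rng.standard_normal(100)
        clinical = make_scores([y[:, None]], names=["clinical"])
        img = make_scores([x[:, None], (2 * x)[:, None]], names=["imgA", "imgB"])
        with pytest.raises(ValueError, match="imgA"):
            component_regression(clinical, img, 1, n_boot=10, seed=0)


class TestStructuralCoefficients:
    def planted(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((120, 6))
        ds = make_dataset([x], names=["clinical"])
        score = ds.views[0].values[:, 0]  # component equals the first item
        scores = make_scores([score[:, None]], names=["clinical"])
        return ds, scores

    def test_component_equal_to_one_item_gives_r_one(self):
        ds, scores = self.planted()
        table = structural_coefficients(scores, ds, n_boot=50, seed=0)
        r0 = table[table["variable"] == "clinical_0"]["r"].iloc[0]
        assert r0 == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_match_direct_correlation_oracle(self):
        ds = random_dataset(6, 80, [7, 5])
        model = fit_sgcca(ds, sparsity=1.0, n_components=2)
        scores = transform(model, ds)
        table = structural_coefficients(scores, ds, n_boot=2, seed=0)
        for _, row in table.iterrows():
            y = scores.view(row["view"])[:, row["component"] - 1]
            x = ds.view(row["view"]).values[
                :, ds.view(row["view"]).variable_names.index(row["variable"])
            ]
            assert row["r"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_sign_flipped_component_flips_r_but_not_significance(self):
        ds = random_dataset(7, 100, [6, 5])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        scores = transform(model, ds)
        flipped = make_scores(
            [-v for v in scores.values], names=list(scores.view_names)
        )
        t1 = structural_coefficients(scores, ds, n_boot=100, seed=3)
        t2 = structural_coefficients(flipped, ds, n_boot=100, seed=3)
        np.testing.assert_allclose(t2["r"], -t1["r"], atol=1e-12)
        np.testing.assert_allclose(t2["p"], t1["p"], atol=1e-12)

    def test_fdr_adjustment_is_monotone_and_at_least_raw_p(self):
        ds = random_dataset(8, 90, [8, 6])
        model = fit_sgcca(ds, sparsity=1.0, n_components=1)
        table = structural_coefficients(transform(model, ds), ds, n_boot=100, seed=1)
        for (_, _), group in table.groupby(["component", "view"]):
            g = group.sort_values("p")
            assert (g["p_fdr"].to_numpy() >= g["p"].to_numpy() - 1e-15).all()
            assert (np.diff(g["p_fdr"].to_numpy()) >= -1e-15).all()

    def test_zero_variance_variable_is_flagged_and_excluded(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((60, 4))
        x[:, 2] = 1.0
        ds = make_dataset([x], names=["v"], standardized=False)
        scores = make_scores([x[:, :1]], names=["v"])
        table = structural_coefficients(scores, ds, n_boot=20, seed=0)
        dead = table[table["variable"] == "v_2"].iloc[0]
        assert not dead["defined"] and not dead["significant"]
        assert np.isnan(dead["r"])


class TestTopItemsAndAggregation:
    def demo_table(self):
        return pd.DataFrame(
            {
                "component": [1] * 4,
                "view": ["clinical"] * 4,
                "variable": ["a", "b", "c", "d"],
                "r": [0.9, -0.5, 0.1, 0.5],
                "p": [0.001] * 4,
                "p_fdr": [0.004] * 4,
                "significant": [True, True, False, True],
                "defined": [True] * 4,
            }
        )

    def test_ranking_by_absolute_value_with_name_tiebreak(self):
        top = top_items(self.demo_table(), component=1, n=2)
        assert top["variable"].tolist() == ["a", "b"]  # |0.9| then tie 0.5: 'b' < 'd'

    def test_n_larger_than_significant_count_returns_all_significant(self):
        top = top_items(self.demo_table(), component=1, n=10)
        assert len(top) == 3 and "c" not in top["variable"].tolist()

    def test_ranking_invariant_to_row_order(self):
        table = self.demo_table().iloc[::-1].reset_index(drop=True)
        assert top_items(table, 1, 2)["variable"].tolist() == ["a", "b"]

    def test_aggregation_signed_and_absolute_modes(self):
        table = self.demo_table()
        smap = {"secA": ["a"], "secB": ["b", "d"], "secC": ["c"]}
        signed = aggregated_loadings(table, smap, view="clinical", mode="signed")
        by_sec = signed.set_index("section")["aggregated_loading"]
        assert by_sec["secA"] == pytest.approx(0.9)  # singleton = its own r
        assert by_sec["secB"] == pytest.approx(0.0)  # mean(-0.5, 0.5)
        absolute = aggregated_loadings(table, smap, view="clinical", mode="absolute")
        assert absolute.set_index("section")["aggregated_loading"]["secB"] == pytest.approx(0.5)

    def test_unmapped_variable_is_an_error(self):
        with pytest.raises(ValueError, match="not covered"):
            aggregated_loadings(self.demo_table(), {"secA": ["a", "b", "c"]}, view="clinical")
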