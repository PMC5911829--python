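"""Latent class core: EM estimation, posteriors, classification diagnostics."""

import numpy as np
import pytest

from lctax.datasets import CategoricalDataset
from lctax.lca import (_em_batch, _onehot_patterns, assign, bootstrap_lrt,
                       classification_error, entropy_r2, fit_lca, l2_statistic,
                       posterior, select_model)
from lctax.simulate import LCAGenSpec, binary_item_probs, make_lca_data

from oracles import (grid_search_2class_binary_ll, naive_classification_error,
                     naive_entropy_r2, naive_posterior)


class TestFitLCA:
    def test_one_class_is_closed_form(self, two_class_data):
        data, _ = two_class_data
        fit = fit_lca(data, 1)
        assert np.allclose(fit.parameters.class_probs, [1.0])
        # item probabilities are the observed marginal frequencies
        for j in range(data.n_items):
            freq = np.bincount(data.responses[:, j], minlength=3)[1:] / data.n_cases
            assert np.allclose(fit.parameters.item_probs[0, j, :2], freq)
        patterns, counts, _ = data.pattern_table()
        ll = 0.0
        for pat, cnt in zip(patterns, counts):
            ll += cnt * sum(np.log(fit.parameters.item_probs[0, j, pat[j] - 1])
                            for j in range(data.n_items))
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_em_matches_grid_search_two_items(self, two_pattern_data):
        fit = fit_lca(two_pattern_data, 2, n_starts=10, seed=3)
        grid_max = grid_search_2class_binary_ll(two_pattern_data.responses, 0.05)
        assert fit.log_likelihood >= grid_max - 1e-4
        # perfectly separated patterns: the saturated maximum is attainable
        assert fit.log_likelihood == pytest.approx(100 * np.log(0.5), abs=1e-6)

    def test_parameter_recovery(self):
        theta = binary_item_probs(0.8, 0.2, 6)
        spec = LCAGenSpec(n_cases=5000, n_classes=2, item_probs=theta,
                          n_categories=np.full(6, 2), class_probs=[0.3, 0.7],
                          seed=99)
        data, _ = make_lca_data(spec)
        fit = fit_lca(data, 2, n_starts=10, seed=5)
        # canonical order puts the larger class (low endorsement) first
        assert np.allclose(fit.parameters.class_probs, [0.7, 0.3], atol=0.03)
        assert np.allclose(fit.parameters.item_probs[0, :, 0], 0.2, atol=0.03)
        assert np.allclose(fit.parameters.item_probs[1, :, 0], 0.8, atol=0.03)

    def test_recovery_bias_shrinks_with_n(self):
        theta = binary_item_probs(0.8, 0.2, 6)
        errs = {}
        for n in (500, 5000):
            spec = LCAGenSpec(n_cases=n, n_classes=2, item_probs=theta,
                              n_categories=np.full(6, 2), class_probs=[0.3, 0.7],
                              seed=1234)
            data, _ = make_lca_data(spec)
            fit = fit_lca(data, 2, n_starts=10, seed=5)
            errs[n] = np.abs(fit.parameters.item_probs[:, :, 0]
                             - theta[::-1, :, 0]).max()
        assert errs[5000] < errs[500]

    def test_more_classes_than_patterns_rejected(self, two_pattern_data):
        with pytest.raises(ValueError, match="not identifiable"):
            fit_lca(two_pattern_data, 3)

    def test_em_loglik_monotone_per_iteration(self, two_class_data):
        data, _ = two_class_data
        patterns, counts, _ = data.pattern_table()
        onehot = _onehot_patterns(patterns, data.n_categories)
        res = _em_batch(onehot, counts[None, :], 2, 5, data.n_categories,
                        np.random.default_rng(11), record_history=True)
        hist = res["ll_history"][0]  # (S, n_iter)
        diffs = np.diff(hist, axis=1)
        assert np.all(diffs >= -1e-10)

    def test_category_relabel_invariance(self, two_class_data):
        data, _ = two_class_data
        fit = fit_lca(data, 2, n_starts=10, seed=21)
        flipped = CategoricalDataset(3 - data.responses)  # swap codes 1<->2
        fit2 = fit_lca(flipped, 2, n_starts=10, seed=21)
        assert fit2.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-6)


class TestPosterior:
    def test_one_class_posterior_is_unity(self, two_class_data):
        data, _ = two_class_data
        fit = fit_lca(data, 1)
        assert np.all(posterior(fit.parameters, data) == 1.0)

    def test_symmetric_bayes_single_item(self):
        from lctax.lca import LCAParameters
        theta = binary_item_probs(0.8, 0.2, 1)
        params = LCAParameters(2, [0.5, 0.5], theta, np.array([2]))
        data = CategoricalDataset(np.array([[1], [2]]))
        post = posterior(params, data)
        assert np.allclose(post[0], [0.8, 0.2])
        assert np.allclose(post[1], [0.2, 0.8])

    def test_matches_naive_bayes_oracle(self, rng):
        c, k = 3, 4
        n_cats = np.array([2, 3, 2, 4])
        theta = np.zeros((c, k, 4))
        for j, m in enumerate(n_cats):
            theta[:, j, :m] = rng.dirichlet(np.ones(m), size=c)
        pi = rng.dirichlet(np.ones(c))
        from lctax.lca import LCAParameters
        params = LCAParameters(c, pi, theta, n_cats)
        responses = np.column_stack(
            [rng.integers(1, m + 1, size=40) for m in n_cats])
        data = CategoricalDataset(responses)
        expected = naive_posterior(pi, theta, n_cats, responses)
        assert np.allclose(posterior(params, data), expected, atol=1e-12)

    def test_rows_normalized(self, two_class_fit):
        assert np.allclose(two_class_fit.posteriors.sum(axis=1), 1.0, atol=1e-10)


class TestAssign:
    @pytest.mark.parametrize("row,method,expected", [
        ([0.9, 0.1], "modal", [1, 0]),
        ([0.5, 0.5], "modal", [1, 0]),  # tie goes to the lowest class index
        ([0.3, 0.7], "proportional", [0.3, 0.7]),
    ])
    def test_assignment_rules(self, row, method, expected):
        out = assign(np.array([row]), method)
        assert np.allclose(out[0], expected)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            assign(np.array([[1.0, 0.0]]), "fuzzy")


class TestClassificationError:
    def test_perfect_separation_gives_identity(self):
        post = np.repeat(np.eye(2), 5, axis=0)
        w = assign(post, "modal")
        ce = classification_error(post, w, np.array([0.5, 0.5]))
        assert np.allclose(ce.D, np.eye(2))
        assert ce.overall_error == pytest.approx(0.0)

    def test_uniform_posteriors_modal_all_to_first(self):
        post = np.full((10, 2), 0.5)
        w = assign(post, "modal")
        ce = classification_error(post, w, np.array([0.5, 0.5]))
        assert np.allclose(ce.D, [[1, 0], [1, 0]])

    def test_matches_naive_double_loop(self, rng):
        post = rng.dirichlet(np.ones(3), size=30)
        w = assign(post, "proportional")
        pi = post.mean(axis=0)
        ce = classification_error(post, w, pi)
        assert np.allclose(ce.D, naive_classification_error(post, w, pi),
                           atol=1e-12)
        assert np.allclose(ce.D.sum(axis=1), 1.0, atol=1e-8)

    def test_empty_class_rejected(self):
        post = np.full((4, 2), 0.5)
        with pytest.raises(ValueError, match="empty class"):
            classification_error(post, post, np.array([1.0, 1e-15]))


class TestEntropyR2:
    def test_one_hot_posteriors_give_one(self):
        post = np.repeat(np.eye(2), 10, axis=0)
        assert entropy_r2(post, np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_uninformative_posteriors_give_zero(self):
        pi = np.array([0.3, 0.7])
        post = np.tile(pi, (20, 1))
        assert entropy_r2(post, pi) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_formula(self, rng):
        post = rng.dirichlet(np.ones(4), size=50)
        pi = rng.dirichlet(np.ones(4))
        assert entropy_r2(post, pi) == pytest.approx(
            naive_entropy_r2(post, pi), abs=1e-12)

    def test_single_class_convention(self):
        assert entropy_r2(np.ones((5, 1)), np.array([1.0])) == 1.0


class TestL2:
    def test_saturated_model_gives_zero(self, two_pattern_data):
        fit = fit_lca(two_pattern_data, 2, n_starts=10, seed=3)
        assert fit.l2 == pytest.approx(0.0, abs=1e-6)

    def test_one_class_hand_computation(self, two_pattern_data):
        fit = fit_lca(two_pattern_data, 1)
        # marginals are 0.5 each; model pattern prob = 0.25; observed 0.5
        expected = 2 * (50 * np.log(0.5 / 0.25) + 50 * np.log(0.5 / 0.25))
        assert fit.l2 == pytest.approx(expected, abs=1e-8)
        assert l2_statistic(fit, two_pattern_data) == pytest.approx(expected,
                                                                   abs=1e-8)

    def test_l2_decreases_with_more_classes(self, two_class_data):
        data, _ = two_class_data
        l2s = [fit_lca(data, c, n_starts=10, seed=13).l2 for c in (1, 2, 3)]
        assert l2s[1] <= l2s[0] + 1e-6
        assert l2s[2] <= l2s[1] + 1e-6


class TestBootstrapLRT:
    def test_detects_second_class(self):
        theta = binary_item_probs(0.85, 0.15, 5)
        spec = LCAGenSpec(n_cases=500, n_classes=2, item_probs=theta,
                          n_categories=np.full(5, 2), class_probs=[0.5, 0.5],
                          seed=77)
        data, _ = make_lca_data(spec)
        res = bootstrap_lrt(data, 1, 2, n_boot=39, seed=5)
        assert res["p_value"] <= 0.05

    def test_p_value_capped_at_one(self, two_class_data):
        data, _ = two_class_data
        # under an over-fitted null (2 classes), adding a 3rd gains little
        res = bootstrap_lrt(data, 2, 3, n_boot=19, seed=8, boot_n_starts=2,
                            max_iter=300)
        assert 0.0 < res["p_value"] <= 1.0

    def test_requires_adjacent_classes(self, two_class_data):
        data, _ = two_class_data
        with pytest.raises(ValueError):
            bootstrap_lrt(data, 1, 3)


class TestSelectModel:
    def test_single_class_row(self, two_class_data):
        data, _ = two_class_data
        table = select_model(data, [1], seed=4)
        assert len(table) == 1
        assert table.loc[0, "entropy_r2"] == 1.0

    def test_rows_match_individual_fits(self, two_class_data):
        data, _ = two_class_data
        table = select_model(data, [1, 2], n_starts=10, seed=42)
        rng = np.random.default_rng(42)
        for _, row in table.iterrows():
            sub_seed = int(rng.integers(2**31))
            fit = fit_lca(data, int(row["n_classes"]), n_starts=10, seed=sub_seed)
            assert row["log_likelihood"] == pytest.approx(fit.log_likelihood,
                                                          abs=1e-9)
            assert row["bic"] == pytest.approx(fit.bic, abs=1e-9)

    def test_bic_prefers_true_class_count(self):
        theta = binary_item_probs(0.85, 0.15, 6)
        hits = 0
        for rep in range(10):
            spec = LCAGenSpec(n_cases=1000, n_classes=2, item_probs=theta,
                              n_categories=np.full(6, 2), class_probs=[0.5, 0.5],
                              seed=500 + rep)
            data, _ = make_lca_data(spec)
            table = select_model(data, [1, 2, 3], n_starts=8, seed=rep)
            hits += int(table.loc[table["bic"].idxmin(), "n_classes"] == 2)
        assert hits >= 9
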