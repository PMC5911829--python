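"""Three-step covariate modeling: naive bias, BCH and ML corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lctax.lca import assign, classification_error, fit_lca
from lctax.simulate import LCAGenSpec, binary_item_probs, make_lca_data
from lctax.stepwise import (bch_weights, compare_methods, fit_one_step,
                            step3_bch, step3_ml, step3_naive)


def _sim_fit(beta=0.25, n=1000, seed=0, theta_hi=0.76, n_items=6, n_starts=8):
    """Generate covariate-driven 2-class data and fit the measurement model.

    Returns the dataset plus a sign that aligns the fitted first class with
    the generator's high-endorsement class (labels can swap when the classes
    are equally sized).
    """
    theta = binary_item_probs(theta_hi, 1 - theta_hi, n_items)
    spec = LCAGenSpec(n_cases=n, n_classes=2, item_probs=theta,
                      n_categories=np.full(n_items, 2),
                      logit_intercepts=[0.0], logit_slopes=[[beta]], seed=seed)
    data, _ = make_lca_data(spec)
    fit = fit_lca(data, 2, n_starts=n_starts, seed=seed + 1)
    sign = 1.0 if (fit.parameters.item_probs[0, 0, 0]
                   > fit.parameters.item_probs[1, 0, 0]) else -1.0
    return data, fit, sign


class TestBCHWeights:
    def test_identity_d_returns_assignment(self, rng):
        w = rng.dirichlet(np.ones(3), size=20)
        assert np.allclose(bch_weights(w, np.eye(3)), w)

    def test_two_by_two_hand_inverse(self):
        d = np.array([[0.9, 0.1], [0.2, 0.8]])
        w = np.array([[1.0, 0.0]])
        expected = np.array([[0.8 / 0.7, -0.1 / 0.7]])
        assert np.allclose(bch_weights(w, d), expected, atol=1e-12)

    def test_singular_d_rejected(self):
        d = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="too poor"):
            bch_weights(np.array([[1.0, 0.0]]), d)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=4))
    def test_row_sums_preserved(self, seed, c):
        rng = np.random.default_rng(seed)
        d = rng.dirichlet(np.ones(c) * 0.5, size=c)
        d = 0.5 * d + 0.5 * np.eye(c)  # keep D invertible
        w = rng.dirichlet(np.ones(c), size=10)
        wstar = bch_weights(w, d)
        assert np.allclose(wstar.sum(axis=1), 1.0, atol=1e-8)

    def test_row_sum_identity_thousand_draws(self):
        rng = np.random.default_rng(31337)
        for _ in range(1000):
            c = int(rng.integers(2, 5))
            d = 0.4 * rng.dirichlet(np.ones(c), size=c) + 0.6 * np.eye(c)
            w = rng.dirichlet(np.ones(c), size=5)
            assert np.allclose(bch_weights(w, d).sum(axis=1), 1.0, atol=1e-8)


class TestDegenerateD:
    """With perfect classification (D = I) all three third steps coincide."""

    def test_naive_bch_ml_agree(self, rng):
        n = 400
        x = rng.standard_normal((n, 1))
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x[:, 0])))
        w = np.zeros((n, 2))
        w[np.arange(n), (rng.random(n) > p).astype(int)] = 1.0
        d = np.eye(2)
        naive = step3_naive(w, x)
        bch = step3_bch(w, d, x)
        ml = step3_ml(w, d, x)
        assert np.allclose(naive.coefficients, bch.coefficients, atol=1e-6)
        assert np.allclose(naive.coefficients, ml.coefficients, atol=1e-6)


class TestStep3Naive:
    def test_equal_proportional_weights_give_zero_slopes(self, rng):
        w = np.full((100, 2), 0.5)
        x = rng.standard_normal((100, 1))
        model = step3_naive(w, x)
        assert np.allclose(model.coefficients[:, 1:], 0.0, atol=1e-6)

    def test_perfect_split_flags_separation(self):
        x = np.linspace(-2, 2, 60).reshape(-1, 1)
        w = np.zeros((60, 2))
        w[x[:, 0] > 0, 0] = 1.0
        w[x[:, 0] <= 0, 1] = 1.0
        model = step3_naive(w, x)
        assert model.separation

    def test_insufficient_class_weight_rejected(self, rng):
        w = np.zeros((30, 2))
        w[:, 0] = 1.0  # class 2 empty
        with pytest.raises(ValueError, match="insufficient"):
            step3_naive(w, rng.standard_normal((30, 1)))

    def test_downward_bias_under_noisy_classification(self):
        """The naive third step underestimates the true effect."""
        betas = []
        for rep in range(25):
            data, fit, sign = _sim_fit(beta=0.25, seed=900 + rep)
            w = assign(fit.posteriors, "modal")
            betas.append(sign * step3_naive(w, data.covariates).coefficients[0, 1])
        assert np.mean(betas) < 0.25


class TestCorrections:
    def test_bch_and_ml_recover_true_effect(self):
        est = {"naive": [], "bch": [], "ml": []}
        for rep in range(25):
            data, fit, sign = _sim_fit(beta=0.25, seed=3000 + rep)
            w = assign(fit.posteriors, "proportional")
            ce = classification_error(fit.posteriors, w,
                                      fit.parameters.class_probs)
            est["naive"].append(sign * step3_naive(w, data.covariates)
                                .coefficients[0, 1])
            est["bch"].append(sign * step3_bch(w, ce.D, data.covariates)
                              .coefficients[0, 1])
            est["ml"].append(sign * step3_ml(w, ce.D, data.covariates)
                             .coefficients[0, 1])
        mc_se = {k: np.std(v, ddof=1) / np.sqrt(len(v)) for k, v in est.items()}
        assert np.mean(est["naive"]) < np.mean(est["bch"])
        assert np.mean(est["naive"]) < np.mean(est["ml"])
        assert abs(np.mean(est["bch"]) - 0.25) < 3 * mc_se["bch"]
        assert abs(np.mean(est["ml"]) - 0.25) < 3 * mc_se["ml"]

    def test_ml_zero_diagonal_rejected(self, rng):
        d = np.array([[0.0, 1.0], [0.2, 0.8]])
        w = rng.dirichlet(np.ones(2), size=50)
        with pytest.raises(ValueError, match="never correctly"):
            step3_ml(w, d, rng.standard_normal((50, 1)))

    def test_class_relabel_antisymmetry(self, rng):
        """Swapping the two class labels flips the slope's sign."""
        n = 300
        x = rng.standard_normal((n, 1))
        p = 1 / (1 + np.exp(-0.8 * x[:, 0]))
        w = np.zeros((n, 2))
        w[np.arange(n), (rng.random(n) > p).astype(int)] = 1.0
        d = np.array([[0.85, 0.15], [0.15, 0.85]])
        m1 = step3_ml(w, d, x, reference_class=1)
        m2 = step3_ml(w[:, ::-1], d, x, reference_class=1)
        assert np.allclose(m1.coefficients[0, 1], -m2.coefficients[0, 1],
                           atol=1e-5)


class TestLogitInvariance:
    def test_covariate_shift_moves_only_intercept(self, rng):
        n = 500
        x = rng.standard_normal((n, 1))
        p = 1 / (1 + np.exp(-(0.3 + 0.9 * x[:, 0])))
        w = np.zeros((n, 2))
        w[np.arange(n), (rng.random(n) > p).astype(int)] = 1.0
        m1 = step3_naive(w, x)
        m2 = step3_naive(w, x + 5.0)
        assert np.allclose(m1.coefficients[:, 1:], m2.coefficients[:, 1:],
                           atol=1e-5)
        assert not np.allclose(m1.coefficients[:, 0], m2.coefficients[:, 0],
                               atol=1e-3)


class TestOneStep:
    def test_single_class_reduces_to_measurement_fit(self, two_class_data):
        data, _ = two_class_data
        fit, structural = fit_one_step(data, 1, seed=3)
        assert structural is None
        assert fit.parameters.n_classes == 1

    def test_recovers_effect(self):
        est = []
        for rep in range(8):
            theta = binary_item_probs(0.8, 0.2, 6)
            spec = LCAGenSpec(n_cases=2000, n_classes=2, item_probs=theta,
                              n_categories=np.full(6, 2),
                              logit_intercepts=[0.0], logit_slopes=[[1.0]],
                              seed=5000 + rep)
            data, _ = make_lca_data(spec)
            fit, structural = fit_one_step(data, 2, n_starts=4, seed=rep)
            sign = 1.0 if (fit.parameters.item_probs[0, 0, 0]
                           > fit.parameters.item_probs[1, 0, 0]) else -1.0
            est.append(sign * structural.coefficients[0, 1])
        assert abs(np.mean(est) - 1.0) < 0.15

    def test_null_effect_not_detected(self):
        cover = 0
        for rep in range(10):
            theta = binary_item_probs(0.8, 0.2, 6)
            spec = LCAGenSpec(n_cases=800, n_classes=2, item_probs=theta,
                              n_categories=np.full(6, 2),
                              logit_intercepts=[0.0], logit_slopes=[[0.0]],
                              seed=7000 + rep)
            data, _ = make_lca_data(spec)
            _, structural = fit_one_step(data, 2, n_starts=4, seed=rep)
            z = abs(structural.coefficients[0, 1] / structural.se[0, 1])
            cover += int(z < 3.0)
        assert cover >= 9


class TestCompareMethods:
    def test_schema_and_method_rows(self):
        data, _, _ = _sim_fit(beta=0.4, n=600, seed=60)
        table = compare_methods(data, 2, n_starts=8, seed=1)
        assert list(table.columns) == ["method", "covariate", "mean", "se", "z"]
        assert set(table["method"]) == {
            "one_step", "proportional", "proportional_ml", "proportional_bch",
            "modal", "modal_ml", "modal_bch"}

    def test_near_perfect_classification_methods_agree(self):
        # extremely separated items: classification is essentially error-free
        data, fit, _ = _sim_fit(beta=0.5, n=800, seed=42, theta_hi=0.97,
                                n_items=8)
        table = compare_methods(data, 2, n_starts=8, seed=2)
        slopes = table.set_index("method")["mean"].abs()
        assert slopes.max() - slopes.min() < 0.05
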