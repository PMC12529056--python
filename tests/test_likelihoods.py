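"""Regression structure of both ZINB models and the total likelihood."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import expit

import mpbspread as mp
from mpbspread.likelihoods import (
    Model1Params,
    Model2Params,
    ModelData,
    PredictorSet,
    Standardization,
    model1_linear_predictors,
    model2_linear_predictors,
    total_loglik,
)
from mpbspread.zinb import zinb_logpmf


@pytest.fixture
def m1():
    return Model1Params(
        gamma0_L=0.4, gamma1_L=1.1, gamma0_J=-2.0, gamma1_J=0.5,
        beta0_L=1.5, beta1_L=0.7, beta0_J=0.2, beta1_J=0.4,
        k_L=0.9, k_J=0.5, c_J=1.3,
    )


@pytest.fixture
def m2():
    std = Standardization(0.5, 1.2, 0.45, 0.3, 7.0, 0.8)
    return Model2Params(
        gamma0=-0.5, gammaB=1.2, gammaQ=0.8, gammaV=0.4, gammaQV=0.1,
        beta0=1.0, betaB=0.8, betaQ=0.5, betaV=0.2, betaQV=0.05,
        k=0.9, standardization=std,
    )


class TestModel1Predictors:
    def test_unit_pressure_exposes_intercepts(self, m1):
        pi, mu, phi = model1_linear_predictors(np.array([1.0]), np.array([True]), m1)
        assert pi[0] == pytest.approx(expit(m1.gamma0_L), rel=1e-14)
        assert mu[0] == pytest.approx(np.exp(m1.beta0_L), rel=1e-14)
        assert phi[0] == m1.k_L

    def test_group_parameter_selection(self, m1):
        B = np.array([2.0, 2.0])
        pi, mu, phi = model1_linear_predictors(B, np.array([True, False]), m1)
        assert pi[0] == pytest.approx(expit(m1.gamma0_L + m1.gamma1_L * np.log(2)))
        assert pi[1] == pytest.approx(expit(m1.gamma0_J + m1.gamma1_J * np.log(2)))
        assert phi[1] == m1.k_J

    def test_brood_doubling_shifts_logit_by_gamma1_log2(self, m1, rng):
        """Through the pressure decomposition: doubling c_J shifts a pure-J
        row's log B by log 2, hence logit pi by gamma1_J * log 2."""
        df = pd.DataFrame({
            "year": 2007, "row": 0, "col": np.arange(5), "I": 0,
            "B_L": 0.0, "B_J": rng.uniform(0.5, 3.0, 5),
            "is_L": False, "Q": 0.05, "volume": 500.0,
        })
        data = ModelData(df=df)
        pi1, _, _ = model1_linear_predictors(data.pressure(m1.c_J), df["is_L"], m1)
        pi2, _, _ = model1_linear_predictors(data.pressure(2 * m1.c_J), df["is_L"], m1)
        shift = np.log(pi2 / (1 - pi2)) - np.log(pi1 / (1 - pi1))
        np.testing.assert_allclose(shift, m1.gamma1_J * np.log(2), rtol=1e-10)

    def test_nonpositive_pressure_rejected(self, m1):
        with pytest.raises(ValueError):
            model1_linear_predictors(np.array([0.0]), np.array([True]), m1)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            Model1Params(0, 0, 0, 0, 0, 0, 0, 0, k_L=-1, k_J=1)


class TestModel2Predictors:
    def test_intercept_only(self, m2):
        p = replace(m2, gammaB=0, gammaQ=0, gammaV=0, gammaQV=0,
                    betaB=0, betaQ=0, betaV=0, betaQV=0)
        _, mu, _ = model2_linear_predictors(
            np.array([3.0, 8.0]), np.array([0.2, 0.9]), np.array([100.0, 900.0]), p
        )
        np.testing.assert_allclose(mu, np.exp(p.beta0), rtol=1e-14)

    def test_counterfactual_q_constant_uses_stored_constants(self, m2):
        std = m2.standardization
        B, V = np.array([2.0, 5.0]), np.array([300.0, 800.0])
        p = PredictorSet.build(B, np.ones(2), V, std)
        expected = (1.0 - std.mean_Q) / std.sd_Q
        np.testing.assert_allclose(p.Q_star, expected, rtol=1e-14)

    def test_linear_predictor_dot_product_oracle(self, m2, rng):
        B = rng.uniform(0.5, 10, 50)
        Q = rng.uniform(0, 1, 50)
        V = rng.uniform(50, 5000, 50)
        pi, mu, phi = model2_linear_predictors(B, Q, V, m2)
        std = m2.standardization
        x = np.column_stack([
            np.ones(50),
            (np.log(B) - std.mean_logB) / std.sd_logB,
            (Q - std.mean_Q) / std.sd_Q,
            (np.log(V) - std.mean_logV) / std.sd_logV,
        ])
        x = np.column_stack([x, x[:, 2] * x[:, 3]])
        g = np.array([m2.gamma0, m2.gammaB, m2.gammaQ, m2.gammaV, m2.gammaQV])
        b = np.array([m2.beta0, m2.betaB, m2.betaQ, m2.betaV, m2.betaQV])
        np.testing.assert_allclose(np.log(pi / (1 - pi)), x @ g, atol=1e-12)
        np.testing.assert_allclose(np.log(mu), x @ b, atol=1e-12)

    def test_raw_product_interaction_switch(self, m2, rng):
        p = replace(m2, qv_raw_product=True)
        B, Q, V = np.array([2.0]), np.array([0.5]), np.array([100.0])
        pred = PredictorSet.build(B, Q, V, p.standardization, qv_raw_product=True)
        assert pred.QV[0] == pytest.approx(0.5 * 100.0)

    def test_standardization_from_training_centers(self, rng):
        logB = rng.normal(2, 3, 400)
        Q = rng.uniform(0, 1, 400)
        logV = rng.normal(7, 1, 400)
        std = Standardization.from_training(logB, Q, logV)
        p = PredictorSet.build(np.exp(logB), Q, np.exp(logV), std)
        for arr in (p.B_star, p.Q_star, p.V):
            assert abs(arr.mean()) < 1e-10
            assert abs(arr.std() - 1) < 1e-10

    def test_requires_standardization(self, m2):
        p = replace(m2, standardization=None)
        with pytest.raises(ValueError):
            model2_linear_predictors(np.array([1.0]), np.array([0.5]),
                                     np.array([10.0]), p)

    def test_nonpositive_volume_rejected(self, m2):
        with pytest.raises(ValueError):
            model2_linear_predictors(np.array([1.0]), np.array([0.5]),
                                     np.array([0.0]), m2)


def _random_data(rng, n=100):
    return ModelData(df=pd.DataFrame({
        "year": 2007, "row": 0, "col": np.arange(n),
        "I": rng.integers(0, 20, n),
        "B_L": rng.uniform(0, 3, n), "B_J": rng.uniform(0.1, 3, n),
        "is_L": rng.random(n) < 0.6,
        "Q": rng.uniform(0, 1, n), "volume": rng.uniform(10, 3000, n),
    }))


class TestTotalLoglik:
    def test_empty_data_is_zero(self, m1):
        data = ModelData(df=_random_data(np.random.default_rng(0)).df.iloc[0:0])
        total, pw = total_loglik(data, m1, "species")
        assert total == 0.0 and len(pw) == 0

    def test_duplicated_row_additivity(self, m1, rng):
        one = _random_data(rng, n=1)
        many = ModelData(df=pd.concat([one.df] * 7, ignore_index=True))
        t1, _ = total_loglik(one, m1, "species")
        t7, _ = total_loglik(many, m1, "species")
        assert t7 == pytest.approx(7 * t1, rel=1e-12)

    @pytest.mark.parametrize("kind", ["species", "covariate"])
    def test_composition_oracle(self, m1, m2, rng, kind):
        """Total equals the sum of independent per-row zinb_logpmf calls."""
        data = _random_data(rng)
        params = m1 if kind == "species" else m2
        total, pw = total_loglik(data, params, kind)
        df = data.df
        expected = []
        for _, row in df.iterrows():
            if kind == "species":
                B = row.B_L + m1.c_J * row.B_J
                pi, mu, phi = model1_linear_predictors(
                    np.array([B]), np.array([row.is_L]), m1)
            else:
                pi, mu, phi = model2_linear_predictors(
                    np.array([row.B_L + row.B_J]), np.array([row.Q]),
                    np.array([row.volume]), m2)
            expected.append(float(zinb_logpmf(row.I, pi, mu, phi)[0]))
        np.testing.assert_allclose(pw, expected, rtol=1e-10)
        assert total == pytest.approx(sum(expected), rel=1e-12)

    def test_row_order_invariance(self, m1, rng):
        data = _random_data(rng)
        shuffled = ModelData(df=data.df.sample(frac=1, random_state=1))
        t1, _ = total_loglik(data, m1, "species")
        t2, _ = total_loglik(shuffled, m1, "species")
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_equal_groups_match_groupless_model(self, rng):
        """With identical coefficients across groups and c_J = 1, the species
        model is observationally identical to a single-group model."""
        shared = dict(gamma0=0.3, gamma1=1.0, beta0=1.2, beta1=0.6, k=0.8)
        p = Model1Params(
            gamma0_L=shared["gamma0"], gamma1_L=shared["gamma1"],
            gamma0_J=shared["gamma0"], gamma1_J=shared["gamma1"],
            beta0_L=shared["beta0"], beta1_L=shared["beta1"],
            beta0_J=shared["beta0"], beta1_J=shared["beta1"],
            k_L=shared["k"], k_J=shared["k"], c_J=1.0,
        )
        data = _random_data(rng)
        total, _ = total_loglik(data, p, "species")
        B = data.pressure(1.0)
        pi = expit(shared["gamma0"] + shared["gamma1"] * np.log(B))
        mu = np.exp(shared["beta0"] + shared["beta1"] * np.log(B))
        groupless = zinb_logpmf(data.df["I"].to_numpy(), pi, mu, shared["k"]).sum()
        assert total == pytest.approx(float(groupless), rel=1e-12)
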