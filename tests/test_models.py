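"""Utility arithmetic, logit kernels, conditional logit, MSL, LR tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cohowtp as cw
from cohowtp.data import ChoiceDataset, DATA_COLUMNS
from cohowtp.models import K_COEF, make_draws


class TestSystematicUtility:
    def test_fish_only_scenario_returns_fish_mean(self):
        # price 0 kills the price term; one fish unit leaves the fish
        # coefficient 1.70 alone
        means = cw.RPLParams().means()
        attrs = cw.ScenarioAttributes(price=0.0, returning_fish=1.0)
        assert cw.systematic_utility(means, attrs) == pytest.approx(
            1.70 - np.exp(0.85) * 0.0
        )

    def test_hand_computed_program_utility(self):
        # -exp(0.85)*1.5 + 2.58 + 1.70*1.75 - 0.88*1.75
        means = cw.RPLParams().means()
        attrs = cw.ScenarioAttributes(price=1.5, recovered=1, returning_fish=1.75)
        expected = -np.exp(0.85) * 1.5 + 2.58 + 1.70 * 1.75 - 0.88 * 1.75
        assert cw.systematic_utility(means, attrs) == pytest.approx(expected)
        assert expected == pytest.approx(0.506, abs=5e-4)

    @given(st.lists(st.floats(-5, 5), min_size=9, max_size=9))
    def test_status_quo_utility_is_the_constant_alone(self, draw):
        from cohowtp.scenario import STATUS_QUO

        assert cw.systematic_utility(draw, STATUS_QUO) == pytest.approx(draw[0])

    @given(
        logprice=st.floats(-10, 10),
        price=st.floats(0.01, 5.0),
    )
    def test_price_always_reduces_utility(self, logprice, price):
        # the exponentiated-price contract: realized price coefficient < 0
        draw = np.zeros(9)
        draw[1] = logprice
        attrs = cw.ScenarioAttributes(price=price)
        assert cw.systematic_utility(draw, attrs) < 0


class TestLogitProbabilities:
    def test_equal_utilities_uniform(self):
        assert np.allclose(cw.logit_probabilities([2.0, 2.0, 2.0]), 1 / 3)

    def test_log_two_closed_form(self):
        assert np.allclose(cw.logit_probabilities([0.0, np.log(2)]), [1 / 3, 2 / 3])

    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=5), st.floats(-50, 50))
    def test_translation_invariance_and_simplex(self, u, c):
        p = cw.logit_probabilities(u)
        q = cw.logit_probabilities(np.asarray(u) + c)
        assert np.allclose(p, q, atol=1e-12)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()

    def test_nonfinite_utilities_rejected(self):
        with pytest.raises(ValueError):
            cw.logit_probabilities([0.0, np.nan])


class TestConditionalLogit:
    def test_null_model_loglik_is_n_log_third(self, homogeneous_dataset):
        # all utility weights zero (log-price -> -inf kills the price term)
        beta = np.zeros(9)
        beta[1] = -np.inf
        ll = cw.conditional_logit_loglik(beta, homogeneous_dataset)
        assert ll == pytest.approx(
            homogeneous_dataset.n_obs * np.log(1 / 3), abs=1e-8
        )

    def test_duplicating_data_doubles_loglik(self, homogeneous_dataset):
        beta = cw.RPLParams().means()
        ll = cw.conditional_logit_loglik(beta, homogeneous_dataset)
        rows2 = homogeneous_dataset.rows.copy()
        rows2["resp_id"] = rows2["resp_id"] + 100_000
        doubled = ChoiceDataset(
            pd.concat([homogeneous_dataset.rows, rows2], ignore_index=True)
        )
        assert cw.conditional_logit_loglik(beta, doubled) == pytest.approx(2 * ll)

    def test_parameter_recovery_from_known_coefficients(self, small_design):
        # n = 2000 homogeneous respondents: estimates within 3 SEs of truth
        params = cw.RPLParams().with_zero_sds()
        cfg = cw.PopulationConfig(
            n_respondents=2000, params=params, seed=21, task_nonresponse_rate=0.0
        )
        _, data = cw.simulate_dataset(cfg, small_design)
        fit = cw.fit_conditional_logit(data)
        assert fit.converged
        truth = params.means()
        z = (fit.estimates - truth) / fit.std_errors
        assert (np.abs(z) < 3).sum() >= 8  # allow one unlucky margin

    def test_loglik_at_fit_matches_reported(self, homogeneous_dataset):
        fit = cw.fit_conditional_logit(homogeneous_dataset)
        ll = cw.conditional_logit_loglik(fit.estimates, homogeneous_dataset)
        assert ll == pytest.approx(fit.loglik, abs=1e-8)


class TestSimulatedLoglik:
    def test_degenerate_mixing_equals_conditional_logit(self, heterogeneous_dataset):
        # all SDs 0: the mixture collapses for any draw count
        params = cw.RPLParams().with_zero_sds()
        cll = cw.conditional_logit_loglik(params.means(), heterogeneous_dataset)
        for n_draws in (1, 7, 64):
            cfg = cw.EstimationConfig(n_draws=n_draws, seed=3)
            sll = cw.simulated_loglik(params, heterogeneous_dataset, cfg)
            assert sll == pytest.approx(cll, abs=1e-10)

    def test_matches_gauss_hermite_quadrature_one_dimension(self):
        # 1 respondent, 1 task, fish coefficient random: MSL vs 60-node
        # Gauss-Hermite integration of the choice probability
        task = cw.generate_design(cw.DesignConfig(n_versions=1, seed=33))[0]
        rows = []
        for a_id, a in enumerate(task.alternatives):
            rows.append(
                dict(
                    resp_id=0,
                    task_id=task.task_id,
                    alt_id=a_id,
                    chosen=int(a_id == 1),
                    **a.as_row(),
                )
            )
        data = ChoiceDataset(pd.DataFrame(rows, columns=DATA_COLUMNS))
        means = cw.RPLParams().means()
        sds = np.zeros(9)
        sds[3] = 0.88
        params = cw.RPLParams.from_arrays(means, sds)

        nodes, weights = np.polynomial.hermite.hermgauss(60)
        acc = 0.0
        for x, w in zip(nodes, weights):
            b = means.copy()
            b[3] = means[3] + sds[3] * np.sqrt(2) * x
            u = [cw.systematic_utility(b, a) for a in task.alternatives]
            acc += w * cw.logit_probabilities(u)[1]
        ll_quad = np.log(acc / np.sqrt(np.pi))

        cfg = cw.EstimationConfig(n_draws=10_000, seed=12)
        ll_msl = cw.simulated_loglik(params, data, cfg)
        assert abs(ll_msl - ll_quad) < 1e-3

    def test_draw_convergence_is_stabilizing(self, heterogeneous_dataset):
        # |LL(2R) - LL(R)| shrinks as the draw count doubles
        params = cw.RPLParams()
        lls = [
            cw.simulated_loglik(
                params,
                heterogeneous_dataset,
                cw.EstimationConfig(n_draws=r, seed=4),
            )
            for r in (50, 100, 200, 400)
        ]
        gaps = np.abs(np.diff(lls))
        assert gaps[-1] < gaps[0]

    def test_deterministic_for_fixed_seed(self, heterogeneous_dataset):
        cfg = cw.EstimationConfig(n_draws=100, seed=5)
        a = cw.simulated_loglik(cw.RPLParams(), heterogeneous_dataset, cfg)
        b = cw.simulated_loglik(cw.RPLParams(), heterogeneous_dataset, cfg)
        assert a == b


class TestHaltonDraws:
    def test_block_per_respondent_and_shape(self):
        cfg = cw.EstimationConfig(n_draws=64, seed=9)
        z = make_draws(5, cfg)
        assert z.shape == (5, 64, K_COEF)
        # scrambled Halton normals: near-zero mean, near-unit variance
        assert np.abs(z.mean(axis=(0, 1))).max() < 0.05
        assert np.abs(z.std(axis=(0, 1)) - 1).max() < 0.05

    def test_pseudo_random_fallback(self):
        cfg = cw.EstimationConfig(n_draws=64, seed=9, draw_type="pseudo-random")
        z = make_draws(5, cfg)
        assert z.shape == (5, 64, K_COEF)


class TestFitRPL:
    def test_degenerate_heterogeneity_recovery(self, homogeneous_dataset):
        # data generated with all SDs = 0: fitted SDs shrink, means match
        # the conditional logit
        cfg = cw.EstimationConfig(n_draws=100, seed=6, max_iterations=400)
        cl = cw.fit_conditional_logit(homogeneous_dataset)
        rpl = cw.fit_rpl(homogeneous_dataset, cfg)
        means, sds = rpl.mean_sd_arrays()
        z = np.abs(means - cl.estimates) / cl.std_errors
        assert (z < 2).sum() >= 8
        assert np.median(sds) < 0.5

    def test_bitwise_reproducible(self, heterogeneous_dataset):
        cfg = cw.EstimationConfig(n_draws=60, seed=7, max_iterations=150)
        a = cw.fit_rpl(heterogeneous_dataset, cfg)
        b = cw.fit_rpl(heterogeneous_dataset, cfg)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.loglik == b.loglik

    def test_reported_sds_nonnegative(self, heterogeneous_dataset):
        cfg = cw.EstimationConfig(n_draws=60, seed=8, max_iterations=150)
        fit = cw.fit_rpl(heterogeneous_dataset, cfg)
        _, sds = fit.mean_sd_arrays()
        assert (sds >= 0).all()


class TestLRTest:
    def test_equal_logliks(self):
        stat, p = cw.lr_test(-100.0, -100.0, 3)
        assert stat == 0.0 and p == 1.0

    def test_published_loglik_arithmetic(self):
        stat, p = cw.lr_test(-2576.9, -2016.16, 9)
        assert stat == pytest.approx(1121.48)
        assert p < 1e-6

    def test_tiny_negative_violation_warns_not_fails(self):
        with pytest.warns(UserWarning):
            stat, p = cw.lr_test(-99.9999999, -100.0, 2)
        assert stat == 0.0 and p == 1.0

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            cw.lr_test(-10.0, -5.0, 0)
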