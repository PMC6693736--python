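"""WTP surfaces, compensating-variation distributions, marginal values, CIs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cohowtp as cw
from cohowtp import defaults
from cohowtp.models import FitResult
from cohowtp.welfare import present_marginal, scenario_wtp_numerator


def scenario(fish=0.0, recovered=0, quick=0):
    return cw.ScenarioAttributes(
        price=0.0, recovered=recovered, returning_fish=fish, quick=quick
    )


class TestSurfaces:
    def test_threatened_slow_at_10k_fish(self):
        s = defaults.WTP_SURFACES[("threatened", "slow")]
        assert round(cw.wtp_surface_eval(s, 0.1), 2) == 5.98

    def test_threatened_quick_at_10k_fish(self):
        s = defaults.WTP_SURFACES[("threatened", "quick")]
        assert round(cw.wtp_surface_eval(s, 0.1), 2) == 49.34

    def test_surface_at_zero_fish_is_intercept(self):
        slow = defaults.WTP_SURFACES[("threatened", "slow")]
        quick = defaults.WTP_SURFACES[("threatened", "quick")]
        assert cw.wtp_surface_eval(slow, 0.0) == 0.0
        assert cw.wtp_surface_eval(quick, 0.0) == pytest.approx(44.41)

    def test_surfaces_additive_marginal_values(self):
        # marginal value from surfaces == difference of evaluations
        slow = defaults.WTP_SURFACES[("threatened", "slow")]
        quick = defaults.WTP_SURFACES[("threatened", "quick")]
        for fish in (0.5, 1.0, 2.25):
            delta = cw.marginal_attribute_value(
                cw.wtp_surface_eval(quick, fish), cw.wtp_surface_eval(slow, fish)
            )
            assert delta == pytest.approx(
                (quick.intercept - slow.intercept)
                + (quick.slope - slow.slope) * fish
            )

    def test_fit_wtp_surface_recovers_line(self):
        fish = [1.0, 1.75, 2.25]
        wtp = [10 + 50 * f for f in fish]
        s = cw.fit_wtp_surface(fish, wtp)
        assert s.intercept == pytest.approx(10.0)
        assert s.slope == pytest.approx(50.0)


class TestWTPDistribution:
    def _degenerate_fit(self, means=None):
        params = (
            cw.RPLParams() if means is None else cw.RPLParams.from_arrays(
                means, np.zeros(9)
            )
        ).with_zero_sds()
        return params

    def test_degenerate_ratio_closed_form(self):
        # beta3 = 1.70, log-price 0.85: WTP = 1.70/exp(0.85)*100
        params = self._degenerate_fit()
        s = cw.simulate_wtp_distribution(params, scenario(fish=1.0), n_draws=100)
        expected = 1.70 / np.exp(0.85) * 100
        assert s.mean == pytest.approx(expected)
        assert s.median == pytest.approx(expected)
        assert expected == pytest.approx(72.66, abs=0.01)

    def test_zero_numerator_degenerate_at_zero(self):
        means = np.zeros(9)
        means[1] = 0.85
        params = cw.RPLParams.from_arrays(means, np.zeros(9))
        s = cw.simulate_wtp_distribution(
            params, scenario(fish=2.0, recovered=1, quick=1), n_draws=500
        )
        assert s.mean == 0.0 and s.median == 0.0

    def test_lognormal_denominator_median_identity(self):
        # only the price coefficient random: median WTP =
        # numerator / exp(logprice_mean) * 100
        means = cw.RPLParams().means()
        sds = np.zeros(9)
        sds[1] = 1.66
        params = cw.RPLParams.from_arrays(means, sds)
        s = cw.simulate_wtp_distribution(
            params, scenario(fish=1.0), n_draws=400_000, seed=2
        )
        expected_median = 1.70 / np.exp(0.85) * 100
        assert s.median == pytest.approx(expected_median, rel=0.02)
        # the mean is inflated by the log-normal inverse moment
        assert s.mean > s.median

    def test_heavy_tail_warning(self):
        means = cw.RPLParams().means()
        sds = np.zeros(9)
        sds[1] = 3.0
        params = cw.RPLParams.from_arrays(means, sds)
        with pytest.warns(UserWarning, match="heavy"):
            cw.simulate_wtp_distribution(
                params, scenario(fish=1.0), n_draws=50_000, seed=3
            )

    @given(scale=st.floats(0.1, 10.0))
    def test_welfare_ratio_scale_invariance(self, scale):
        # multiplying all non-price coefficients and exp(b1) by the same
        # constant leaves per-draw WTP unchanged
        rng = np.random.default_rng(0)
        beta = rng.normal(size=9)
        sc = scenario(fish=1.75, recovered=1)
        base = 100 * scenario_wtp_numerator(beta, sc) / np.exp(beta[1])
        beta2 = beta.copy()
        beta2[2:] *= scale
        beta2[1] = beta[1] + np.log(scale)
        scaled = 100 * scenario_wtp_numerator(beta2, sc) / np.exp(beta2[1])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_quick_premium_declines_in_fish(self):
        # with a negative quick x fish interaction mean, the quick-minus-slow
        # WTP difference shrinks as returns grow
        params = cw.RPLParams().with_zero_sds()
        gaps = []
        for fish in (1.0, 1.75, 2.25, 3.75):
            q = cw.simulate_wtp_distribution(
                params, scenario(fish=fish, quick=1), n_draws=10
            ).mean
            s = cw.simulate_wtp_distribution(
                params, scenario(fish=fish), n_draws=10
            ).mean
            gaps.append(q - s)
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestMarginalValues:
    def test_published_recovered_premiums(self):
        # Recovered-vs-threatened at 175,000 fish (slow): $135.19 - $104.57
        d1 = cw.marginal_attribute_value(135.19, 104.57)
        assert d1 == pytest.approx(30.62)
        assert present_marginal(d1) == 31
        # at 225,000 fish: $144.02 - $134.45
        d2 = cw.marginal_attribute_value(144.02, 134.45)
        assert d2 == pytest.approx(9.57)
        assert present_marginal(d2) == 10

    def test_identity_and_rounding_convention(self):
        assert cw.marginal_attribute_value(12.3, 12.3) == 0.0
        assert present_marginal(0.5) == 1  # half away from zero
        assert present_marginal(-0.5) == -1


class TestKrinskyRobb:
    def _fit(self, cov_scale=1.0, n=50):
        means = cw.RPLParams().means()
        est = means.copy()
        cov = cov_scale * np.eye(9) * 0.01
        return FitResult(
            model="clogit",
            coef_names=list(cw.COEF_NAMES),
            estimates=est,
            std_errors=np.sqrt(np.diag(cov)),
            cov=cov,
            loglik=-100.0,
            converged=True,
            n_obs=n,
            n_respondents=n,
        )

    def test_zero_covariance_collapses_to_point(self):
        fit = self._fit(cov_scale=0.0)
        s = cw.krinsky_robb_ci(fit, scenario(fish=1.0), n_boot=200, inner_draws=1)
        point = 1.70 / np.exp(0.85) * 100
        assert s.ci_low == pytest.approx(point)
        assert s.ci_high == pytest.approx(point)

    def test_interval_nesting(self):
        fit = self._fit()
        wide = cw.krinsky_robb_ci(
            fit, scenario(fish=1.0), level=0.95, n_boot=500, seed=5, inner_draws=1
        )
        narrow = cw.krinsky_robb_ci(
            fit, scenario(fish=1.0), level=0.80, n_boot=500, seed=5, inner_draws=1
        )
        assert wide.ci_low <= narrow.ci_low <= narrow.ci_high <= wide.ci_high

    def test_missing_covariance_raises(self):
        fit = self._fit()
        fit.cov = None
        with pytest.raises(ValueError, match="se_method"):
            cw.krinsky_robb_ci(fit, scenario(fish=1.0))

    def test_coverage_of_true_wtp(self, small_design):
        # 60 homogeneous-population datasets: the 95% interval should cover
        # the true (degenerate) mean WTP in roughly 95% of fits
        params = cw.RPLParams().with_zero_sds()
        true_wtp = 1.70 / np.exp(0.85) * 100
        sc = scenario(fish=1.0)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = cw.PopulationConfig(
                n_respondents=250,
                params=params,
                seed=1000 + rep,
                task_nonresponse_rate=0.0,
            )
            _, data = cw.simulate_dataset(cfg, small_design)
            fit = cw.fit_conditional_logit(data)
            if not fit.converged:
                continue
            s = cw.krinsky_robb_ci(
                fit, sc, n_boot=300, seed=rep, inner_draws=1
            )
            hits += s.ci_low <= true_wtp <= s.ci_high
        assert 0.85 * n_rep <= hits <= n_rep
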