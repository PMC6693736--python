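"""Willingness-to-pay: compensating variation, WTP surfaces, marginal values.

A household's compensating variation for a scenario is the annual payment
that equates the utility of the scenario with the utility of no change.
With the linear-in-attributes utility and the exponentiated price
coefficient, each realized coefficient vector implies

    WTP ($/y) = 100 * (non-price systematic utility of the scenario) / exp(b1),

the factor 100 converting from the $100 price coding.  Because exp(b1) is
log-normal the population WTP distribution has a fat right tail; the mean
and median are therefore both first-class summaries here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import FitResult, K_COEF, RPLParams
from .scenario import ScenarioAttributes

__all__ = [
    "WTPSurface",
    "WTPDistributionSummary",
    "wtp_surface_eval",
    "fit_wtp_surface",
    "simulate_wtp_distribution",
    "marginal_attribute_value",
    "present_marginal",
    "krinsky_robb_ci",
    "scenario_wtp_numerator",
]


@dataclass(frozen=True)
class WTPSurface:
    """A linear household WTP function of the fish increase.

    ``intercept`` and ``slope`` are in $/household/year, the slope per
    100,000 returning fish; ``esa_status`` and ``rate`` label the scenario
    context the surface conditions on.
    """

    esa_status: str  # "threatened" | "recovered"
    rate: str  # "slow" | "quick"
    intercept: float
    slope: float


@dataclass(frozen=True)
class WTPDistributionSummary:
    """Central tendency and interval of a simulated household WTP distribution."""

    mean: float
    median: float
    ci_low: float
    ci_high: float
    level: float
    n_draws: int
    estimator: str = "mean"
    heavy_tailed: bool = False

    @property
    def point(self) -> float:
        return self.mean if self.estimator == "mean" else self.median


def wtp_surface_eval(surface: WTPSurface, returning_fish: float) -> float:
    """Evaluate a WTP surface at a fish increase (100,000s); unrounded dollars."""
    if returning_fish < 0:
        raise ValueError("returning_fish must be non-negative")
    return surface.intercept + surface.slope * returning_fish


def fit_wtp_surface(
    fish_levels, wtp_values, esa_status: str = "", rate: str = ""
) -> WTPSurface:
    """Least-squares line through (fish, WTP) scenario points."""
    slope, intercept = np.polyfit(
        np.asarray(fish_levels, float), np.asarray(wtp_values, float), 1
    )
    return WTPSurface(esa_status, rate, float(intercept), float(slope))


def scenario_wtp_numerator(beta: np.ndarray, attrs: ScenarioAttributes) -> np.ndarray:
    """Non-price systematic utility of a scenario relative to no change.

    ``beta`` may be a single draw (9,) or an array of draws (..., 9); the
    status-quo constant and price term are excluded by construction.
    """
    b = np.asarray(beta, dtype=float)
    return (
        b[..., 2] * attrs.recovered
        + b[..., 3] * attrs.returning_fish
        + b[..., 4] * attrs.quick
        + b[..., 5] * attrs.fishing1
        + b[..., 6] * attrs.fishing2
        + b[..., 7] * attrs.recovered * attrs.returning_fish
        + b[..., 8] * attrs.quick * attrs.returning_fish
    )


def _wtp_draws(means, sds, attrs, n_draws, rng) -> np.ndarray:
    z = rng.standard_normal((n_draws, K_COEF))
    beta = means + sds * z
    return 100.0 * scenario_wtp_numerator(beta, attrs) / np.exp(beta[..., 1])


def _resolve_params(fit) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fit, RPLParams):
        return fit.means(), fit.sds()
    if isinstance(fit, FitResult):
        if not fit.converged:
            raise ValueError("fit did not converge; refusing to simulate WTP")
        return fit.mean_sd_arrays()
    raise TypeError("expected FitResult or RPLParams")


def simulate_wtp_distribution(
    fit,
    scenario: ScenarioAttributes,
    n_draws: int = 100_000,
    seed: int = 0,
    estimator: str = "mean",
    level: float = 0.95,
    tail_ratio_warn: float = 5.0,
) -> WTPDistributionSummary:
    """Simulate the household WTP distribution for one scenario.

    Coefficient vectors are drawn from the fitted mixing distributions and
    the per-draw compensating variation computed; returns the configured
    central tendency with symmetric-tail quantile bounds.  A warning is
    issued when the mean/median ratio exceeds ``tail_ratio_warn`` (the
    log-normal denominator can make the mean fat-tailed).
    """
    means, sds = _resolve_params(fit)
    rng = np.random.default_rng(seed)
    w = _wtp_draws(means, sds, scenario, n_draws, rng)
    mean = float(w.mean())
    median = float(np.median(w))
    lo, hi = np.quantile(w, [(1 - level) / 2, 1 - (1 - level) / 2])
    heavy = median != 0 and abs(mean / median) > tail_ratio_warn
    if estimator == "mean" and heavy:
        warnings.warn(
            f"mean/median WTP ratio {mean / median:.2f} exceeds "
            f"{tail_ratio_warn}; the mean is heavy-tailed — consider the median",
            stacklevel=2,
        )
    return WTPDistributionSummary(
        mean=mean,
        median=median,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_draws=n_draws,
        estimator=estimator,
        heavy_tailed=heavy,
    )


def marginal_attribute_value(wtp_a: float, wtp_b: float) -> float:
    """Difference of two household WTP values on the same $/year scale."""
    return wtp_a - wtp_b


def present_marginal(value: float) -> int:
    """Presentation rounding for marginal values: nearest dollar, half away from zero."""
    return int(np.sign(value) * np.floor(abs(value) + 0.5))


def krinsky_robb_ci(
    fit: FitResult,
    scenario: ScenarioAttributes,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    inner_draws: int = 2000,
    statistic: str = "mean",
) -> WTPDistributionSummary:
    """Krinsky-Robb percentile interval for a WTP statistic.

    Parameter vectors are resampled from the asymptotic normal sampling
    distribution of the estimates (using the fit's covariance); for each
    resample the WTP statistic is recomputed over a common set of mixing
    draws and the percentile interval of the resampled statistics returned.
    """
    if fit.cov is None:
        raise ValueError(
            "fit has no covariance matrix; re-estimate with se_method='hessian' "
            "or 'sandwich'"
        )
    rng = np.random.default_rng(seed)
    k = len(fit.estimates)
    # symmetric square root tolerant of a (near-)singular covariance
    vals, vecs = np.linalg.eigh(0.5 * (fit.cov + fit.cov.T))
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    thetas = fit.estimates + rng.standard_normal((n_boot, k)) @ root.T

    z = rng.standard_normal((inner_draws, K_COEF))  # common random numbers
    stats_out = np.empty(n_boot)
    for b in range(n_boot):
        if fit.model == "rpl":
            means = thetas[b, :K_COEF]
            sds = np.abs(thetas[b, K_COEF : 2 * K_COEF])
        else:
            means = thetas[b, :K_COEF]
            sds = np.zeros(K_COEF)
        beta = means + sds * z
        w = 100.0 * scenario_wtp_numerator(beta, scenario) / np.exp(beta[..., 1])
        stats_out[b] = w.mean() if statistic == "mean" else np.median(w)

    lo, hi = np.quantile(stats_out, [(1 - level) / 2, 1 - (1 - level) / 2])
    return WTPDistributionSummary(
        mean=float(stats_out.mean()),
        median=float(np.median(stats_out)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_draws=n_boot,
        estimator=statistic,
    )
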