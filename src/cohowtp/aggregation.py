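"""Scaling household WTP to population-level annual benefits.

Two aggregation rules bracket the population benefit: a conservative lower
bound multiplies sample WTP by only the response-rate share of households
(treating non-respondents as having zero WTP), and an upper bound
multiplies a demographically adjusted WTP by every Pacific Northwest
household.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import FitResult, K_COEF
from .scenario import ScenarioAttributes
from .welfare import scenario_wtp_numerator

__all__ = [
    "AggregationInputs",
    "BenefitEstimate",
    "AdjustedWTP",
    "lower_bound_households",
    "aggregate_benefits",
    "population_adjust_wtp",
]


@dataclass(frozen=True)
class AggregationInputs:
    """Household counts and response rates for benefit aggregation.

    Defaults are the Pacific Northwest census counts and the survey's
    Oregon / non-Oregon response rates.
    """

    households_oregon: int = 1_570_430
    households_other_pnw: int = 7_837_629
    response_rate_oregon: float = 0.254
    response_rate_other: float = 0.178
    households_total: int = 9_408_059

    def __post_init__(self) -> None:
        for r in (self.response_rate_oregon, self.response_rate_other):
            if not 0 <= r <= 1:
                raise ValueError("response rates must be in [0, 1]")
        for c in (
            self.households_oregon,
            self.households_other_pnw,
            self.households_total,
        ):
            if c < 0:
                raise ValueError("household counts must be non-negative")


@dataclass(frozen=True)
class BenefitEstimate:
    """A population benefit: household WTP times the households it covers."""

    scenario: str
    household_wtp: float  # $/household/year
    households_used: int
    bound: str  # "lower" | "upper"
    total: float  # $/year, exact product

    def present(self) -> str:
        """Printed precision: nearest $million, billions to two decimals."""
        if self.total >= 1e9:
            return f"${self.total / 1e9:.2f} billion"
        return f"${self.total / 1e6:.0f} million"


def lower_bound_households(inputs: AggregationInputs) -> int:
    """Households assumed to hold non-zero WTP under the lower-bound rule.

    Each state group contributes its response-rate share, rounded to the
    nearest household before summation.
    """
    oregon = round(inputs.response_rate_oregon * inputs.households_oregon)
    other = round(inputs.response_rate_other * inputs.households_other_pnw)
    return int(oregon) + int(other)


def aggregate_benefits(
    household_wtp: float,
    households: int,
    scenario: str = "",
    bound: str = "lower",
) -> BenefitEstimate:
    """Annual population benefit = household WTP x household count."""
    if household_wtp < 0:
        raise ValueError("household_wtp must be non-negative")
    return BenefitEstimate(
        scenario=scenario,
        household_wtp=household_wtp,
        households_used=int(households),
        bound=bound,
        total=float(household_wtp) * int(households),
    )


@dataclass(frozen=True)
class AdjustedWTP:
    scenario: ScenarioAttributes
    sample_wtp: float
    adjusted_wtp: float


def population_adjust_wtp(
    fit: FitResult,
    scenarios: Sequence[ScenarioAttributes],
    population_share: float,
    sample_share: float,
    targets: Sequence[str] = ("recovered", "fish", "quick"),
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[AdjustedWTP]:
    """Re-evaluate mean WTP with interacted coefficient means at population shares.

    ``fit`` must include demographic-interaction coefficients
    (``mod_x_<target>``) on the conservation parameters.  The mean of each
    interacted coefficient is shifted from its value at the sample share of
    the demographic group to its value at the population share; SDs are
    left unchanged.  Returns the sample-share and population-share mean WTP
    per scenario (identical draws for both, so the contrast is exact).
    """
    gammas = fit.extra_coefs()
    missing = [t for t in targets if f"mod_x_{t}" not in gammas]
    if missing:
        raise ValueError(
            f"fit lacks demographic-interaction coefficients for {missing}; "
            "re-estimate with moderator interactions on (recovered, fish, quick)"
        )
    from .models import ATTRIBUTE_COLUMNS  # local import to avoid cycle at import time

    means, sds = fit.mean_sd_arrays()
    shift = np.zeros(K_COEF)
    for t in targets:
        shift[ATTRIBUTE_COLUMNS[t]] = gammas[f"mod_x_{t}"]
    means_sample = means + shift * sample_share
    means_pop = means + shift * population_share

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, K_COEF))
    out = []
    for sc in scenarios:
        beta_s = means_sample + sds * z
        beta_p = means_pop + sds * z
        w_s = 100.0 * scenario_wtp_numerator(beta_s, sc) / np.exp(beta_s[..., 1])
        w_p = 100.0 * scenario_wtp_numerator(beta_p, sc) / np.exp(beta_p[..., 1])
        out.append(AdjustedWTP(sc, float(w_s.mean()), float(w_p.mean())))
    return out
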