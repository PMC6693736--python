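"""Published point estimates and census inputs for the Oregon Coast coho study.

These constants are the worked-example inputs the package documents and
tests against: the estimated utility parameters (used as synthetic-
population generating values via :class:`cohowtp.models.RPLParams`
defaults), the printed linear WTP surfaces, the scenario WTP table, and the
household counts and response rates used for benefit aggregation.
"""

from __future__ import annotations

from .aggregation import AggregationInputs
from .models import RPLParams
from .welfare import WTPSurface

#: Estimated coefficient means/SDs of the preferred RPL model.
STUDY_PARAMS = RPLParams()

#: Log-likelihoods of the fitted RPL and the comparable conditional logit.
RPL_LOGLIK = -2016.16
CLOGIT_LOGLIK = -2576.9

#: Usable choice tasks and completed surveys behind the fit.
N_OBS = 2734
N_RESPONDENTS = 926

#: Fitted linear household WTP surfaces ($/household/year as a function of
#: the fish increase in 100,000s) for scenarios that leave the stock
#: threatened.  The threatened/slow surface passes through the origin.
WTP_SURFACES = {
    ("threatened", "slow"): WTPSurface("threatened", "slow", 0.0, 59.75),
    ("threatened", "quick"): WTPSurface("threatened", "quick", 44.41, 49.28),
}

#: Per-100,000-fish WTP slopes quoted for recovered-status scenarios.
RECOVERED_SLOW_SLOPE = 11.77
RECOVERED_QUICK_SLOPE = 4.55

#: Scenario WTP table: (status, fish in 100,000s, rate) ->
#: (sample mean WTP, population-adjusted mean WTP), $/household/year.
SCENARIO_WTP = {
    ("threatened", 1.0, "slow"): (59.75, 55.13),
    ("threatened", 1.75, "slow"): (104.57, 96.47),
    ("threatened", 2.25, "slow"): (134.45, 124.04),
    ("threatened", 1.0, "quick"): (93.69, 84.62),
    ("threatened", 1.75, "quick"): (130.65, 118.29),
    ("threatened", 2.25, "quick"): (154.99, 140.43),
    ("recovered", 1.75, "slow"): (135.19, 123.45),
    ("recovered", 2.25, "slow"): (144.02, 130.04),
    ("recovered", 3.75, "slow"): (170.58, 150.08),
    ("recovered", 1.75, "quick"): (164.88, 149.29),
    ("recovered", 2.25, "quick"): (168.29, 150.53),
    ("recovered", 3.75, "quick"): (179.19, 155.30),
}

#: Pacific Northwest household counts and survey response rates.
AGGREGATION_INPUTS = AggregationInputs()

#: Share of adults with a 4-year college degree: survey sample vs census.
SAMPLE_COLLEGE_SHARE = 0.54
POPULATION_COLLEGE_SHARE = 0.358

#: College-graduate WTP premium per 100,000 returning fish ($/y).
COLLEGE_FISH_WTP_PREMIUM = 31.0

#: Overall survey response rate after undeliverables.
RESPONSE_RATE = 0.21
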