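"""Representativeness and sample-selection diagnostics.

Two complementary checks of whether survey respondents' preferences can be
generalized: (1) likelihood-ratio tests of demographic interactions with
the conservation utility parameters (recovered status, returning fish,
quick returns), and (2) a selection-on-unobservables test that fits a
response-propensity model on the full sampling frame (with a mail-delivery
exclusion variable), centers the fitted propensities (``pdiff``), and
tests whether preferences vary with ``pdiff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import ChoiceDataset
from .models import (
    EstimationConfig,
    FitResult,
    fit_conditional_logit,
    fit_rpl,
    lr_test,
)

__all__ = [
    "SelectionFit",
    "LRTestResult",
    "fit_selection_model",
    "compute_pdiff",
    "interaction_lr_test",
]

DEFAULT_SELECTION_COVARIATES = (
    "college",
    "age65",
    "male",
    "white",
    "oregon",
    "cluster_box",
)


@dataclass
class SelectionFit:
    """A fitted binary response-propensity model over the sampling frame."""

    params: pd.Series
    std_errors: pd.Series
    pvalues: pd.Series
    propensities: np.ndarray
    mean_propensity: float
    exclusion_variable: str
    model: str  # "logit" | "probit"
    converged: bool
    loglik: float

    @property
    def exclusion_coef(self) -> float:
        return float(self.params[self.exclusion_variable])

    @property
    def exclusion_pvalue(self) -> float:
        return float(self.pvalues[self.exclusion_variable])


def fit_selection_model(
    frame: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_SELECTION_COVARIATES,
    outcome: str = "responded",
    exclusion: str = "cluster_box",
    model: str = "logit",
) -> SelectionFit:
    """Fit the selection equation P(respond | covariates) on the full frame.

    The frame must cover respondents and non-respondents; ``exclusion``
    names the covariate serving as the exclusion restriction (reported with
    its coefficient and significance).
    """
    y = frame[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"outcome '{outcome}' is constant; cannot fit selection model")
    if exclusion not in covariates:
        raise ValueError(f"exclusion variable '{exclusion}' not among covariates")
    covs = list(covariates)
    # constant covariates carry no information; drop them (reported as 0/NaN)
    dropped = [c for c in covs if frame[c].nunique() <= 1]
    kept = [c for c in covs if c not in dropped]
    X = sm.add_constant(frame[kept].astype(float), has_constant="add")
    cls = sm.Logit if model == "logit" else sm.Probit
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = cls(y, X).fit(disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as e:  # perfect separation and friends
            raise ValueError(f"selection model failed to fit: {e}") from e
    prop = np.asarray(res.predict(X))
    order = ["const"] + covs
    params = res.params.reindex(order, fill_value=0.0)
    bse = res.bse.reindex(order)
    pvalues = res.pvalues.reindex(order)
    return SelectionFit(
        params=params,
        std_errors=bse,
        pvalues=pvalues,
        propensities=prop,
        mean_propensity=float(prop.mean()),
        exclusion_variable=exclusion,
        model=model,
        converged=converged,
        loglik=float(res.llf),
    )


def compute_pdiff(selection: SelectionFit) -> np.ndarray:
    """Centered response propensities: propensity_i minus the frame mean.

    Sums to zero over the estimation sample by construction.
    """
    return selection.propensities - selection.mean_propensity


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p_value: float
    fit_base: FitResult
    fit_full: FitResult


def interaction_lr_test(
    data: ChoiceDataset,
    moderator,
    targets: Sequence[str] = ("recovered", "fish", "quick"),
    config: EstimationConfig | None = None,
    model: str = "rpl",
    start=None,
) -> LRTestResult:
    """LR test of moderator interactions with the conservation parameters.

    Fits the choice model with and without mean shifts
    ``moderator x {recovered, fish, quick}``.  For the RPL both fits use
    identical draws (same config seed and respondent count) so the
    statistic is not contaminated by simulation noise; df equals the number
    of interactions.  ``moderator`` is a per-respondent value (dict,
    Series indexed by resp_id, or array in respondent order).
    """
    config = config or EstimationConfig()
    if model == "rpl":
        base = fit_rpl(data, config, start=start)
        full = fit_rpl(data, config, start=np.concatenate(
            [base.estimates, np.zeros(len(targets))]
        ), moderator=moderator, targets=targets)
    elif model == "clogit":
        base = fit_conditional_logit(data, config, start=start)
        full = fit_conditional_logit(
            data,
            config,
            start=np.concatenate([base.estimates, np.zeros(len(targets))]),
            moderator=moderator,
            targets=targets,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    stat, p = lr_test(base.loglik, full.loglik, df=len(targets))
    return LRTestResult(stat, len(targets), p, base, full)
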