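"""Choice-experiment attribute space, design generation, and fish-return trajectories.

A conservation alternative ("salmon recovery program") is a bundle of a
household price, an official recovery-status indicator, an increase in
returning adult fish above the 150,000-fish status quo baseline, a quick/slow
rate-of-increase indicator, and two mutually exclusive fishing-regulation
indicators.  Every choice task pairs two priced programs with an unpriced
status quo.  Price is coded in $100s per household per year and the fish
increase in 100,000s of fish, the coding under which the utility model of
:mod:`cohowtp.models` is expressed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioAttributes",
    "ChoiceTask",
    "DesignConfig",
    "TrajectoryParams",
    "QUICK_TRAJECTORY",
    "SLOW_TRAJECTORY",
    "STATUS_QUO",
    "generate_design",
    "d0_error",
    "beta_growth_trajectory",
    "design_to_frame",
    "frame_to_design",
    "write_design",
    "read_design",
]

#: Minimum fish increase (in 100,000s) at which "recovered" status is feasible.
RECOVERED_MIN_FISH = 1.75


class DesignError(ValueError):
    """Raised when a design configuration admits no feasible tasks."""


@dataclass(frozen=True)
class ScenarioAttributes:
    """One alternative's attribute bundle.

    Parameters
    ----------
    price
        Annual household cost in units of $100 (so ``1.5`` means $150/y).
    recovered
        1 if the stock is officially recovered off the endangered-species
        list under the scenario, else 0.
    returning_fish
        Increase in returning adult fish above the baseline, in 100,000s.
    quick
        1 if the increase in returns is achieved quickly, 0 if slowly.
    fishing1, fishing2
        Mutually exclusive season indicators (annual season with a 5 or a
        10 fish/year bag limit respectively).
    is_status_quo
        1 for the no-program alternative (all other fields must be 0).
    """

    price: float = 0.0
    recovered: int = 0
    returning_fish: float = 0.0
    quick: int = 0
    fishing1: int = 0
    fishing2: int = 0
    is_status_quo: int = 0

    def __post_init__(self) -> None:
        if self.price < 0:
            raise ValueError(f"price must be non-negative, got {self.price}")
        if self.returning_fish < 0:
            raise ValueError(
                f"returning_fish must be non-negative, got {self.returning_fish}"
            )
        for name in ("recovered", "quick", "fishing1", "fishing2", "is_status_quo"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.fishing1 and self.fishing2:
            raise ValueError("fishing1 and fishing2 are mutually exclusive")
        if self.is_status_quo:
            if (
                self.price != 0
                or self.recovered
                or self.returning_fish != 0
                or self.quick
                or self.fishing1
                or self.fishing2
            ):
                raise ValueError("status quo alternative must have all attributes 0")
        if self.recovered and self.returning_fish < RECOVERED_MIN_FISH:
            raise ValueError(
                "recovered status requires returning_fish >= "
                f"{RECOVERED_MIN_FISH} (100,000s); got {self.returning_fish}"
            )

    def as_row(self) -> dict:
        return {
            "is_status_quo": self.is_status_quo,
            "price": self.price,
            "recovered": self.recovered,
            "returning_fish": self.returning_fish,
            "quick": self.quick,
            "fishing1": self.fishing1,
            "fishing2": self.fishing2,
        }


#: The no-program alternative shown in every task at $0 cost.
STATUS_QUO = ScenarioAttributes(is_status_quo=1)


@dataclass(frozen=True)
class ChoiceTask:
    """One survey question: a status quo plus two priced programs."""

    task_id: str
    alternatives: tuple[ScenarioAttributes, ...]

    def __post_init__(self) -> None:
        if len(self.alternatives) != 3:
            raise ValueError("a choice task has exactly 3 alternatives")
        n_sq = sum(a.is_status_quo for a in self.alternatives)
        if n_sq != 1:
            raise ValueError("exactly one alternative must be the status quo")
        for a in self.alternatives:
            if not a.is_status_quo and a.price <= 0:
                raise ValueError("program alternatives must have price > 0")


@dataclass(frozen=True)
class DesignConfig:
    """Levels and structure for random restricted-grid design generation.

    The fish levels default to the scenario increases used in the survey
    (100,000 / 175,000 / 225,000 / 375,000 fish); recovered status is only
    feasible at 175,000 fish and above.  Price levels are configurable; the
    defaults span $25-$350/household/year.
    """

    price_levels: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.5, 3.5)
    fish_levels: tuple[float, ...] = (1.0, 1.75, 2.25, 3.75)
    allow_recovered_at: tuple[float, ...] = (1.75, 2.25, 3.75)
    tasks_per_respondent: int = 3
    n_versions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.price_levels or not self.fish_levels:
            raise DesignError("price_levels and fish_levels must be non-empty")
        if min(self.price_levels) <= 0:
            raise DesignError("program price levels must be positive")
        if self.tasks_per_respondent < 1 or self.n_versions < 1:
            raise DesignError("tasks_per_respondent and n_versions must be >= 1")


def _feasible_programs(config: DesignConfig) -> list[ScenarioAttributes]:
    """Enumerate the restricted grid of feasible program alternatives."""
    out = []
    allowed = set(config.allow_recovered_at)
    for price, fish, rec, quick, fishing in itertools.product(
        config.price_levels, config.fish_levels, (0, 1), (0, 1), (0, 1, 2)
    ):
        if rec and fish not in allowed:
            continue
        out.append(
            ScenarioAttributes(
                price=price,
                recovered=rec,
                returning_fish=fish,
                quick=quick,
                fishing1=1 if fishing == 1 else 0,
                fishing2=1 if fishing == 2 else 0,
            )
        )
    if not out:
        raise DesignError(
            "no feasible program alternatives: the recovered-status restriction "
            f"(recovered only at fish levels {sorted(allowed)}) excludes every "
            "combination of the configured levels"
        )
    return out


def generate_design(
    config: DesignConfig, optimize_steps: int = 0
) -> list[ChoiceTask]:
    """Draw a restricted-grid design of ``n_versions * tasks_per_respondent`` tasks.

    Each task pairs the status quo with two distinct programs sampled
    uniformly from the feasible grid.  With ``optimize_steps > 0`` the design
    is improved by greedy random swaps accepted whenever they lower the
    utility-neutral D-error (:func:`d0_error`).  Deterministic for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    programs = _feasible_programs(config)
    if len(programs) < 2:
        raise DesignError("feasible grid has fewer than 2 programs")

    def draw_task(tid: str) -> ChoiceTask:
        i, j = rng.choice(len(programs), size=2, replace=False)
        return ChoiceTask(tid, (STATUS_QUO, programs[i], programs[j]))

    tasks = [
        draw_task(f"v{v}_t{t}")
        for v in range(config.n_versions)
        for t in range(config.tasks_per_respondent)
    ]

    if optimize_steps > 0:
        current = d0_error(tasks)
        for _ in range(optimize_steps):
            k = int(rng.integers(len(tasks)))
            candidate = list(tasks)
            candidate[k] = draw_task(tasks[k].task_id)
            try:
                trial = d0_error(candidate)
            except np.linalg.LinAlgError:
                continue
            if trial < current:
                tasks, current = candidate, trial
    return tasks


# ---------------------------------------------------------------------------
# D-error

def _task_matrix(task) -> np.ndarray:
    """Attribute matrix of a task in the 9-column utility coding."""
    if isinstance(task, np.ndarray):
        return np.asarray(task, dtype=float)
    rows = []
    for a in task.alternatives:
        rows.append(
            [
                a.is_status_quo,
                a.price,
                a.recovered,
                a.returning_fish,
                a.quick,
                a.fishing1,
                a.fishing2,
                a.recovered * a.returning_fish,
                a.quick * a.returning_fish,
            ]
        )
    return np.asarray(rows, dtype=float)


def d0_error(
    design: Sequence, parameter_count: int | None = None
) -> float:
    """Utility-neutral D-error of a design.

    Computes the Fisher information of the conditional logit at zero
    coefficients (all alternatives equally likely) summed over tasks and
    returns ``det(I)**(-1/K)``; lower is better.  ``design`` may be a
    sequence of :class:`ChoiceTask` (coded with all 9 utility columns) or a
    sequence of per-task attribute matrices (alternatives x K).

    Raises
    ------
    numpy.linalg.LinAlgError
        If the information matrix is singular (e.g. an attribute with no
        contrast anywhere in the design); the message reports the rank.
    """
    mats = [_task_matrix(t) for t in design]
    k = mats[0].shape[1]
    if parameter_count is None:
        parameter_count = k
    info = np.zeros((k, k))
    for X in mats:
        p = np.full(X.shape[0], 1.0 / X.shape[0])
        xbar = p @ X
        Xc = X - xbar
        info += Xc.T @ (Xc * p[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        rank = np.linalg.matrix_rank(info)
        raise np.linalg.LinAlgError(
            f"singular information matrix (rank {rank} < {k}): some attribute "
            "has no contrast across alternatives; D-error is undefined/infinite"
        )
    return float(np.exp(-logdet / parameter_count))


# ---------------------------------------------------------------------------
# Returning-fish trajectories

@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the determinate-growth return trajectory.

    ``t_peak`` is the time of maximum growth rate (the sigmoid inflection)
    and ``t_end`` the time at which growth completes, both in years.
    """

    baseline: float = 150_000.0
    increase: float = 100_000.0
    horizon_years: float = 50.0
    t_peak: float = 25.0
    t_end: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.t_peak < self.t_end <= self.horizon_years):
            raise ValueError("require 0 < t_peak < t_end <= horizon_years")
        if self.baseline < 0 or self.increase < 0:
            raise ValueError("baseline and increase must be non-negative")


#: Illustrative presets sharing the 50-year endpoint.
QUICK_TRAJECTORY = TrajectoryParams(t_peak=8.0, t_end=20.0)
SLOW_TRAJECTORY = TrajectoryParams(t_peak=25.0, t_end=50.0)


def beta_growth_trajectory(params: TrajectoryParams, t) -> np.ndarray | float:
    """Returning-fish count at time ``t`` (years) under a beta sigmoid.

    Uses the determinate-growth form of Yin et al. (2003): with ``te``
    growth-completion time and ``tm`` inflection time, the completed
    fraction is ``(1 + (te - t)/(te - tm)) * (t/te)**(te/(te - tm))`` for
    ``t <= te`` and 1 afterwards.  The trajectory starts at ``baseline`` and
    plateaus at ``baseline + increase`` from ``t_end`` onwards.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > params.horizon_years):
        raise ValueError(
            f"t must lie in [0, {params.horizon_years}] years"
        )
    te, tm = params.t_end, params.t_peak
    tt = np.minimum(t_arr, te)
    with np.errstate(divide="ignore"):
        frac = (1.0 + (te - tt) / (te - tm)) * (tt / te) ** (te / (te - tm))
    frac = np.clip(frac, 0.0, 1.0)
    out = params.baseline + params.increase * frac
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Serialization

DESIGN_COLUMNS = [
    "version",
    "task_id",
    "alt_id",
    "is_status_quo",
    "price",
    "recovered",
    "returning_fish",
    "quick",
    "fishing1",
    "fishing2",
]


def design_to_frame(tasks: Iterable[ChoiceTask]) -> pd.DataFrame:
    rows = []
    for task in tasks:
        version = task.task_id.split("_")[0] if "_" in task.task_id else ""
        for alt_id, alt in enumerate(task.alternatives):
            rows.append(
                {"version": version, "task_id": task.task_id, "alt_id": alt_id}
                | alt.as_row()
            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def frame_to_design(frame: pd.DataFrame) -> list[ChoiceTask]:
    tasks = []
    for task_id, grp in frame.groupby("task_id", sort=False):
        grp = grp.sort_values("alt_id")
        alts = tuple(
            ScenarioAttributes(
                price=float(r.price),
                recovered=int(r.recovered),
                returning_fish=float(r.returning_fish),
                quick=int(r.quick),
                fishing1=int(r.fishing1),
                fishing2=int(r.fishing2),
                is_status_quo=int(r.is_status_quo),
            )
            for r in grp.itertuples()
        )
        tasks.append(ChoiceTask(str(task_id), alts))
    return tasks


def write_design(tasks: Iterable[ChoiceTask], path) -> None:
    design_to_frame(tasks).to_csv(path, index=False)


def read_design(path) -> list[ChoiceTask]:
    return frame_to_design(pd.read_csv(path))
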