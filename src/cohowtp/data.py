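"""Long-format choice-experiment dataset container and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChoiceDataset", "DATA_COLUMNS", "ChoiceDataError"]

DATA_COLUMNS = [
    "resp_id",
    "task_id",
    "alt_id",
    "is_status_quo",
    "price",
    "recovered",
    "returning_fish",
    "quick",
    "fishing1",
    "fishing2",
    "chosen",
]

_BINARY_COLS = ["is_status_quo", "recovered", "quick", "fishing1", "fishing2", "chosen"]


class ChoiceDataError(ValueError):
    """Raised when a choice dataset violates its structural invariants."""


@dataclass
class ChoiceDataset:
    """Panel of respondents x choice tasks x alternatives with observed choices.

    ``rows`` is a long-format frame with one row per alternative (columns
    :data:`DATA_COLUMNS`); ``respondents`` optionally carries one row per
    respondent with demographics and selection covariates.
    """

    rows: pd.DataFrame
    respondents: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.rows
        missing = [c for c in DATA_COLUMNS if c not in df.columns]
        if missing:
            raise ChoiceDataError(f"missing columns: {missing}")

        dup = df.duplicated(subset=["resp_id", "task_id", "alt_id"])
        if dup.any():
            row = df.index[dup][0]
            raise ChoiceDataError(
                f"duplicate (resp_id, task_id, alt_id) at row {row}: "
                f"{tuple(df.loc[row, ['resp_id', 'task_id', 'alt_id']])}"
            )

        for col in _BINARY_COLS:
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = df.index[bad][0]
                raise ChoiceDataError(
                    f"column '{col}' must be 0/1; offending row {row} has "
                    f"value {df.loc[row, col]!r}"
                )
        for col in ("price", "returning_fish"):
            bad = df[col] < 0
            if bad.any():
                row = df.index[bad][0]
                raise ChoiceDataError(
                    f"column '{col}' must be non-negative; offending row {row}"
                )
        both = (df["fishing1"] == 1) & (df["fishing2"] == 1)
        if both.any():
            row = df.index[both][0]
            raise ChoiceDataError(
                f"fishing1 and fishing2 both 1 at row {row} "
                f"(task {df.loc[row, 'task_id']!r})"
            )

        n_chosen = df.groupby(["resp_id", "task_id"], sort=False)["chosen"].sum()
        bad = n_chosen[n_chosen != 1]
        if len(bad):
            resp, task = bad.index[0]
            raise ChoiceDataError(
                f"task {task!r} of respondent {resp!r} has {int(bad.iloc[0])} "
                "chosen alternatives (expected exactly 1)"
            )
        n_alts = df.groupby(["resp_id", "task_id"], sort=False).size()
        if (n_alts < 2).any():
            resp, task = n_alts.index[n_alts < 2][0]
            raise ChoiceDataError(
                f"task {task!r} of respondent {resp!r} has fewer than 2 alternatives"
            )

    @property
    def n_respondents(self) -> int:
        return self.rows["resp_id"].nunique()

    @property
    def n_obs(self) -> int:
        """Number of usable choice tasks."""
        return len(self.rows.drop_duplicates(["resp_id", "task_id"]))

    def subset_respondents(self, resp_ids) -> "ChoiceDataset":
        keep = self.rows["resp_id"].isin(set(resp_ids))
        resp = None
        if self.respondents is not None:
            resp = self.respondents[
                self.respondents["resp_id"].isin(set(resp_ids))
            ].reset_index(drop=True)
        return ChoiceDataset(self.rows[keep].reset_index(drop=True), resp)
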