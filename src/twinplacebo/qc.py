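"""Trial- and participant-level exclusion rules.

Two rules, applied in a fixed order and fully logged:

1. Trials are dropped when the intensity-rating reaction time is above
   5.01 s (non-response: the rating window was five seconds) or below 0.02 s
   (too fast to be a deliberate rating).  The inequalities are strict: the
   boundary values themselves are retained.  A missing reaction time counts
   as a non-response.
2. After trial exclusion, a participant is retained only if, in each of the
   four modality x condition cells, they still have at least one trial at a
   minimum of two of the three stimulus levels.  ("Complete sets of
   conditions for more than one stimulus level.")

Both filters are idempotent; the trial rule always runs before the
participant rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import RT_HIGH, RT_LOW

__all__ = ["ExclusionLog", "exclude_trials_by_rt", "exclude_incomplete_participants", "run_qc"]

_CELLS = [(m, c) for m in ("thermal", "mechanical") for c in ("control", "placebo")]


@dataclass
class ExclusionLog:
    n_trials_in: int = 0
    n_trials_dropped_rt: int = 0
    n_trials_dropped_participants: int = 0
    participants_dropped: dict[str, str] = field(default_factory=dict)
    n_out: int = 0

    def check(self) -> None:
        assert self.n_trials_in == (
            self.n_out + self.n_trials_dropped_rt + self.n_trials_dropped_participants
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def lines(self) -> list[str]:
        frac = self.n_trials_dropped_rt / self.n_trials_in if self.n_trials_in else 0.0
        out = [
            f"trials in: {self.n_trials_in}",
            f"trials dropped by RT rule: {self.n_trials_dropped_rt} ({100 * frac:.2f}%)",
        ]
        for pid, reason in self.participants_dropped.items():
            out.append(f"participant {pid} dropped: {reason}")
        out.append(f"trials out: {self.n_out}")
        return out


def exclude_trials_by_rt(
    table: pd.DataFrame, rt_col: str = "rt_intensity"
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop trials with rating RT outside the open interval (0.02, 5.01) s."""
    if rt_col not in table.columns:
        raise KeyError(f"missing reaction-time column {rt_col!r}")
    log = ExclusionLog(n_trials_in=len(table))
    rt = table[rt_col]
    bad = (rt < RT_LOW) | (rt > RT_HIGH) | rt.isna()
    kept = table.loc[~bad].copy()
    log.n_trials_dropped_rt = int(bad.sum())
    log.n_out = len(kept)
    log.check()
    return kept, log


def _complete_enough(participant_trials: pd.DataFrame) -> bool:
    for modality, condition in _CELLS:
        cell = participant_trials[
            (participant_trials["modality"] == modality)
            & (participant_trials["condition"] == condition)
        ]
        if cell["stimulus_level"].nunique() < 2:
            return False
    return True


def exclude_incomplete_participants(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop participants lacking >= 2 stimulus levels in any factorial cell."""
    log = ExclusionLog(n_trials_in=len(table))
    keep_ids = []
    for pid, sub in table.groupby("participant_id", sort=False):
        if _complete_enough(sub):
            keep_ids.append(pid)
        else:
            log.participants_dropped[str(pid)] = (
                "fewer than two stimulus levels in at least one modality x condition cell"
            )
    kept = table[table["participant_id"].isin(keep_ids)].copy()
    log.n_trials_dropped_participants = len(table) - len(kept)
    log.n_out = len(kept)
    log.check()
    return kept, log


def run_qc(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply both rules in the fixed trial-then-participant order."""
    after_rt, log_rt = exclude_trials_by_rt(table)
    after_part, log_part = exclude_incomplete_participants(after_rt)
    log = ExclusionLog(
        n_trials_in=log_rt.n_trials_in,
        n_trials_dropped_rt=log_rt.n_trials_dropped_rt,
        n_trials_dropped_participants=log_part.n_trials_dropped_participants,
        participants_dropped=log_part.participants_dropped,
        n_out=log_part.n_out,
    )
    log.check()
    return after_part, log
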