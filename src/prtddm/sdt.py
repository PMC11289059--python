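"""Signal-detection indices of the PRT.

Response bias (log b) and discriminability (log d) are the standard
logarithmic PRT indices, computed from a rich/lean x correct/incorrect
contingency table with a 0.5 count correction added to every cell so both
indices stay finite:

    log b = 1/2 * log10[ (RC + .5)(LI + .5) / ((RI + .5)(LC + .5)) ]
    log d = 1/2 * log10[ (RC + .5)(LC + .5) / ((RI + .5)(LI + .5)) ]

Positive log b indicates a preference for the rich response.  The
reward-learning score is the block-3 minus block-1 difference in log b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "SDTIndices",
    "tabulate",
    "log_b",
    "log_d",
    "reward_learning",
    "indices_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Rich/lean x correct/incorrect counts for one participant-block."""

    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int

    def __post_init__(self) -> None:
        for name, c in self.__dict__.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"{name} must be a non-negative integer, got {c}")

    @property
    def total(self) -> int:
        return (self.rich_correct + self.rich_incorrect
                + self.lean_correct + self.lean_incorrect)

    def swapped(self) -> "ContingencyTable":
        """Relabel rich <-> lean."""
        return ContingencyTable(self.lean_correct, self.lean_incorrect,
                                self.rich_correct, self.rich_incorrect)


@dataclass(frozen=True)
class SDTIndices:
    participant_id: str
    block: int
    log_b: float
    log_d: float


def tabulate(trials: pd.DataFrame, participant, block: int) -> ContingencyTable:
    """Count one participant-block's filtered trials by stimulus x correctness."""
    sub = trials[(trials["participant_id"] == participant)
                 & (trials["block"] == block)]
    if "training" in sub.columns:
        sub = sub[~sub["training"].astype(bool)]
    if len(sub) == 0:
        raise ValueError(
            f"no valid trials for participant {participant!r}, block {block}"
        )
    rich = sub["stimulus"] == "rich"
    corr = sub["correct"].astype(bool)
    return ContingencyTable(
        rich_correct=int((rich & corr).sum()),
        rich_incorrect=int((rich & ~corr).sum()),
        lean_correct=int((~rich & corr).sum()),
        lean_incorrect=int((~rich & ~corr).sum()),
    )


def log_b(table: ContingencyTable) -> float:
    """Response bias; antisymmetric under rich/lean relabelling."""
    rc, ri = table.rich_correct + 0.5, table.rich_incorrect + 0.5
    lc, li = table.lean_correct + 0.5, table.lean_incorrect + 0.5
    return 0.5 * np.log10((rc * li) / (ri * lc))


def log_d(table: ContingencyTable) -> float:
    """Discriminability; symmetric under rich/lean relabelling."""
    rc, ri = table.rich_correct + 0.5, table.rich_incorrect + 0.5
    lc, li = table.lean_correct + 0.5, table.lean_incorrect + 0.5
    return 0.5 * np.log10((rc * lc) / (ri * li))


def reward_learning(logb_by_block: dict) -> float:
    """Block-3 minus block-1 response bias (the reward-learning score)."""
    for b in (1, 3):
        if b not in logb_by_block:
            raise ValueError(f"log b for block {b} missing")
    return float(logb_by_block[3] - logb_by_block[1])


def indices_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, block) log b / log d over a filtered trial table."""
    rows = []
    for (pid, block), _ in trials.groupby(["participant_id", "block"], sort=True):
        tab = tabulate(trials, pid, block)
        rows.append({"participant_id": pid, "block": int(block),
                     "group": trials.loc[trials["participant_id"] == pid, "group"].iloc[0]
                     if "group" in trials.columns else "all",
                     "log_b": log_b(tab), "log_d": log_d(tab)})
    return pd.DataFrame(rows)
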