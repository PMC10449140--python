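"""Group-level statistics: is the SNR significantly above the SNR-wall?

Every subject contributes one (SNR, SNR-wall) pair per task and filter
setup.  Both numbers are random variables across subjects, so
detectability at the group level is decided with a one-sided paired
t-test on the within-subject differences ``d_i = SNR_i - wall_i``
(H1: mean d > 0) at level alpha (default 0.05, uncorrected per cell; a
Holm-corrected verdict is reported alongside for transparency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FILTER_SETUPS

__all__ = ["SubjectPair", "GroupResult", "task_test", "detectability_table", "holm_correct"]


@dataclass
class SubjectPair:
    """One subject's SNR / SNR-wall pair for a task under a filter setup."""

    subject: str
    task: str
    filter_setup: str
    snr_db: float
    wall_db: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.snr_db) and math.isfinite(self.wall_db)):
            raise ValueError(
                "non-finite SNR or wall; exclude -inf walls before the group test"
            )


@dataclass
class GroupResult:
    task: str
    filter_setup: str
    n: int
    mean_snr_db: float
    sd_snr_db: float
    mean_wall_db: float
    sd_wall_db: float
    t_stat: float
    p_value: float
    significant: bool
    alpha: float
    paired: bool = True
    degenerate: bool = False  # zero-variance differences


def task_test(
    pairs: list[SubjectPair], alpha: float = 0.05, paired: bool = True
) -> GroupResult:
    """One-sided test of ``mean(SNR - wall) > 0`` for one task x filter cell.

    Pairs must all belong to the same cell and (for the paired default)
    to distinct subjects.  A zero-variance set of differences is
    degenerate: the verdict follows the sign of the common difference
    and the result is flagged.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two subjects for a t-test")
    tasks = {p.task for p in pairs}
    setups = {p.filter_setup for p in pairs}
    if len(tasks) != 1 or len(setups) != 1:
        raise ValueError(f"pairs mix cells: tasks={tasks}, setups={setups}")
    subjects = [p.subject for p in pairs]
    if paired and len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject in paired test")

    snr = np.array([p.snr_db for p in pairs])
    wall = np.array([p.wall_db for p in pairs])
    degenerate = False
    if paired:
        diff = snr - wall
        if np.ptp(diff) == 0.0:
            degenerate = True
            t_stat = math.inf if diff[0] > 0 else (-math.inf if diff[0] < 0 else 0.0)
            p_value = 0.0 if diff[0] > 0 else 1.0
        else:
            t_stat, p_value = stats.ttest_rel(snr, wall, alternative="greater")
    else:
        if np.ptp(snr) == 0.0 and np.ptp(wall) == 0.0:
            degenerate = True
            d = snr[0] - wall[0]
            t_stat = math.inf if d > 0 else (-math.inf if d < 0 else 0.0)
            p_value = 0.0 if d > 0 else 1.0
        else:
            t_stat, p_value = stats.ttest_ind(snr, wall, alternative="greater")

    return GroupResult(
        task=pairs[0].task,
        filter_setup=pairs[0].filter_setup,
        n=len(pairs),
        mean_snr_db=float(snr.mean()),
        sd_snr_db=float(snr.std(ddof=1)),
        mean_wall_db=float(wall.mean()),
        sd_wall_db=float(wall.std(ddof=1)),
        t_stat=float(t_stat),
        p_value=float(p_value),
        significant=bool(p_value < alpha),
        alpha=alpha,
        paired=paired,
        degenerate=degenerate,
    )


def holm_correct(results: list[GroupResult]) -> dict:
    """Holm step-down adjusted p-values keyed by (task, filter_setup)."""
    items = sorted(results, key=lambda r: r.p_value)
    m = len(items)
    adjusted, running = {}, 0.0
    for rank, r in enumerate(items):
        p_adj = min(1.0, (m - rank) * r.p_value)
        running = max(running, p_adj)
        adjusted[(r.task, r.filter_setup)] = running
    return adjusted

def detectability_table(results: list[GroupResult], star: str = "*") -> pd.DataFrame:
    """Task x filter star table of significant detectability.

    Rows are tasks (in first-seen order), columns the five filter
    setups; a cell holds ``*`` iff the group test for that cell was
    significant, else an empty string.
    """
    tasks = list(dict.fromkeys(r.task for r in results))
    setups = [s for s in FILTER_SETUPS if any(r.filter_setup == s for r in results)]
    table = pd.DataFrame("", index=tasks, columns=setups)
    for r in results:
        table.loc[r.task, r.filter_setup] = star if r.significant else ""
    table.index.name = "task"
    return table
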