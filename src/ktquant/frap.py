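"""FRAP normalization and percent-recovery quantification.

A kinetochore cluster bleached in metaphase is followed through anaphase;
its intensity trace, normalized to the prebleach frame, measures how much
new protein loads onto the bleached structure.  Percent recovery is
100 * (I_end - I_post) / (I_pre - I_post) with I_pre = 1 after
normalization, I_post the mean of the first frames after the bleach, and
I_end the mean of the final frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FrapCurve:
    """One photobleaching time course (mother and daughter clusters)."""

    times_min: np.ndarray
    mother: np.ndarray
    daughter: np.ndarray
    prebleach_index: int
    postbleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "mother", np.asarray(self.mother, dtype=float))
        object.__setattr__(self, "daughter", np.asarray(self.daughter, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.prebleach_index < self.postbleach_index < len(t):
            raise ValueError("need prebleach index < first post-bleach index")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FrapCurve":
        """Build a curve from a table with time_min/mother/daughter/event.

        The ``event`` column marks the first post-bleach frame with 1; the
        prebleach frame is the one immediately before it.
        """
        event = np.flatnonzero(frame["event"].to_numpy())
        if len(event) != 1:
            raise ValueError("expected exactly one bleach event marker")
        post = int(event[0])
        return cls(
            times_min=frame["time_min"].to_numpy(),
            mother=frame["mother"].to_numpy(),
            daughter=frame["daughter"].to_numpy(),
            prebleach_index=post - 1,
            postbleach_index=post,
        )

    def trace(self, which: str) -> np.ndarray:
        if which not in ("mother", "daughter"):
            raise ValueError("trace must be 'mother' or 'daughter'")
        return getattr(self, which)


def normalize_frap(curve: FrapCurve) -> FrapCurve:
    """Divide both traces by their prebleach value.

    After normalization the prebleach frame is exactly 1.0, making curves
    from cells of different absolute brightness comparable.
    """
    out = {}
    for which in ("mother", "daughter"):
        trace = curve.trace(which)
        pre = trace[curve.prebleach_index]
        if not pre > 0:
            raise ValueError(f"non-positive prebleach intensity in {which} trace")
        out[which] = trace / pre
    return replace(curve, mother=out["mother"], daughter=out["daughter"])


def percent_recovery(
    curve: FrapCurve,
    which: str = "mother",
    post_window: int = 1,
    end_window: int = 2,
    flag_range: tuple[float, float] = (0.0, 150.0),
) -> tuple[float, bool]:
    """Percent fluorescence recovery of one normalized trace.

    Returns ``(recovery_percent, flagged)`` where ``flagged`` marks values
    outside ``flag_range`` (left unclamped).  ``post_window`` frames after
    the bleach define the bleach floor and ``end_window`` final frames
    define the endpoint.  Raises if the bleach floor is not below the
    prebleach level (failed bleach).
    """
    norm = normalize_frap(curve)
    trace = norm.trace(which)
    post = float(np.mean(trace[norm.postbleach_index : norm.postbleach_index + post_window]))
    end = float(np.mean(trace[-end_window:]))
    i_pre = 1.0
    if post >= i_pre:
        raise ValueError("post-bleach intensity is not below prebleach; bleach failed")
    recovery = 100.0 * (end - post) / (i_pre - post)
    flagged = not (flag_range[0] <= recovery <= flag_range[1])
    return recovery, flagged


@dataclass(frozen=True)
class RecoverySummary:
    """Group statistics of percent recovery with a Welch t test."""

    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t_statistic: float
    p_value: float


def recovery_summary(
    curves_a: Sequence[FrapCurve],
    curves_b: Sequence[FrapCurve],
    names: tuple[str, str] = ("group_a", "group_b"),
    which: str = "mother",
    post_window: int = 1,
    end_window: int = 2,
) -> RecoverySummary:
    """Mean/SD of percent recovery per group and a two-tailed Welch t test."""
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("each group needs at least two curves")
    rec_a = np.array(
        [percent_recovery(c, which, post_window, end_window)[0] for c in curves_a]
    )
    rec_b = np.array(
        [percent_recovery(c, which, post_window, end_window)[0] for c in curves_b]
    )
    if rec_a.std(ddof=1) == 0 and rec_b.std(ddof=1) == 0:
        t_stat = 0.0
        p_val = 1.0 if rec_a.mean() == rec_b.mean() else 0.0
    else:
        t_stat, p_val = stats.ttest_ind(rec_a, rec_b, equal_var=False)
    return RecoverySummary(
        group_names=names,
        means=(float(rec_a.mean()), float(rec_b.mean())),
        sds=(float(rec_a.std(ddof=1)), float(rec_b.std(ddof=1))),
        ns=(len(rec_a), len(rec_b)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
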