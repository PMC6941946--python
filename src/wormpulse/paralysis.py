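"""Aldicarb paralysis-assay analysis.

Aldicarb is a cholinesterase inhibitor: acetylcholine accumulates at the
neuromuscular junction until the animal paralyzes, so faster paralysis
indicates stronger cholinergic synaptic transmission.  Populations
(e.g. optogenetically exercised vs sedentary) are scored every
``observation_interval`` minutes until no animal responds to touch; the
readouts are

* per-group fraction-moving step curves (with unweighted averaging over
  replicates), and
* a two-group logrank test on the per-worm paralysis times, with ties
  handled by the standard hypergeometric variance — mandatory here, since
  interval observation records many animals at the same 10-minute mark.

Censoring is supported in the data model but defaults to none, matching
the run-to-completion protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "ParalysisDataset",
    "SurvivalComparison",
    "StepCurve",
    "fraction_moving_curve",
    "average_replicates",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group logrank comparison."""

    chi_square: float
    df: int
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.chi_square < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid logrank result")

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


@dataclass
class ParalysisDataset:
    """Per-worm paralysis times (minutes) grouped by population label."""

    groups: dict[str, np.ndarray]
    censored: dict[str, np.ndarray] = field(default_factory=dict)
    observation_interval: float = 10.0

    def __post_init__(self) -> None:
        for name, times in self.groups.items():
            times = np.asarray(times, dtype=float)
            if times.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if np.any(times <= 0):
                raise ValueError(f"group {name!r} has non-positive times")
            self.groups[name] = times
            if name not in self.censored:
                self.censored[name] = np.zeros(times.size, dtype=bool)

    @classmethod
    def from_csv(cls, source, observation_interval: float = 10.0):
        """Read ``worm_id,group,paralysis_time_min[,censored]`` CSV."""
        df = pd.read_csv(source)
        groups: dict[str, np.ndarray] = {}
        censored: dict[str, np.ndarray] = {}
        for name, sub in df.groupby("group", sort=False):
            groups[str(name)] = sub["paralysis_time_min"].to_numpy(float)
            if "censored" in sub:
                censored[str(name)] = sub["censored"].to_numpy(bool)
        return cls(groups=groups, censored=censored,
                   observation_interval=observation_interval)

    def compare(self, group_a: str, group_b: str) -> SurvivalComparison:
        return logrank_test(
            self.groups[group_a],
            self.groups[group_b],
            self.censored.get(group_a),
            self.censored.get(group_b),
        )


@dataclass(frozen=True)
class StepCurve:
    """A right-continuous percent-moving step function on a time grid."""

    times: np.ndarray
    percent_moving: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "percent_moving": self.percent_moving}
        )


def fraction_moving_curve(
    times, interval: float, horizon: float | None = None
) -> StepCurve:
    """Percent of worms still moving at each observation time.

    At each multiple of ``interval`` up to ``horizon`` (default: the last
    paralysis time), the value is the percentage of worms whose paralysis
    time exceeds that time: the curve starts at 100, is non-increasing,
    and reaches 0 once every animal is paralyzed.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no paralysis times given")
    if np.any(times <= 0):
        raise ValueError("paralysis times must be positive")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if horizon is None:
        horizon = float(times.max())
    grid = np.arange(0.0, horizon + interval / 2, interval)
    pct = 100.0 * (times[None, :] > grid[:, None]).mean(axis=1)
    return StepCurve(times=grid, percent_moving=pct)


def average_replicates(curves) -> StepCurve:
    """Unweighted pointwise mean of replicate curves on a shared grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    grid = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(grid) or not np.allclose(c.times, grid):
            raise ValueError("replicate curves must share the same time grid")
    pct = np.mean([c.percent_moving for c in curves], axis=0)
    return StepCurve(times=grid.copy(), percent_moving=pct)


def logrank_test(
    times_a,
    times_b,
    censored_a=None,
    censored_b=None,
) -> SurvivalComparison:
    """Standard two-group logrank test on paralysis times.

    At each distinct event time the observed minus expected number of
    events in group A is accumulated under the hypergeometric model (with
    the standard tie correction); the statistic is chi-square distributed
    with 1 degree of freedom.  Two-sided p-value.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups need at least one animal")
    ea = np.ones(ta.size, bool) if censored_a is None else ~np.asarray(censored_a, bool)
    eb = np.ones(tb.size, bool) if censored_b is None else ~np.asarray(censored_b, bool)
    if not (ea.any() or eb.any()):
        raise ValueError("at least one observed event is required")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    if chi2 < 0:  # numeric guard; the statistic is a square
        chi2 = 0.0
    return SurvivalComparison(
        chi_square=chi2,
        df=1,
        p_value=float(res.p_value),
        n_a=int(ta.size),
        n_b=int(tb.size),
    )
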