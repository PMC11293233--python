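"""Kaplan–Meier estimation and log-rank testing across score classes.

Follow-up is administratively censored 55 days after ICU admission: any
time beyond the boundary is truncated to it with the event removed;
deaths occurring exactly at the boundary still count as events.  The
multi-group log-rank test (k-1 degrees of freedom) is applied first;
pairwise tests over all unordered pairs follow, Bonferroni-adjusted by
the number of pairs tested within the family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DEFAULT_CENSOR_DAYS = 55.0


@dataclass
class GroupSurvival:
    """Product-limit estimate for one group."""

    label: str
    durations: np.ndarray       # truncated follow-up times
    events: np.ndarray          # death indicator after truncation
    event_times: np.ndarray     # distinct event times
    at_risk: np.ndarray         # number at risk just before each event time
    n_events: np.ndarray        # deaths at each event time
    survival: np.ndarray        # S(t) just after each event time

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass
class SurvivalFit:
    groups: list[GroupSurvival]
    censor_at: float

    def group(self, label) -> GroupSurvival:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def _truncate(times, events, censor_at):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    # strictly-after-boundary times become censored at the boundary;
    # a death exactly at the boundary remains an event
    over = t > censor_at
    return np.where(over, censor_at, t), np.where(over, False, e)


def km_fit(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
    censor_at: float = DEFAULT_CENSOR_DAYS,
) -> SurvivalFit:
    """Kaplan–Meier product-limit estimator per group."""
    t, e = _truncate(times, events, censor_at)
    labels = np.asarray(groups)
    if labels.shape != t.shape:
        raise ValueError("groups must align with times")
    fits = []
    for label in sorted(set(labels.tolist())):
        mask = labels == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        table = kmf.event_table
        observed = table[table["observed"] > 0]
        fits.append(
            GroupSurvival(
                label=label,
                durations=t[mask],
                events=e[mask],
                event_times=observed.index.to_numpy(dtype=float),
                at_risk=observed["at_risk"].to_numpy(dtype=int),
                n_events=observed["observed"].to_numpy(dtype=int),
                survival=kmf.survival_function_at_times(
                    observed.index.to_numpy(dtype=float)
                ).to_numpy(dtype=float),
            )
        )
    return SurvivalFit(groups=fits, censor_at=censor_at)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    pairwise: Optional[dict] = None  # (label_a, label_b) -> Bonferroni-adjusted p


def logrank(fit: SurvivalFit, pairwise: bool = False) -> LogRankResult:
    """k-group log-rank test on a fitted survival object.

    With ``pairwise=True`` every unordered pair of groups is compared
    and each raw p-value is multiplied by the number of pairs (capped at
    1).  Ties at an event time use the standard discrete (hypergeometric
    variance) formulation.
    """
    if len(fit.groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    for g in fit.groups:
        if g.n == 0:
            raise ValueError(f"group {g.label!r} is empty")
    durations = np.concatenate([g.durations for g in fit.groups])
    events = np.concatenate([g.events for g in fit.groups])
    labels = np.concatenate([np.repeat(g.label, g.n) for g in fit.groups])
    overall = multivariate_logrank_test(durations, labels, events)
    result = LogRankResult(
        statistic=float(overall.test_statistic),
        df=len(fit.groups) - 1,
        p_value=float(overall.p_value),
    )
    if pairwise:
        pairs = list(combinations([g.label for g in fit.groups], 2))
        adjusted = {}
        for la, lb in pairs:
            ga, gb = fit.group(la), fit.group(lb)
            sub = multivariate_logrank_test(
                np.concatenate([ga.durations, gb.durations]),
                np.concatenate([np.repeat(la, ga.n), np.repeat(lb, gb.n)]),
                np.concatenate([ga.events, gb.events]),
            )
            adjusted[(la, lb)] = min(1.0, float(sub.p_value) * len(pairs))
        result.pairwise = adjusted
    return result
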