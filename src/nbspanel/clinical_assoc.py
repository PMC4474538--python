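"""Subtype-clinical association: Kaplan-Meier, log-rank, Fisher's exact.

Subtypes are clinically meaningful only if they separate outcomes.  We
test survival separation with the K-sample log-rank test (chi-square with
K - 1 degrees of freedom over observed-vs-expected events per risk set)
and association with categorical covariates such as tumor grade or stage
with Fisher's exact test — exact hypergeometric for 2x2 tables, a seeded
Monte-Carlo exact test for larger tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "KmCurve",
    "LogRankResult",
    "FisherResult",
    "km_estimate",
    "logrank_test",
    "fisher_association",
]


@dataclass
class KmCurve:
    """Product-limit survival estimate: step function over event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")

    def to_frame(self, group: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )
        if group is not None:
            df.insert(0, "group", group)
        return df


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class FisherResult:
    p_value: float
    method: str  # "exact" or "monte-carlo"
    n_simulations: int | None = None


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Returns the curve evaluated at the distinct observed times (events and
    censorings); all-censored data give a flat curve at 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("no observations")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and 0 not in times else kmf.event_table
    grid = np.asarray(table.index, float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = table["at_risk"].to_numpy()
    return KmCurve(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(times, events, groups) -> LogRankResult:
    """K-sample log-rank test of survival equality across groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if not (times.shape == events.shape == groups.shape):
        raise ValueError("times, events and groups must have equal length")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("every group must be non-empty")
    res = multivariate_logrank_test(times, groups, events)
    df = int(uniq.size - 1)
    return LogRankResult(
        statistic=float(res.test_statistic), df=df, p_value=float(res.p_value)
    )


def _table_log_prob(table: np.ndarray) -> float:
    """Log-probability of a contingency table under fixed margins
    (multivariate hypergeometric)."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def fisher_association(
    labels,
    categories,
    *,
    n_simulations: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Fisher's exact test of association between two categorical vectors.

    2x2 tables use the exact two-sided hypergeometric rule (sum of the
    probabilities of all tables no more likely than the observed one).
    Larger tables use a Monte-Carlo exact test: tables are drawn with the
    observed margins (Patefield's algorithm) and the p-value is the
    fraction with probability <= that of the observed table, with the
    +1/+1 continuity correction.
    """
    labels = np.asarray(labels)
    categories = np.asarray(categories)
    if labels.shape != categories.shape:
        raise ValueError("label and category vectors must have equal length")
    table = pd.crosstab(pd.Series(labels), pd.Series(categories)).to_numpy()
    if min(table.shape) < 2:
        raise ValueError("both variables need at least 2 levels for an association test")
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FisherResult(p_value=float(p), method="exact")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(size=n_simulations, random_state=rng)
    obs_lp = _table_log_prob(table)
    sim_lp = np.array([_table_log_prob(t) for t in draws])
    hits = int((sim_lp <= obs_lp + 1e-9).sum())
    p = (hits + 1) / (n_simulations + 1)
    return FisherResult(p_value=float(p), method="monte-carlo", n_simulations=n_simulations)
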