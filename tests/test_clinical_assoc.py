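"""Survival and contingency associations, checked against hand oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from nbspanel.clinical_assoc import (
    fisher_association,
    km_estimate,
    logrank_test,
)
from nbspanel.config import AnalysisConfig
from nbspanel.data_io import filter_samples
from nbspanel.model import NetworkStratification
from nbspanel.synthetic_data import gen_clinical, gen_cohort, gen_network


# ---------------------------------------------------------------- oracles


def logrank_oracle(times, events, groups):
    """Hand tabulation of the K-sample log-rank chi-square: risk sets at
    each distinct event time, observed minus expected per group, full
    hypergeometric covariance, quadratic form over the first K-1 groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    G = len(labels)
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = ((times == t) & (events == 1)).sum()
        n_gt = np.array([(at_risk & (groups == g)).sum() for g in labels])
        d_gt = np.array([((times == t) & (events == 1) & (groups == g)).sum() for g in labels])
        O += d_gt
        E += d_t * n_gt / n_t
        if n_t > 1:
            frac = n_gt / n_t
            V += (
                d_t * (n_t - d_t) / (n_t - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    z = (O - E)[:-1]
    return float(z @ np.linalg.solve(V[:-1, :-1], z))


def fisher_2x2_oracle(table):
    """Exact rational enumeration of all 2x2 tables with the observed
    margins; two-sided p sums the probabilities no larger than the
    observed one (with the customary 1+1e-7 tie guard)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs * Fraction(10_000_001, 10_000_000):
            total += prob(x)
    return float(total)


# ------------------------------------------------------------------ tests


class TestKmEstimate:
    def test_two_events_product_limit_by_hand(self):
        curve = km_estimate([1.0, 2.0], [1, 1])
        assert curve.survival == pytest.approx([0.5, 0.0])
        assert curve.at_risk.tolist() == [2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert curve.survival == pytest.approx([1.0, 1.0, 1.0])

    def test_single_event_drops_to_zero(self):
        curve = km_estimate([5.0], [1])
        assert curve.survival == pytest.approx([0.0])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a"] * 3 + ["b"] * 3
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_statistic_matches_hand_tabulation(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(logrank_oracle(times, events, groups), rel=1e-9)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_multigroup_statistic_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        times = rng.exponential(10, n).round(2)
        events = rng.integers(0, 2, n)
        groups = rng.integers(0, 3, n)
        events[:3] = 1  # keep at least a few events
        res = logrank_test(times, events, groups)
        assert res.df == 2
        assert res.statistic == pytest.approx(logrank_oracle(times, events, groups), rel=1e-6)

    def test_invariant_to_relabeling_and_time_shift(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 40)
        events = rng.integers(0, 2, 40)
        groups = rng.integers(0, 2, 40)
        base = logrank_test(times, events, groups)
        relabeled = logrank_test(times, events, np.where(groups == 0, "z", "y"))
        shifted = logrank_test(times + 100.0, events, groups)
        assert relabeled.statistic == pytest.approx(base.statistic)
        assert shifted.statistic == pytest.approx(base.statistic)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestFisher:
    def test_2x2_matches_enumeration_oracle(self):
        labels = np.repeat([0, 1], [10, 14])
        cats = np.concatenate([np.repeat(["x", "y"], [1, 9]), np.repeat(["x", "y"], [11, 3])])
        res = fisher_association(labels, cats)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(fisher_2x2_oracle([[1, 9], [11, 3]]), abs=1e-12)

    def test_balanced_independent_table_gives_one(self):
        labels = np.repeat([0, 1], 10)
        cats = np.tile(np.repeat(["x", "y"], 5), 2)
        assert fisher_association(labels, cats).p_value == pytest.approx(1.0)

    def test_concordant_diagonal_table_is_significant(self):
        labels = np.repeat([0, 1], 20)
        cats = np.repeat(["x", "y"], 20)
        res = fisher_association(labels, cats)
        assert res.p_value < 0.001
        assert res.p_value == pytest.approx(fisher_2x2_oracle([[20, 0], [0, 20]]), abs=1e-12)

    def test_larger_tables_use_seeded_monte_carlo(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 90)
        cats = rng.integers(0, 3, 90)
        res = fisher_association(labels, cats, n_simulations=20_000, seed=5)
        assert res.method == "monte-carlo" and res.n_simulations == 20_000
        again = fisher_association(labels, cats, n_simulations=20_000, seed=5)
        assert res.p_value == again.p_value
        # under independence the p-value should not be extreme
        assert res.p_value > 0.001

    def test_single_level_variable_raises(self):
        with pytest.raises(ValueError):
            fisher_association([0, 0, 0], ["x", "y", "x"])


def test_pipeline_subtypes_detect_survival_differences():
    """Subtype hazard ratios {1, 2, 4} at n=150: the fitted labels yield
    log-rank p < 0.05 in at least 80% of 20 master seeds."""
    hits = 0
    for seed in range(20):
        net, truth = gen_network(150, 3, seed=40 + seed)
        cohort, truth = gen_cohort(net, truth, 150, 3, seed=60 + seed)
        clinical, truth = gen_clinical(
            truth, cohort.samples, hazard_ratios={0: 1.0, 1: 2.0, 2: 4.0}, seed=80 + seed
        )
        filtered = filter_samples(cohort, "full")
        model = NetworkStratification(
            filtered, net, clinical=clinical, config=AnalysisConfig(n_reps=30, K_list=[3])
        )
        res = model.fit(3, seed=seed)
        hits += res.logrank().p_value < 0.05
    assert hits >= 16
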