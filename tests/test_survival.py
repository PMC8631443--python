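import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nkdeconv import (
    SimulationCondition,
    apply_censoring,
    bh_adjust,
    cox_association,
    group_abundance_compare,
    km_estimate,
    logit_transform,
    logrank_test,
    median_split_strata,
    simulate_run,
    stratified_survival,
)


class TestLogit:
    def test_midpoint_and_clipping(self):
        assert logit_transform(0.5) == pytest.approx(0.0)
        assert np.isfinite(logit_transform(0.0))
        assert logit_transform(0.0) == pytest.approx(np.log(1e-6 / (1 - 1e-6)))

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None)
    def test_antisymmetry(self, p):
        assert logit_transform(p) == pytest.approx(-logit_transform(1 - p), abs=1e-9)


class TestCox:
    def test_power_under_strong_signal_with_truth_proportions(
        self, compendium, survival_pool
    ):
        """Slope 1, truth proportions fed directly: focal p < 0.05 nearly always."""
        cond = SimulationCondition(n_replicates=500, slope=1.0, foreign_prop=0.0)
        leaves = list(dict.fromkeys(compendium.cell_types))
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            ms = simulate_run(cond, compendium, survival_pool, "nk_il2", seed=100 + s)
            cen = apply_censoring(ms, 0.5, seed=200 + s)
            props = pd.DataFrame(cen.proportions[:, : len(leaves)], columns=leaves)
            res = cox_association(props, cen.pfs_time, cen.event)
            hits += res.significant("nk_il2")
        assert hits >= n_rep - 2

    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(61)
        n = 200
        props = pd.DataFrame({"a": np.clip(rng.uniform(0.2, 0.8, n), 0, 1)})
        times = rng.exponential(500, n) + 1
        events = rng.integers(0, 2, n)
        events[0] = 1
        res = cox_association(props, times, events)
        assert abs(res.table.loc["a", "coef"]) < 0.5
        assert not res.significant("a")

    def test_input_validation(self):
        props = pd.DataFrame({"a": np.linspace(0.1, 0.9, 20)})
        with pytest.raises(ValueError):
            cox_association(props.iloc[:5], np.ones(5), np.ones(5, dtype=int))
        with pytest.raises(ValueError):
            cox_association(props, np.ones(20), np.zeros(20, dtype=int))

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(62)
        n = 50
        props = pd.DataFrame(
            {"varies": rng.uniform(0.1, 0.9, n), "flat": np.full(n, 0.25)}
        )
        res = cox_association(props, rng.exponential(300, n) + 1, np.ones(n, dtype=int))
        assert res.dropped == ["flat"]
        assert "flat" not in res.table.index


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert [km(t) for t in (0.5, 1.0, 2.0, 3.0)] == pytest.approx(
            [1.0, 2 / 3, 1 / 3, 0.0]
        )

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km(10.0) == 1.0 and km(0.0) == 1.0

    def test_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(63)
        times = rng.exponential(100, 80) + 1
        events = rng.integers(0, 2, 80)
        km = km_estimate(times, events)
        assert km(0.0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(64)
        times = rng.exponential(100, 60) + 1
        km = km_estimate(times, np.ones(60, dtype=int))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(65)
        times = rng.exponential(100, 100) + 1
        events = rng.integers(0, 2, 100)
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert km(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _brute_force_logrank_2group(times, groups, events):
    """Mantel-Cox O-E chi-square computed directly from the risk tables."""
    times = np.asarray(times, float)
    groups = np.asarray(groups)
    events = np.asarray(events, int)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_are_null(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        stat, p = logrank_test(groups, times, [1] * 6)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_on_toy_data(self):
        times = [1.0, 2.0, 3.0, 4.0]
        groups = ["a", "a", "b", "b"]
        events = [1, 1, 1, 1]
        stat, p = logrank_test(groups, times, events)
        expected = _brute_force_logrank_2group(times, groups, events)
        assert stat == pytest.approx(expected, rel=1e-9)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(expected, 1), rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(66)
        times = rng.exponential(100, 40) + 1
        events = rng.integers(0, 2, 40)
        groups = np.array(["a", "b"] * 20)
        swapped = np.where(groups == "a", "b", "a")
        assert logrank_test(groups, times, events)[0] == pytest.approx(
            logrank_test(swapped, times, events)[0]
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestBH:
    def test_stepup_on_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(deadline=None)
    def test_never_decreases_and_capped(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestMedianSplit:
    def test_two_group_with_ties_to_low(self):
        assert list(median_split_strata([1, 2, 3, 4])) == ["L", "L", "H", "H"]
        assert list(median_split_strata([1, 2, 2, 4])) == ["L", "L", "L", "H"]

    def test_four_group_cross(self):
        labels = median_split_strata([1, 1, 4, 4], [1, 4, 1, 4], mode="four_group")
        assert list(labels) == ["L/L", "L/H", "H/L", "H/H"]

    def test_hh_vs_rest_collapse(self):
        labels = median_split_strata([1, 1, 4, 4], [1, 4, 1, 4], mode="hh_vs_rest")
        assert list(labels) == ["rest", "rest", "rest", "HH"]
        assert (labels == "HH").sum() == 1

    def test_degenerate_and_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            median_split_strata([2, 2, 2])
        with pytest.raises(ValueError):
            median_split_strata([1, 2, 3], mode="four_group")


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        values = [1.0, 2.0, 3.0, 4.0] * 2
        labels = ["a"] * 4 + ["b"] * 4
        _, p = group_abundance_compare(values, labels)
        assert p > 0.9

    def test_separated_groups_highly_significant(self):
        values = np.r_[np.arange(20), np.arange(100, 120)]
        labels = ["lo"] * 20 + ["hi"] * 20
        _, p = group_abundance_compare(values, labels)
        assert p < 0.001

    def test_rank_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(67)
        values = rng.uniform(1, 10, 30)
        labels = np.array(["a", "b"] * 15)
        s1, p1 = group_abundance_compare(values, labels)
        s2, p2 = group_abundance_compare(np.log(values), labels)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_signed_rank_variant_requires_pairing(self):
        x = np.arange(10, dtype=float)
        labels = ["a"] * 10 + ["b"] * 10
        stat, p = group_abundance_compare(np.r_[x, x + 0.5], labels, test="signed_rank")
        assert p < 0.05
        with pytest.raises(ValueError):
            group_abundance_compare(np.r_[x, x[:5]], ["a"] * 10 + ["b"] * 5, test="signed_rank")


def test_stratified_survival_end_to_end():
    rng = np.random.default_rng(68)
    n = 120
    risk = rng.uniform(0.1, 0.9, n)
    times = rng.exponential(200, n) * (1 + 2 * (risk < np.median(risk))) + 1
    events = np.ones(n, dtype=int)
    strata = stratified_survival(risk, times, events)
    assert set(strata.labels) == {"L", "H"}
    assert set(strata.curves) == {"L", "H"}
    assert strata.p_value < 0.05
    for curve in strata.curves.values():
        assert curve(0.0) == 1.0
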