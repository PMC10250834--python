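"""Narrow-funnel statistic, criteria grid search and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from funnelscan.funnel import (
    FunnelCriteria,
    NarrowFunnelScreen,
    classify_funnel,
    compare_groups,
    criteria_grid_search,
    narrow_funnel_fraction,
    reduce_max_per_fraction,
    significance_stars,
    summarize,
)

from conftest import metrics_from_values


@pytest.fixture()
def hand_table():
    # 10 decoys; exactly 3 satisfy energy <= -5 and irms <= 10.
    energies = [-20, -8, -6, -4, -1, 0, 1, 2, 3, 4]
    irms = [1, 4, 9, 2, 3, 30, 20, 25, 28, 15]
    return metrics_from_values(energies, irms)


class TestNarrowFunnelFraction:
    def test_hand_count(self, hand_table):
        assert narrow_funnel_fraction(hand_table, -5.0, 10.0) == pytest.approx(30.0)

    def test_thresholds_at_extremes_include_everything(self, hand_table):
        df = hand_table.df
        frac = narrow_funnel_fraction(
            hand_table, df.energy_kcal_mol.max(), df.irms_A.max()
        )
        assert frac == pytest.approx(100.0)

    def test_inclusive_boundaries(self):
        table = metrics_from_values([-5.0, -4.9], [10.0, 10.1])
        assert narrow_funnel_fraction(table, -5.0, 10.0) == pytest.approx(50.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_both_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        table = metrics_from_values(
            rng.normal(-5, 5, size=30), rng.uniform(0, 30, size=30)
        )
        e_grid = np.sort(rng.uniform(-15, 5, size=5))
        r_grid = np.sort(rng.uniform(0, 30, size=5))
        last_by_r = {}
        for e in e_grid:
            prev = -1.0
            for r in r_grid:
                frac = narrow_funnel_fraction(table, e, r)
                assert frac >= prev  # monotone in irms_max
                assert frac >= last_by_r.get(r, -1.0)  # monotone in e_max
                prev = frac
                last_by_r[r] = frac


class TestClassifyFunnel:
    def test_fraction_above_criterion(self, hand_table):
        verdict = classify_funnel(hand_table, FunnelCriteria(-5.0, 10.0, 2.0))
        assert verdict.fraction == pytest.approx(30.0)
        assert verdict.is_narrow_funnel

    def test_boundary_is_inclusive(self):
        table = metrics_from_values([-10, 0], [1, 20])  # fraction 50%
        assert classify_funnel(table, FunnelCriteria(-5, 10, 50.0)).is_narrow_funnel

    def test_zero_fraction_is_never_narrow(self):
        table = metrics_from_values([5, 6], [20, 25])
        verdict = classify_funnel(table, FunnelCriteria(-5, 10, 0.1))
        assert verdict.fraction == 0.0
        assert not verdict.is_narrow_funnel

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            FunnelCriteria(-5, -1.0, 2.0)
        with pytest.raises(ValueError):
            FunnelCriteria(-5, 10.0, 0.0)


def brute_force_rates(tables, e_grid, r_grid, f_grid):
    """Independent nested-loop computation of narrow-funnel pass rates."""
    out = np.zeros((len(f_grid), len(e_grid), len(r_grid)))
    for fi, f in enumerate(f_grid):
        for ei, e in enumerate(e_grid):
            for ri, r in enumerate(r_grid):
                passed = 0
                for t in tables:
                    df = t.df
                    inside = (df.energy_kcal_mol <= e) & (df.irms_A <= r)
                    frac = 100.0 * inside.sum() / len(df)
                    passed += frac >= f
                out[fi, ei, ri] = 100.0 * passed / len(tables)
    return out


class TestCriteriaGridSearch:
    def test_identical_groups_give_zero_difference(self, hand_table):
        tables = [hand_table] * 5
        grid = criteria_grid_search(tables, tables)
        assert np.allclose(grid.diff, 0.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(17)
        pos = [
            metrics_from_values(rng.normal(-8, 4, 40), rng.uniform(0, 15, 40))
            for _ in range(6)
        ]
        neg = [
            metrics_from_values(rng.normal(0, 3, 40), rng.uniform(5, 30, 40))
            for _ in range(6)
        ]
        e_grid = np.linspace(-12, 0, 5)
        r_grid = np.array([5.0, 10.0, 20.0])
        f_grid = np.array([1.0, 5.0, 10.0])
        grid = criteria_grid_search(pos, neg, e_grid, r_grid, f_grid)
        assert np.allclose(grid.tp_rate, brute_force_rates(pos, e_grid, r_grid, f_grid))
        assert np.allclose(grid.fp_rate, brute_force_rates(neg, e_grid, r_grid, f_grid))
        criteria, best = grid.best
        assert best == pytest.approx(grid.diff.max())
        assert np.all(grid.diff <= best)
        assert -100.0 <= grid.diff.min() and grid.diff.max() <= 100.0

    def test_counting_example(self):
        # At (-5, 10, 50%): 8 of 10 positives pass, 1 of 10 negatives.
        pos = [metrics_from_values([-9, -8], [2, 3])] * 8 + [
            metrics_from_values([0, 1], [20, 25])
        ] * 2
        neg = [metrics_from_values([-9, -8], [2, 3])] * 1 + [
            metrics_from_values([0, 1], [20, 25])
        ] * 9
        grid = criteria_grid_search(
            pos, neg, np.array([-5.0]), np.array([10.0]), np.array([50.0])
        )
        assert grid.diff[0, 0, 0] == pytest.approx(70.0)

    def test_empty_axis_rejected(self, hand_table):
        with pytest.raises(ValueError):
            criteria_grid_search([hand_table], [hand_table], np.array([]), None)


class TestReduceMaxPerFraction:
    def test_row_max_matches_brute_force(self):
        rng = np.random.default_rng(23)
        pos = [metrics_from_values(rng.normal(-6, 4, 30), rng.uniform(0, 20, 30))
               for _ in range(5)]
        neg = [metrics_from_values(rng.normal(-1, 4, 30), rng.uniform(0, 30, 30))
               for _ in range(5)]
        grid = criteria_grid_search(pos, neg)
        reduced = reduce_max_per_fraction(grid)
        for k, frac in enumerate(grid.fraction_grid):
            assert reduced.iloc[k].max_diff_percent == pytest.approx(grid.diff[k].max())
        # the global best appears in its fraction row
        criteria, best = grid.best
        row = reduced[reduced.fraction_min_percent == criteria.fraction_min]
        assert row.max_diff_percent.iloc[0] == pytest.approx(best)

    def test_all_zero_grid_reduces_to_zero(self, hand_table):
        grid = criteria_grid_search([hand_table], [hand_table])
        assert (reduce_max_per_fraction(grid).max_diff_percent == 0).all()


class TestSummarize:
    def test_mean_and_median(self):
        table = metrics_from_values([-1, -2, -3], [0.0, 10.0, 20.0])
        s = summarize(table)
        assert s.mean["irms"] == pytest.approx(10.0)
        assert s.median["irms"] == pytest.approx(10.0)
        assert s.mean["energy"] == pytest.approx(-2.0)
        assert s.n_decoys == 3

    def test_single_decoy(self):
        s = summarize(metrics_from_values([-4.5], [7.25]))
        assert s.mean["irms"] == s.median["irms"] == pytest.approx(7.25)


class TestCompareGroups:
    def _summaries(self, values):
        return [summarize(metrics_from_values([v], [v])) for v in values]

    def test_identical_groups(self):
        a = self._summaries([1.0, 2.0, 3.0])
        result = compare_groups(a, a, "irms")
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert result.stars == ""

    def test_matches_pooled_variance_formula(self):
        a = self._summaries([1.0, 2.0, 3.0])
        b = self._summaries([4.0, 5.0, 6.0])
        result = compare_groups(a, b, "irms")
        # textbook pooled-variance computation by hand:
        # means 2 and 5, each sample variance 1, pooled s^2 = 1,
        # t = (2-5) / sqrt(1 * (1/3 + 1/3)) = -3 / sqrt(2/3)
        expected_t = -3.0 / np.sqrt(2.0 / 3.0)
        assert result.t_statistic == pytest.approx(expected_t, abs=1e-12)
        assert result.p_value == pytest.approx(
            2 * stats.t.sf(abs(expected_t), df=4), abs=1e-12
        )
        assert result.stars == "*"

    def test_symmetry_up_to_sign(self):
        a = self._summaries([1.0, 2.0, 3.5])
        b = self._summaries([4.0, 5.5, 6.0])
        r1 = compare_groups(a, b, "irms")
        r2 = compare_groups(b, a, "irms")
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_planted_three_sigma_shift_is_detected(self):
        rng = np.random.default_rng(5)
        a = self._summaries(rng.normal(0.0, 1.0, size=20))
        b = self._summaries(rng.normal(3.0, 1.0, size=20))
        assert compare_groups(a, b, "irms").p_value < 0.05

    def test_small_groups_rejected(self):
        a = self._summaries([1.0])
        with pytest.raises(ValueError):
            compare_groups(a, a, "irms")

    @pytest.mark.parametrize(
        "p, expected",
        [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0004, "***")],
    )
    def test_star_convention(self, p, expected):
        assert significance_stars(p) == expected


class TestNarrowFunnelScreen:
    def _data(self):
        rng = np.random.default_rng(31)
        pos = [metrics_from_values(
            np.concatenate([rng.normal(-15, 2, 8), rng.normal(0, 2, 32)]),
            np.concatenate([rng.uniform(0, 3, 8), rng.uniform(5, 30, 32)]))
            for _ in range(8)]
        neg = [metrics_from_values(rng.normal(0, 2, 40), rng.uniform(5, 30, 40))
               for _ in range(8)]
        return pos + neg, ["positive"] * 8 + ["negative"] * 8

    def test_fit_predict_recovers_labels(self):
        X, y = self._data()
        screen = NarrowFunnelScreen().fit(X, y)
        assert screen.best_diff_ > 0
        assert (screen.predict(X) == np.array(y)).mean() >= 0.9

    def test_sklearn_clone_and_params_round_trip(self):
        screen = NarrowFunnelScreen(fraction_grid=(1.0, 2.0))
        cloned = clone(screen)
        assert cloned.get_params()["fraction_grid"] == (1.0, 2.0)
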