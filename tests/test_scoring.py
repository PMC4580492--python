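"""Quartile scoring engine: breakpoint oracles, mapping rules, totals, screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import catchvuln as cv
from catchvuln.registry import (
    EXPOSURE,
    LOWER_IS_WORSE,
    SENSITIVITY,
    UNDEFINED_WHEN_ABSENT,
    ZERO_SCORES_ZERO,
    VariableSpec,
    default_registry,
    variable_names,
)
from catchvuln.scoring import Breakpoints


def oracle_quartiles(values):
    """Independent sorted-linear-interpolation percentile oracle."""
    v = sorted(values)
    n = len(v)

    def pct(q):
        h = (n - 1) * q
        lo = math.floor(h)
        frac = h - lo
        return v[lo] if lo + 1 >= n else v[lo] + frac * (v[lo + 1] - v[lo])

    return pct(0.25), pct(0.50), pct(0.75)


def oracle_score(value, q25, q50, q75):
    """Brute-force bin assignment for higher_is_worse / zero-scores-zero."""
    if value == 0:
        return 0
    return 1 + sum(value > e for e in (q25, q50, q75))


class TestBreakpoints:
    def test_frozen_interpolation_values(self):
        bp = cv.compute_breakpoints(range(1, 9))
        assert (bp.q25, bp.q50, bp.q75) == (2.75, 4.5, 6.25)

    def test_zeros_stay_in_pool(self):
        bp = cv.compute_breakpoints([0, 0, 0, 0, 4, 8, 12, 16])
        assert bp.q50 == 2.0

    def test_constant_pool(self):
        bp = cv.compute_breakpoints([3.0] * 10)
        assert bp.q25 == bp.q50 == bp.q75 == 3.0

    def test_absent_dropped_only_under_undefined_rule(self):
        vals = [np.nan, 1, 2, 3, 4, np.nan]
        bp = cv.compute_breakpoints(vals, UNDEFINED_WHEN_ABSENT)
        assert (bp.q25, bp.q50, bp.q75) == (1.75, 2.5, 3.25)
        with pytest.raises(ValueError):
            cv.compute_breakpoints(vals, ZERO_SCORES_ZERO)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cv.compute_breakpoints([1, 2, 3])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=50))
    def test_matches_oracle(self, values):
        bp = cv.compute_breakpoints(values)
        o25, o50, o75 = oracle_quartiles(values)
        assert bp.q25 == pytest.approx(o25)
        assert bp.q50 == pytest.approx(o50)
        assert bp.q75 == pytest.approx(o75)


class TestScoreVariable:
    spec_up = VariableSpec("x", SENSITIVITY)
    spec_down = VariableSpec("x", SENSITIVITY, direction=LOWER_IS_WORSE)
    breaks = Breakpoints(2.0, 4.0, 6.0)

    def test_zero_scores_zero(self):
        assert cv.score_variable([0.0], self.spec_up, self.breaks)[0] == 0

    def test_top_bin(self):
        assert cv.score_variable([6.01], self.spec_up, self.breaks)[0] == 4

    def test_edges_upper_inclusive(self):
        scores = cv.score_variable([2.0, 4.0, 6.0], self.spec_up, self.breaks)
        assert scores.tolist() == [1, 2, 3]

    def test_inverted_minimum_scores_four(self):
        # lowest precipitation is most sensitive
        scores = cv.score_variable([0.5, 2.0, 5.0, 7.0], self.spec_down, self.breaks)
        assert scores.tolist() == [4, 4, 2, 1]

    def test_absent_scores_zero_under_undefined_rule(self):
        spec = VariableSpec("x", EXPOSURE, direction=LOWER_IS_WORSE,
                            zero_rule=UNDEFINED_WHEN_ABSENT)
        scores = cv.score_variable([np.nan, 1.0, 7.0], spec, self.breaks)
        assert scores.tolist() == [0, 4, 1]

    def test_absent_rejected_under_zero_rule(self):
        with pytest.raises(ValueError):
            cv.score_variable([np.nan], self.spec_up, self.breaks)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv.score_variable([-1.0], self.spec_up, self.breaks)

    def test_fixed_breakpoints(self):
        spec = default_registry()["pct_impervious"]  # edges 0, 1, 5, 10
        scores = cv.score_variable([0.0, 0.5, 1.0, 3.0, 5.0, 9.0, 10.0, 50.0], spec)
        assert scores.tolist() == [0, 1, 1, 2, 2, 3, 3, 4]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=50))
    def test_quartile_bins_match_bruteforce(self, pool):
        bp = cv.compute_breakpoints(pool)
        scores = cv.score_variable(pool, self.spec_up, bp)
        expected = [oracle_score(v, bp.q25, bp.q50, bp.q75) for v in pool]
        assert scores.tolist() == expected

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e4, allow_nan=False), min_size=4, max_size=40))
    def test_rank_invariance_under_monotone_transform(self, pool):
        """Quartile scores depend only on order and zeros: applying a strictly
        increasing zero-preserving transform leaves every score unchanged."""
        # rank transform: exact, strictly increasing, maps 0 to 0 and keeps
        # positives positive
        position = {v: i for i, v in enumerate(sorted(set(pool)))}
        transformed = [0.0 if v == 0 else float(position[v] + 1) for v in pool]
        s1 = cv.score_variable(pool, self.spec_up, cv.compute_breakpoints(pool))
        s2 = cv.score_variable(transformed, self.spec_up,
                               cv.compute_breakpoints(transformed))
        assert s1.tolist() == s2.tolist()

    def test_monotonicity_in_value(self):
        pool = np.linspace(0, 10, 30)
        bp = cv.compute_breakpoints(pool)
        scores = cv.score_variable(pool, self.spec_up, bp)
        assert (np.diff(scores) >= 0).all()


class TestTotals:
    def test_all_zero(self):
        reg = default_registry()
        frame = pd.DataFrame({"huc12_id": ["a"], "play": ["P"],
                              **{n: [0] for n in reg}})
        out = cv.total_scores(frame)
        assert out.loc[0, ["S", "E", "V"]].tolist() == [0, 0, 0]

    def test_maxima(self):
        reg = default_registry()
        frame = pd.DataFrame({"huc12_id": ["a"], "play": ["P"],
                              **{n: [4] for n in reg}})
        out = cv.total_scores(frame)
        assert out.loc[0, ["S", "E", "V"]].tolist() == [28, 40, 1120]

    def test_random_table_matches_bruteforce(self):
        reg = default_registry()
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({"huc12_id": [str(i) for i in range(20)],
                              "play": "P",
                              **{n: rng.integers(0, 5, 20) for n in reg}})
        out = cv.total_scores(frame)
        sens = variable_names(reg, SENSITIVITY)
        expo = variable_names(reg, EXPOSURE)
        for _, row in out.iterrows():
            s = sum(row[v] for v in sens)
            e = sum(row[v] for v in expo)
            assert (row["S"], row["E"], row["V"]) == (s, e, s * e)

    def test_missing_column_raises(self, score_table):
        with pytest.raises(ValueError):
            cv.total_scores(score_table.drop(columns=["dam_density"]))


class TestScoreTable:
    def test_bounds_and_identity(self, score_table):
        reg = default_registry()
        for name in reg:
            assert score_table[name].between(0, 4).all()
        assert score_table["S"].between(0, 28).all()
        assert score_table["E"].between(0, 40).all()
        assert (score_table["V"] == score_table["S"] * score_table["E"]).all()

    def test_well_free_catchments_score_zero_proximity(self, catchment_table, score_table):
        no_wells = catchment_table["vertical_well_density"] == 0
        assert (score_table.loc[no_wells.to_numpy(), "vertical_well_proximity"] == 0).all()


class TestScreening:
    def test_monotone_transform_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 100)
        table = pd.DataFrame({"road_density": x, "mine_density": np.sqrt(x)})
        flags = cv.screen_correlations(table)
        assert len(flags) == 1 and flags[0].rho == pytest.approx(1.0)

    def test_independent_permutations_not_flagged(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"road_density": rng.permutation(1000),
                              "mine_density": rng.permutation(1000)})
        assert cv.screen_correlations(table) == []

    def test_threshold_one_flags_nothing_but_exact(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=50)
        table = pd.DataFrame({"road_density": x, "mine_density": x ** 2,
                              "dam_density": rng.uniform(size=50)})
        flags = cv.screen_correlations(table, threshold=1.0)
        assert flags == []  # |rho| > 1 is impossible; exact ties give rho = 1, not > 1

    def test_constant_variable_skipped(self):
        table = pd.DataFrame({"road_density": [1.0] * 10,
                              "mine_density": np.arange(10.0)})
        assert cv.screen_correlations(table) == []
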