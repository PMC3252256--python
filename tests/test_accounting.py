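import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wardstock import (
    ConsumptionSeries,
    FlowRecord,
    SalesRecord,
    StockSnapshot,
    aggregate_intervals,
    build_paired_registrations,
    impute_missing_blocks,
    non_consumption_share,
    percent_difference,
    weekly_pharmacy_consumption,
    weekly_ward_consumption,
)
from wardstock.errors import (
    ConfigurationError,
    SequencingError,
    ValidationError,
)


def snap(boundary, packs, ward="w1", agent="unit"):
    return StockSnapshot(ward_id=ward, week_index=boundary,
                         counts={agent: packs})


def flow(ftype, amount, week=1, ward="w1", agent="unit"):
    return FlowRecord(ward_id=ward, week_index=week, agent_id=agent,
                      flow_type=ftype, amount_ddd=amount)


def series(method, values, n_weeks, wards=("w1",), agents=("a",)):
    """Grid series from a (ward, agent, week) -> ddd mapping or constant."""
    rows = []
    for w in wards:
        for a in agents:
            for week in range(1, n_weeks + 1):
                if callable(values):
                    v = values(w, a, week)
                else:
                    v = values.get((w, a, week), 0.0) if isinstance(
                        values, dict) else values
                rows.append({"ward_id": w, "agent_id": a, "week": week,
                             "ddd": float(v), "imputed": False})
    return ConsumptionSeries(method=method, data=pd.DataFrame(rows),
                             n_weeks=n_weeks)


class TestWeeklyWardConsumption:
    @pytest.mark.parametrize(
        "prev_ddd, curr_ddd, flows, expected",
        [
            (10.0, 10.0, [], 0.0),  # nothing moved
            (30.0, 12.0,
             [("delivery", 10.0), ("discard", 2.0)], 26.0),
            (5.0, 20.0,
             [("delivery", 10.0), ("loan_in", 9.0), ("loan_out", 3.0)], 1.0),
            # returns netted like discards on the ward side
            (10.0, 5.0, [("return_to_pharmacy", 2.0)], 3.0),
        ],
    )
    def test_balance_equation(self, small_ref, prev_ddd, curr_ddd, flows,
                              expected):
        flow_records = [flow(t, a, week=1) for t, a in flows]
        out = weekly_ward_consumption(
            snap(0, prev_ddd), snap(1, curr_ddd), flow_records, small_ref
        )
        assert out["unit"] == pytest.approx(expected)

    def test_mismatched_wards_rejected(self, small_ref):
        with pytest.raises(SequencingError):
            weekly_ward_consumption(
                snap(0, 1, ward="w1"), snap(1, 1, ward="w2"), [], small_ref
            )

    def test_non_consecutive_weeks_rejected(self, small_ref):
        with pytest.raises(SequencingError):
            weekly_ward_consumption(snap(0, 1), snap(2, 1), [], small_ref)

    def test_unknown_agent_rejected(self, small_ref):
        bad = flow("delivery", 1.0, agent="mystery")
        with pytest.raises(KeyError):
            weekly_ward_consumption(snap(0, 1), snap(1, 1), [bad], small_ref)


class TestWeeklyPharmacyConsumption:
    def test_empty_input_is_all_zero(self):
        out = weekly_pharmacy_consumption([], [], ["w1"], ["a"], 4)
        assert out.total() == 0.0
        assert len(out.data) == 4

    def test_orders_minus_returns(self):
        sales = [
            SalesRecord("w1", 1, "a", 10.0, "o1"),
            SalesRecord("w1", 1, "a", 5.0, "o2"),
        ]
        returns = [flow("return_to_pharmacy", 5.0, ward="w1", agent="a")]
        out = weekly_pharmacy_consumption(sales, returns, ["w1"], ["a"], 2)
        assert out.cell("w1", "a", 1) == 10.0
        assert out.cell("w1", "a", 2) == 0.0

    def test_matches_brute_force_accumulation(self, rng):
        """Cell-wise series equals a per-record accumulation oracle."""
        wards, agents, weeks = ["w1", "w2", "w3"], ["a", "b"], 4
        sales, returns = [], []
        expected = {}
        for _ in range(200):
            w = wards[rng.integers(len(wards))]
            a = agents[rng.integers(len(agents))]
            week = int(rng.integers(1, weeks + 1))
            amt = float(rng.integers(1, 20))
            if rng.random() < 0.8:
                sales.append(SalesRecord(w, week, a, amt))
                expected[(w, a, week)] = expected.get((w, a, week), 0.0) + amt
            else:
                returns.append(
                    FlowRecord(w, week, a, "return_to_pharmacy", amt)
                )
                expected[(w, a, week)] = expected.get((w, a, week), 0.0) - amt
        out = weekly_pharmacy_consumption(sales, returns, wards, agents,
                                          weeks)
        for w in wards:
            for a in agents:
                for week in range(1, weeks + 1):
                    assert out.cell(w, a, week) == pytest.approx(
                        expected.get((w, a, week), 0.0)
                    )

    def test_wrong_flow_type_rejected(self):
        with pytest.raises(ValidationError):
            weekly_pharmacy_consumption(
                [], [flow("discard", 1.0, agent="a")], ["w1"], ["a"], 2
            )


class TestImputation:
    def test_single_week_block_is_identity(self):
        s = series("pharmacy", {("w1", "a", 2): 7.0}, 4)
        out = impute_missing_blocks(s, [(2, 2)])
        assert out.cell("w1", "a", 2) == 7.0
        assert out.imputed_weeks == {2}

    def test_block_average(self):
        s = series("pharmacy", {("w1", "a", 10): 30.0}, 12)
        out = impute_missing_blocks(s, [(10, 12)])
        for week in (10, 11, 12):
            assert out.cell("w1", "a", week) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 100), min_size=8, max_size=8),
           st.integers(1, 6))
    def test_conservation(self, values, start):
        """Total over the study window is identical before and after."""
        s = series("pharmacy",
                   {("w1", "a", w + 1): v for w, v in enumerate(values)}, 8)
        end = min(start + 2, 8)
        out = impute_missing_blocks(s, [(start, end)])
        assert out.total() == pytest.approx(s.total(), rel=1e-12, abs=1e-9)

    def test_block_outside_window_rejected(self):
        s = series("pharmacy", 1.0, 4)
        with pytest.raises(ValidationError):
            impute_missing_blocks(s, [(3, 6)])


class TestAggregation:
    def test_k1_is_identity(self):
        s = series("ward", lambda w, a, week: week * 1.5, 26)
        out = aggregate_intervals(s, 1)
        assert len(out) == 26
        assert list(out["ddd"]) == [w * 1.5 for w in range(1, 27)]

    def test_26_weeks_k2_gives_13_intervals(self):
        s = series("ward", 1.0, 26)
        out = aggregate_intervals(s, 2)
        assert out["interval"].nunique() == 13
        assert (out["ddd"] == 2.0).all()

    def test_k4_with_omission_matches_brute_force(self, rng):
        values = {("w1", "a", w): float(rng.integers(0, 30))
                  for w in range(1, 27)}
        s = series("ward", values, 26)
        out = aggregate_intervals(s, 4, omit_weeks={12, 26})
        assert out["interval"].nunique() == 6
        retained = [w for w in range(1, 27) if w not in (12, 26)]
        for i in range(6):
            block = retained[4 * i:4 * (i + 1)]
            expected = sum(values[("w1", "a", w)] for w in block)
            got = float(out[out["interval"] == i + 1]["ddd"].iloc[0])
            assert got == pytest.approx(expected)

    def test_totals_conserved_for_every_k(self, rng):
        values = {("w1", "a", w): float(rng.normal(10, 3))
                  for w in range(1, 27)}
        s = series("ward", values, 26)
        for k, omit in [(1, ()), (2, ()), (3, (12, 26)), (4, (12, 26))]:
            out = aggregate_intervals(s, k, omit_weeks=omit)
            expected = sum(v for (w_, a_, week), v in values.items()
                           if week not in omit)
            assert out["ddd"].sum() == pytest.approx(expected)

    def test_non_divisible_length_names_remainder(self):
        s = series("ward", 1.0, 26)
        with pytest.raises(ConfigurationError, match="remainder 2"):
            aggregate_intervals(s, 4)


class TestPairedRegistrations:
    def test_pair_count_and_double_zero_retention(self, small_ref):
        wards = [f"w{i}" for i in range(3)]
        agents = ["unit", "unit_po"]
        pharm = series("pharmacy", 0.0, 6, wards=wards, agents=agents)
        ward = series("ward", 0.0, 6, wards=wards, agents=agents)
        pairs = build_paired_registrations(pharm, ward, 1)
        assert len(pairs) == 3 * 2 * 6  # all-zero cells are retained
        oral = build_paired_registrations(pharm, ward, 1, stratum="oral",
                                          ref=small_ref)
        assert len(oral) == 3 * 1 * 6
        par = build_paired_registrations(pharm, ward, 1, stratum="parenteral",
                                         ref=small_ref)
        assert len(par) == 3 * 1 * 6

    def test_grand_total_identity_for_every_k(self, rng):
        """Pharmacy minus ward grand total equals the sum of pairwise
        differences, independent of the interval length."""
        values_p = {("w1", "a", w): float(rng.integers(0, 30))
                    for w in range(1, 27)}
        values_w = {("w1", "a", w): float(rng.integers(0, 30))
                    for w in range(1, 27)}
        pharm = series("pharmacy", values_p, 26)
        ward = series("ward", values_w, 26)
        for k, omit in [(1, ()), (2, ()), (3, (12, 26)), (4, (12, 26))]:
            pairs = build_paired_registrations(pharm, ward, k, omit)
            diff_sum = (pairs["pharmacy_ddd"] - pairs["ward_ddd"]).sum()
            p_total = sum(v for (w_, a_, wk), v in values_p.items()
                          if wk not in omit)
            w_total = sum(v for (w_, a_, wk), v in values_w.items()
                          if wk not in omit)
            assert diff_sum == pytest.approx(p_total - w_total)

    def test_shape_mismatch_rejected(self):
        pharm = series("pharmacy", 1.0, 6, wards=("w1",))
        ward = series("ward", 1.0, 6, wards=("w1", "w2"))
        with pytest.raises(ValidationError):
            build_paired_registrations(pharm, ward, 1)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "p, w, expected",
        [
            (3977.2, 3969.7, 0.2),
            (1144.8, 1194.2, -4.3),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_examples(self, p, w, expected):
        assert percent_difference(p, w) == pytest.approx(expected, abs=0.05)

    def test_zero_pharmacy_is_missing(self):
        assert math.isnan(percent_difference(0.0, 5.0))

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(1.0, 1e4),
           w1=st.floats(0.0, 1e4), w2=st.floats(0.0, 1e4))
    def test_strictly_decreasing_in_ward_value(self, p, w1, w2):
        lo, hi = sorted([w1, w2])
        if hi - lo < 1e-3:  # below float resolution of the percentage
            return
        assert percent_difference(p, lo) > percent_difference(p, hi)


class TestNonConsumptionShare:
    def test_published_magnitude(self):
        flows = [
            flow("discard", 10.5),
            flow("discharge_takeaway", 18.0),
            flow("loan_out", 14.5),
            flow("loan_in", 9.0),       # not counted
            flow("delivery", 100.0),    # not counted
        ]
        share = non_consumption_share(flows, 3969.7)
        assert round(share, 1) == 1.1

    def test_zero_and_forced_ratio(self):
        assert non_consumption_share([], 100.0) == 0.0
        assert non_consumption_share([flow("discard", 50.0)], 1000.0) == 5.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValidationError):
            non_consumption_share([], 0.0)
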