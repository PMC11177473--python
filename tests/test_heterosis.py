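"""Mid-parent heterosis statistics and Duncan multiple-range letters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import triadhet as th
from triadhet.heterosis import mean_trend_deltas

from _oracles import welch_all_pairs_distinct


def trait_rows(variety, values, day=45, p1="", p2=""):
    return [
        {"variety": variety, "parent1": p1, "parent2": p2, "day": day,
         "replicate": i + 1, "value": v}
        for i, v in enumerate(values)
    ]


class TestMPH:
    def test_identity_and_arithmetic(self):
        assert th.mph(120.0, 120.0) == 0.0
        assert th.mph(61.25, 50.0) == pytest.approx(22.5)
        assert th.mph(40.0, 50.0) == pytest.approx(-20.0)

    def test_nonpositive_midparent_rejected(self):
        with pytest.raises(ValueError):
            th.mph(10.0, 0.0)
        with pytest.raises(ValueError):
            th.mph(10.0, -5.0)

    @given(
        st.floats(1e-3, 1e6), st.floats(1e-3, 1e6),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, f1, mp, c):
        assert th.mph(c * f1, c * mp) == pytest.approx(th.mph(f1, mp), rel=1e-6)


class TestMPHSeries:
    def test_parents_only_gives_empty(self):
        table = pd.DataFrame(
            trait_rows("A", [1.0, 2.0]) + trait_rows("B", [2.0, 3.0])
        )
        assert th.mph_series(table).empty

    def test_schedule_inversion_exact(self):
        cfg = th.default_biomass_config(seed=0, noise_cv=0.0)
        series = th.mph_series(th.simulate_biomass(cfg))
        assert len(series) == len(cfg.hybrids) * len(cfg.timepoints_days)
        for _, row in series.iterrows():
            assert row["MPH_pct"] == pytest.approx(
                cfg.mph_schedule[(row["hybrid"], int(row["day"]))], abs=1e-9
            )

    def test_missing_parent_day_skipped_with_warning(self, caplog):
        table = pd.DataFrame(
            trait_rows("A", [10, 10], day=38)
            + trait_rows("B", [20, 20], day=38)
            + trait_rows("AxB", [18, 18], day=38, p1="A", p2="B")
            + trait_rows("AxB", [19, 19], day=45, p1="A", p2="B")  # parents unmeasured at 45
        )
        with caplog.at_level("WARNING"):
            series = th.mph_series(table)
        assert list(series["day"]) == [38]
        assert "45" in caplog.text

    def test_designed_point_value(self):
        table = pd.DataFrame(
            trait_rows("A", [40, 40], day=45)
            + trait_rows("B", [60, 60], day=45)
            + trait_rows("AxB", [61.25, 61.25], day=45, p1="A", p2="B")
        )
        series = th.mph_series(table)
        assert series["MPH_pct"].iloc[0] == pytest.approx(22.5)


class TestTrendDeltas:
    def _series(self, mph_by_day, hybrid="H"):
        return pd.DataFrame(
            {"hybrid": hybrid, "day": list(mph_by_day),
             "F1": 1.0, "MP": 1.0, "MPH_pct": list(mph_by_day.values())}
        )

    def test_simple_rise_is_key_period(self):
        deltas = th.trend_deltas(self._series({45: 10.0, 52: 25.0}))
        assert deltas["delta_points"].iloc[0] == pytest.approx(15.0)
        assert deltas["key_period"].iloc[0]

    def test_constant_series_has_no_key_period(self):
        deltas = th.trend_deltas(self._series({38: 5.0, 45: 5.0, 52: 5.0}))
        assert np.allclose(deltas["delta_points"], 0.0)
        assert not deltas["key_period"].any()

    def test_tie_broken_to_earliest_interval(self):
        deltas = th.trend_deltas(self._series({38: 0.0, 45: 10.0, 52: 20.0}))
        key = deltas[deltas["key_period"]]
        assert len(key) == 1
        assert (key["day_from"].iloc[0], key["day_to"].iloc[0]) == (38, 45)

    def test_designed_maximum_rise_located(self):
        cfg = th.default_biomass_config(seed=0, noise_cv=0.0)
        series = th.mph_series(th.simulate_biomass(cfg))
        deltas = th.trend_deltas(series)
        key = deltas[(deltas["hybrid"] == "Va116xGDH94") & deltas["key_period"]]
        assert (int(key["day_from"].iloc[0]), int(key["day_to"].iloc[0])) == (45, 52)
        assert key["delta_points"].iloc[0] == pytest.approx(14.99, abs=1e-9)

    def test_single_timepoint_yields_no_rows(self):
        assert th.trend_deltas(self._series({45: 10.0})).empty

    def test_across_hybrid_mean_deltas(self):
        series = pd.concat(
            [self._series({38: 0.0, 45: 10.0}, "H1"),
             self._series({38: 0.0, 45: 20.0}, "H2")]
        )
        mean_d = mean_trend_deltas(series)
        assert mean_d["delta_points"].iloc[0] == pytest.approx(15.0)


class TestDuncanLetters:
    def test_identical_varieties_share_a(self):
        table = pd.DataFrame(
            trait_rows("A", [5.0, 5.0, 5.0]) + trait_rows("B", [5.0, 5.0, 5.0])
        )
        g = th.duncan_letters(table, day=45)
        assert g.letters == {"A": "a", "B": "a"}

    def test_three_separated_means_get_distinct_letters(self):
        table = pd.DataFrame(
            trait_rows("A", [99.0, 100.0, 101.0])
            + trait_rows("B", [49.0, 50.0, 51.0])
            + trait_rows("C", [9.0, 10.0, 11.0])
        )
        g = th.duncan_letters(table, day=45)
        assert g.letters == {"A": "a", "B": "b", "C": "c"}
        groups = {v: [r["value"] for r in trait_rows(v, x)]
                  for v, x in [("A", [99, 100, 101]), ("B", [49, 50, 51]),
                               ("C", [9, 10, 11])]}
        oracle = welch_all_pairs_distinct(groups, 0.05)
        assert all(oracle.values())

    def test_two_equal_one_low_merges_top_pair(self):
        table = pd.DataFrame(
            trait_rows("A", [99.0, 100.0, 101.0])
            + trait_rows("B", [99.0, 100.0, 101.0])
            + trait_rows("C", [9.0, 10.0, 11.0])
        )
        g = th.duncan_letters(table, day=45)
        assert g.letters["A"] == g.letters["B"] == "a"
        assert g.letters["C"] == "b"

    def test_largest_mean_holds_letter_a(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(5):
            rows += trait_rows(f"V{i}", list(rng.normal(50 + 5 * i, 2, 4)))
        g = th.duncan_letters(pd.DataFrame(rows), day=45)
        top = max(g.means, key=g.means.get)
        assert "a" in g.letters[top]

    def test_two_group_case_matches_pooled_t_test(self):
        """Duncan with p=2 reduces to the pooled-variance LSD."""
        rng = np.random.default_rng(17)
        for trial in range(200):
            shift = rng.uniform(0, 3)
            a = rng.normal(10, 1, 3)
            b = rng.normal(10 + shift, 1, 3)
            table = pd.DataFrame(trait_rows("A", list(a)) + trait_rows("B", list(b)))
            g = th.duncan_letters(table, day=45)
            share = set(g.letters["A"]) & set(g.letters["B"])
            t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert bool(share) == (t_p >= 0.05), (trial, t_p, g.letters)

    def test_zero_variance_distinct_means_all_distinct(self):
        table = pd.DataFrame(
            trait_rows("A", [10.0, 10.0]) + trait_rows("B", [5.0, 5.0])
        )
        g = th.duncan_letters(table, day=45)
        assert set(g.letters["A"]) & set(g.letters["B"]) == set()

    def test_requires_replication(self):
        table = pd.DataFrame(trait_rows("A", [1.0]) + trait_rows("B", [2.0, 3.0]))
        with pytest.raises(ValueError):
            th.duncan_letters(table, day=45)
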