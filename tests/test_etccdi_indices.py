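"""Index definitions against brute-force oracles and calendar logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import winterx as wx
from winterx.etccdi_indices import winter_calendar_days

from conftest import constant_winter, make_series


def brute_spell_days(mask, min_run=6):
    """Independent run-length scanner: total days in runs >= min_run."""
    total = run = 0
    for flag in list(mask) + [False]:
        if flag:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total


class TestThresholds:
    def test_constant_history_gives_constant_threshold(self):
        s = make_series("A", "1960-12-01", values=2.0, n=31 * 366)
        thr = wx.compute_thresholds(s, 1995)
        assert thr.base_years == (1961, 1990)
        assert all(v == pytest.approx(-2.0) for v in thr.p_low_tn.values())
        assert all(v == pytest.approx(6.0) for v in thr.p_high_tx.values())

    def test_percentile_matches_order_statistic_rule(self):
        """Pooled sample 1..100: p90 by linear interpolation = 90.1."""
        n_years = 20
        vals = np.arange(1.0, 101.0)
        # 5 calendar days x 20 years = 100 pooled values around Jan 15
        dates = pd.date_range("1980-12-01", periods=n_years * 366 + 31, freq="D")
        data = pd.DataFrame({"tmax": np.nan, "tmin": np.nan, "tmean": np.nan},
                            index=dates)
        k = 0
        for year in range(1981, 2001):
            for day in range(13, 18):
                data.loc[pd.Timestamp(year, 1, day), ["tmax", "tmin", "tmean"]] = vals[k]
                k += 1
        series = wx.StationDailySeries(station_id="A", data=data)
        thr = wx.compute_thresholds(series, 2001, base_span=20, mode="fixed",
                                    fixed_base=(1981, 2000), days=[(1, 15)])
        assert thr.p_high_tx[(1, 15)] == pytest.approx(np.percentile(vals, 90))
        assert thr.p_low_tn[(1, 15)] == pytest.approx(np.percentile(vals, 10))

    def test_dynamic_base_window_follows_decades(self):
        s = make_series("A", "1960-12-01", values=0.0, n=80 * 366)
        assert wx.compute_thresholds(s, 2035).base_years == (2001, 2030)
        assert wx.compute_thresholds(s, 2040).base_years == (2001, 2030)
        assert wx.compute_thresholds(s, 2041).base_years == (2011, 2040)

    def test_insufficient_history_rejected(self):
        s = make_series("A", "1980-01-01", values=0.0, n=5 * 365)
        with pytest.raises(wx.ValidationError, match="insufficient"):
            wx.compute_thresholds(s, 1995)

    def test_feb29_has_a_threshold(self):
        s = make_series("A", "1960-12-01", values=1.0, n=31 * 366)
        thr = wx.compute_thresholds(s, 1995)
        assert (2, 29) in thr.p_low_tn
        assert len(thr.p_low_tn) == len(winter_calendar_days())


class TestDayCounts:
    def test_frost_and_ice_days_constructed(self):
        tn = np.full(90, 2.0)
        tn[[3, 10, 20, 40, 80]] = -1.0     # exactly 5 frost days
        w = constant_winter("A", 1990, 0.0)
        w.data["tmin"] = tn
        w.data["tmax"] = 1.0               # never below zero
        assert wx.count_days(w, "FD0") == 5
        assert wx.count_days(w, "ID0") == 0

    def test_relative_counts_attain_window_bound(self):
        w = constant_winter("A", 1990, 0.0)
        thr = wx.ThresholdSet(
            station_id="A",
            p_low_tn={d: 0.0 for d in winter_calendar_days()},     # tn=-4 < 0 always
            p_high_tx={d: 0.0 for d in winter_calendar_days()},    # tx=+4 > 0 always
            base_years=(1960, 1989), day_window=5)
        assert wx.count_days(w, "TN10p", thr) == 90
        assert wx.count_days(w, "TX90p", thr) == 90

    def test_relative_count_requires_thresholds(self):
        w = constant_winter("A", 1990, 0.0)
        with pytest.raises(wx.ValidationError):
            wx.count_days(w, "TN10p")

    def test_counts_invariant_under_common_shift(self):
        rng = np.random.default_rng(3)
        w = constant_winter("A", 1990, 0.0)
        w.data["tmin"] = rng.normal(-5, 3, 90)
        thr_at = lambda c: wx.ThresholdSet(
            "A", {d: c for d in winter_calendar_days()},
            {d: c + 10 for d in winter_calendar_days()}, (1960, 1989), 5)
        base = wx.count_days(w, "TN10p", thr_at(-5.0))
        w.data["tmin"] += 7.5
        assert wx.count_days(w, "TN10p", thr_at(-5.0 + 7.5)) == base


class TestSpells:
    @staticmethod
    def _winter_with_mask(mask):
        w = constant_winter("A", 1990, 0.0)
        tx = np.where(mask, 5.0, -5.0)
        w.data["tmax"] = tx
        w.data["tmin"] = tx - 8.0
        thr = wx.ThresholdSet(
            "A", {d: -20.0 for d in winter_calendar_days()},
            {d: 0.0 for d in winter_calendar_days()}, (1960, 1989), 5)
        return w, thr

    def test_single_run_counts_all_its_days(self):
        mask = np.zeros(90, bool)
        mask[10:17] = True                   # one run of 7
        w, thr = self._winter_with_mask(mask)
        assert wx.spell_duration(w, thr, "warm") == 7

    def test_run_below_minimum_ignored(self):
        mask = np.zeros(90, bool)
        mask[10:15] = True                   # run of 5 < 6
        w, thr = self._winter_with_mask(mask)
        assert wx.spell_duration(w, thr, "warm") == 0

    def test_two_runs_sum(self):
        mask = np.zeros(90, bool)
        mask[5:11] = True                    # 6
        mask[20:28] = True                   # 8
        w, thr = self._winter_with_mask(mask)
        assert wx.spell_duration(w, thr, "warm") == 14

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            mask = rng.random(90) < 0.45
            assert wx.spell_days(mask) == brute_spell_days(mask)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=0, max_size=120),
           st.integers(min_value=1, max_value=8))
    def test_spell_days_equals_oracle(self, mask, min_run):
        assert wx.spell_days(np.array(mask, bool), min_run) == \
            brute_spell_days(mask, min_run)

    def test_wsdi_bounded_by_exceedance_count(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mask = rng.random(90) < 0.5
            assert wx.spell_days(mask) <= int(mask.sum())


class TestExtremesAndDtr:
    def test_constant_series(self):
        w = constant_winter("A", 1990, 3.0, spread=0.0)
        assert wx.extreme_value(w, "TXx") == 3.0
        assert wx.extreme_value(w, "TNn") == 3.0
        assert wx.dtr(w) == 0.0

    def test_random_series_matches_brute_force(self):
        rng = np.random.default_rng(8)
        w = constant_winter("A", 1990, 0.0)
        tn = rng.normal(-8, 4, 90)
        tx = tn + rng.uniform(2, 12, 90)
        w.data["tmin"], w.data["tmax"] = tn, tx
        assert wx.extreme_value(w, "TXx") == pytest.approx(max(tx))
        assert wx.extreme_value(w, "TNn") == pytest.approx(min(tn))
        assert wx.extreme_value(w, "TNn") <= wx.extreme_value(w, "TXx")
        assert wx.dtr(w) == pytest.approx(float(np.mean(tx - tn)))
        assert wx.dtr(w) >= 0.0

    def test_fixed_offset_gives_exact_dtr(self):
        w = constant_winter("A", 1990, 0.0, spread=4.0)   # tx - tn = 8
        assert wx.dtr(w) == pytest.approx(8.0)


class TestGsl:
    def test_warm_all_year_runs_to_december(self):
        s = make_series("A", "1995-01-01", values=10.0, n=365)
        assert wx.gsl(s, 1995) == 365

    def test_cold_all_year_is_zero(self):
        s = make_series("A", "1995-01-01", values=0.0, n=365)
        assert wx.gsl(s, 1995) == 0

    def test_constructed_onset_and_termination(self):
        tm = np.full(365, 0.0)
        tm[59:250] = 10.0        # warm from day 60; cold run starts day 251...
        s = make_series("A", "1995-01-01", values=tm)
        # onset day 60 (index 59); first >=6-day cold run after 1 July starts
        # at index 250 -> GSL = 250 - 59 = 191 days
        assert wx.gsl(s, 1995) == 191

    def test_termination_before_july_ignored(self):
        tm = np.full(365, 10.0)
        tm[100:140] = 0.0        # cold spell in spring must not terminate
        s = make_series("A", "1995-01-01", values=tm)
        assert wx.gsl(s, 1995) == 365


def test_winter_index_table_is_tidy(member7):
    t = wx.index_table({"NE001": member7.series["NE001"]}, winters=[1995],
                       mode="fixed", fixed_base=(1991, 1994), base_span=4,
                       include_gsl=True)
    assert set(t["index"]) == set(wx.etccdi_indices.ALL_INDEX_NAMES)
    vals = t.set_index("index")["value"]
    assert vals["TNn"] <= vals["TXx"]
    assert 0 <= vals["TN10p"] <= 90
    assert vals["CSDI"] <= vals["TN10p"]
    assert vals["WSDI"] <= vals["TX90p"]
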