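"""Dynamic-baseline grading, regional aggregation and decadal frequency."""

import numpy as np
import pandas as pd
import pytest

import winterx as wx


def _baseline(ta=0.0, sigma=1.0, unit="A", decade=2031):
    return wx.Baseline(unit_id=unit, decade=decade, ta=ta, sigma=sigma,
                       window=(decade - 30, decade - 1), n=30)


class TestBaseline:
    def test_identical_winters_degenerate(self):
        means = pd.Series(2.0, index=range(1971, 2001))
        b = wx.dynamic_baseline(means, 2005, unit_id="A")
        assert b.ta == 2.0 and b.sigma == 0.0

    def test_alternating_winters_sample_sd(self):
        means = pd.Series([(-1.0) ** i for i in range(30)], index=range(1971, 2001))
        b = wx.dynamic_baseline(means, 2005)
        assert b.ta == 0.0
        assert b.sigma == pytest.approx(np.sqrt(30 / 29))

    def test_window_updates_each_decade(self):
        means = pd.Series(0.0, index=range(1961, 2101))
        assert wx.dynamic_baseline(means, 2035).window == (2001, 2030)
        assert wx.dynamic_baseline(means, 2040).window == (2001, 2030)
        assert wx.dynamic_baseline(means, 2041).window == (2011, 2040)
        assert wx.baseline_window(2035) == (2001, 2030)

    def test_missing_baseline_winter_rejected(self):
        means = pd.Series(0.0, index=range(1975, 2001))
        with pytest.raises(wx.ValidationError, match="incomplete"):
            wx.dynamic_baseline(means, 2005)


class TestStationGrade:
    def test_half_sigma_is_warm(self):
        assert wx.classify_station(0.5, _baseline(), 2035).grade == "warm"

    def test_one_and_a_half_sigma_is_strong(self):
        assert wx.classify_station(1.5, _baseline(), 2035).grade == "strong"

    def test_zero_anomaly_is_none(self):
        rec = wx.classify_station(0.0, _baseline(), 2035)
        assert rec.grade == "none" and rec.anomaly == 0.0

    def test_thresholds_are_strict(self):
        assert wx.classify_station(0.43, _baseline(), 2035).grade == "none"
        assert wx.classify_station(1.29, _baseline(), 2035).grade == "warm"

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(wx.ValidationError, match="degenerate"):
            wx.classify_station(1.0, _baseline(sigma=0.0), 2035)

    def test_monotone_in_temperature(self):
        order = {"none": 0, "warm": 1, "strong": 2}
        grades = [order[wx.classify_station(t, _baseline(), 2035).grade]
                  for t in np.linspace(-2, 3, 101)]
        assert grades == sorted(grades)


class TestRegionalGrade:
    @staticmethod
    def _records(n_strong, n_warm, n_none, wy=2035):
        recs = []
        for grade, count in (("strong", n_strong), ("warm", n_warm), ("none", n_none)):
            for i in range(count):
                recs.append(wx.WarmWinterRecord("station", f"{grade}{i}", wy,
                                                0.0, grade))
        return recs

    def test_six_of_ten_warm_is_regional_warm(self):
        rec = wx.classify_region(self._records(0, 6, 4), "NE")
        assert rec.grade == "warm"

    def test_five_of_ten_is_not_warm(self):
        assert wx.classify_region(self._records(0, 5, 5), "NE").grade == "none"

    def test_strong_majority_is_regional_strong(self):
        assert wx.classify_region(self._records(6, 1, 3), "NE").grade == "strong"

    def test_no_stations_rejected(self):
        with pytest.raises(wx.ValidationError):
            wx.classify_region([], "NE")


class TestDecadalFrequency:
    def test_bounds(self):
        recs = [wx.WarmWinterRecord("region", "NE", wy, np.nan, "warm")
                for wy in range(2021, 2031)]
        assert wx.decadal_frequency(recs, "NE", 2021) == (10, 0)
        assert wx.decadal_frequency(recs, "NE", 2031) == (0, 0)

    def test_random_grades_match_brute_force(self):
        rng = np.random.default_rng(17)
        grades = rng.choice(["none", "warm", "strong"], size=10)
        recs = [wx.WarmWinterRecord("region", "NE", 2021 + i, np.nan, g)
                for i, g in enumerate(grades)]
        warm, strong = wx.decadal_frequency(recs, "NE", 2021)
        assert warm == sum(g in ("warm", "strong") for g in grades)
        assert strong == sum(g == "strong" for g in grades)


class TestDynamicVsStatic:
    def test_dynamic_baseline_damps_late_century_frequency(self):
        """Under sustained warming the moving normal tracks the trend, so the
        dynamic count of warm winters in late decades is at most the static."""
        rng = np.random.default_rng(42)
        years = np.arange(1961, 2101)
        t = 0.04 * (years - 1961) + rng.normal(0, 1.0, len(years))
        means = pd.Series(t, index=years)
        wm = pd.DataFrame({"station_id": "A", "winter_year": years, "tm_bar": t})
        stations = pd.DataFrame({"region": ["NE"]}, index=pd.Index(["A"], name="station_id"))
        dyn = wx.classify_network(wm, stations, mode="dynamic")
        stat = wx.classify_network(wm, stations, mode="static",
                                   static_window=(1961, 1990))
        for decade in (2071, 2081, 2091):
            nd = wx.decadal_frequency([r for r in dyn if r.level == "station"],
                                      "A", decade)[0]
            ns = wx.decadal_frequency([r for r in stat if r.level == "station"],
                                      "A", decade)[0]
            assert nd <= ns

    def test_network_levels_present(self, network7):
        rng = np.random.default_rng(1)
        years = np.arange(1961, 2021)
        rows = []
        for sid in network7.index:
            rows.append(pd.DataFrame({
                "station_id": sid, "winter_year": years,
                "tm_bar": rng.normal(0, 1, len(years))}))
        wm = pd.concat(rows, ignore_index=True)
        recs = wx.classify_network(wm, network7, mode="dynamic")
        levels = {r.level for r in recs}
        assert levels == {"station", "region", "national"}
        # every classifiable winter yields one national record
        nat = [r for r in recs if r.level == "national"]
        assert sorted({r.winter_year for r in nat}) == list(range(1991, 2021))
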