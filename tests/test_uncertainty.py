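"""Variance partition: reconstruction identity and component recovery."""

import numpy as np
import pytest

import winterx as wx

YEARS = np.arange(1961, 2101)


def _decomp(values, model="M0", scenario="S0"):
    return wx.fit_member(YEARS, values, reference_period=(1995, 2014),
                         model=model, scenario=scenario)


class TestFitMember:
    def test_quartic_series_has_zero_residual(self):
        t = (YEARS - YEARS.mean()) / 50.0
        x = 1.0 + 0.5 * t - 0.2 * t ** 2 + 0.1 * t ** 4
        d = _decomp(x)
        np.testing.assert_allclose(d.residual, 0.0, atol=1e-10)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, len(YEARS))
        d = _decomp(x)
        np.testing.assert_allclose(d.reconstruct(), x - 0.0, atol=1e-9)
        assert d.offset == pytest.approx(
            x[(YEARS >= 1995) & (YEARS <= 2014)].mean())

    def test_white_noise_residual_variance_loses_five_dof(self):
        """A degree-4 fit absorbs 5 degrees of freedom: E var(eps) = s2 (n-5)/n."""
        rng = np.random.default_rng(42)
        n, s2, reps = len(YEARS), 1.0, 200
        ratios = []
        for _ in range(reps):
            d = _decomp(rng.normal(0.0, np.sqrt(s2), n))
            ratios.append(np.var(d.residual) / s2)
        assert np.mean(ratios) == pytest.approx((n - 5) / n, abs=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(wx.ValidationError):
            wx.fit_member(YEARS[:10], np.zeros(10))


class TestComponents:
    def test_zero_residuals_give_zero_internal(self):
        t = (YEARS - YEARS.mean()) / 50.0
        ds = [_decomp(1.0 + t ** 2, model=f"M{i}") for i in range(3)]
        assert wx.internal_variability(ds) == pytest.approx(0.0, abs=1e-20)

    def test_doubling_residuals_quadruples_internal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, len(YEARS))
        v1 = wx.internal_variability([_decomp(x)])
        d2 = _decomp(x)
        d2.residual = d2.residual * 2.0
        assert wx.internal_variability([d2]) == pytest.approx(4.0 * v1)

    def test_injected_residual_sd_recovered(self):
        """6 models x 2 scenarios x 140 years with sd 0.4 -> V ~ 0.16."""
        rng = np.random.default_rng(5)
        ds = [_decomp(rng.normal(0, 0.4, len(YEARS)), model=f"M{m}", scenario=s)
              for m in range(6) for s in ("A", "B")]
        assert wx.internal_variability(ds) == pytest.approx(0.16, rel=0.15)

    def test_identical_models_give_zero_model_uncertainty(self):
        t = (YEARS - YEARS.mean()) / 50.0
        ds = [_decomp(t ** 2, model=f"M{i}") for i in range(4)]
        np.testing.assert_allclose(wx.model_uncertainty(ds), 0.0, atol=1e-18)

    def test_model_uncertainty_shift_invariant(self):
        rng = np.random.default_rng(2)
        t = (YEARS - YEARS.mean()) / 50.0
        base = [rng.normal(0, 0.5) * t for _ in range(5)]
        ds = [_decomp(b, model=f"M{i}") for i, b in enumerate(base)]
        shifted = [_decomp(b + 3.0 * t ** 2, model=f"M{i}") for i, b in enumerate(base)]
        np.testing.assert_allclose(wx.model_uncertainty(shifted),
                                   wx.model_uncertainty(ds), atol=1e-12)

    def test_single_model_rejected(self):
        with pytest.raises(wx.ValidationError):
            wx.model_uncertainty([_decomp(np.zeros(len(YEARS)))])

    def test_scenario_uncertainty_two_point_oracle(self):
        slope_a, slope_b = 0.01, 0.04
        t = YEARS - YEARS.mean()
        ds = [_decomp(slope_a * t, model="M0", scenario="A"),
              _decomp(slope_b * t, model="M0", scenario="B")]
        s = wx.scenario_uncertainty(ds)
        # each fit is slope * (t - mean over the reference period), so the
        # population variance of the two scenario curves is (diff/2)^2
        t_ref = t[(YEARS >= 1995) & (YEARS <= 2014)].mean()
        expected = ((slope_b - slope_a) * (t - t_ref) / 2.0) ** 2
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_identical_scenarios_give_zero(self):
        t = YEARS - YEARS.mean()
        ds = [_decomp(0.01 * t, model="M0", scenario=s) for s in ("A", "B")]
        np.testing.assert_allclose(wx.scenario_uncertainty(ds), 0.0, atol=1e-18)


class TestFractions:
    def test_known_fractions(self):
        c = wx.UncertaintyCurves(years=np.array([2000]), internal=1.0,
                                 model=np.array([1.0]), scenario=np.array([2.0]))
        f_v, f_m, f_s = c.fractions()
        assert (f_v[0], f_m[0], f_s[0]) == (0.25, 0.25, 0.5)

    def test_fractions_sum_to_one_everywhere(self):
        rng = np.random.default_rng(3)
        ds = [_decomp(rng.normal(0, 0.3, len(YEARS))
                      + (0.02 + 0.01 * m) * (YEARS - YEARS.mean())
                      + (0.015 if s == "B" else 0.0) * np.maximum(YEARS - 2015, 0),
                      model=f"M{m}", scenario=s)
              for m in range(4) for s in ("A", "B")]
        curves = wx.partition(ds)
        f_v, f_m, f_s = curves.fractions()
        np.testing.assert_allclose(f_v + f_m + f_s, 1.0, atol=1e-12)
        assert ((f_v >= 0) & (f_v <= 1)).all()

    def test_scenario_share_overtakes_model_share_late(self):
        """Scenario divergence after 2015 grows until it dominates the
        model spread; early in the record the model spread dominates."""
        rng = np.random.default_rng(8)
        t = YEARS - YEARS.mean()
        post = np.maximum(YEARS - 2015.0, 0.0)
        ds = []
        for m in range(6):
            slope = 0.010 + 0.004 * (m - 2.5)          # model spread in trend
            for s, extra in (("A", 0.0), ("B", 0.04)):  # scenario divergence
                ds.append(_decomp(slope * t + extra * post
                                  + rng.normal(0, 0.2, len(YEARS)),
                                  model=f"M{m}", scenario=s))
        curves = wx.partition(ds)
        _, f_m, f_s = curves.fractions()
        early = YEARS <= 2000
        late = YEARS >= 2090
        assert f_m[early].mean() > f_s[early].mean()
        assert f_s[late].mean() > f_m[late].mean()
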