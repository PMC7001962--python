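"""Weather generator: fitting, generation fidelity, change factors, QC, I/O."""

import io

import numpy as np
import pandas as pd
import pytest

import agriwx as ax
from agriwx import metforcing, wxgen
from agriwx.wxgen import DAYS_IN_MONTH


class TestGeneration:
    def test_deterministic_under_seed(self, baseline_clim):
        a = ax.generate_series(baseline_clim, 5, seed=123)
        b = ax.generate_series(baseline_clim, 5, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, baseline_clim):
        a = ax.generate_series(baseline_clim, 2, seed=1)
        b = ax.generate_series(baseline_clim, 2, seed=2)
        assert not np.allclose(a["precip"], b["precip"])

    def test_constructive_invariants(self, baseline_clim):
        s = ax.generate_series(baseline_clim, 50, seed=3)
        assert np.all(s["tmax"] >= s["tmin"])
        assert np.all(s["precip"] >= 0)
        dl = metforcing.daylength(baseline_clim.latitude, s["doy"].to_numpy())
        assert np.all(s["sun_hours"] >= 0)
        assert np.all(s["sun_hours"].to_numpy() <= dl + 1e-9)
        assert len(s) == 50 * 365
        # contiguous 365-day calendar
        assert list(s["doy"][:365]) == list(range(1, 366))

    def test_monthly_means_match_climatology(self, baseline_clim):
        """2000 generated years reproduce the implied monthly temperature
        means within a 3-sigma central-limit bound (inflated for the AR(1)
        day-to-day correlation), and annual precipitation within 1%."""
        n_years = 2000
        s = ax.generate_series(baseline_clim, n_years, seed=17)
        infl = np.sqrt((1 + baseline_clim.temp_autocorr)
                       / (1 - baseline_clim.temp_autocorr))
        for var, mean_fn, var_fn in [
            ("tmax", baseline_clim.expected_monthly_tmax,
             baseline_clim.monthly_tmax_variance),
            ("tmin", baseline_clim.expected_monthly_tmin,
             baseline_clim.monthly_tmin_variance),
        ]:
            got = s.groupby("month")[var].mean().to_numpy()
            want = mean_fn()
            bound = 3 * infl * np.sqrt(var_fn() / (DAYS_IN_MONTH * n_years))
            assert np.all(np.abs(got - want) < bound + 0.02), var
        annual = s["precip"].sum() / n_years
        expected = baseline_clim.expected_monthly_precip().sum()
        assert annual == pytest.approx(expected, rel=0.01)

    def test_wet_day_frequency_matches_chain(self, baseline_clim):
        s = ax.generate_series(baseline_clim, 2000, seed=19)
        pi = baseline_clim.stationary_wet_prob()
        # Occurrence state = any rain at all.
        occ = (s["precip"] > 0).groupby(s["month"]).mean().to_numpy()
        assert np.all(np.abs(occ - pi) < 0.01)
        # Classified at the fitting threshold, the frequency sits slightly
        # below the chain probability (trace-rain gamma draws < 0.1 mm).
        wet = (s["precip"] >= wxgen.WET_DAY_THRESHOLD_MM).groupby(
            s["month"]).mean().to_numpy()
        assert np.all(wet <= occ)
        assert np.all(np.abs(wet - pi) < 0.04)

    def test_rejects_zero_years(self, baseline_clim):
        with pytest.raises(ValueError):
            ax.generate_series(baseline_clim, 0, seed=1)


class TestFitting:
    def test_recovers_generating_parameters(self, baseline_clim):
        """Monte Carlo: parameters fitted from 500 generated years sit within
        sampling error (plus the documented trace-rain reclassification
        effect) of the generating parameters."""
        s = ax.generate_series(baseline_clim, 500, seed=31)
        fit = ax.fit_climatology(s, latitude=baseline_clim.latitude)
        assert np.allclose(fit.tmax_mean_dry, baseline_clim.tmax_mean_dry, atol=0.3)
        assert np.allclose(fit.tmin_mean_wet, baseline_clim.tmin_mean_wet, atol=0.3)
        assert np.allclose(fit.tmax_sd_dry, baseline_clim.tmax_sd_dry, atol=0.3)
        assert np.allclose(fit.p_wet_wet, baseline_clim.p_wet_wet, atol=0.05)
        assert np.allclose(fit.p_wet_dry, baseline_clim.p_wet_dry, atol=0.05)
        # Expected totals are insensitive to the wet-day classification detail.
        assert np.allclose(fit.expected_monthly_precip(),
                           baseline_clim.expected_monthly_precip(), rtol=0.08)

    def test_round_trip_monthly_mean_tmax(self, baseline_clim):
        """Fit from a 30-year fixture, regenerate at large N: monthly mean
        tmax agrees with the fixture to < 0.2 degC."""
        fixture = ax.generate_series(baseline_clim, 30, seed=37)
        fit = ax.fit_climatology(fixture, latitude=baseline_clim.latitude)
        regen = ax.generate_series(fit, 3000, seed=41)
        a = fixture.groupby("month")["tmax"].mean()
        b = regen.groupby("month")["tmax"].mean()
        assert np.all(np.abs(a - b) < 0.2)

    def test_constant_weather_degenerates_cleanly(self):
        n = 12 * 365
        df = pd.DataFrame({
            "year": np.repeat(np.arange(12), 365),
            "month": np.tile(wxgen.MONTH_OF_DOY + 1, 12),
            "doy": np.tile(np.arange(1, 366), 12),
            "tmax": 15.0, "tmin": 5.0, "precip": 0.0, "sun_hours": 4.0,
        })
        assert len(df) == n
        with pytest.warns(UserWarning, match="wet days"):
            fit = ax.fit_climatology(df, latitude=52.0)
        assert np.all(fit.p_wet_wet == 0)
        assert np.all(fit.p_wet_dry == 0)
        assert np.all(fit.tmax_sd_dry == 0)
        assert np.all(fit.tmax_mean_dry == 15.0)

    def test_requires_ten_years(self, baseline_clim):
        s = ax.generate_series(baseline_clim, 5, seed=1)
        with pytest.raises(ValueError, match="10"):
            ax.fit_climatology(s, latitude=52.0)


class TestChangeFactors:
    def test_neutral_is_identity(self, baseline_clim):
        out = ax.apply_change_factors(baseline_clim, wxgen.ChangeFactorSet.neutral())
        for name in wxgen._CLIM_ARRAY_FIELDS:
            assert np.array_equal(getattr(out, name), getattr(baseline_clim, name))

    def test_expected_precip_scales_exactly(self, baseline_clim):
        rng = np.random.default_rng(5)
        ratio = rng.uniform(0.5, 1.5, 12)
        cf = wxgen.ChangeFactorSet("x", "RCP8.5", "2050",
                                   np.zeros(12), np.zeros(12), ratio)
        out = ax.apply_change_factors(baseline_clim, cf)
        assert np.allclose(out.expected_monthly_precip(),
                           ratio * baseline_clim.expected_monthly_precip(),
                           rtol=1e-12)

    def test_temperature_shift_is_exact_with_paired_seed(self, baseline_clim):
        dt = np.zeros(12)
        dt[7] = 3.0  # +3 degC August tmax
        cf = wxgen.ChangeFactorSet("x", "RCP8.5", "2050",
                                   dt, np.zeros(12), np.ones(12))
        shifted = ax.apply_change_factors(baseline_clim, cf)
        a = ax.generate_series(baseline_clim, 20, seed=9)
        b = ax.generate_series(shifted, 20, seed=9)
        aug = a["month"] == 8
        delta = b.loc[aug, "tmax"] - a.loc[aug, "tmax"]
        # tmin clipping to tmax can nudge a handful of days; the mean is exact
        # to well under a hundredth of a degree.
        assert delta.mean() == pytest.approx(3.0, abs=0.01)
        other = b.loc[~aug, "tmax"] - a.loc[~aug, "tmax"]
        assert np.abs(other).max() < 1e-12

    def test_precip_ratio_scales_july_with_paired_seed(self, baseline_clim):
        ratio = np.ones(12)
        ratio[6] = 0.8
        cf = wxgen.ChangeFactorSet("x", "RCP8.5", "2050",
                                   np.zeros(12), np.zeros(12), ratio)
        a = ax.generate_series(baseline_clim, 50, seed=13)
        b = ax.generate_series(ax.apply_change_factors(baseline_clim, cf),
                               50, seed=13)
        jul = a["month"] == 7
        assert b.loc[jul, "precip"].sum() == pytest.approx(
            0.8 * a.loc[jul, "precip"].sum(), rel=1e-9)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError, match="precip_ratio"):
            wxgen.ChangeFactorSet("x", "s", "p", np.zeros(12), np.zeros(12),
                                  np.full(12, -0.1))


class TestSyntheticEnsemble:
    def test_envelope_and_labels(self):
        members = ax.make_synthetic_ensemble(seed=2, n_members=16)
        assert len(members) == 16
        assert len({m.gcm_id for m in members}) == 16
        assert any("wet" in m.gcm_id for m in members)
        assert any("dry" in m.gcm_id for m in members)
        for m in members:
            # Midwinter and midsummer hit the seasonal extremes; every other
            # month interpolates between them, so global bounds follow.
            assert 0.90 - 1e-9 <= m.precip_ratio[0] <= 1.40 + 1e-9   # Jan
            assert 0.70 - 1e-9 <= m.precip_ratio[6] <= 1.30 + 1e-9   # Jul
            assert np.all(m.precip_ratio >= 0.70 - 1e-9)
            assert np.all(m.precip_ratio <= 1.40 + 1e-9)
            assert 0.2 - 1e-9 <= m.annual_mean_warming() <= 3.0 + 1e-9

    def test_no_member_exceeds_3_degrees_annual_warming(self):
        for m in ax.make_synthetic_ensemble(seed=8, n_members=16):
            assert m.annual_mean_warming() <= 3.0 + 1e-9

    def test_single_member_is_neutral(self):
        (m,) = ax.make_synthetic_ensemble(seed=2, n_members=1)
        assert np.all(m.dtmax == 0) and np.all(m.dtmin == 0)
        assert np.all(m.precip_ratio == 1)

    def test_deterministic(self):
        a = ax.make_synthetic_ensemble(seed=4, n_members=8)
        b = ax.make_synthetic_ensemble(seed=4, n_members=8)
        for x, y in zip(a, b):
            assert np.array_equal(x.precip_ratio, y.precip_ratio)


def _series_with(n_years=12, seed=0, clim=None):
    clim = clim or ax.synthetic_site_climatology()
    return ax.generate_series(clim, n_years, seed)


class TestQC:
    def test_clean_series_untouched(self):
        s = _series_with()
        out, report = ax.qc_series(s, latitude=52.0)
        assert report.n_flagged == 0
        assert report.fraction_flagged == 0.0
        assert np.allclose(out["tmax"], s["tmax"])

    def test_inverted_temperatures_flagged_and_filled(self):
        s = _series_with()
        i = 500
        s.loc[i, "tmax"], s.loc[i, "tmin"] = 2.0, 8.0
        out, report = ax.qc_series(s, latitude=52.0)
        assert report.flags_by_rule["tmax_lt_tmin"] == 1
        assert report.fraction_flagged == pytest.approx(1 / len(s))
        assert out.loc[i, "tmax"] >= out.loc[i, "tmin"]
        # filled with the calendar-day climatology of the other years
        same_doy = s[(s["doy"] == s.loc[i, "doy"]) & (s.index != i)]
        assert out.loc[i, "tmax"] == pytest.approx(same_doy["tmax"].mean())

    def test_negative_precip_flagged(self):
        s = _series_with()
        s.loc[100, "precip"] = -3.0
        out, report = ax.qc_series(s, latitude=52.0)
        assert report.flags_by_rule["negative_precip"] == 1
        assert out.loc[100, "precip"] >= 0

    def test_excess_missing_rejects_site(self):
        s = _series_with()
        k = int(0.12 * len(s))
        s.loc[s.index[:k], "precip"] = np.nan
        with pytest.raises(wxgen.SiteRejectedError, match="precip"):
            ax.qc_series(s, latitude=52.0)


class TestCSV:
    def test_weather_round_trip_drops_feb29(self, tmp_path):
        s = _series_with(n_years=2)
        p = tmp_path / "w.csv"
        wxgen.write_weather_csv(s, p)
        back = wxgen.read_weather_csv(p)
        assert len(back) == len(s)
        assert np.allclose(back["tmax"], np.round(s["tmax"], 4))
        # a hand-written file with a leap day
        txt = "date,tmax,tmin,precip,sun_hours\n" \
              "2000-02-28,5,1,0,2\n2000-02-29,5,1,0,2\n2000-03-01,6,2,1,3\n"
        p2 = tmp_path / "leap.csv"
        p2.write_text(txt)
        df = wxgen.read_weather_csv(p2)
        assert len(df) == 2
        assert list(df["doy"]) == [59, 60]

    def test_unparseable_date_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("date,tmax,tmin,precip,sun_hours\n"
                     "2000-01-01,5,1,0,2\nnot-a-date,5,1,0,2\n")
        with pytest.raises(ValueError, match="line 3"):
            wxgen.read_weather_csv(p)

    def test_change_factor_round_trip(self, tmp_path):
        members = ax.make_synthetic_ensemble(seed=3, n_members=4)
        p = tmp_path / "cf.csv"
        wxgen.write_change_factor_csv(members, p)
        back = wxgen.read_change_factor_csv(p)
        assert [m.gcm_id for m in back] == [m.gcm_id for m in members]
        for x, y in zip(members, back):
            assert np.allclose(x.precip_ratio, y.precip_ratio)
            assert x.co2_ppm == y.co2_ppm

    def test_climatology_dict_round_trip(self, baseline_clim):
        back = wxgen.SiteClimatology.from_dict(baseline_clim.to_dict())
        assert np.allclose(back.precip_scale, baseline_clim.precip_scale)
        assert back.latitude == baseline_clim.latitude
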