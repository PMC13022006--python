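"""Buoyancy frequency, mixed layer, nutriclines, NAI and oxygen saturation."""

import math

import numpy as np
import pandas as pd
import pytest

from plumetroph import (
    buoyancy_frequency,
    cline_depth,
    mixed_layer_depth,
    nai,
    o2_saturation,
    plume_thickness,
    sigma_theta,
    station_features,
)
from plumetroph.hydro import G, RHO0


class TestBuoyancyFrequency:
    def test_uniform_density_gives_zero(self):
        prof = pd.DataFrame({"depth": [0, 10, 20, 30], "temperature": 28.0,
                             "salinity": 35.0, "sigma_theta": 23.0})
        bv = buoyancy_frequency(prof)
        np.testing.assert_array_equal(bv["n2"].to_numpy(), 0.0)

    def test_two_layer_profile_has_single_spike(self, two_layer_cast):
        bv = buoyancy_frequency(two_layer_cast)
        n2 = bv["n2"].to_numpy()
        assert (n2 > 0).sum() == 1
        spike = bv.loc[bv["n2"].idxmax()]
        assert spike["depth"] == pytest.approx(20.5)
        assert spike["n2"] == pytest.approx(G / RHO0 * 2.0)

    def test_linear_density_gives_constant_n2(self):
        z = np.linspace(0, 100, 21)
        slope = 0.03  # kg m-3 per m
        prof = pd.DataFrame({"depth": z, "temperature": 20.0, "salinity": 35.0,
                             "sigma_theta": 22.0 + slope * z})
        n2 = buoyancy_frequency(prof)["n2"].to_numpy()
        np.testing.assert_allclose(n2, G / RHO0 * slope, rtol=1e-12)

    def test_stable_stratification_is_nonnegative(self, rng):
        sig = np.sort(22 + rng.random(30) * 4)
        prof = pd.DataFrame({"depth": np.arange(30.0), "temperature": 20.0,
                             "salinity": 35.0, "sigma_theta": sig})
        assert (buoyancy_frequency(prof)["n2"].to_numpy() >= 0).all()

    def test_too_few_levels_rejected(self):
        prof = pd.DataFrame({"depth": [0, 10], "temperature": 20.0,
                             "salinity": 35.0, "sigma_theta": [22, 23]})
        with pytest.raises(ValueError):
            buoyancy_frequency(prof)

    def test_sigma_computed_from_t_s_when_absent(self):
        prof = pd.DataFrame({"depth": [0.0, 10.0, 20.0],
                             "temperature": [29.0, 28.0, 20.0],
                             "salinity": [30.0, 32.0, 36.0]})
        n2 = buoyancy_frequency(prof)["n2"].to_numpy()
        assert (n2 > 0).all()  # warm fresh over cold salty is stable


class TestSigmaTheta:
    def test_standard_seawater_value(self):
        # one-atmosphere check value: rho(25 degC, S=35) = 1023.343 kg m-3
        assert sigma_theta(25.0, 35.0) == pytest.approx(23.343, abs=0.01)

    def test_fresher_is_lighter(self):
        assert sigma_theta(28.0, 25.0) < sigma_theta(28.0, 36.0)


class TestMixedLayerDepth:
    def test_two_layer_recovers_pycnocline(self, two_layer_cast):
        bv = buoyancy_frequency(two_layer_cast)
        assert mixed_layer_depth(bv) == pytest.approx(20.5)

    def test_monotone_n2_gives_deepest_midpoint(self):
        depths = np.array([5.0, 15.0, 25.0])
        assert mixed_layer_depth(np.array([0.001, 0.002, 0.003]), depths) == 25.0

    def test_constant_positive_n2_ties_to_shallowest(self):
        depths = np.array([5.0, 15.0, 25.0])
        assert mixed_layer_depth(np.array([0.01, 0.01, 0.01]), depths) == 5.0

    def test_all_zero_n2_is_missing(self):
        assert math.isnan(mixed_layer_depth(np.zeros(3), np.array([5.0, 15.0, 25.0])))

    def test_first_local_maximum_option(self):
        depths = np.array([5.0, 15.0, 25.0, 35.0])
        n2 = np.array([0.001, 0.01, 0.002, 0.02])
        assert mixed_layer_depth(n2, depths) == 35.0
        assert mixed_layer_depth(n2, depths, method="first_local") == 15.0


class TestClineDepth:
    def test_surface_exceeding_threshold_is_zero(self):
        assert cline_depth([0, 10], [1.5, 3.0], 1.0) == 0.0

    def test_linear_interpolation(self):
        assert cline_depth([10, 20], [0.5, 1.5], 1.0) == pytest.approx(15.0)

    def test_never_reached_is_missing(self):
        assert math.isnan(cline_depth([0, 50], [0.2, 0.8], 1.0))

    def test_zero_threshold_is_surface(self):
        assert cline_depth([0, 10], [0.0, 5.0], 0.0) == 0.0

    def test_missing_levels_dropped(self):
        assert cline_depth([0, 5, 10, 20], [0.5, np.nan, 0.5, 1.5], 1.0) == pytest.approx(15.0)


class TestNai:
    def test_replete_surface_branch(self):
        prof = pd.DataFrame({"depth": [0, 20], "nox": [2.4, 5.0]})
        assert nai(prof) == pytest.approx(2.4)

    def test_nitracline_branch_interpolates(self):
        prof = pd.DataFrame({"depth": [0, 40, 60], "nox": [0.2, 1.0, 3.0]})
        assert nai(prof) == pytest.approx(-50.0)

    def test_bottom_branch(self):
        prof = pd.DataFrame({"depth": [0, 60, 120], "nox": [0.2, 0.5, 1.5]})
        assert nai(prof) == pytest.approx(-120.0)

    def test_bottom_depth_column_honoured(self):
        prof = pd.DataFrame({"depth": [0, 60], "nox": [0.2, 1.5], "bottom_depth": 150.0})
        assert nai(prof) == pytest.approx(-150.0)

    def test_shares_interpolation_with_cline_depth(self):
        depth, nox = [0, 40, 60], [0.2, 1.0, 3.0]
        prof = pd.DataFrame({"depth": depth, "nox": nox})
        assert nai(prof) == pytest.approx(-cline_depth(depth, nox, 2.0))

    def test_missing_surface_is_missing(self):
        assert math.isnan(nai(pd.DataFrame({"depth": [0], "nox": [np.nan]})))


class TestO2Saturation:
    def test_monotone_decreasing_in_temperature(self):
        assert o2_saturation(25, 35) < o2_saturation(15, 35)

    def test_monotone_decreasing_in_salinity(self):
        assert o2_saturation(20, 36) < o2_saturation(20, 34)

    def test_against_independent_fit_transcription(self):
        """Cross-check against the mL/L-unit combined fit (44.6596 µmol/mL)."""
        a = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
        b = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
        c0 = -4.88682e-7
        for t, s in [(20.0, 35.0), (28.0, 30.0), (10.0, 36.0)]:
            ts = math.log((298.15 - t) / (273.15 + t))
            ln_c = sum(ai * ts**i for i, ai in enumerate(a))
            ln_c += s * sum(bi * ts**i for i, bi in enumerate(b))
            ln_c += c0 * s**2
            ml_per_l = math.exp(ln_c)
            mm_oracle = ml_per_l * 44.6596 / 1000.0  # µmol/L -> mM
            assert o2_saturation(t, s) == pytest.approx(mm_oracle, rel=1e-3)

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            o2_saturation(45.0, 35.0)


class TestPlumeThickness:
    def test_oceanic_surface_has_no_plume(self):
        prof = pd.DataFrame({"depth": [0, 20], "salinity": [36.0, 36.2]})
        assert math.isnan(plume_thickness(prof))

    def test_interpolated_halocline(self):
        prof = pd.DataFrame({"depth": [0, 10, 20], "salinity": [30.0, 30.0, 36.0]})
        # crossing 35 between (10 m, S=30) and (20 m, S=36)
        assert plume_thickness(prof) == pytest.approx(10 + 10 * (35 - 30) / (36 - 30))

    def test_entirely_fresh_cast_extends_to_bottom(self):
        prof = pd.DataFrame({"depth": [0, 50, 100], "salinity": [20.0, 25.0, 30.0]})
        assert plume_thickness(prof) == 100.0


class TestStationFeatures:
    def test_synthetic_cast_populates_all_fields(self, scenario):
        from plumetroph import gen_ctd_cast

        ctd, nut = gen_ctd_cast(scenario, mld=20.0)
        feats = station_features(ctd, nut, surface_chla=0.5)
        assert feats["mld"] == pytest.approx(20.0, abs=scenario.grid_dz)
        assert feats["mld"] == feats["n2_max_depth"]
        for key in ("n2_max", "nai", "nitracline", "phosphocline", "silicacline",
                    "plume_thickness", "surface_oxygen", "o2_saturation",
                    "surface_temperature", "surface_salinity", "dcm_depth",
                    "surface_chla"):
            assert np.isfinite(feats[key]), key

    def test_oceanic_cast_hits_bottom_nai_branch(self, scenario):
        from plumetroph import gen_ctd_cast

        ctd, nut = gen_ctd_cast(scenario, surface_nox=0.1, deep_nox=1.5, oceanic=True)
        feats = station_features(ctd, nut)
        assert feats["nai"] == pytest.approx(-scenario.bottom_depth)
        assert math.isnan(feats["plume_thickness"])

    def test_missing_oxygen_sensor_tolerated(self, two_layer_cast):
        feats = station_features(two_layer_cast.drop(columns=[]), None)
        assert math.isnan(feats["surface_oxygen"])
        assert math.isnan(feats["nai"])
        assert np.isfinite(feats["mld"])
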