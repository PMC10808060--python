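"""Production, TFP calibration, simulation, impacts and distribution."""

import numpy as np
import pandas as pd
import pytest

import natcapclim as nc
from natcapclim import economy
from natcapclim.economy import (
    UnidentifiedError,
    assign_country_elasticities,
    calibrate_elasticities,
    calibrate_tfp,
    damage_distribution,
    es_flow,
    gdp,
    impacts,
    simulate,
    step_capital,
)
from natcapclim.synthetic_data import PlantedTruth, WorldConfig, with_noiseless


@pytest.fixture(scope="module")
def big_panel_world():
    """40 countries x 20 years, noiseless production structure."""
    cfg = WorldConfig(n_lat=18, n_lon=40, n_countries=40, n_biomes=3, seed=21)
    truth = with_noiseless(PlantedTruth())
    world = nc.make_world(cfg, truth)
    return world, nc.make_accounts(world, truth)


class TestCalibrateElasticities:
    def test_noiseless_exact_recovery(self, big_panel_world):
        world, acc = big_panel_world
        fit = calibrate_elasticities(acc.panel)
        truth = world.truth
        assert fit.gamma1 == pytest.approx(truth.gamma1, abs=1e-6)
        for region, b in fit.b_region.items():
            assert b == pytest.approx(truth.b_region[region], abs=1e-6)
        # the panel plants the mean timber share as the common elasticity
        assert fit.gamma3 == pytest.approx(acc.accounts["gamma3"].mean(),
                                           abs=1e-6)

    def test_noisy_recovery_within_two_se(self):
        cfg = WorldConfig(n_lat=18, n_lon=40, n_countries=40, n_biomes=3,
                          seed=5)
        truth = PlantedTruth(gdp_noise_sd=0.02)
        world = nc.make_world(cfg, truth)
        acc = nc.make_accounts(world, truth)
        # conventional OLS covariance: with only five macro regions the
        # clustered covariance is unreliable for a coverage check.  Six
        # coefficients are asserted jointly, so the per-coefficient bound is
        # 3 SE (multiplicity), with most b's additionally within 2 SE.
        fit = calibrate_elasticities(acc.panel, cluster_by_region=False)
        assert abs(fit.gamma1 - truth.gamma1) < 3 * fit.se["g1"]
        n_within_2se = 0
        for region, b in fit.b_region.items():
            dev = abs(b - truth.b_region[region])
            assert dev < 3 * fit.se[f"b[{region}]"]
            n_within_2se += dev < 2 * fit.se[f"b[{region}]"]
        assert n_within_2se >= 4

    def test_null_b_recovered(self):
        cfg = WorldConfig(n_lat=12, n_lon=24, n_countries=20, n_biomes=2,
                          seed=9)
        truth = PlantedTruth(gdp_noise_sd=0.02,
                             b_region={r: 0.0 for r in
                                       ("ASIA", "LAM", "MAF", "OECD", "REF")})
        world = nc.make_world(cfg, truth)
        acc = nc.make_accounts(world, truth)
        fit = calibrate_elasticities(acc.panel)
        for region, b in fit.b_region.items():
            assert abs(b) < 2 * fit.se[f"b[{region}]"] + 5e-3

    def test_constant_global_stock_unidentified(self, big_panel_world):
        _, acc = big_panel_world
        panel = acc.panel.copy()
        panel["global_nonmarket"] = 1e12
        with pytest.raises(UnidentifiedError):
            calibrate_elasticities(panel)


class TestElasticityAssignment:
    def test_hand_example(self):
        g3, g2 = assign_country_elasticities(0.004, 0.5)
        assert g3 == 0.004 and g2 == pytest.approx(0.496)

    def test_zero_share(self):
        g3, g2 = assign_country_elasticities(0.0, 0.5)
        assert g3 == 0.0 and g2 == 0.5

    def test_crs_holds_for_random_shares(self, rng):
        for share in rng.uniform(0.0, 0.4, 50):
            g3, g2 = assign_country_elasticities(share, 0.5)
            assert 0.5 + g2 + g3 == pytest.approx(1.0, abs=1e-14)

    def test_infeasible_share_rejected(self):
        with pytest.raises(ValueError):
            assign_country_elasticities(0.6, 0.5)


class TestProduction:
    def test_all_unit_inputs_return_tfp(self):
        assert gdp(2.5, 1, 1, 1, 1, 0.5, 0.45, 0.05, 0.2) == 2.5

    def test_labour_homogeneity(self):
        base = gdp(1.0, 2.0, 4.0, 3.0, 1.0, 0.5, 0.45, 0.05, 0.2)
        double = gdp(1.0, 2.0, 8.0, 3.0, 1.0, 0.5, 0.45, 0.05, 0.2)
        assert double == pytest.approx(base * np.sqrt(2), rel=1e-12)

    def test_crs_scaling_of_private_factors(self):
        lam = 3.7
        base = gdp(1.0, 5.0, 2.0, 3.0, 0.5, 0.5, 0.45, 0.05, 0.2)
        scaled = gdp(1.0, 5.0, 2.0 * lam, 3.0 * lam, 0.5 * lam,
                     0.5, 0.45, 0.05, 0.2)
        assert scaled == pytest.approx(lam * base, rel=1e-12)

    def test_matches_log_space_oracle(self, rng):
        for _ in range(50):
            tfp, S, L, K, mN = rng.uniform(0.5, 10, 5)
            g1 = rng.uniform(0.2, 0.6)
            g3 = rng.uniform(0.0, 0.1)
            g2 = 1 - g1 - g3
            b = rng.uniform(0.0, 0.6)
            expected = np.exp(np.log(tfp) + b * np.log(S) + g1 * np.log(L)
                              + g2 * np.log(K) + g3 * np.log(mN))
            assert gdp(tfp, S, L, K, mN, g1, g2, g3, b) == \
                pytest.approx(expected, rel=1e-12)

    def test_zero_input_with_positive_exponent_gives_zero(self):
        assert gdp(1.0, 1.0, 0.0, 1.0, 1.0, 0.5, 0.45, 0.05, 0.2) == 0.0

    def test_zero_input_with_zero_exponent_is_neutral(self):
        assert gdp(1.0, 1.0, 1.0, 1.0, 0.0, 0.5, 0.5, 0.0, 0.2) == 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            gdp(1.0, 1.0, -1.0, 1.0, 1.0, 0.5, 0.45, 0.05, 0.2)


class TestStepCapital:
    def test_no_saving_no_depreciation_identity(self):
        assert step_capital(100.0, 50.0, 0.0, delta=0.0, step_years=5) == 100.0

    def test_hand_arithmetic(self):
        got = step_capital(100.0, 100.0, 0.25, delta=0.1, step_years=5)
        assert got == pytest.approx(100 * 0.9**5 + 125, rel=1e-12)

    def test_monotone_in_output(self, rng):
        for g1, g2 in rng.uniform(10, 1000, (20, 2)):
            lo, hi = min(g1, g2), max(g1, g2)
            assert step_capital(50.0, lo, 0.2) <= step_capital(50.0, hi, 0.2)

    def test_invalid_savings_rejected(self):
        with pytest.raises(ValueError):
            step_capital(1.0, 1.0, 1.5)


class TestCalibrateTfp:
    def _params(self, countries):
        return pd.DataFrame(
            {"gamma1": 0.5, "gamma2": 0.46, "gamma3": 0.04, "b_r": 0.2},
            index=countries)

    def test_steady_state_gives_constant_tfp(self):
        years = [2015, 2020, 2025, 2030]
        countries = ["A"]
        target = pd.DataFrame({"A": 100.0}, index=years)
        labour = pd.DataFrame({"A": 10.0}, index=years)
        delta, s, step = 0.1, 0.25, 5
        k_ss = step * s * 100.0 / (1 - (1 - delta) ** step)
        tfp, k = calibrate_tfp(target, labour, pd.Series({"A": k_ss}),
                               pd.Series({"A": 5.0}), pd.Series({"A": 50.0}),
                               self._params(countries), savings=s)
        assert tfp["A"].nunique() == 1
        np.testing.assert_allclose(k["A"], k_ss, rtol=1e-12)

    def test_two_period_hand_oracle(self):
        years = [2015, 2020]
        target = pd.DataFrame({"A": [100.0, 110.0]}, index=years)
        labour = pd.DataFrame({"A": [10.0, 10.5]}, index=years)
        k0, mn0, nn0 = 300.0, 5.0, 50.0
        p = self._params(["A"])
        tfp, k = calibrate_tfp(target, labour, pd.Series({"A": k0}),
                               pd.Series({"A": mn0}), pd.Series({"A": nn0}), p)
        k1 = k0 * 0.9**5 + 5 * 0.25 * 100.0
        assert k.loc[2020, "A"] == pytest.approx(k1, rel=1e-12)
        denom = 50.0**0.2 * 10.5**0.5 * k1**0.46 * 5.0**0.04
        assert tfp.loc[2020, "A"] == pytest.approx(110.0 / denom, rel=1e-12)

    def test_nonpositive_target_rejected(self):
        years = [2015]
        target = pd.DataFrame({"A": [0.0]}, index=years)
        labour = pd.DataFrame({"A": [1.0]}, index=years)
        with pytest.raises(ValueError):
            calibrate_tfp(target, labour, pd.Series({"A": 1.0}),
                          pd.Series({"A": 1.0}), pd.Series({"A": 1.0}),
                          self._params(["A"]))


@pytest.fixture(scope="module")
def economy_setup(small_accounts):
    acc = small_accounts.accounts
    traj = small_accounts.trajectories
    years = list(range(2015, 2101, 5))
    labour = traj.pivot(index="year", columns="country",
                        values="labour").loc[years]
    target = traj.pivot(index="year", columns="country",
                        values="gdp_baseline").loc[years]
    pop = traj.pivot(index="year", columns="country",
                     values="population").loc[years]
    tfp, _ = calibrate_tfp(target, labour, acc["manufactured_capital"],
                           acc["market_natcap"], acc["nonmarket_natcap"], acc)
    return acc, labour, target, pop, tfp


def _theta(countries, th_n, th_m):
    rows = []
    for i, c in enumerate(countries):
        rows.append({"country": c, "target": "nN",
                     "theta": th_n if np.isscalar(th_n) else th_n[i]})
        rows.append({"country": c, "target": "mN",
                     "theta": th_m if np.isscalar(th_m) else th_m[i]})
    return pd.DataFrame(rows)


class TestSimulate:
    def test_baseline_reproduces_target_path(self, economy_setup):
        acc, labour, target, _, tfp = economy_setup
        run = simulate(acc, tfp, labour, mode="baseline")
        got = run.pivot(index="year", columns="country", values="gdp")
        np.testing.assert_allclose(got, target.loc[got.index, got.columns],
                                   rtol=1e-10)

    def test_zero_theta_damaged_identical_to_baseline(self, economy_setup):
        acc, labour, _, _, tfp = economy_setup
        path = nc.make_temperature_path(end_warming=4.0)
        base = simulate(acc, tfp, labour, mode="baseline")
        dam = simulate(acc, tfp, labour,
                       theta=_theta(list(tfp.columns), 0.0, 0.0),
                       temp_path=path, mode="damaged")
        for col in ("gdp", "capital", "nonmarket_natcap", "es_flow"):
            assert (base[col].to_numpy() == dam[col].to_numpy()).all()

    def test_damage_scales_stock_by_expected_factor(self, economy_setup):
        acc, labour, _, _, tfp = economy_setup
        path = nc.TemperaturePath(
            pd.Series({y: 2.0 for y in tfp.index}), base_period=(2015, 2015))
        dam = simulate(acc, tfp, labour,
                       theta=_theta(list(tfp.columns), -0.1, 0.0),
                       temp_path=path, mode="damaged")
        got = dam.pivot(index="year", columns="country",
                        values="nonmarket_natcap")
        for c in tfp.columns:
            np.testing.assert_allclose(
                got[c], 0.8 * acc.loc[c, "nonmarket_natcap"], rtol=1e-12)

    def test_more_negative_market_theta_weakly_lowers_gdp(self, economy_setup):
        acc, labour, _, _, tfp = economy_setup
        path = nc.make_temperature_path(end_warming=3.0)
        countries = list(tfp.columns)
        target_country = countries[0]
        results = []
        for th in (0.0, -0.05, -0.15):
            th_m = [th if c == target_country else 0.0 for c in countries]
            run = simulate(acc, tfp, labour,
                           theta=_theta(countries, 0.0, th_m),
                           temp_path=path, mode="damaged")
            results.append(
                run[(run.country == target_country)
                    & (run.year == 2100)]["gdp"].iloc[0])
        assert results[0] >= results[1] >= results[2]
        assert results[2] < results[0]

    def test_extreme_damage_floors_stock_at_zero(self, economy_setup):
        acc, labour, _, _, tfp = economy_setup
        path = nc.TemperaturePath(
            pd.Series({y: 5.0 for y in tfp.index}), base_period=(2015, 2015))
        dam = simulate(acc, tfp, labour,
                       theta=_theta(list(tfp.columns), -1.0, 0.0),
                       temp_path=path, mode="damaged")
        assert (dam["nonmarket_natcap"] == 0.0).all()


class TestEsFlow:
    def test_perpetuity_flow(self):
        assert es_flow(100.0, 0.03, 0.0) == pytest.approx(3.0)

    def test_zero_stock_zero_flow(self):
        assert es_flow(0.0, 0.03, 50.0) == 0.0

    def test_income_growth_adjustment(self):
        assert es_flow(100.0, 0.03, 10.0, 0.00596) == \
            pytest.approx(3.0 * (1 + 0.0596), rel=1e-12)


class TestImpacts:
    def _runs(self, pct):
        base = pd.DataFrame(
            {"year": 2100, "country": ["A", "B"], "gdp": [100.0, 200.0],
             "es_flow": [10.0, 20.0]})
        dam = base.copy()
        dam["gdp"] = base["gdp"] * (1 + np.asarray(pct) / 100)
        dam["es_flow"] = base["es_flow"]
        return base, dam

    def test_identical_runs_zero_impacts(self):
        base, _ = self._runs([0.0, 0.0])
        pop = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=[2100])
        out = impacts(base, base, pop, eval_year=2100)
        assert out.global_pct_gdp == 0.0
        assert (out.by_country["pct_gdp"] == 0.0).all()

    def test_equal_population_mean(self):
        base, dam = self._runs([-10.0, 0.0])
        pop = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=[2100])
        out = impacts(base, dam, pop, eval_year=2100)
        assert out.global_pct_gdp == pytest.approx(-5.0)

    def test_matches_bruteforce_weighted_mean(self, rng):
        for _ in range(20):
            pct = rng.uniform(-20, 5, 2)
            w = rng.uniform(0.5, 5, 2)
            base, dam = self._runs(pct)
            pop = pd.DataFrame({"A": [w[0]], "B": [w[1]]}, index=[2100])
            out = impacts(base, dam, pop, eval_year=2100)
            expected = (pct * w).sum() / w.sum()
            assert out.global_pct_gdp == pytest.approx(expected, rel=1e-9)


class TestDamageDistribution:
    def test_four_country_hand_example(self):
        losses = pd.Series({"p1": 4.0, "p2": 3.0, "p3": 2.0, "p4": 1.0})
        gdppc = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0})
        pop = pd.Series({"p1": 1.0, "p2": 1.0, "p3": 1.0, "p4": 1.0})
        out = damage_distribution(losses, gdppc, pop)
        assert out["bottom_share"] == pytest.approx(0.7)
        assert out["bottom_countries"] == ["p1", "p2"]

    def test_single_damaged_country_all_or_nothing(self):
        losses = pd.Series({"a": 0.0, "b": 5.0, "c": 0.0})
        gdppc = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        pop = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        out = damage_distribution(losses, gdppc, pop, bottom_frac=0.4)
        assert out["bottom_share"] in (0.0, 1.0)

    def test_disjoint_group_shares_sum_below_one(self, rng):
        for _ in range(20):
            n = 10
            idx = [f"c{i}" for i in range(n)]
            losses = pd.Series(rng.uniform(0, 5, n), index=idx)
            gdppc = pd.Series(rng.uniform(1, 50, n), index=idx)
            pop = pd.Series(rng.uniform(1, 9, n), index=idx)
            out = damage_distribution(losses, gdppc, pop,
                                      bottom_frac=0.3, top_frac=0.1)
            if set(out["bottom_countries"]) & set(out["top_countries"]):
                continue
            assert out["bottom_share"] + out["top_share"] <= 1.0 + 1e-12

    def test_gains_excluded_from_shares(self):
        losses = pd.Series({"a": 4.0, "b": -2.0, "c": 1.0})
        gdppc = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        pop = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        out = damage_distribution(losses, gdppc, pop)
        assert out["total_losses"] == 5.0
        assert out["total_gains"] == 2.0

    def test_zero_total_damage_rejected(self):
        losses = pd.Series({"a": 0.0, "b": -1.0})
        gdppc = pd.Series({"a": 1.0, "b": 2.0})
        pop = pd.Series({"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError):
            damage_distribution(losses, gdppc, pop)
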