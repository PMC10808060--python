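"""Subset selection, forest perturbation, apportionment and elasticities."""

import numpy as np
import pandas as pd
import pytest

import natcapclim as nc
from natcapclim import attribution
from natcapclim.attribution import (
    InsufficientDataError,
    NoVegetationError,
    apportion_natcap,
    estimate_elasticities,
    perturbation_values,
    scaling_factors,
    select_subset,
    train_value_model,
)
from natcapclim.synthetic_data import PlantedTruth


@pytest.fixture(scope="module")
def profile(small_vegs):
    cols = attribution.cover_columns(small_vegs)
    return small_vegs[cols].mean()


class TestSelectSubset:
    def test_exact_profile_match_ranks_first(self, small_vegs):
        cols = attribution.cover_columns(small_vegs)
        target = small_vegs[small_vegs.benefit_type == "non-market"].iloc[17]
        sub = select_subset(small_vegs, target[cols], "non-market", k=5)
        assert sub.iloc[0]["record_id"] == target["record_id"]

    def test_k_equal_table_size_is_identity(self, small_vegs, profile):
        nm = small_vegs[small_vegs.benefit_type == "non-market"]
        sub = select_subset(small_vegs, profile, "non-market", k=len(nm))
        assert set(sub["record_id"]) == set(nm["record_id"])

    def test_matches_bruteforce_distance_sort(self, small_vegs, profile, rng):
        cols = attribution.cover_columns(small_vegs)
        nm = small_vegs[small_vegs.benefit_type == "non-market"]
        dists = {
            row["record_id"]: np.sqrt(((row[cols] - profile) ** 2).sum())
            for _, row in nm.iterrows()
        }
        expected = [rid for rid, _ in sorted(dists.items(),
                                             key=lambda kv: (kv[1], kv[0]))][:5]
        sub = select_subset(small_vegs, profile, "non-market", k=5)
        assert list(sub["record_id"]) == expected

    def test_insufficient_records_raise(self, small_vegs, profile):
        tiny = small_vegs.head(5)
        with pytest.raises(InsufficientDataError):
            select_subset(tiny, profile, "non-market", k=30)


class TestValueModel:
    def test_constant_targets_predict_the_constant(self, small_vegs, profile):
        sub = small_vegs[small_vegs.benefit_type == "non-market"].head(30).copy()
        sub["value_per_ha_yr"] = 7.0
        model = train_value_model(sub, seed=0)
        assert model.predict_log_value(profile, 5000.0, 0.5) == pytest.approx(
            np.log(7.0))

    def test_same_seed_same_predictions(self, small_vegs, profile):
        sub = small_vegs[small_vegs.benefit_type == "non-market"]
        m1 = train_value_model(sub, seed=3)
        m2 = train_value_model(sub, seed=3)
        for g in (1000.0, 20000.0):
            assert m1.predict_log_value(profile, g, 0.4) == \
                m2.predict_log_value(profile, g, 0.4)

    def test_perturbation_ignoring_model_gives_equal_values(self, small_vegs,
                                                            profile):
        sub = small_vegs[small_vegs.benefit_type == "non-market"].head(30).copy()
        sub["value_per_ha_yr"] = 7.0
        model = train_value_model(sub, seed=0)
        es_hat = perturbation_values(model, profile, 5000.0, 0.5)
        assert es_hat.nunique() == 1
        assert (es_hat > 0).all()

    def test_more_valuable_biome_wins_perturbation(self, small_world):
        """With the last biome planted twice as valuable per cover point, its
        +10pp perturbation raises the prediction most."""
        weights = np.array([1.0, 1.0, 2.0])
        truth = PlantedTruth(noise_sd=0.2, biome_value_weights=weights * 5)
        vegs = nc.make_vegs_table(small_world, truth, n_obs=600, seed=2)
        nm = vegs[vegs.benefit_type == "non-market"]
        model = train_value_model(nm, seed=0)
        # probe at the lower quartile so the +10pp perturbation stays inside
        # the forest's training support
        profile = nm[attribution.cover_columns(nm)].quantile(0.25)
        es_hat = perturbation_values(model, profile, np.exp(9.0), 0.4)
        assert es_hat["biome_2"] > es_hat["biome_0"]
        assert es_hat["biome_2"] > es_hat["biome_1"]


class TestScalingAndApportionment:
    def test_hand_example(self):
        x = scaling_factors(pd.Series({"b1": 2.0, "b2": 4.0}), "b1")
        assert x["b1"] == 1.0 and x["b2"] == 2.0

    def test_equal_predictions_unit_factors(self):
        x = scaling_factors(pd.Series({"a": 3.0, "b": 3.0, "c": 3.0}), "b")
        assert (x == 1.0).all()

    def test_label_permutation_permutes_factors(self, rng):
        es = pd.Series(rng.uniform(0.5, 5.0, 4),
                       index=["b0", "b1", "b2", "b3"])
        x = scaling_factors(es, "b1")
        perm = ["b2", "b0", "b3", "b1"]
        x_perm = scaling_factors(es.loc[perm], "b1")
        assert (x.loc[perm] == x_perm).all()

    def test_apportionment_hand_computation(self):
        es = apportion_natcap(1000.0, pd.Series({"b1": 10.0, "b2": 20.0}),
                              pd.Series({"b1": 1.0, "b2": 2.0}), r=0.03)
        assert es["b1"] == pytest.approx(0.6)
        assert es["b2"] == pytest.approx(1.2)
        # reconstruction identity
        assert (es * pd.Series({"b1": 10.0, "b2": 20.0})).sum() / 0.03 == \
            pytest.approx(1000.0)

    def test_single_biome_closed_form(self):
        es = apportion_natcap(500.0, pd.Series({"b": 25.0}),
                              pd.Series({"b": 1.0}), r=0.03)
        assert es["b"] == pytest.approx(0.03 * 500.0 / 25.0)

    def test_zero_total_gives_zero_values(self):
        es = apportion_natcap(0.0, pd.Series({"a": 1.0, "b": 2.0}),
                              pd.Series({"a": 1.0, "b": 1.0}))
        assert (es == 0).all()

    def test_no_vegetation_raises(self):
        with pytest.raises(NoVegetationError):
            apportion_natcap(10.0, pd.Series({"a": 0.0}), pd.Series({"a": 1.0}))


class TestElasticities:
    def test_noiseless_exact_recovery(self, small_world):
        truth = PlantedTruth(noise_sd=0.0,
                             biome_value_weights=np.zeros(3))
        vegs = nc.make_vegs_table(small_world, truth, n_obs=200, seed=4)
        est = estimate_elasticities(vegs)
        assert est.coef("non-market", "area") == pytest.approx(-0.103, abs=1e-8)
        assert est.coef("non-market", "carbon") == pytest.approx(0.282, abs=1e-8)
        assert est.coef("non-market", "income") == pytest.approx(0.00596,
                                                                 abs=1e-8)

    def test_null_carbon_elasticity_recovered(self, small_world):
        truth = PlantedTruth(eta_carbon=0.0, noise_sd=0.3)
        vegs = nc.make_vegs_table(small_world, truth, n_obs=1000, seed=9)
        est = estimate_elasticities(vegs)
        coef = est.coef("non-market", "carbon")
        assert abs(coef) < 2 * est.se("non-market", "carbon")

    def test_constant_regressor_raises(self, small_vegs):
        bad = small_vegs.copy()
        bad["carbon_kg_m2"] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            estimate_elasticities(bad)


class TestFullAttribution:
    def test_reconstruction_and_design_count(self, small_vegs, base_areas,
                                             small_accounts):
        """Per-hectare values reconstruct every national stock exactly, and
        the full design trains countries x benefit types x typologies
        models."""
        acc = small_accounts.accounts
        result = attribution.attribute_all(
            small_vegs, base_areas, acc,
            typologies=("lpj", "orchidee", "caraib"), seed=1)
        assert result.n_models == len(acc) * 2 * 3
        amat = base_areas.area_matrix()
        stock = {"non-market": "nonmarket_natcap", "market": "market_natcap"}
        for (typ, country, btype), grp in result.per_hectare.groupby(
                ["typology", "country", "benefit_type"]):
            es = grp.set_index("biome")["value_per_ha_yr"]
            total = (amat.loc[country] * es.loc[amat.columns]).sum() / 0.03
            assert total == pytest.approx(acc.loc[country, stock[btype]],
                                          rel=1e-10)
        assert (result.per_hectare["value_per_ha_yr"] >= 0).all()
        assert (result.scaling.groupby(
            ["typology", "country", "benefit_type"])["x"].max() > 0).all()

    def test_doubling_totals_doubles_values(self, small_vegs, base_areas,
                                            small_accounts):
        acc = small_accounts.accounts
        doubled = acc.copy()
        doubled[["nonmarket_natcap", "market_natcap"]] *= 2.0
        r1 = attribution.attribute_all(small_vegs, base_areas, acc, seed=1)
        r2 = attribution.attribute_all(small_vegs, base_areas, doubled, seed=1)
        np.testing.assert_allclose(r2.per_hectare["value_per_ha_yr"],
                                   2.0 * r1.per_hectare["value_per_ha_yr"],
                                   rtol=1e-12)
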