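"""Carbonate-budget operations against hand-computed and brute-force oracles."""

import math

import numpy as np
import pytest

from reefshield.budget import (
    accretion_potential,
    aggregate_zones,
    apply_zonal_elevation,
    framework_density,
    gross_production,
    parrotfish_bioerosion,
    project_elevation,
    read_ascii_grid,
    site_budget,
    substrate_bioerosion,
    urchin_bioerosion,
    write_ascii_grid,
)
from reefshield.census import (
    FishObservation,
    MissingRateError,
    RateTable,
    UrchinObservation,
    ValidationError,
)
from reefshield.synthetic import SynthParams, gen_census

from conftest import make_site


class TestGrossProduction:
    def test_full_acropora_cover_effective_rate(self, rates):
        G, breakdown = gross_production({"Acropora palmata": 1.0}, rates)
        assert G == pytest.approx(36.24, abs=0.005)
        assert breakdown["Acropora palmata"] == pytest.approx(G)

    def test_zero_coral_cover(self, rates):
        G, _ = gross_production({"sand": 0.7, "dead coral": 0.3}, rates)
        assert G == 0.0

    def test_two_taxon_hand_arithmetic(self):
        # c x r of 5 and 10 at 20 % and 30 % cover: 1.0 + 3.0
        rt = RateTable(
            calcification={"a": 5.0, "b": 5.0},
            rugosity_correction={"b": 2.0},
        )
        G, breakdown = gross_production({"a": 0.2, "b": 0.3}, rt)
        assert G == pytest.approx(4.0, abs=1e-12)
        assert sum(breakdown.values()) == pytest.approx(G, abs=1e-12)

    def test_missing_calcifier_rate_names_taxon(self, rates):
        rt = RateTable(coral_density={"mystery coral": 1500.0})
        with pytest.raises(MissingRateError, match="mystery coral"):
            gross_production({"mystery coral": 0.1}, rt)

    def test_cover_outside_unit_interval_rejected(self, rates):
        with pytest.raises(ValidationError):
            gross_production({"Acropora palmata": 1.2}, rates)


class TestParrotfishBioerosion:
    def test_zero_fish(self, rates):
        assert parrotfish_bioerosion([], rates) == 0.0

    def test_single_fish_hand_arithmetic(self, rates):
        # 1 fish at 120,000 g/ind/y in one 120 m2 belt, none on the other
        obs = [FishObservation("Sparisoma viride", 165, "initial", 1, 1)]
        assert parrotfish_bioerosion(obs, rates, belt_area=120.0) == pytest.approx(0.5)

    def test_transect_exchange_symmetry(self, rates):
        a = [
            FishObservation("Sparisoma viride", 165, "initial", 3, 1),
            FishObservation("Scarus vetula", 210, "terminal", 2, 2),
        ]
        b = [
            FishObservation("Sparisoma viride", 165, "initial", 3, 2),
            FishObservation("Scarus vetula", 210, "terminal", 2, 1),
        ]
        assert parrotfish_bioerosion(a, rates) == parrotfish_bioerosion(b, rates)

    def test_missing_rate_entry_errors(self, rates):
        obs = [FishObservation("Sparisoma viride", 300, "initial", 1, 1)]
        with pytest.raises(MissingRateError):
            parrotfish_bioerosion(obs, rates)

    def test_single_transect_strict_vs_lenient(self, rates):
        obs = [FishObservation("Sparisoma viride", 165, "initial", 1, 1)]
        with pytest.raises(ValidationError):
            parrotfish_bioerosion(obs, rates, n_transects=1, strict=True)
        val = parrotfish_bioerosion(obs, rates, n_transects=1, strict=False)
        assert val == pytest.approx(1.0)  # single-belt value used as-is


class TestUrchinBioerosion:
    def test_zero_urchins(self, rates):
        assert urchin_bioerosion([], rates) == 0.0

    def test_hand_arithmetic_with_reingestion(self, rates):
        # 10 urchins / 10 m2, constant 0.2 kg rate: 1 x 0.2 x 0.57
        obs = [UrchinObservation("Echinometra lucunter", 20, 10)]
        assert urchin_bioerosion(obs, rates, transect_area=10.0) == pytest.approx(0.114)

    def test_linearity_in_counts(self, rates):
        obs = [
            UrchinObservation("Echinometra lucunter", 20, 3),
            UrchinObservation("Diadema antillarum", 60, 2),
        ]
        double = [
            UrchinObservation("Echinometra lucunter", 20, 6),
            UrchinObservation("Diadema antillarum", 60, 4),
        ]
        assert urchin_bioerosion(double, rates) == pytest.approx(
            2 * urchin_bioerosion(obs, rates)
        )

    def test_size_outside_domain_errors(self, rates):
        obs = [UrchinObservation("Diadema antillarum", 200, 1)]  # mid 210 mm
        with pytest.raises(ValidationError):
            urchin_bioerosion(obs, rates)


class TestSubstrateBioerosion:
    @pytest.mark.parametrize(
        "dead,avail,expected",
        [
            (1.0, 1.0, (0.4, 0.27)),
            (0.0, 0.0, (0.0, 0.0)),
            (0.5, 0.5, (0.20, 0.135)),
        ],
    )
    def test_hand_arithmetic(self, rates, dead, avail, expected):
        macro, micro = substrate_bioerosion(dead, avail, rates)
        assert (macro, micro) == pytest.approx(expected)

    def test_fraction_bounds_enforced(self, rates):
        with pytest.raises(ValidationError):
            substrate_bioerosion(1.2, 0.5, rates)


class TestFrameworkDensity:
    def test_single_species_identity(self, rates):
        assert framework_density({"coral B": 0.2}, rates) == 1800.0

    def test_equal_cover_symmetry(self, rates):
        assert framework_density({"Acropora palmata": 0.1, "coral B": 0.1}, rates) == (
            pytest.approx(1650.0)
        )

    def test_weighted_hand_arithmetic(self):
        rt = RateTable(coral_density={"a": 1000.0, "b": 2000.0})
        assert framework_density({"a": 0.1, "b": 0.3}, rt) == pytest.approx(1750.0)

    def test_zero_cover_errors(self, rates):
        with pytest.raises(ValidationError):
            framework_density({}, rates)


class TestAccretionPotential:
    def test_zero_net(self, rates):
        F, A = accretion_potential(0.0, 1670.0, rates)
        assert F == 0.0 and A == 0.0

    def test_positive_branch_multiplier(self, rates):
        F, A = accretion_potential(1.670, 1670.0, rates)
        assert F == pytest.approx(1.0)
        assert A == pytest.approx(100.0 / 49.0)

    def test_negative_net_no_credit(self, rates):
        F, A = accretion_potential(-1.670, 1670.0, rates)
        assert F == pytest.approx(-1.0)
        assert A == F


class TestProjectElevation:
    @pytest.mark.parametrize(
        "rate,year,expected",
        [(7.38, 2100, 0.620), (7.38, 2050, 0.251), (0.0, 2100, 0.0)],
    )
    def test_projection(self, rate, year, expected):
        assert project_elevation(rate, year) == pytest.approx(expected, abs=5e-4)

    def test_past_target_errors(self):
        with pytest.raises(ValidationError):
            project_elevation(1.0, 2000)


class TestSiteBudget:
    def test_all_abiotic_site_micro_only(self, rates):
        site = make_site(images=[{"pavement": 75}] * 10)
        res = site_budget(site, rates, micro_substrate=1.0)
        assert res.gross_production == 0.0
        assert res.parrotfish_bioerosion == 0.0
        assert res.urchin_bioerosion == 0.0
        assert res.macro_bioerosion == 0.0
        assert res.micro_bioerosion == pytest.approx(0.27)
        assert res.accretion_potential < 0
        assert res.framework_density == rates.default_density

    def test_against_brute_force_oracle(self, rates):
        """Budget equals an independent recomputation from raw tallies."""
        site = make_site(
            images=[
                {"Acropora palmata": 15, "coral B": 15, "dead coral": 30, "sand": 15},
                {"crustose coralline algae": 15, "dead coral": 45, "sand": 15},
            ],
            fish=[
                FishObservation("Sparisoma viride", 165, "initial", 2, 1),
                FishObservation("Scarus vetula", 210, "terminal", 1, 2),
            ],
            urchins=[UrchinObservation("Echinometra lucunter", 20, 5)],
        )
        res = site_budget(site, rates)
        # brute force from the raw tallies, written independently
        total_pts = 150
        cov = lambda n: n / total_pts
        G = (
            cov(15) * 10.88 * 3.3309
            + cov(15) * 5.0 * 2.0
            + cov(15) * 1.0 * 1.0
        )
        P = ((2 * 120_000.0) / 120.0 / 1000.0 + (1 * 60_000.0) / 120.0 / 1000.0) / 2
        U = (5 / 10.0) * (200.0 / 1000.0) * 0.57
        dead = cov(75)
        Ma, Mi = dead * 0.4, dead * 0.27
        net = G - (P + U + Ma + Mi)
        assert res.gross_production == pytest.approx(G, abs=1e-12)
        assert res.parrotfish_bioerosion == pytest.approx(P, abs=1e-12)
        assert res.urchin_bioerosion == pytest.approx(U, abs=1e-12)
        assert (res.macro_bioerosion, res.micro_bioerosion) == pytest.approx((Ma, Mi))
        assert res.net_production == pytest.approx(net, abs=1e-12)
        if net > 0:
            D = (0.5 * 1500.0) + (0.5 * 1800.0)  # equal coral covers
            assert res.framework_density == pytest.approx(D)
            assert res.accretion_potential == pytest.approx(
                1000 * net / D * 100 / 49, abs=1e-9
            )

    def test_determinism(self, rates):
        site = make_site(images=[{"Acropora palmata": 30, "sand": 45}])
        assert site_budget(site, rates) == site_budget(site, rates)

    def test_budget_identity_and_eq2_structure_on_synthetic_sites(self, rates):
        """net = G - (P+U+Ma+Mi) to 1e-12 and the exact A/F branch ratio."""
        params = SynthParams(seed=7)
        params.fish_lambda = {("Sparisoma viride", 165, "initial"): 1.0}
        params.urchin_lambda = {("Echinometra lucunter", 20): 2.0}
        sites, _ = gen_census(params)
        rt = rates
        n_pos = 0
        for site in sites[:20]:
            res = site_budget(site, rt)
            assert res.net_production == pytest.approx(
                res.gross_production - res.total_bioerosion, abs=1e-12
            )
            if res.net_production > 0:
                n_pos += 1
                assert res.accretion_potential / res.framework_accretion == (
                    pytest.approx(100.0 / 49.0, abs=1e-12)
                )
            else:
                assert res.accretion_potential == res.framework_accretion

    def test_monotonic_in_coral_cover(self, rates):
        """More live coral (substrate fixed) never lowers accretion potential."""
        low = make_site(images=[{"Acropora palmata": 15, "sand": 30, "dead coral": 30}])
        high = make_site(images=[{"Acropora palmata": 30, "sand": 15, "dead coral": 30}])
        a_low = site_budget(low, rates, micro_substrate=0.4).accretion_potential
        a_high = site_budget(high, rates, micro_substrate=0.4).accretion_potential
        assert a_high >= a_low


class TestAggregateZones:
    def _results(self, rates, values):
        sites, results = [], []
        for i, v in enumerate(values):
            site = make_site(site_id=f"S{i}", images=[{"sand": 75}])
            res = site_budget(site, rates)
            res.accretion_potential = v  # inject known values for the oracle
            sites.append(site)
            results.append(res)
        return results, sites

    def test_closed_form_mean_and_se(self, rates):
        results, sites = self._results(rates, [1.0, 2.0, 3.0])
        df = aggregate_zones(results, sites, include_overall=False)
        row = df.iloc[0]
        assert row["n_sites"] == 3
        assert row["accretion_potential_mean"] == pytest.approx(2.0)
        assert row["accretion_potential_se"] == pytest.approx(
            np.std([1, 2, 3], ddof=1) / math.sqrt(3)
        )
        assert row["accretion_potential_se"] == pytest.approx(0.5774, abs=1e-4)

    def test_single_site_group_flagged(self, rates):
        results, sites = self._results(rates, [1.5])
        df = aggregate_zones(results, sites, include_overall=False)
        assert not df.iloc[0]["se_defined"]
        assert df.iloc[0]["accretion_potential_se"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            aggregate_zones([], [])

    def test_zone_means_recover_generator_truth(self, rates):
        """Gross production per zone within 2 SE of the closed-form expectation."""
        params = SynthParams(seed=11)
        params.fish_lambda = {}
        params.urchin_lambda = {}
        sites, truth = gen_census(params)
        results = [site_budget(s, rates) for s in sites]
        df = aggregate_zones(results, sites, include_overall=True)
        p = truth["cover_probs"]
        expected_G = sum(
            p[t] * rates.calcification[t] * rates.rugosity_correction.get(t, 1.0)
            for t in rates.calcification
            if t in p
        )
        overall = df[df["sector"] == "all"].iloc[0]
        se = max(overall["gross_production_se"], 1e-6)
        assert abs(overall["gross_production_mean"] - expected_G) <= 2 * se


class TestZonalElevation:
    def test_zero_deltas_identity(self):
        bathy = np.arange(9.0).reshape(3, 3)
        zones = np.full((3, 3), "crest")
        out = apply_zonal_elevation(bathy, zones, {"crest": 0.0})
        np.testing.assert_array_equal(out, bathy)

    def test_single_zone_uniform_drop(self):
        bathy = np.zeros((2, 4))
        zones = np.full((2, 4), "crest")
        out = apply_zonal_elevation(bathy, zones, {"crest": -0.13})
        np.testing.assert_allclose(out, -0.13)

    def test_checkerboard_per_cell_oracle(self):
        rng = np.random.default_rng(0)
        bathy = rng.normal(size=(6, 6))
        zones = np.where((np.indices((6, 6)).sum(axis=0) % 2) == 0, "a", "b")
        deltas = {"a": 0.1, "b": -0.2}
        out = apply_zonal_elevation(bathy, zones, deltas)
        for i in range(6):
            for j in range(6):
                assert out[i, j] == pytest.approx(bathy[i, j] + deltas[zones[i, j]])

    def test_unlabelled_and_nodata_cells_unchanged(self):
        bathy = np.array([[1.0, -9999.0], [2.0, 3.0]])
        zones = np.array([["crest", "crest"], ["none", "crest"]])
        out = apply_zonal_elevation(bathy, zones, {"crest": 1.0}, nodata=-9999.0)
        assert out[0, 0] == 2.0
        assert out[0, 1] == -9999.0
        assert out[1, 0] == 2.0

    def test_shape_mismatch_and_unknown_label_error(self):
        with pytest.raises(ValidationError):
            apply_zonal_elevation(np.zeros((2, 2)), np.full((3, 3), "a"), {"a": 0.0})
        with pytest.raises(ValidationError, match="mystery"):
            apply_zonal_elevation(
                np.zeros((2, 2)), np.full((2, 2), "mystery"), {"a": 0.0}
            )

    def test_ascii_grid_round_trip(self, tmp_path):
        arr = np.array([[0.5, -1.25], [3.0, -9999.0]])
        path = tmp_path / "grid.asc"
        write_ascii_grid(arr, path, {"nodata_value": -9999.0, "cellsize": 10.0})
        back, header = read_ascii_grid(path)
        np.testing.assert_allclose(back, arr)
        assert header["cellsize"] == 10.0
        assert header["nodata_value"] == -9999.0
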