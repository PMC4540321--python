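"""Allometric dry-weight models and secondary production."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import treeholes as th


class TestDryWeightModels:
    @pytest.mark.parametrize("fn,args,expected", [
        # hand arithmetic: 40²·1000/1.6e6 = 1 µg wet × 0.25
        (th.dw_volumetric_nematode, (1000, 40, 0.25), 0.25),
        # 0.8·200·50·50 µm³ = 4e5 µm³ → 0.4 µg wet → 0.1 µg dry
        (th.dw_box_volume, (200, 50, 50, 0.25), 0.1),
        # 0.0024 × 10^3.0651
        (th.dw_power_law, (10, 0.0024, 3.0651), 0.0024 * 10 ** 3.0651),
        (th.dw_power_law, (7.3, 1.0, 0.0), 1.0),
        (th.dw_power_law, (1.0, 0.0024, 3.0651), 0.0024),
        # 4.4e3 · e⁴
        (th.dw_exponential, (5, 4.4e3, 0.8), 4.4e3 * math.exp(4.0)),
        (th.dw_exponential, (1, 1.0, math.log(2.0)), 2.0),
    ])
    def test_hand_oracles(self, fn, args, expected):
        assert fn(*args) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn,args", [
        (th.dw_volumetric_nematode, (0, 40, 0.25)),
        (th.dw_volumetric_nematode, (1000, -1, 0.25)),
        (th.dw_box_volume, (0, 50, 50, 0.25)),
        (th.dw_power_law, (-2, 0.0024, 3.0651)),
        (th.dw_exponential, (0, 4.4e3, 0.8)),
    ])
    def test_non_positive_dimension_is_domain_error(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_doubling_width_quadruples_nematode_dw(self):
        base = th.dw_volumetric_nematode(1000, 40, 0.25)
        assert th.dw_volumetric_nematode(1000, 80, 0.25) == pytest.approx(4 * base)

    def test_box_volume_symmetric_in_width_height(self):
        assert th.dw_box_volume(200, 30, 70, 0.2) == pytest.approx(
            th.dw_box_volume(200, 70, 30, 0.2))

    @given(l1=st.floats(0.01, 50), scale=st.floats(1.001, 10))
    @settings(deadline=None, max_examples=50)
    def test_all_models_strictly_increasing_in_length(self, l1, scale):
        l2 = l1 * scale
        assert th.dw_volumetric_nematode(l2 * 1000, 40, 0.25) > \
            th.dw_volumetric_nematode(l1 * 1000, 40, 0.25)
        assert th.dw_box_volume(l2 * 1000, 50, 50, 0.25) > \
            th.dw_box_volume(l1 * 1000, 50, 50, 0.25)
        assert th.dw_power_law(l2, 0.0024, 3.0651) > th.dw_power_law(l1, 0.0024, 3.0651)
        assert th.dw_exponential(l2, 4.4e3, 0.8) > th.dw_exponential(l1, 4.4e3, 0.8)


class TestSizeClasses:
    def test_midpoint_basic(self):
        assert th.size_class_midpoint(0, [0, 0.25, 0.5]) == pytest.approx(0.125)

    def test_nematode_second_class_midpoint(self):
        # class "0.25-<0.5 mm" has representative length 0.375 mm
        edges = th.default_taxa()["Nematoda"].size_class_edges
        assert th.size_class_midpoint(1, edges) == pytest.approx(0.375)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            th.size_class_midpoint(2, [0, 0.25, 0.5])

    def test_degenerate_edges_rejected(self):
        with pytest.raises(ValueError):
            th.size_class_midpoint(0, [1.0, 1.0])


class TestSampleBiomass:
    @pytest.fixture()
    def nematode(self):
        # midpoint 1.0 mm = 1000 µm, width 40 µm → 0.25 µg per individual
        return th.TaxonSpec("Nematoda", "meiofauna", "volumetric_nematode",
                            {"dry_wet_ratio": 0.25, "width_ratio": 0.04},
                            [0.5, 1.5], length_unit_for_formula="um")

    def test_ten_nematodes_areal_normalization(self, nematode):
        cup = th.CupSample("K-O", "T01", "2012-05", {"Nematoda": np.array([10])},
                           th.EnvironmentalRecord(), bottom_area=71.0)
        est = th.sample_biomass(cup, {"Nematoda": nematode})["Nematoda"]
        assert est.dw_per_cup_ug == pytest.approx(2.5)
        assert est.dw_per_100cm2_ug == pytest.approx(2.5 * 100 / 71)

    def test_zero_counts_give_zero_biomass(self, nematode):
        cup = th.CupSample("K-O", "T01", "2012-05", {"Nematoda": np.array([0])},
                           th.EnvironmentalRecord())
        est = th.sample_biomass(cup, {"Nematoda": nematode})["Nematoda"]
        assert est.dw_per_cup_ug == 0.0
        assert est.n_individuals == 0

    def test_additive_over_taxa(self, nematode, rotifer_spec):
        env = th.EnvironmentalRecord()
        mixed = th.CupSample("s", "t", "d", {"Nematoda": np.array([3]),
                                             "Rotifer": np.array([2, 1, 0])}, env)
        single_n = th.CupSample("s", "t", "d", {"Nematoda": np.array([3])}, env)
        single_r = th.CupSample("s", "t", "d", {"Rotifer": np.array([2, 1, 0])}, env)
        specs = {"Nematoda": nematode, "Rotifer": rotifer_spec}
        got = th.sample_biomass(mixed, specs)
        expect = {**th.sample_biomass(single_n, specs),
                  **th.sample_biomass(single_r, specs)}
        for t in got:
            assert got[t].dw_per_cup_ug == pytest.approx(expect[t].dw_per_cup_ug)

    def test_missing_spec_is_configuration_error(self):
        cup = th.CupSample("s", "t", "d", {"Mystery": np.array([1])},
                           th.EnvironmentalRecord())
        with pytest.raises(th.ConfigurationError):
            th.sample_biomass(cup, {})

    def test_mg_output_unit_converted_to_ug(self):
        spec = th.TaxonSpec("fly", "macrofauna", "power_law", {"a": 1.0, "b": 1.0},
                            [1.0, 3.0], dw_output_unit="mg")
        # midpoint 2 mm → 2 mg → 2000 µg
        assert th.individual_dw_ug(spec, 0) == pytest.approx(2000.0)


class TestMaxIndividualDw:
    def test_largest_occupied_class_across_cups(self):
        spec = th.TaxonSpec("fly", "macrofauna", "power_law", {"a": 1.0, "b": 1.0},
                            [1.0, 3.0, 5.0], dw_output_unit="mg")
        env = th.EnvironmentalRecord()
        cups = [
            th.CupSample("s", "t1", "d", {"fly": np.array([2, 0])}, env),
            th.CupSample("s", "t2", "d", {"fly": np.array([0, 1])}, env),
        ]
        # largest occupied class midpoint 4 mm → 4 mg
        assert th.max_individual_dw_mg(cups, spec) == pytest.approx(4.0)

    def test_absent_taxon_rejected(self):
        spec = th.TaxonSpec("fly", "macrofauna", "power_law", {"a": 1.0, "b": 1.0},
                            [1.0, 3.0], dw_output_unit="mg")
        cup = th.CupSample("s", "t", "d", {"fly": np.array([0])},
                           th.EnvironmentalRecord())
        with pytest.raises(ValueError):
            th.max_individual_dw_mg([cup], spec)


class TestFitPowerLaw:
    def test_exact_recovery_of_measured_constants(self):
        lengths = np.linspace(2, 20, 40)
        dws = 0.0024 * lengths ** 3.0651
        fit = th.fit_power_law(lengths, dws)
        assert fit.a == pytest.approx(0.0024, rel=1e-9)
        assert fit.b == pytest.approx(3.0651, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_recovery_simple(self):
        lengths = np.array([1.0, 2.0, 4.0, 8.0])
        fit = th.fit_power_law(lengths, 2.0 * lengths ** 3)
        assert (fit.a, fit.b) == (pytest.approx(2.0), pytest.approx(3.0))

    def test_noisy_recovery_within_band(self):
        # lognormal multiplicative noise σ=0.1, n=40: the slope SE is ~0.02,
        # so every replicate should land within ±0.15 of the true exponent
        rng = np.random.default_rng(42)
        devs = []
        for _ in range(200):
            lengths = rng.uniform(2, 20, size=40)
            dws = 0.0024 * lengths ** 3.0651 * np.exp(rng.normal(0, 0.1, size=40))
            devs.append(abs(th.fit_power_law(lengths, dws).b - 3.0651))
        assert max(devs) <= 0.15

    @pytest.mark.parametrize("lengths,dws", [
        ([1, 2], [1, 2]),
        ([1, -2, 3], [1, 2, 3]),
        ([1, 2, 3], [1, 0, 3]),
    ])
    def test_domain_errors(self, lengths, dws):
        with pytest.raises(ValueError):
            th.fit_power_law(lengths, dws)


class TestAnnualProduction:
    def test_arithmetic_oracle(self):
        # 10^(0.06 + 0.79·0 − 0.16·0 + 0.05·10.1) = 10^0.565
        est = th.annual_production(1.0, 1.0, 10.1, carbon_fraction=1.0)
        assert est.p_dw_g_m2 == pytest.approx(10 ** 0.565, rel=1e-12)

    def test_zero_temperature(self):
        est = th.annual_production(1.0, 1.0, 0.0)
        assert est.p_dw_g_m2 == pytest.approx(10 ** 0.06, rel=1e-12)

    def test_zero_biomass_short_circuits(self):
        assert th.annual_production(0.0, 5.0, 10.1).p_dw_g_m2 == 0.0

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            th.annual_production(-0.1, 1.0, 10.1)

    def test_carbon_is_fraction_of_dry_weight(self):
        est = th.annual_production(2.0, 3.0, 10.1, carbon_fraction=0.5)
        assert est.p_carbon_g_m2 == pytest.approx(0.5 * est.p_dw_g_m2)

    @given(b=st.floats(0.01, 100), scale=st.floats(1.01, 5))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_biomass_and_mmax(self, b, scale):
        base = th.annual_production(b, 1.0, 10.0).p_dw_g_m2
        assert th.annual_production(b * scale, 1.0, 10.0).p_dw_g_m2 > base
        assert th.annual_production(b, scale, 10.0).p_dw_g_m2 < base
        assert th.annual_production(b, 1.0, 12.0).p_dw_g_m2 > base


class TestCommunityProduction:
    def _inputs(self, rows):
        return pd.DataFrame(rows, columns=["taxon", "group", "biomass_g_m2",
                                           "m_max_mg"])

    def test_single_taxon_full_share(self):
        out = th.community_production(
            self._inputs([("a", "meiofauna", 1.0, 1.0)]), 10.1)
        assert out.loc[out.taxon == "a", "share_pct"].item() == pytest.approx(100.0)

    def test_two_identical_taxa_split_evenly(self):
        out = th.community_production(
            self._inputs([("a", "meiofauna", 1.0, 1.0),
                          ("b", "macrofauna", 1.0, 1.0)]), 10.1)
        shares = out[out.group != "all"].set_index("taxon")["share_pct"]
        assert shares["a"] == pytest.approx(50.0)
        assert shares["b"] == pytest.approx(50.0)

    def test_shares_sum_to_100_and_relabel_invariant(self):
        rows = [("a", "meiofauna", 0.3, 0.1), ("b", "macrofauna", 1.2, 8.0),
                ("c", "macrofauna", 0.4, 2.0)]
        out = th.community_production(self._inputs(rows), 10.1)
        per_taxon = out[~out.taxon.str.startswith("TOTAL")]
        assert per_taxon["share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        relabeled = [("c2", r[1], r[2], r[3]) for r in rows[::-1]]
        out2 = th.community_production(self._inputs(relabeled), 10.1)
        assert sorted(per_taxon["share_pct"]) == pytest.approx(
            sorted(out2[~out2.taxon.str.startswith("TOTAL")]["share_pct"]))

    def test_group_totals_partition_overall(self):
        rows = [("a", "meiofauna", 0.3, 0.1), ("b", "macrofauna", 1.2, 8.0)]
        out = th.community_production(self._inputs(rows), 10.1).set_index("taxon")
        assert out.loc["TOTAL", "p_dw_g_m2"] == pytest.approx(
            out.loc["TOTAL_meiofauna", "p_dw_g_m2"]
            + out.loc["TOTAL_macrofauna", "p_dw_g_m2"])
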