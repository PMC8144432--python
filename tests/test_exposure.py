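"""Exposure aggregation: trophic binning, intake allocation, Eq.-1 sums."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mehgrisk as m
from mehgrisk.exposure import GLOBAL

from conftest import random_small_world


class TestBinConcentrations:
    def test_geometric_mean_within_bin(self):
        out = m.bin_concentrations([(3.0, 1.0), (3.2, 100.0)])
        assert set(out) == {m.TrophicBin.TL_25_35}
        assert out[m.TrophicBin.TL_25_35] == pytest.approx(10.0)

    def test_single_sample_identity(self):
        out = m.bin_concentrations([(4.0, 0.3)])
        assert out == {m.TrophicBin.TL_35_45: pytest.approx(0.3)}

    def test_empty_bins_absent_not_zero(self):
        out = m.bin_concentrations([(2.1, 0.05)])
        assert m.TrophicBin.TL_45_5 not in out

    def test_matches_log_space_average_oracle(self):
        rng = np.random.default_rng(42)
        concs = np.exp(rng.uniform(np.log(0.01), np.log(1.0), size=50))
        tls = rng.uniform(3.5, 4.5, size=50)
        expected = math.exp(np.mean(np.log(concs)))  # independent hand computation
        out = m.bin_concentrations(list(zip(tls, concs)))
        assert out[m.TrophicBin.TL_35_45] == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_concentration_naming_sample(self):
        with pytest.raises(ValueError, match="sample 1"):
            m.bin_concentrations([(3.0, 1.0), (3.5, 0.0)])

    def test_rejects_trophic_level_outside_range(self):
        with pytest.raises(ValueError, match="outside"):
            m.bin_concentrations([(5.5, 1.0)])


class TestAllocateFishConsumption:
    def test_proportional_split(self):
        out = m.allocate_fish_consumption(20.0, fractions=(0.1, 0.6, 0.25, 0.05))
        assert [out[b] for b in m.TrophicBin] == pytest.approx([2.0, 12.0, 5.0, 1.0])

    def test_mti_fallback_single_bin(self):
        out = m.allocate_fish_consumption(10.0, mti=3.0)
        assert out[m.TrophicBin.TL_25_35] == pytest.approx(10.0)
        assert sum(out.values()) == pytest.approx(10.0)

    def test_zero_intake_all_zero(self):
        out = m.allocate_fish_consumption(0.0, mti=3.0)
        assert all(v == 0.0 for v in out.values())

    def test_mti_triangular_spread_conserves_total(self):
        out = m.allocate_fish_consumption(10.0, mti=3.0, spread=True)
        assert sum(out.values()) == pytest.approx(10.0)
        assert out[m.TrophicBin.TL_25_35] > out[m.TrophicBin.TL_2_25] > 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fractions": (0.5, 0.5, 0.5, 0.0)},
            {"fractions": (-0.1, 0.6, 0.25, 0.25)},
            {"mti": 5.5},
            {},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            m.allocate_fish_consumption(10.0, **kwargs)


class TestComputeExposure:
    def test_hand_sum_of_products(self, simple_tables):
        intake, conc = simple_tables
        res = m.compute_exposure(intake, conc, "AAA")
        assert res.total == pytest.approx(3.0)
        assert res.by_pathway == pytest.approx(
            {"seafood": 1.0, "freshwater_fish": 1.0, "rice": 1.0}
        )

    def test_zero_intakes_zero_exposure(self, simple_tables):
        _, conc = simple_tables
        intake = m.FoodIntakeTable.from_records(
            [("AAA", "seafood", "2.5-3.5", 0.0), ("AAA", "rice", None, 0.0)]
        )
        assert m.compute_exposure(intake, conc, "AAA").total == 0.0

    def test_missing_country_is_hard_error(self, simple_tables):
        intake, conc = simple_tables
        with pytest.raises(KeyError, match="BBB"):
            m.compute_exposure(intake, conc, "BBB")

    def test_missing_concentration_after_fallback_names_key(self, simple_tables):
        intake, _ = simple_tables
        conc = m.ConcentrationTable.from_records(
            [("GLOBAL", "rice", None, "n/a", 0.005, 2.0)]
        )
        with pytest.raises(KeyError, match="seafood"):
            m.compute_exposure(intake, conc, "AAA")

    def test_farm_fraction_geometric_mixture(self, simple_tables):
        intake, conc = simple_tables
        res = m.compute_exposure(intake, conc, "AAA", farm_fraction=0.5)
        # seafood: exp(0.5 ln 0.05 + 0.5 ln 0.1) * 10
        assert res.by_pathway["seafood"] == pytest.approx(
            10.0 * math.exp(0.5 * math.log(0.05) + 0.5 * math.log(0.1))
        )

    def test_fallback_consistency_with_global_means(self):
        """Dropping a country's own records must reproduce the GLOBAL result."""
        rng = np.random.default_rng(7)
        intake, conc, ff = random_small_world(rng)
        country = intake.countries[0]
        with_own = conc.df
        without_own = m.ConcentrationTable(with_own[with_own["country"] != country])
        global_only = m.ConcentrationTable(with_own[with_own["country"] == GLOBAL])
        a = m.compute_exposure(intake, without_own, country, farm_fraction=ff)
        b = m.compute_exposure(intake, global_only, country, farm_fraction=ff)
        assert a.total == pytest.approx(b.total, rel=1e-12)

    def test_maldives_like_exposure_rank(self, default_world):
        """The calibrated island flagship tops per-capita seafood exposure."""
        frame, _ = m.run_baseline(default_world)
        assert frame.loc["I00", "exposure_seafood"] == pytest.approx(33.0)
        assert frame["exposure_seafood"].idxmax() == "I00"


class TestInvariants:
    def test_additivity_and_homogeneity(self):
        rng = np.random.default_rng(11)
        intake, conc, ff = random_small_world(rng)
        for country in intake.countries:
            res = m.compute_exposure(intake, conc, country, farm_fraction=ff)
            assert res.total == pytest.approx(sum(res.by_pathway.values()), rel=1e-12)
        doubled = m.FoodIntakeTable(intake.df.assign(intake=intake.df["intake"] * 2))
        c0 = intake.countries[0]
        assert m.compute_exposure(doubled, conc, c0, farm_fraction=ff).total == pytest.approx(
            2 * m.compute_exposure(intake, conc, c0, farm_fraction=ff).total, rel=1e-12
        )
        conc2 = m.ConcentrationTable(
            conc.df.assign(concentration=conc.df["concentration"] * 2)
        )
        assert m.compute_exposure(intake, conc2, c0, farm_fraction=ff).total == pytest.approx(
            2 * m.compute_exposure(intake, conc, c0, farm_fraction=ff).total, rel=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pipeline_matches_triple_loop_oracle(self, seed):
        """Eq.-1 pipeline equals an independent triple-loop recomputation."""
        rng = np.random.default_rng(seed)
        intake, conc, ff = random_small_world(rng)
        lookup = {
            (r.country, r.category, r.trophic_bin or None, r.origin): r.concentration
            for r in conc.df.itertuples()
        }

        def conc_of(country, cat, b, origin):
            return lookup.get((country, cat, b, origin), lookup[(GLOBAL, cat, b, origin)])

        for country in intake.countries:
            expected = 0.0
            for r in intake.df[intake.df["country"] == country].itertuples():
                b = r.trophic_bin or None
                if r.category == "rice":
                    c = conc_of(country, "rice", None, "n/a")
                else:
                    f = ff[country]
                    cw = conc_of(country, r.category, b, "wild")
                    cf = conc_of(country, r.category, b, "farm")
                    c = cw if f == 0 else math.exp(f * math.log(cf) + (1 - f) * math.log(cw))
                expected += r.intake * c
            got = m.compute_exposure(intake, conc, country, farm_fraction=ff).total
            assert got == pytest.approx(expected, rel=1e-10)


class TestTables:
    def test_intake_round_trip(self, simple_tables, tmp_path):
        intake, conc = simple_tables
        intake.to_csv(tmp_path / "i.csv")
        conc.to_csv(tmp_path / "c.csv")
        assert m.FoodIntakeTable.from_csv(tmp_path / "i.csv").df.equals(intake.df)
        assert m.ConcentrationTable.from_csv(tmp_path / "c.csv").df.equals(conc.df)

    def test_annual_kg_conversion_constant(self):
        assert 190.0 * m.KG_PER_YEAR_TO_G_PER_DAY == pytest.approx(520.19, abs=0.01)

    def test_rice_rows_must_not_carry_bins(self):
        with pytest.raises(ValueError, match="rice"):
            m.FoodIntakeTable.from_records([("AAA", "rice", "2-2.5", 1.0)])

    def test_concentration_table_requires_global_fallback(self):
        with pytest.raises(ValueError, match="GLOBAL"):
            m.ConcentrationTable.from_records(
                [("AAA", "seafood", "2-2.5", "wild", 0.1, 2.0)]
            )
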