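"""Group-contribution solubility parameters: worked values, hand-summed
oracles, scaling laws and copolymer averaging."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import asdscreen as asd
from asdscreen.errors import (
    ConfigurationError,
    DomainError,
    UnknownGroupError,
    ValidationError,
)
from asdscreen.groups import (
    FedorsEntry,
    GroupContributionTable,
    copolymer_parameters,
    fedors_parameters,
    polymer_chain_volume,
    van_krevelen_parameters,
)

IBU_COUNTS = {"CH3": 3, "CH": 2, "CH2": 1, "phenylene": 1, "COOH": 1}


class TestFedors:
    def test_ibuprofen_matches_published_row_exactly(self, fedors_table):
        """3 CH3 + 2 CH + CH2 + p-phenylene + COOH -> 20.9 MPa^0.5, 195.5 cm3/mol."""
        p = fedors_parameters(IBU_COUNTS, fedors_table)
        assert round(p.delta_total, 1) == 20.9
        assert round(p.molar_volume, 1) == 195.5

    def test_single_group_ratio_identity(self):
        """E numerically equal to V gives delta = 1 exactly."""
        table = GroupContributionTable(
            "fedors", {"X": FedorsEntry(cohesive_energy=16.1, molar_volume=16.1)}
        )
        p = fedors_parameters({"X": 1}, table)
        assert p.delta_total == pytest.approx(1.0, abs=1e-12)
        assert p.molar_volume == pytest.approx(16.1)

    def test_naproxen_against_hand_summed_oracle(self, fedors_table, compounds):
        """Manually summed table rows for the naproxen fragmentation.

        E = 2*4710 + 3430 + 27630 + 3350 + 31940 + 2*4310 + 2*4310 + 1050
            + 2*1670 = 97400 J/mol
        V = 67.0 - 1.0 + 28.5 + 3.8 + 52.4 + 27.0 - 11.0 + 16.0 - 4.4
            = 178.3 cm3/mol
        """
        counts = compounds["NAP"].counts_for("fedors")
        p = fedors_parameters(counts, fedors_table)
        assert p.molar_volume == pytest.approx(178.3, abs=1e-9)
        assert p.delta_total == pytest.approx(math.sqrt(97400 / 178.3), abs=1e-9)

    def test_unknown_group_names_the_label(self, fedors_table):
        with pytest.raises(UnknownGroupError, match="quux"):
            fedors_parameters({"quux": 1}, fedors_table)

    def test_rejects_empty_and_negative_counts(self, fedors_table):
        with pytest.raises(DomainError):
            fedors_parameters({"CH3": 0}, fedors_table)
        with pytest.raises(DomainError):
            fedors_parameters({"CH3": 1, "CH2": -1}, fedors_table)

    def test_nonpositive_total_volume_is_domain_error(self):
        table = GroupContributionTable("fedors", {"C": FedorsEntry(1470, -19.2)})
        with pytest.raises(DomainError):
            fedors_parameters({"C": 2}, table)

    @given(k=st.floats(min_value=0.1, max_value=50))
    def test_scaling_law(self, k):
        """Scaling all counts by k leaves delta unchanged and scales v by k."""
        table = asd.load_bundled_table("fedors")
        base = fedors_parameters(IBU_COUNTS, table)
        scaled = fedors_parameters({g: k * n for g, n in IBU_COUNTS.items()}, table)
        assert scaled.delta_total == pytest.approx(base.delta_total, rel=1e-12)
        assert scaled.molar_volume == pytest.approx(k * base.molar_volume, rel=1e-12)

    def test_units_round_trip(self, fedors_table):
        """delta from (kJ/mol, m^3/mol) after conversion equals delta from
        (J/mol, cm^3/mol) to 1e-9 relative."""
        pairs = [(n, fedors_table[g]) for g, n in IBU_COUNTS.items()]
        e_kj = sum(n * ent.cohesive_energy / 1e3 for n, ent in pairs)
        v_m3 = sum(n * ent.molar_volume / 1e6 for n, ent in pairs)
        # kJ/m^3 = 1e-3 J/cm^3 = 1e-3 MPa
        delta_converted = math.sqrt(e_kj / v_m3 * 1e-3)
        direct = fedors_parameters(IBU_COUNTS, fedors_table).delta_total
        assert delta_converted == pytest.approx(direct, rel=1e-9)


class TestVanKrevelen:
    def test_ibuprofen_components_match_published_row(self, vk_table):
        p = van_krevelen_parameters(IBU_COUNTS, vk_table)
        assert round(p.delta_d, 1) == 17.9
        assert round(p.delta_p, 1) == 2.2
        assert round(p.delta_h, 1) == 7.2
        assert round(p.delta_total, 1) == 19.4

    def test_zero_polar_and_hbond_groups(self, vk_table):
        """Purely dispersive molecule: delta_p = delta_h = 0, total = dispersive."""
        p = van_krevelen_parameters({"CH3": 2, "CH2": 4}, vk_table)
        assert p.delta_p == 0.0
        assert p.delta_h == 0.0
        assert p.delta_total == pytest.approx(p.delta_d, abs=1e-12)

    def test_carbamazepine_against_hand_summed_oracle(self, vk_table, compounds):
        """Manually summed attraction constants for the carbamazepine split.

        Fd = 2*1270 + 2*200 + 20 + 280 + 290 + 190 = 3720
        sum(Fp^2) = 2*110^2 + 800^2 + 770^2 = 1257100
        Eh = 5000 + 8400 + 2000 = 15400;  V = 168.8 cm3/mol
        """
        counts = compounds["CAR"].counts_for("van_krevelen")
        p = van_krevelen_parameters(counts, vk_table)
        assert p.molar_volume == pytest.approx(168.8, abs=1e-9)
        assert p.delta_d == pytest.approx(3720 / 168.8, abs=1e-9)
        assert p.delta_p == pytest.approx(math.sqrt(1257100) / 168.8, abs=1e-9)
        assert p.delta_h == pytest.approx(math.sqrt(15400 / 168.8), abs=1e-9)

    def test_quadrature_identity_for_single_units(self, vk_table, compounds):
        for abbr in ("IBU", "NAP", "CAR", "ITR", "PK30"):
            p = van_krevelen_parameters(compounds[abbr].counts_for("van_krevelen"), vk_table)
            quad = math.sqrt(p.delta_d**2 + p.delta_p**2 + p.delta_h**2)
            assert p.delta_total == pytest.approx(quad, abs=1e-9)

    @given(k=st.floats(min_value=0.2, max_value=20))
    def test_polar_component_scales_inversely_with_sqrt_unit_size(self, k):
        """delta_d and delta_h are intensive under count scaling; delta_p is
        not -- it picks up a factor 1/sqrt(k).  This asymmetry is a property
        of the squared-constant polar convention, asserted explicitly."""
        table = asd.load_bundled_table("van_krevelen")
        base = van_krevelen_parameters(IBU_COUNTS, table)
        scaled = van_krevelen_parameters(
            {g: k * n for g, n in IBU_COUNTS.items()}, table
        )
        assert scaled.delta_d == pytest.approx(base.delta_d, rel=1e-12)
        assert scaled.delta_h == pytest.approx(base.delta_h, rel=1e-12)
        assert scaled.delta_p == pytest.approx(base.delta_p / math.sqrt(k), rel=1e-12)

    def test_method_mismatch_is_configuration_error(self, fedors_table, vk_table):
        with pytest.raises(ConfigurationError):
            van_krevelen_parameters(IBU_COUNTS, fedors_table)
        with pytest.raises(ConfigurationError):
            fedors_parameters(IBU_COUNTS, vk_table)


class TestCopolymers:
    def test_single_unit_identity(self, fedors_table, compounds):
        counts = compounds["PK30"].counts_for("fedors")
        single = fedors_parameters(counts, fedors_table)
        combo = copolymer_parameters([(counts, 1.0)], fedors_table)
        assert combo.delta_total == pytest.approx(single.delta_total, abs=1e-12)
        assert combo.molar_volume == pytest.approx(single.molar_volume, abs=1e-12)

    def test_two_identical_units_symmetry(self, fedors_table, compounds):
        counts = compounds["PK30"].counts_for("fedors")
        single = fedors_parameters(counts, fedors_table)
        combo = copolymer_parameters([(counts, 0.5), (counts, 0.5)], fedors_table)
        assert combo.delta_total == pytest.approx(single.delta_total, abs=1e-12)

    def test_pvpva_reproduces_published_value(self, fedors_table, compounds):
        """Vinylpyrrolidone:vinyl acetate at 0.6:0.4 -> 25.1 MPa^0.5."""
        p = asd.compound_parameters(compounds["PVA"], fedors_table)
        assert p.delta_total == pytest.approx(25.1, abs=0.15)
        assert p.molar_volume == pytest.approx(69.7, abs=0.5)

    def test_fraction_validation(self, fedors_table, compounds):
        counts = compounds["PK30"].counts_for("fedors")
        with pytest.raises(ValidationError):
            copolymer_parameters([(counts, 0.6), (counts, 0.3)], fedors_table)

    def test_unknown_mode_is_configuration_error(self, fedors_table, compounds):
        counts = compounds["PK30"].counts_for("fedors")
        with pytest.raises(ConfigurationError):
            copolymer_parameters([(counts, 1.0)], fedors_table, mode="geometric")

    def test_averaging_modes_agree_on_molar_volume(self, fedors_table, compounds):
        """Volume is linear in counts, so both conventions give the same v;
        the delta values differ (parameters are not linear in counts)."""
        pva = compounds["PVA"]
        units = [
            (u.group_counts["fedors"], u.fraction) for u in pva.repeat_units
        ]
        avg_param = copolymer_parameters(units, fedors_table, mode="parameter_average")
        avg_counts = copolymer_parameters(units, fedors_table, mode="repeat_unit_average")
        assert avg_param.molar_volume == pytest.approx(avg_counts.molar_volume, abs=1e-9)
        assert avg_param.delta_total != pytest.approx(avg_counts.delta_total, abs=1e-3)


class TestChainVolume:
    def test_unit_ratio(self):
        assert polymer_chain_volume(1.0, 1.0) == 1.0

    @pytest.mark.parametrize(
        "abbr, expected",
        [("SOL", 115000 / 1.03), ("HP50", 78000 / 1.82)],
        ids=["soluplus", "hp50"],
    )
    def test_published_polymer_chain_volumes(self, compounds, abbr, expected):
        c = compounds[abbr]
        assert polymer_chain_volume(c.mw, c.true_density) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            polymer_chain_volume(0.0, 1.0)
        with pytest.raises(DomainError):
            polymer_chain_volume(100.0, -1.0)


def test_negative_volume_requires_branching_designation():
    with pytest.raises(ValidationError):
        GroupContributionTable("fedors", {"OH": FedorsEntry(29800, -10.0)})
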