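"""Standard-state energies, activity coefficients, speciation, and dG_r."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poregibbs import (
    METHANOGENESIS,
    SULFATE_REDUCTION,
    Reaction,
    SiteConditions,
    activity_coefficient,
    carbonate_speciation,
    gibbs_energy,
    species_table,
    standard_gibbs_reaction,
)
from poregibbs.errors import MissingSpeciesError, RangeError
from poregibbs.thermo import freshwater_carbonate_constants

R_KJ = 8.31446261815324e-3


class TestSpeciesTable:
    def test_contains_exactly_the_nine_reaction_species(self):
        expected = {"HCO3-", "CO2(aq)", "CO3--", "CH4(aq)", "H2(aq)", "SO4--", "HS-", "H+", "H2O"}
        assert set(species_table()) == expected

    def test_charged_species_have_positive_ion_size(self):
        for sp in species_table().values():
            if sp.charge != 0:
                assert sp.ion_size > 0


class TestReaction:
    def test_builtins_are_balanced(self):
        # construction would raise otherwise; spot-check the coefficients
        assert METHANOGENESIS.stoichiometry["H2(aq)"] == -4
        assert SULFATE_REDUCTION.stoichiometry["H2O"] == 4

    def test_unbalanced_charge_rejected(self):
        with pytest.raises(ValueError, match="charge"):
            Reaction("bad", {"HCO3-": -1, "CH4(aq)": 1})

    def test_unbalanced_elements_rejected(self):
        with pytest.raises(ValueError):
            Reaction("bad", {"H2(aq)": -1, "H2O": 1})

    def test_all_zero_stoichiometry_rejected(self):
        with pytest.raises(ValueError):
            Reaction("null", {"H2O": 0})

    def test_unknown_species_rejected(self):
        with pytest.raises(MissingSpeciesError):
            Reaction("bad", {"acetate-": -1, "H+": 1})


class TestStandardGibbs:
    def test_methanogenesis_at_site_temperature(self):
        # reproduces the reported in-situ standard-state anchor
        assert standard_gibbs_reaction(METHANOGENESIS, 24.0) == pytest.approx(-229.59, abs=1.5)

    def test_reference_temperature_matches_independent_table_sum(self):
        # oracle: spreadsheet-style sum over the bundled CSV, bypassing the API
        from importlib import resources

        with resources.files("poregibbs.data").joinpath("species.csv").open() as fh:
            raw = pd.read_csv(fh).set_index("name")
        nu = METHANOGENESIS.stoichiometry
        expected = sum(c * raw.loc[s, "dG_f_kJ_mol"] for s, c in nu.items())
        assert standard_gibbs_reaction(METHANOGENESIS, 25.0) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("reaction", [METHANOGENESIS, SULFATE_REDUCTION])
    @pytest.mark.parametrize("temperature", [4.0, 24.0, 28.5])
    def test_reversal_antisymmetry(self, reaction, temperature):
        fwd = standard_gibbs_reaction(reaction, temperature)
        rev = standard_gibbs_reaction(reaction.reversed(), temperature)
        assert fwd + rev == pytest.approx(0.0, abs=1e-9)

    def test_temperature_out_of_range(self):
        with pytest.raises(RangeError):
            standard_gibbs_reaction(METHANOGENESIS, 60.0)


class TestActivityCoefficient:
    def test_monovalent_anion_at_study_conditions(self):
        assert activity_coefficient(-1, 0.7, 24.0) == pytest.approx(0.661, rel=0.02)

    def test_neutral_species_is_unity(self):
        assert activity_coefficient(0, 0.7, 24.0) == 1.0

    def test_hand_evaluated_formula(self):
        # independent arithmetic with the documented parameters at 25 C
        A, B, a_ring, bdot, I = 0.5092, 0.3283, 3.787, 0.041, 0.1
        si = math.sqrt(I)
        expected = 10 ** (-A * si / (1 + B * a_ring * si) + bdot * I)
        assert activity_coefficient(-1, 0.1, 25.0) == pytest.approx(expected, rel=1e-6)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(RangeError):
            activity_coefficient(-1, -0.1, 24.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_gamma_decreases_with_ionic_strength(self, i1, i2):
        lo, hi = sorted((i1, i2))
        if hi - lo > 1e-6:
            assert activity_coefficient(-1, hi, 25.0) <= activity_coefficient(-1, lo, 25.0)

    def test_gamma_decreases_with_charge_magnitude(self):
        g1 = activity_coefficient(-1, 0.7, 24.0)
        g2 = activity_coefficient(-2, 0.7, 24.0)
        assert g2 < g1 < 1.2


class TestCarbonateSpeciation:
    def test_bicarbonate_fraction_at_study_conditions(self):
        _, f_hco3, _ = carbonate_speciation(7.2, 24.0, 35.0)
        assert f_hco3 == pytest.approx(0.94, abs=0.01)

    def test_explicit_freshwater_constants(self):
        # hand oracle: 1 / (1 + 10^(pK1-pH) + 10^(pH-pK2))
        _, f_hco3, _ = carbonate_speciation(7.2, 25.0, 0.0, constants=(6.35, 10.33))
        assert f_hco3 == pytest.approx(0.8756, abs=1e-4)

    def test_default_freshwater_branch_is_close_to_classic_constants(self):
        pk1, pk2 = freshwater_carbonate_constants(25.0)
        assert pk1 == pytest.approx(6.35, abs=0.01)
        assert pk2 == pytest.approx(10.33, abs=0.01)

    def test_equal_fractions_at_pk1(self):
        pk1, _ = freshwater_carbonate_constants(25.0)
        f_co2, f_hco3, _ = carbonate_speciation(pk1, 25.0, 0.0)
        assert f_co2 == pytest.approx(f_hco3, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(2.0, 12.0), st.floats(0.0, 35.0), st.floats(0.0, 40.0))
    def test_fractions_sum_to_one_and_are_positive(self, pH, T, S):
        fractions = carbonate_speciation(pH, T, S)
        assert sum(fractions) == pytest.approx(1.0, abs=1e-12)
        assert all(f > 0 for f in fractions)

    def test_salinity_out_of_range(self):
        with pytest.raises(RangeError):
            carbonate_speciation(7.2, 24.0, 55.0)


class TestGibbsEnergy:
    def test_unit_activities_return_standard_value(self):
        acts = {s: 1.0 for s in METHANOGENESIS.stoichiometry}
        assert gibbs_energy(METHANOGENESIS, -229.59, acts, 24.0) == pytest.approx(-229.59)

    def test_worked_porewater_example(self):
        # hand oracle: dG = dG° + RT ln Q with Q assembled term by term
        acts = {"CH4(aq)": 1e-3, "HCO3-": 6.61e-3, "H2(aq)": 5e-10, "H+": 10**-7.2}
        ln_q = (
            math.log(1e-3) - math.log(6.61e-3) - 4 * math.log(5e-10) - math.log(10**-7.2)
        )
        expected = -229.59 + R_KJ * 297.15 * ln_q
        got = gibbs_energy(METHANOGENESIS, -229.59, acts, 24.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(18.3, abs=0.2)  # methane oxidation exergonic

    def test_equilibrium_activities_give_zero(self):
        dg0 = -229.59
        T = 297.15
        # put the whole quotient on H2: Q = a_H2^-4 = exp(-dG0 / RT)
        a_h2 = math.exp(dg0 / (4 * R_KJ * T))
        acts = {"CH4(aq)": 1.0, "HCO3-": 1.0, "H+": 1.0, "H2(aq)": a_h2}
        assert gibbs_energy(METHANOGENESIS, dg0, acts, 24.0) == pytest.approx(0.0, abs=1e-9)

    def test_zero_activity_names_species(self):
        acts = {"CH4(aq)": 0.0, "HCO3-": 1.0, "H2(aq)": 1.0, "H+": 1.0}
        with pytest.raises(RangeError, match="CH4"):
            gibbs_energy(METHANOGENESIS, -229.59, acts, 24.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_chemical_potential_oracle(self, seed):
        # independent path: dG = sum nu_i (mu°_i + RT ln a_i) species by species
        rng = np.random.default_rng(seed)
        T = 24.0
        acts = {s: float(rng.uniform(1e-10, 1.0)) for s in METHANOGENESIS.stoichiometry}
        table = species_table()
        RT = R_KJ * (T + 273.15)
        mu = {
            s: p.dG_formation_ref - p.S_ref * 1e-3 * (T - 25.0)
            for s, p in table.items()
        }
        expected = sum(
            nu * (mu[s] + RT * math.log(acts[s]))
            for s, nu in METHANOGENESIS.stoichiometry.items()
        )
        dg0 = standard_gibbs_reaction(METHANOGENESIS, T)
        assert gibbs_energy(METHANOGENESIS, dg0, acts, T) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_reversal_antisymmetry_with_activities(self, seed):
        rng = np.random.default_rng(seed)
        acts = {s: float(rng.uniform(1e-8, 1.0)) for s in SULFATE_REDUCTION.stoichiometry}
        dg0 = standard_gibbs_reaction(SULFATE_REDUCTION, 24.0)
        fwd = gibbs_energy(SULFATE_REDUCTION, dg0, acts, 24.0)
        rev = gibbs_energy(SULFATE_REDUCTION.reversed(), -dg0, acts, 24.0)
        assert fwd + rev == pytest.approx(0.0, abs=1e-9)


class TestSiteConditions:
    def test_validation(self):
        with pytest.raises(RangeError):
            SiteConditions(temperature=50.0, salinity=35.0)
        with pytest.raises(RangeError):
            SiteConditions(temperature=24.0, salinity=35.0, pH=15.0)
        with pytest.raises(RangeError):
            SiteConditions(temperature=24.0, salinity=35.0, ionic_strength=0.0)
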