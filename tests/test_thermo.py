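"""Thermodynamic core: van't Hoff, Davies, seawater recipe, Fe hydrolysis."""

import math

import numpy as np
import pytest

from fespec import thermo
from fespec.thermo import (
    Component,
    ConfigError,
    MineralPhase,
    Reaction,
    ThermoDataset,
    activity_coefficient,
    adjust_logK_temperature,
    convert_ph_scale,
    fe_prime_solubility,
    inorganic_fe_speciation,
    seawater_major_ions,
)


def _rx(logK, dH, nH=1):
    return Reaction("FeOHx", 3 - nH, {"Fe3": 1, "H": -nH}, logK, dH)


class TestVantHoff:
    @pytest.mark.parametrize("T", [275.0, 298.15, 310.0])
    def test_zero_enthalpy_is_temperature_independent(self, T):
        assert adjust_logK_temperature(_rx(4.0, 0.0), T) == 4.0

    def test_reference_temperature_returns_reference_constant(self):
        assert adjust_logK_temperature(_rx(-2.19, 43000.0), 298.15) == -2.19

    def test_hand_evaluated_correction(self):
        # log10K = 4 - (50000/(R ln10)) (1/278.15 - 1/298.15)
        assert adjust_logK_temperature(_rx(4.0, 50000.0), 278.15) == pytest.approx(
            3.370, abs=1e-3
        )

    def test_monotone_in_inverse_temperature(self):
        rx = _rx(4.0, 50000.0)
        vals = [adjust_logK_temperature(rx, T) for T in (275.0, 285.0, 295.0, 310.0)]
        assert vals == sorted(vals)  # endothermic: K grows with T

    @pytest.mark.parametrize("T", [250.0, 330.0])
    def test_extrapolation_refused(self, T):
        with pytest.raises(ValueError, match="outside supported range"):
            adjust_logK_temperature(_rx(4.0, 1.0), T)


class TestDavies:
    def test_uncharged_species_and_infinite_dilution(self):
        assert activity_coefficient(0, 0.7) == 1.0
        assert activity_coefficient(2, 0.0) == 1.0

    def test_hand_evaluated_monovalent_seawater(self):
        # A(25 degC) = 0.5115
        assert activity_coefficient(1, 0.7, 298.15) == pytest.approx(0.749, abs=2e-3)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            activity_coefficient(1, -0.1)

    def test_charge_symmetry(self):
        assert activity_coefficient(2, 0.5) == activity_coefficient(-2, 0.5)


class TestSeawaterRecipe:
    def test_freshwater_limit(self):
        sw = seawater_major_ions(0.0)
        assert sw.ionic_strength == 0.0
        assert all(v == 0.0 for v in sw.concentrations.values())

    def test_reference_salinity_ionic_strength(self):
        sw = seawater_major_ions(35.0)
        assert 0.68 <= sw.ionic_strength <= 0.74

    def test_linearity_in_salinity(self):
        full = seawater_major_ions(35.0).concentrations
        half = seawater_major_ions(17.5).concentrations
        for ion in full:
            assert half[ion] == pytest.approx(full[ion] / 2.0, rel=1e-14)

    def test_out_of_range_salinity(self):
        with pytest.raises(ValueError):
            seawater_major_ions(50.0)


def toy_dataset(reactions=(), minerals=()):
    comps = (
        Component("Fe3", 3), Component("H", 1), Component("Mg", 2),
        Component("Ca", 2), Component("Na", 1), Component("K", 1),
        Component("Cl", -1), Component("SO4", -2),
    )
    ds = ThermoDataset(comps, tuple(reactions), tuple(minerals))
    ds.validate()
    return ds


class TestInorganicSpeciation:
    def test_no_hydrolysis_reactions(self):
        ds = toy_dataset()
        out = inorganic_fe_speciation(1e-12, 8.0, 10.0, 35.0, ds)
        assert out["Fe_prime"] == 1e-12

    def test_single_reaction_with_unit_conditional_ratio(self):
        # choose logK so that [FeOH]/[Fe3+] = 1 at pH_free 8 (conditional mode)
        rx = Reaction("FeOH", 2, {"Fe3": 1, "H": -1}, -8.0, 0.0)
        ds = toy_dataset([rx])
        out = inorganic_fe_speciation(
            2e-13, 8.0, 25.0, 35.0, ds, activity_model="conditional"
        )
        assert out["Fe_prime"] == pytest.approx(4e-13, rel=1e-12)

    def test_linearity_in_free_fe(self, dataset):
        base = inorganic_fe_speciation(1e-15, 7.9, 5.0, 34.7, dataset)["Fe_prime"]
        for k in range(1, 7):  # six decades
            scaled = inorganic_fe_speciation(1e-15 * 10 ** k, 7.9, 5.0, 34.7,
                                             dataset)["Fe_prime"]
            assert scaled == pytest.approx(base * 10 ** k, rel=1e-12)

    def test_mass_action_consistency(self, dataset):
        """log10(activity quotient) equals log10 K(T) for every solved species."""
        pH, T, S = 7.8, 6.0, 34.8
        sw = seawater_major_ions(S, T)
        out = inorganic_fe_speciation(1e-14, pH, T, S, dataset)
        TK = T + 273.15
        gH = activity_coefficient(1, sw.ionic_strength, TK)
        g3 = activity_coefficient(3, sw.ionic_strength, TK)
        aH = gH * 10 ** (-pH)
        aFe = g3 * 1e-14
        for rx in dataset.reactions:
            gz = activity_coefficient(rx.charge, sw.ionic_strength, TK)
            a_prod = out[rx.product] * gz
            nH = -rx.stoichiometry["H"]
            quotient = math.log10(a_prod) - math.log10(aFe) + nH * math.log10(aH)
            assert quotient == pytest.approx(
                adjust_logK_temperature(rx, TK), abs=1e-10
            )

    def test_undefined_component_raises(self):
        rx = Reaction("FeX", 2, {"Fe3": 1, "X": -1}, 0.0, 0.0)
        comps = (Component("Fe3", 3), Component("H", 1), Component("X", 1))
        ds = ThermoDataset(comps, (rx,), ())
        with pytest.raises(ConfigError):
            toy_dataset([rx])  # X undefined in the toy basis


class TestSolubility:
    def test_increases_as_ph_decreases(self, dataset):
        for T in (2.0, 8.0, 14.0):
            sols = [fe_prime_solubility(ph, T, 34.7, dataset)
                    for ph in np.arange(7.2, 8.21, 0.1)]
            assert all(a >= b for a, b in zip(sols, sols[1:]))

    def test_increases_as_temperature_decreases(self, dataset):
        for ph in (7.3, 7.7, 8.1):
            sols = [fe_prime_solubility(ph, T, 34.7, dataset)
                    for T in np.arange(1.6, 16.1, 1.2)]
            assert all(a >= b for a, b in zip(sols, sols[1:]))

    def test_definition_chaining(self):
        """With Fe'/[Fe3+] fixed at 1e10, solubility is ratio * Ks * {H+}^3."""
        ratio_minus_1 = 1e10 - 1.0
        rx = Reaction("FeOHn", 3, {"Fe3": 1}, math.log10(ratio_minus_1), 0.0)
        mineral = MineralPhase("authFeOH", logKs_ref=3.0)
        ds = toy_dataset([rx], [mineral])
        got = fe_prime_solubility(8.0, 25.0, 35.0, ds, activity_model="conditional")
        assert got == pytest.approx(1e10 * 10 ** 3.0 * (1e-8) ** 3, rel=1e-9)

    def test_missing_mineral_raises(self, dataset):
        ds = ThermoDataset(dataset.components, dataset.reactions, ())
        with pytest.raises(ConfigError, match="authFeOH"):
            fe_prime_solubility(7.8, 5.0, 34.7, ds)


class TestPhScales:
    def test_identity(self):
        assert convert_ph_scale(7.9, "total", "total", 35, 10) == 7.9

    @pytest.mark.parametrize("scales", [("total", "free"), ("total", "NBS"),
                                        ("free", "NBS")])
    def test_round_trip(self, scales):
        a, b = scales
        ph = convert_ph_scale(convert_ph_scale(8.0, a, b, 34.5, 6.0),
                              b, a, 34.5, 6.0)
        assert ph == pytest.approx(8.0, abs=1e-12)

    def test_free_exceeds_total_in_seawater(self):
        # bisulfate association binds free protons: pH_free > pH_total
        assert convert_ph_scale(8.0, "total", "free", 35, 10) > 8.0

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="unknown pH scale"):
            convert_ph_scale(8.0, "total", "seawater", 35, 10)


class TestDatasetValidation:
    def test_duplicate_component_names(self):
        comps = (Component("H", 1), Component("H", 1))
        with pytest.raises(ConfigError, match="duplicate"):
            ThermoDataset(comps, (), ()).validate()

    def test_charge_imbalance_detected(self):
        comps = (Component("Fe3", 3), Component("H", 1))
        rx = Reaction("FeOH", 1, {"Fe3": 1, "H": -1}, 0.0)  # should be +2
        with pytest.raises(ConfigError, match="charge"):
            ThermoDataset(comps, (rx,), ()).validate()

    def test_default_dataset_is_valid(self, dataset):
        dataset.validate()
        assert dataset.mineral("authFeOH").logKs_ref is not None
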