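"""NICA-Donnan isotherm, Donnan electrostatics, siderophore, affinity spectrum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fespec import nica, thermo
from fespec.nica import (
    DiscreteLigand,
    NicaSiteGroup,
    NicaDonnanPhase,
    donnan_volume,
    nica_bound_amount,
    siderophore_speciation,
    sips_density,
    solve_donnan_potential,
    weighted_mean_occupied_logK,
)
from conftest import single_group_phase


class TestIsotherm:
    def test_langmuir_half_saturation(self):
        phase = single_group_phase(Qmax=1.0, logK_H=0.0, n_H=1.0, p=1.0)
        bound = nica_bound_amount(phase, {"H": 1.0})
        assert bound["H"] == pytest.approx(0.5, abs=1e-10)

    def test_symmetric_ions_bind_equally(self):
        ions = {"Mg": (3.0, 0.7), "Ca": (3.0, 0.7)}
        phase = single_group_phase(Qmax=2.0, logK_H=4.0, n_H=0.7, p=0.8, ions=ions)
        bound = nica_bound_amount(phase, {"H": 1e-8, "Mg": 1e-3, "Ca": 1e-3})
        assert bound["Mg"] == pytest.approx(bound["Ca"], rel=1e-12)

    def test_hand_evaluated_sublinear_isotherm(self):
        # single ion, n = 0.5, p = 1, (Kc)=100: theta = 10/11
        phase = single_group_phase(Qmax=1.0, logK_H=2.0, n_H=0.5, p=1.0)
        bound = nica_bound_amount(phase, {"H": 1.0})
        assert bound["H"] == pytest.approx(10.0 / 11.0, rel=1e-12)

    def test_all_zero_concentrations_bind_nothing(self, phases):
        bound = nica_bound_amount(phases["dom"], {"H": 0.0, "Fe3": 0.0})
        assert all(v == 0.0 for v in bound.values())

    @given(
        logK_H=st.floats(0.0, 10.0), n_H=st.floats(0.3, 1.0),
        p=st.floats(0.3, 1.0), logc=st.floats(-10.0, 0.0),
        logK_M=st.floats(-3.0, 15.0), n_M=st.floats(0.2, 1.0),
        logcM=st.floats(-9.0, -1.0),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_site_conservation(self, logK_H, n_H, p, logc, logK_M, n_M, logcM):
        """Total occupancy never exceeds the site density of a group."""
        g = NicaSiteGroup(Qmax=1.0, logK_H=logK_H, n_H=n_H, p=p,
                          ions={"Mg": (logK_M, n_M)})
        phase = NicaDonnanPhase("t", (g, NicaSiteGroup(0.0, 0, 1, 1, {})), 0.5)
        bound = nica_bound_amount(phase, {"H": 10 ** logc, "Mg": 10 ** logcM})
        theta_sum = bound["H"] * n_H / (1.0 * n_H) + bound["Mg"] * n_H / n_M
        assert theta_sum <= 1.0 + 1e-12

    def test_bound_fe_monotone_in_free_fe_and_antitone_in_protons(self, phases):
        dom = phases["dom"]
        fe_grid = np.geomspace(1e-20, 1e-12, 12)
        b = [nica_bound_amount(dom, {"H": 1e-8, "Mg": 3e-2, "Ca": 6e-3,
                                     "Fe3": c})["Fe3"] for c in fe_grid]
        assert all(x < y for x, y in zip(b, b[1:]))
        h_grid = np.geomspace(1e-9, 1e-6, 10)
        bh = [nica_bound_amount(dom, {"H": h, "Mg": 3e-2, "Ca": 6e-3,
                                      "Fe3": 1e-15})["Fe3"] for h in h_grid]
        assert all(x > y for x, y in zip(bh, bh[1:]))


class TestDonnan:
    @pytest.mark.parametrize("b,I,expect", [
        (0.7, 10.0, 0.1), (0.3, 10.0, 0.1),  # forced at log10 I = 1
        (0.7, 1.0, 10 ** -0.3), (0.7, 0.7, 0.6433),
    ])
    def test_volume_law(self, b, I, expect):
        assert donnan_volume(b, I) == pytest.approx(expect, rel=1e-3)

    def test_volume_requires_positive_ionic_strength(self):
        with pytest.raises(ValueError):
            donnan_volume(0.5, 0.0)

    def test_zero_charge_phase_has_unit_boltzmann_factor(self, seawater):
        phase = NicaDonnanPhase(
            "null",
            (NicaSiteGroup(0.0, 0, 1, 1, {}), NicaSiteGroup(0.0, 0, 1, 1, {})),
            0.5,
        )
        state = solve_donnan_potential(phase, seawater, 8.0)
        assert state.chi == 1.0
        assert state.psi_D == 0.0

    def test_net_negative_phase_enriches_cations(self, phases, seawater):
        state = solve_donnan_potential(phases["dom"], seawater, 8.0)
        assert state.chi > 1.0
        assert state.psi_D < 0.0

    def test_chi_matches_independent_bisection(self, phases, seawater):
        """Brent result equals a hand-rolled bisection on the charge residual."""
        rng = np.random.default_rng(42)
        charges = {"Na": 1, "Mg": 2, "Ca": 2, "K": 1, "Cl": -1, "SO4": -2}
        ions = [(c, charges[k]) for k, c in seawater.concentrations.items()]
        for _ in range(10):
            ph = rng.uniform(7.2, 8.2)
            ions_ph = ions + [(10 ** -ph, 1)]  # free protons carry excess too
            binding = {"H": 10 ** -ph,
                       "Mg": seawater.concentrations["Mg"],
                       "Ca": seawater.concentrations["Ca"]}
            phase = phases["dom"] if rng.random() < 0.5 else phases["pom"]
            VD = donnan_volume(phase.donnan_b, seawater.ionic_strength)
            state = solve_donnan_potential(phase, seawater, ph)

            def resid(chi):
                return nica.donnan_residual(phase, chi, ions_ph, binding, VD)

            lo, hi = 1e-3, 1e3
            for _ in range(200):  # plain bisection oracle
                mid = math.sqrt(lo * hi)
                if resid(mid) < 0:
                    lo = mid
                else:
                    hi = mid
            assert state.chi == pytest.approx(math.sqrt(lo * hi), rel=1e-8)

    def test_electroneutrality_residual_per_litre(self, phases, seawater):
        phase = phases["dom"].with_mass(5e-6)
        charges = {"Na": 1, "Mg": 2, "Ca": 2, "K": 1, "Cl": -1, "SO4": -2}
        ions = [(c, charges[k]) for k, c in seawater.concentrations.items()]
        state = solve_donnan_potential(phase, seawater, 8.0)
        binding = {"H": 1e-8, "Mg": seawater.concentrations["Mg"],
                   "Ca": seawater.concentrations["Ca"]}
        VD = donnan_volume(phase.donnan_b, seawater.ionic_strength)
        resid_per_kg = nica.donnan_residual(phase, state.chi, ions, binding, VD)
        assert abs(resid_per_kg * phase.mass) < 1e-10  # mol charge per litre


def _ligand(total=1e-10):
    return DiscreteLigand("ferrioxamine B proxy", total,
                          [10.84, 9.46, 9.0, 8.3], 4.3, 2.64, 30.6)


class TestSiderophore:
    def test_absent_ligand_and_absent_metal(self, seawater):
        fes, _ = siderophore_speciation(_ligand(0.0), 1e-12, seawater, 8.0)
        assert fes == 0.0
        fes, _ = siderophore_speciation(_ligand(1e-10), 0.0, seawater, 8.0)
        assert fes == 0.0

    def test_near_stoichiometric_binding_at_high_affinity(self, seawater):
        """Fe in excess of the ligand saturates it: FeSid -> ligand total."""
        fes, _ = siderophore_speciation(_ligand(1e-10), 1e-12, seawater, 8.0)
        assert fes / 1e-10 > 0.99

    def test_bounded_by_ligand_total(self, seawater):
        for fe3 in (1e-20, 1e-15, 1e-10, 1e-6):
            fes, _ = siderophore_speciation(_ligand(2e-10), fe3, seawater, 8.0)
            assert 0.0 <= fes <= 2e-10


class TestAffinitySpectrum:
    def test_sips_density_normalized(self):
        for p in (0.3, 0.5, 0.8):
            u = np.linspace(-80.0, 80.0, 20001)
            assert np.trapezoid(sips_density(u, p), u) == pytest.approx(1.0, abs=1e-6)

    def test_sips_integral_reproduces_nica_isotherm(self):
        """Quadrature of the local isotherm over the Sips density recovers the
        closed-form NICA binding — the integral representation is exact."""
        for p in (0.4, 0.7):
            for x in (1e-3, 0.1, 1.0, 30.0):
                u = np.linspace(-60.0 / p, 60.0 / p, 40001)
                f = sips_density(u, p)
                theta = np.trapezoid(f * x * np.exp(u) / (1 + x * np.exp(u)), u)
                assert theta == pytest.approx(x ** p / (1 + x ** p), rel=1e-6)

    def test_homogeneous_limit_returns_conditional_logk(self, seawater):
        """n = p = 1, single group: every occupied site has the median affinity,
        independent of coverage."""
        phase = single_group_phase(Qmax=1.0, logK_H=4.0, n_H=1.0, p=1.0,
                                   ions={"Fe3": (10.0, 1.0)})
        for fe in (1e-14, 1e-10, 1e-6):
            rep = weighted_mean_occupied_logK(
                phase, 1.0, {"H": 1e-8, "Fe3": fe})
            assert rep.mean_logK == pytest.approx(10.0, abs=1e-12)

    def test_mean_lies_within_sampled_support(self, phases):
        rep = weighted_mean_occupied_logK(
            phases["dom"], 5.0, {"H": 1e-8, "Mg": 3e-2, "Ca": 6e-3, "Fe3": 1e-16}
        )
        assert rep.support.min() <= rep.mean_logK <= rep.support.max()

    def test_mean_non_increasing_with_fe_load(self, phases):
        chi = 5.0
        means = []
        for fe in np.geomspace(1e-18, 1e-8, 12):
            rep = weighted_mean_occupied_logK(
                phases["dom"], chi, {"H": 1e-8, "Mg": 3e-2, "Ca": 6e-3, "Fe3": fe}
            )
            means.append(rep.mean_logK)
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_quadrature_self_convergence(self, phases):
        args = (phases["dom"], 5.0,
                {"H": 1e-8, "Mg": 3e-2, "Ca": 6e-3, "Fe3": 1e-15})
        coarse = weighted_mean_occupied_logK(*args, n_nodes=2048).mean_logK
        fine = weighted_mean_occupied_logK(*args, n_nodes=8192).mean_logK
        assert coarse == pytest.approx(fine, abs=1e-4)

    def test_no_bound_fe_yields_missing_marker(self, phases):
        rep = weighted_mean_occupied_logK(phases["dom"], 5.0,
                                          {"H": 1e-8, "Fe3": 0.0})
        assert math.isnan(rep.mean_logK)


class TestConfig:
    def test_default_phases_shapes(self, phases):
        dom, pom = phases["dom"], phases["pom"]
        assert len(dom.groups) == 2 and len(pom.groups) == 2
        # POM: 1 mol sites/kg total, split 3:1 low:high affinity
        assert pom.Q_total == pytest.approx(1.0)
        assert pom.groups[0].Qmax / pom.groups[1].Qmax == pytest.approx(3.0)

    def test_invalid_heterogeneity_rejected(self):
        with pytest.raises(thermo.ConfigError):
            NicaSiteGroup(Qmax=1.0, logK_H=1.0, n_H=1.0, p=1.5, ions={})
        with pytest.raises(thermo.ConfigError):
            NicaSiteGroup(Qmax=1.0, logK_H=1.0, n_H=1.0, p=0.5,
                          ions={"Fe3": (10.0, 1.2)})
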