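"""Materials, photon cross sections, Compton sampling and stopping powers."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from cemamc.constants import ELECTRON_REST_MEV as MEC2
from cemamc.constants import THOMSON_CROSS_SECTION_CM2
from cemamc.materials import MATERIALS, Material, air, graphite, pmma, water
from cemamc.stopping import (
    RangeTable,
    StoppingPowerTable,
    csda_energy_after_step,
    hard_moller_cross_section,
    moller_dcs,
    restricted_stopping_power,
    unrestricted_collision_stopping_power,
)
from cemamc.xsections import (
    compton_edge,
    compton_mu,
    klein_nishina_dcs,
    klein_nishina_total_cross_section,
    pair_mu,
    photoelectric_mu,
    sample_compton,
    sample_interaction_type,
    total_attenuation,
)


class TestMaterials:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            Material.from_composition("bad", 1.0, {"H": 0.3, "O": 0.3}, 75.0)

    def test_electron_density_follows_z_over_a(self, water):
        by_hand = 6.02214076e23 * (0.111894 * 1 / 1.008 + 0.888106 * 8 / 15.999)
        assert water.electron_density_per_g == pytest.approx(by_hand, rel=1e-9)
        # liquid water: ~3.34e23 electrons per gram
        assert water.electron_density_per_g == pytest.approx(3.343e23, rel=1e-3)

    @pytest.mark.parametrize("mat", [water(), air(), pmma(), graphite()])
    def test_builtin_materials_are_consistent(self, mat):
        assert sum(e.mass_fraction for e in mat.composition) == pytest.approx(1.0, abs=1e-9)
        assert mat.mass_density > 0
        assert 0.3 < mat.radiation_length_g_cm2 / 36.08 < 2.5  # within a factor of water


class TestPhotonCrossSections:
    def test_thomson_limit(self):
        # per-electron cross section approaches 0.6652 barn as E -> 0
        assert klein_nishina_total_cross_section(1e-7) == pytest.approx(
            THOMSON_CROSS_SECTION_CM2, rel=1e-6
        )

    def test_total_is_sum_of_components_below_pair_threshold(self, water):
        e = 0.5
        assert pair_mu(water, e) == 0.0
        assert total_attenuation(water, e) == pytest.approx(
            compton_mu(water, e) + photoelectric_mu(water, e), rel=1e-12
        )

    def test_components_nonnegative_and_sum_exactly(self, water):
        for e in np.geomspace(0.002, 40, 25):
            parts = [compton_mu(water, e), photoelectric_mu(water, e), pair_mu(water, e)]
            assert all(p >= 0 for p in parts)
            assert total_attenuation(water, e) == pytest.approx(sum(parts), rel=1e-12)

    def test_klein_nishina_total_matches_angular_quadrature(self, water):
        # independent brute-force integration of the differential cross section
        e = 1.25
        val, _ = quad(lambda c: 2 * math.pi * klein_nishina_dcs(e, c) * 1e24, -1, 1, limit=200)
        assert val * 1e-24 == pytest.approx(klein_nishina_total_cross_section(e), rel=1e-6)
        assert compton_mu(water, e) == pytest.approx(
            val * 1e-24 * water.electron_density_per_cm3, rel=1e-6
        )

    def test_energy_range_errors(self, water):
        with pytest.raises(ValueError, match="range"):
            total_attenuation(water, 1e-4)
        with pytest.raises(ValueError, match="range"):
            total_attenuation(water, 100.0)

    def test_water_attenuation_magnitudes_are_realistic(self, water):
        # order-of-magnitude anchors (no Rayleigh in this engine)
        assert total_attenuation(water, 1.25) == pytest.approx(0.063, rel=0.05)
        assert total_attenuation(water, 0.1) == pytest.approx(0.17, rel=0.15)

    def test_interaction_type_sampling(self, water):
        assert sample_interaction_type(water, 0.5, 0.999) != "pair"
        # deterministic u-sweep: branch fractions equal component ratios
        u = (np.arange(2000) + 0.5) / 2000
        kinds = np.array([sample_interaction_type(water, 0.05, float(x)) for x in u])
        mc, mp = compton_mu(water, 0.05), photoelectric_mu(water, 0.05)
        frac_c = np.mean(kinds == "compton")
        assert frac_c == pytest.approx(mc / (mc + mp), abs=5.1e-4)


class TestComptonSampling:
    def test_energy_conservation_is_exact(self, rng):
        for _ in range(500):
            e = float(rng.uniform(0.05, 6.0))
            e_sc, _, t_el, _ = sample_compton(e, rng)
            assert e_sc + t_el == pytest.approx(e, abs=1e-15)
            assert t_el <= compton_edge(e) * (1 + 1e-12)

    def test_kinematic_edge_values(self):
        # 1.33 MeV line: edge at 1.116 MeV ("about 1.1"); backscattered
        # 0.511 MeV photon keeps exactly a third of its energy
        assert compton_edge(1.33) == pytest.approx(1.1157, abs=2e-3)
        k = 0.511 / MEC2
        e_back = 0.511 / (1 + 2 * k)
        assert e_back == pytest.approx(0.511 / 3, rel=1e-3)

    @pytest.mark.parametrize("energy", [0.3, 1.25, 6.0])
    def test_sampler_follows_klein_nishina(self, energy, rng):
        n = 200_000
        cos = np.empty(n)
        for i in range(n):
            _, c, _, _ = sample_compton(energy, rng)
            cos[i] = c
        bins = np.linspace(-1, 1, 21)
        obs, _ = np.histogram(cos, bins=bins)
        centers_int = []
        for a, b in zip(bins[:-1], bins[1:]):
            val, _ = quad(lambda c: klein_nishina_dcs(energy, c) * 1e24, a, b)
            centers_int.append(val)
        exp = np.array(centers_int)
        exp = exp / exp.sum() * n
        _, p = chisquare(obs, exp)
        assert p > 0.01


class TestStoppingPowers:
    def test_restricted_matches_moller_quadrature(self, water):
        # closed form vs direct quadrature of the Moller spectrum:
        # S_col - L_Delta = n_e * int_Delta^{E/2} T' dsigma/dT' dT'
        for e in (0.1, 0.5, 1.0, 5.0):
            su = unrestricted_collision_stopping_power(water, e, density_correction=False)
            lr = restricted_stopping_power(water, e, 0.010, density_correction=False)
            val, _ = quad(lambda eps: eps * e * moller_dcs(e, eps) * 1e25, 0.010 / e, 0.5, limit=300)
            hard = val * 1e-25 * water.electron_density_per_cm3 / water.mass_density
            assert su - lr == pytest.approx(hard, rel=1e-6)

    def test_restricted_monotonically_decreasing_at_low_energy(self, water):
        grid = np.linspace(0.02, 1.0, 80)
        vals = [restricted_stopping_power(water, float(e), 0.010) for e in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_restriction_inactive_above_half_energy(self, water):
        e = 0.6
        assert restricted_stopping_power(water, e, e / 2) == pytest.approx(
            unrestricted_collision_stopping_power(water, e), rel=1e-12
        )

    def test_monotone_in_delta(self, water):
        e = 1.0
        deltas = [0.001, 0.005, 0.010, 0.050, 0.2, 0.5]
        vals = [restricted_stopping_power(water, e, d) for d in deltas]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self, water):
        with pytest.raises(ValueError):
            restricted_stopping_power(water, 0.005, 0.010)
        with pytest.raises(ValueError):
            restricted_stopping_power(water, 1.0, -1.0)

    def test_restricted_below_unrestricted_everywhere(self, water):
        t = StoppingPowerTable.build(water, 0.010)
        assert np.all(t.restricted_collision <= t.unrestricted_collision * (1 + 1e-12))
        assert np.all(t.restricted_collision > 0)

    def test_water_anchor_values(self, water):
        # ESTAR-grade anchors at the few-percent level
        assert unrestricted_collision_stopping_power(water, 1.0) == pytest.approx(1.85, rel=0.02)
        assert unrestricted_collision_stopping_power(water, 0.01) == pytest.approx(22.5, rel=0.03)

    def test_hard_moller_cross_section_threshold(self, water):
        assert hard_moller_cross_section(water, 0.015, 0.010) == 0.0
        assert hard_moller_cross_section(water, 1.0, 0.010) > 0.0


class TestCsda:
    def test_zero_step_keeps_energy(self, water):
        assert csda_energy_after_step(water, 1.0, 0.0) == 1.0

    def test_linear_slowing_in_constant_stopping_toy(self, water):
        # constant S*rho = 2 MeV/cm <=> range r(E) = E/2
        grid = np.geomspace(1e-3, 10, 200)
        toy = RangeTable(water, grid, grid / 2.0)
        out = csda_energy_after_step(water, 1.0, 0.25, range_table=toy)
        assert out == pytest.approx(0.5, rel=1e-9)

    def test_path_energy_round_trip(self, water):
        table = StoppingPowerTable.build(water, 0.010)
        rt = RangeTable.build(table)
        e = 1.0
        ds = 0.1
        e2 = csda_energy_after_step(water, e, ds, range_table=rt)
        back = rt.range_of(e) - rt.range_of(e2)
        assert back == pytest.approx(ds, abs=1e-8)
        assert rt.energy_of(rt.range_of(e)) == pytest.approx(e, abs=1e-8)

    def test_range_table_matches_quadrature(self, water):
        from cemamc.stopping import radiative_stopping_power

        table = StoppingPowerTable.build(water, 0.010)
        rt = RangeTable.build(table, total=True)

        def inv_s(e):
            s = unrestricted_collision_stopping_power(water, e) + radiative_stopping_power(water, e)
            return 1.0 / (water.mass_density * s)

        val, _ = quad(inv_s, 0.01, 1.0, limit=200)
        ours = rt.range_of(1.0) - rt.range_of(0.01)
        assert ours == pytest.approx(val, rel=1e-3)

    def test_csda_range_magnitude(self, water):
        # ~0.44 cm for 1 MeV electrons in water
        table = StoppingPowerTable.build(water, 0.010)
        rt = RangeTable.build(table, total=True)
        assert rt.range_of(1.0) == pytest.approx(0.437, rel=0.02)
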