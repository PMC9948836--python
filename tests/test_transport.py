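"""Engine-level behaviour: determinism, energy bookkeeping, the analytic
attenuation oracle, XCSE weight algebra and unbiasedness, Russian roulette."""

import math

import numpy as np
import pytest

from conftest import make_big_disc_geometry
from cemamc.geometry import build_setup
from cemamc.sources import SourceConfig, SpectrumTable, co60_lines
from cemamc.transport import (
    Particle,
    TransportOptions,
    run_simulation,
    russian_roulette,
    xcse_split_weights,
)
from cemamc.xsections import total_attenuation


def mono_line(energy: float) -> SpectrumTable:
    return SpectrumTable("discrete", np.array([1.0]), energies=np.array([energy]))


@pytest.fixture(scope="module")
def co60_source():
    return SourceConfig("collimated_point", co60_lines())


class TestWeightAlgebra:
    def test_split_weights_exact(self):
        wi, ws = xcse_split_weights(1.0, 128.0)
        assert wi == 0.0078125
        assert ws == 1.0 - 0.0078125
        assert wi + ws == 1.0  # exact, not approximate

    def test_split_conserves_for_random_weights(self, rng):
        for _ in range(200):
            w = float(rng.uniform(1e-6, 10))
            b = float(rng.uniform(1.01, 2048))
            wi, ws = xcse_split_weights(w, b)
            assert wi + ws == w

    def test_split_requires_b_above_one(self):
        with pytest.raises(ValueError):
            xcse_split_weights(1.0, 1.0)

    def test_rr_survivor_weight_restored(self, rng):
        # a scattered photon of weight w/b surviving roulette at 1/b is
        # restored to analog weight
        p = Particle("photon", 1.0, (0, 0, 0), (0, 0, 1.0), weight=1.0 / 128)
        out = russian_roulette(p, 1.0, rng)
        assert out.weight == p.weight
        boosted = None
        while boosted is None:
            boosted = russian_roulette(p, 1.0 / 128, rng)
        assert boosted.weight == pytest.approx(1.0)


class TestRussianRoulette:
    def test_survival_one_never_kills(self, rng):
        p = Particle("photon", 1.0, (0, 0, 0), (0, 0, 1.0))
        for _ in range(100):
            assert russian_roulette(p, 1.0, rng) is not None

    def test_expectation_preserved(self, rng):
        p = Particle("photon", 1.0, (0, 0, 0), (0, 0, 1.0))
        n = 50_000
        total = 0.0
        for _ in range(n):
            out = russian_roulette(p, 0.5, rng)
            if out is not None:
                total += out.weight
        # surviving total weight ~ Binomial(n, 1/2) * 2: sigma = sqrt(n)
        assert abs(total - n) < 4 * math.sqrt(n)

    def test_invalid_probability(self, rng):
        p = Particle("photon", 1.0, (0, 0, 0), (0, 0, 1.0))
        with pytest.raises(ValueError):
            russian_roulette(p, 0.0, rng)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, co60_source):
        geo = build_setup("external_disc", r=0.75, xcse_factor=64.0)
        opt = TransportOptions()
        a = run_simulation(geo, co60_source, opt, 3000, seed=77)
        b = run_simulation(geo, co60_source, opt, 3000, seed=77)
        assert np.array_equal(a.tallies.dose_acc, b.tallies.dose_acc)
        assert np.array_equal(a.tallies.flu_acc, b.tallies.flu_acc)
        assert np.array_equal(a.tallies.audit, b.tallies.audit)

    def test_fluence_scoring_is_passive(self, co60_source):
        # same seed with fluence tallies attached vs detached: bit-identical
        # dose tallies (scoring consumes no random numbers)
        geo = build_setup("external_disc", r=0.75, xcse_factor=64.0)
        opt = TransportOptions()
        on = run_simulation(geo, co60_source, opt, 3000, seed=77, score_fluence=True)
        off = run_simulation(geo, co60_source, opt, 3000, seed=77, score_fluence=False)
        assert np.array_equal(on.tallies.dose_acc, off.tallies.dose_acc)
        assert np.array_equal(on.tallies.te_acc, off.tallies.te_acc)
        assert off.tallies.flu_acc.sum() == 0.0

    def test_different_seed_differs(self, co60_source):
        geo = build_setup("external_disc", r=0.75, xcse_factor=64.0)
        opt = TransportOptions()
        a = run_simulation(geo, co60_source, opt, 3000, seed=77)
        b = run_simulation(geo, co60_source, opt, 3000, seed=78)
        assert not np.array_equal(a.tallies.dose_acc, b.tallies.dose_acc)


class TestEnergyBookkeeping:
    @pytest.mark.parametrize("b,r", [(1.0, 0.0), (64.0, 0.75)])
    def test_per_history_energy_balance(self, co60_source, b, r):
        # emitted + rest-mass sources + roulette boosts equals deposited +
        # escaped + roulette kills + rest-mass sinks, history by history
        geo = build_setup("external_disc", r=r, xcse_factor=b)
        res = run_simulation(geo, co60_source, TransportOptions(), 5000, seed=3)
        assert res.audit["max_history_imbalance"] < 1e-10

    def test_sub_pcut_primary_deposited_immediately(self):
        src = SourceConfig("isotropic_point", mono_line(0.005))
        geo = build_setup("immersed_voxel", r=0.0, xcse_factor=1.0)
        res = run_simulation(geo, src, TransportOptions(), 2000, seed=1)
        a = res.audit
        assert a["discarded_below_pcut"] == pytest.approx(a["emitted"])
        assert a["deposited"] == pytest.approx(a["emitted"])
        assert res.tallies.flu_acc.sum() == 0.0


class TestAttenuationOracle:
    def test_uncollided_fraction_matches_closed_form(self, water):
        # narrow mono-energetic beam through the 30 cm phantom: the fraction
        # of primaries escaping without interaction is exp(-mu * 30)
        src = SourceConfig("collimated_point", mono_line(1.25), field_size=0.1)
        geo = build_setup("external_disc", r=0.0, xcse_factor=1.0)
        n = 50_000
        res = run_simulation(geo, src, TransportOptions(), n, seed=5)
        p = math.exp(-total_attenuation(water, 1.25) * 30.0)
        observed = res.audit["primary_uncollided"] / n
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 4 * sigma

    def test_interaction_density_scales_with_enhancement(self, co60_source):
        # the site density inside a b=64 region is 64x the analog density
        geo_on = build_setup("external_disc", r=0.75, xcse_factor=64.0)
        geo_off = build_setup("external_disc", r=0.75, xcse_factor=1.0000001)
        n = 20_000
        on = run_simulation(geo_on, co60_source, TransportOptions(), n, seed=9)
        off = run_simulation(geo_off, co60_source, TransportOptions(), n, seed=9)
        shell = 2
        n_on = on.tallies.sites[shell]
        n_off = off.tallies.sites[shell]
        ratio = n_on / n_off
        sigma = ratio * math.sqrt(1.0 / n_on + 1.0 / n_off)
        assert abs(ratio - 64.0) < 4 * sigma


@pytest.fixture(scope="module")
def analog():
    geo = make_big_disc_geometry(1.0, 0.0)
    src = SourceConfig("collimated_point", co60_lines())
    return run_simulation(geo, src, TransportOptions(), 40_000, seed=21)


class TestXcseUnbiasedness:
    @pytest.mark.parametrize("b", [2.0, 64.0])
    def test_cavity_dose_agrees_with_analog(self, analog, b):
        from cemamc.scoring import history_uncertainty

        geo = make_big_disc_geometry(b, 0.5)
        src = SourceConfig("collimated_point", co60_lines())
        res = run_simulation(geo, src, TransportOptions(), 40_000, seed=22)
        cav_a = 2  # analog: single body
        cav_v = len(geo.bodies) + 1  # shell + cavity
        n = 40_000
        da = analog.tallies.dose_acc[cav_a] / n
        dv = res.tallies.dose_acc[cav_v] / n
        ua = history_uncertainty(analog.tallies.dose_acc[cav_a], analog.tallies.dose_sq[cav_a], n)
        uv = history_uncertainty(res.tallies.dose_acc[cav_v], res.tallies.dose_sq[cav_v], n)
        z = (da - dv) / math.hypot(da * ua, dv * uv)
        assert abs(z) < 3.0


class TestElectronTransport:
    def test_low_energy_photon_source_all_track_ends_local(self):
        # 30 keV photons: photoelectrons above Delta are tracked and
        # terminate as track ends; total track-end energy is bounded by the
        # deposited energy
        src = SourceConfig("isotropic_point", mono_line(0.030))
        geo = build_setup("immersed_voxel", r=0.0, xcse_factor=1.0)
        res = run_simulation(geo, src, TransportOptions(), 3000, seed=4)
        assert res.tallies.te_acc.sum() > 0
        assert res.tallies.te_acc.sum() <= res.tallies.dose_acc.sum() + 1e-12

    def test_raised_far_ecut_leaves_cavity_dose_unchanged(self):
        # raising the electron cutoff in a region > 5 cm from the cavity is
        # a safe range-rejection-style economy
        from cemamc.geometry import Cylinder, GeometryModel, Region
        from cemamc.materials import MATERIALS
        from cemamc.scoring import history_uncertainty

        water_m = MATERIALS["water"]
        base = make_big_disc_geometry(16.0, 0.5)
        far = Cylinder((0.0, 0.0, 5.0), 3.0, 2.0, Region(2, water_m, 1.0, 0.2))
        raised = GeometryModel(
            base.phantom_half_size,
            base.phantom_region,
            (far,) + tuple(
                Cylinder(b.center, b.radius, b.half_height,
                         Region(b.region.id + 1, b.region.material,
                                b.region.xcse_factor, b.region.ecut_kinetic,
                                b.region.is_scoring_cavity))
                for b in base.bodies
            ),
            name="raised_far_ecut",
        )
        src = SourceConfig("collimated_point", co60_lines())
        n = 30_000
        a = run_simulation(base, src, TransportOptions(), n, seed=6)
        b = run_simulation(raised, src, TransportOptions(), n, seed=6)
        cav_a, cav_b = 3, 4
        da, db = a.tallies.dose_acc[cav_a] / n, b.tallies.dose_acc[cav_b] / n
        ua = history_uncertainty(a.tallies.dose_acc[cav_a], a.tallies.dose_sq[cav_a], n)
        ub = history_uncertainty(b.tallies.dose_acc[cav_b], b.tallies.dose_sq[cav_b], n)
        z = (da - db) / math.hypot(da * ua, db * ub)
        assert abs(z) < 3.0

    def test_particle_validation(self):
        with pytest.raises(ValueError):
            Particle("electron", 1.0, (0, 0, 0), (0, 0, 1.0), weight=0.0)
        with pytest.raises(ValueError):
            Particle("electron", 1.0, (0, 0, 0), (0, 0.5, 1.0))
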