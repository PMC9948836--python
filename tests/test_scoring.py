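"""Scoring arithmetic: fluence apportionment, dose conversion, cema,
uncertainty estimation, efficiency, de-noising and edge location."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cemamc.materials import water as make_water
from cemamc.scoring import (
    FluenceSpectrum,
    cema_integrand,
    denoise_spectrum,
    efficiency,
    finalize_dose,
    finalize_fluence,
    history_uncertainty,
    locate_compton_edges,
    locate_edges,
    relative_gain,
    restricted_cema,
    score_step_fluence,
    track_end_from_dose,
)
from cemamc.stopping import RangeTable, StoppingPowerTable


@pytest.fixture(scope="module")
def water_range():
    w = make_water()
    return RangeTable.build(StoppingPowerTable.build(w, 0.010))


def linear_range_table():
    # constant S*rho = 2 MeV/cm: r(E) = E/2
    grid = np.geomspace(1e-3, 10, 400)
    return RangeTable(make_water(), grid, grid / 2.0)


class TestHistoryUncertainty:
    def test_hand_computed_two_history_case(self):
        # x = {1, 3}: mean 2, s(mean) = 1, relative 0.5 -- exactly
        assert history_uncertainty(4.0, 10.0, 2) == 0.5

    def test_identical_histories_give_zero(self):
        assert history_uncertainty(50.0, 250.0, 10) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_histories(self):
        with pytest.raises(ValueError):
            history_uncertainty(1.0, 1.0, 1)

    def test_gaussian_stream_oracle(self, rng):
        x = rng.normal(10.0, 1.0, size=10_000)
        rel = history_uncertainty(float(x.sum()), float((x**2).sum()), len(x))
        expected = 1.0 / math.sqrt(len(x)) / 10.0
        assert rel == pytest.approx(expected, rel=0.10)


class TestStepFluence:
    def test_step_inside_one_bin(self, water_range):
        edges = 0.010 + 0.005 * np.arange(11)
        out = np.zeros(10)
        score_step_fluence(edges, 0.0131, 0.0129, 0.2, 1.5, water_range, out)
        assert out[0] == pytest.approx(0.3)
        assert out[1:].sum() == 0.0

    def test_constant_s_splits_evenly(self):
        # uniform slowing: a step spanning two equal bins symmetrically
        # deposits half its length in each
        rt = linear_range_table()
        edges = np.array([0.01, 0.02, 0.03])
        out = np.zeros(2)
        score_step_fluence(edges, 0.025, 0.015, 1.0, 2.0, rt, out)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(1.0)

    @given(
        e_hi=st.floats(0.02, 5.0),
        frac=st.floats(0.05, 0.95),
        ds=st.floats(1e-4, 1.0),
        w=st.floats(0.01, 4.0),
    )
    def test_conservation(self, water_range, e_hi, frac, ds, w):
        e_lo = max(0.0101, e_hi * frac)
        edges = 0.010 + 0.005 * np.arange(1202)
        out = np.zeros(1201)
        score_step_fluence(edges, e_hi, min(e_lo, e_hi), ds, w, water_range, out)
        assert out.sum() == pytest.approx(w * ds, rel=1e-9)

    def test_contract_violation(self, water_range):
        with pytest.raises(ValueError):
            score_step_fluence(np.array([0.01, 0.015]), 0.011, 0.013, 0.1, 1.0,
                               water_range, np.zeros(1))


class TestFinalize:
    def test_unit_fluence_case(self):
        # one particle crossing a 1 cm^3 cavity with ds = 1 cm, one 1 MeV
        # bin, divisor 1 -> spectral fluence exactly 1 cm^-2 MeV^-1
        spec = finalize_fluence(
            np.array([1.0]), np.array([1.0]), 1, np.array([0.0, 1.0]), 1.0, 1.0
        )
        assert spec.fluence[0] == 1.0

    def test_linearity_in_histories(self):
        a = finalize_fluence(np.array([4.0]), np.array([2.0]), 100,
                             np.array([0.0, 1.0]), 1.0, 100.0)
        b = finalize_fluence(np.array([8.0]), np.array([4.0]), 200,
                             np.array([0.0, 1.0]), 1.0, 200.0)
        assert a.fluence[0] == pytest.approx(b.fluence[0])

    def test_dose_unit_conversion(self):
        d, _ = finalize_dose(1.0, 1.0, 1, 1.0, 1.0)
        assert d == 1.602176634e-10

    def test_dose_additivity(self):
        one, _ = finalize_dose(0.3 + 0.7, 0.0, 1, 1.0, 1.0)
        other, _ = finalize_dose(1.0, 0.0, 1, 1.0, 1.0)
        assert one == other

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            finalize_fluence(np.array([1.0]), np.array([1.0]), 1,
                             np.array([0.0, 1.0]), 0.0, 1.0)


def table_with_values(centers, values, delta=0.010):
    """A stopping table whose restricted total equals ``values`` exactly at
    ``centers`` (zero radiative part, log-log interpolation nodes)."""
    w = make_water()
    return StoppingPowerTable(
        w, delta, np.asarray(centers, float), np.asarray(values, float),
        np.asarray(values, float), np.zeros(len(values))
    )


class TestCema:
    def test_arithmetic_example(self):
        # PhiE = (2, 1), S = (2, 1.5), dW = 0.5, TE = 0.5 -> 3.25
        edges = np.array([0.25, 0.75, 1.25])
        spec = FluenceSpectrum(edges, np.array([2.0, 1.0]), np.zeros(2), "e", "u")
        stopping = table_with_values([0.5, 1.0], [2.0, 1.5], delta=0.2)
        res = restricted_cema(spec, stopping, 0.5)
        assert res.c_delta == pytest.approx(3.25)
        assert res.integral_term == pytest.approx(2.75)
        assert res.track_end_term == 0.5

    def test_zero_spectrum(self):
        edges = np.array([0.25, 0.75])
        spec = FluenceSpectrum(edges, np.zeros(1), np.zeros(1), "e", "u")
        res = restricted_cema(spec, table_with_values([0.5], [2.0], delta=0.2), 0.0)
        assert res.c_delta == 0.0

    def test_bins_below_delta_rejected(self):
        edges = np.array([0.005, 0.015])
        spec = FluenceSpectrum(edges, np.ones(1), np.zeros(1), "e", "u")
        with pytest.raises(ValueError, match="below Delta"):
            restricted_cema(spec, table_with_values([0.01], [2.0], delta=0.010), 0.0)

    def test_track_end_from_dose(self):
        edges = np.array([0.25, 0.75])
        spec = FluenceSpectrum(edges, np.array([5.4]), np.zeros(1), "e", "u")
        stopping = table_with_values([0.5], [1.0], delta=0.2)
        assert track_end_from_dose(3.0, spec, stopping) == pytest.approx(3.0 - 2.7)
        assert track_end_from_dose(2.7, spec, stopping) == pytest.approx(0.0, abs=1e-12)


class TestEfficiency:
    def test_figure_of_merit(self):
        rep = efficiency(2.0, 0.01)
        assert rep.efficiency == pytest.approx(50.0)

    def test_invariant_under_history_doubling(self):
        a = efficiency(2.0, 0.01)
        b = efficiency(4.0, 0.005)
        assert relative_gain(b, a) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="deterministic"):
            efficiency(1.0, 0.0)


class TestDenoise:
    def test_window_one_is_identity(self, rng):
        v = rng.random(50)
        assert np.array_equal(denoise_spectrum(v, 1), v)

    def test_constant_unchanged(self):
        v = np.full(40, 3.7)
        assert np.allclose(denoise_spectrum(v, 5), v, atol=1e-14)

    @given(st.integers(2, 7))
    def test_integral_preserved_for_padded_spectra(self, window):
        rng = np.random.default_rng(window)
        v = np.zeros(60)
        v[window : 60 - window] = rng.random(60 - 2 * window)
        out = denoise_spectrum(v, window)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            denoise_spectrum(np.ones(5), 0)


class TestEdgeLocation:
    def test_synthetic_step_found(self):
        e = 0.0125 + 0.005 * np.arange(260)
        v = np.where(e < 0.9, 5.0, 0.05) + 0.01 * np.sin(70 * e)
        edges = locate_edges(e, v, n_edges=1, e_min=0.5, e_max=1.2)
        assert abs(edges[0] - 0.9) < 0.01

    def test_two_line_slowing_down_spectrum(self):
        # synthetic equilibrium spectrum of a two-line source: each line
        # contributes ~1/S(E) up to its kinematic edge
        from cemamc.stopping import unrestricted_collision_stopping_power

        w = make_water()
        e = 0.0125 + 0.005 * np.arange(260)
        s = np.array([unrestricted_collision_stopping_power(w, x) for x in e])
        lines = np.array([1.1732, 1.3325])
        v = np.zeros_like(e)
        for ln in lines:
            t = 2 * ln * ln / (0.51099895 + 2 * ln)
            v += np.where(e < t, 1.0 / s, 0.0)
        found = locate_compton_edges(e, v, lines, [0.5, 0.5], 2)
        assert abs(found[0] - 1.116) < 0.011
        assert abs(found[1] - 0.960) < 0.011
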