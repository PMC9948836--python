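"""Tallies and derived dosimetric quantities.

The engine accumulates, per region and history, weighted deposited energy
(dose), weighted sub-threshold kinetic energy (track ends) and, per energy
bin, the weighted charged-particle track length in the scoring cavity
(track-length fluence estimator: the mean fluence in a volume is the summed
track length per unit volume).  This module finalizes those raw sums into

* spectral fluence per energy bin with history-by-history uncertainties,
* absorbed dose D,
* restricted cema  C_Delta = sum_i PhiE_i * (S_Delta/rho)_i * dW + TE_Delta
  (bin-centre stopping powers, first bin above Delta),
* the track-end term both directly (sum of sub-Delta kinetic energies) and
  as the dose difference TE_Delta ~ D - sum_i PhiE_i (S_Delta/rho)_i dW,
* the efficiency figure of merit eps = 1/(T sigma^2) and relative gains,

plus the spectrum post-processing used for reporting (moving-average
de-noising and Compton-edge location).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GRAY_PER_MEV_PER_G
from .stopping import RangeTable, StoppingPowerTable

__all__ = [
    "FluenceSpectrum",
    "CemaResult",
    "EfficiencyReport",
    "score_step_fluence",
    "finalize_fluence",
    "finalize_dose",
    "history_uncertainty",
    "restricted_cema",
    "cema_integrand",
    "track_end_from_dose",
    "efficiency",
    "relative_gain",
    "denoise_spectrum",
    "locate_edges",
    "locate_compton_edges",
]


def history_uncertainty(sum_x: float, sum_x2: float, n: int) -> float:
    """Relative standard uncertainty of the mean from history-by-history
    sums: s^2(mean) = [sum_x2/N - (sum_x/N)^2] / (N-1).

    Per-history totals must already aggregate all correlated contributions
    of one history (e.g. from XCSE splitting).
    """
    if n < 2:
        raise ValueError("need at least 2 histories for an uncertainty estimate")
    mean = sum_x / n
    if mean == 0.0:
        return 0.0
    var = (sum_x2 / n - mean * mean) / (n - 1)
    if var < 0.0:
        var = 0.0
    return math.sqrt(var) / abs(mean)


def score_step_fluence(
    bin_edges: np.ndarray,
    e_start: float,
    e_end: float,
    step_length: float,
    weight: float,
    range_table: RangeTable,
    out: np.ndarray,
) -> None:
    """Reference implementation of the sub-step track-length apportionment.

    The step's track length is distributed over every energy bin intersected
    by [e_end, e_start], each bin weighted by its share of the CSDA path
    dl = dE / (rho S(E)); the shares sum to the full step length exactly.
    (The compiled kernel implements the same algorithm.)
    """
    if e_end > e_start:
        raise ValueError("e_end must not exceed e_start")
    delta = bin_edges[0]
    if e_start <= delta:
        return
    e_end = max(e_end, delta)
    i_lo = int(np.searchsorted(bin_edges, e_end, side="right")) - 1
    i_hi = int(np.searchsorted(bin_edges, e_start, side="right")) - 1
    i_hi = min(i_hi, len(out) - 1)
    i_lo = max(i_lo, 0)
    if i_lo == i_hi:
        out[i_lo] += weight * step_length
        return
    r_hi = range_table.range_of(e_start)
    r_lo = range_table.range_of(e_end)
    denom = r_hi - r_lo
    if denom <= 0.0:
        out[i_hi] += weight * step_length
        return
    r_prev = r_lo
    for i in range(i_lo, i_hi + 1):
        eb = bin_edges[i + 1] if i < i_hi else e_start
        eb = min(eb, e_start)
        r_next = range_table.range_of(eb) if eb < e_start else r_hi
        out[i] += weight * step_length * (r_next - r_prev) / denom
        r_prev = r_next


@dataclass
class FluenceSpectrum:
    """Spectral fluence result for one species (or combined)."""

    bin_edges: np.ndarray
    fluence: np.ndarray  # per-bin spectral fluence [unit/MeV]
    rel_uncertainty: np.ndarray
    species: str
    unit: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_mev": self.bin_edges[:-1],
                "bin_high_mev": self.bin_edges[1:],
                "fluence": self.fluence,
                "rel_uncertainty": self.rel_uncertainty,
                "species": self.species,
            }
        )


def finalize_fluence(
    flu_acc: np.ndarray,
    flu_sq: np.ndarray,
    n_histories: int,
    bin_edges: np.ndarray,
    cavity_volume: float,
    divisor: float,
    species: str = "electron",
    unit: str = "MeV^-1 cm^-2",
) -> FluenceSpectrum:
    """Spectral fluence PhiE_i = L_i / (V dW divisor) with history-by-history
    relative uncertainties per bin (L_i: accumulated weighted track length)."""
    if cavity_volume <= 0:
        raise ValueError("cavity volume must be > 0")
    dw = float(bin_edges[1] - bin_edges[0])
    phi = flu_acc / (cavity_volume * dw * divisor)
    rel = np.zeros_like(phi)
    if n_histories >= 2:
        for i in range(len(phi)):
            if flu_acc[i] > 0:
                rel[i] = history_uncertainty(flu_acc[i], flu_sq[i], n_histories)
    return FluenceSpectrum(bin_edges, phi, rel, species, unit)


def finalize_dose(
    dose_acc: float, dose_sq: float, n_histories: int, mass_g: float, divisor: float
) -> tuple[float, float]:
    """(dose, relative uncertainty); dose in Gy (or Gy cm^2 under external
    per-fluence normalization)."""
    if mass_g <= 0:
        raise ValueError("mass must be > 0")
    dose = dose_acc / mass_g * GRAY_PER_MEV_PER_G / divisor
    rel = history_uncertainty(dose_acc, dose_sq, n_histories) if n_histories >= 2 else 0.0
    return dose, rel


@dataclass
class CemaResult:
    """Restricted cema and its two components; units follow the run's
    normalization convention (Gy or Gy cm^2)."""

    c_delta: float
    integral_term: float
    track_end_term: float
    relative_standard_uncertainty: float
    delta: float
    bin_width: float

    def __post_init__(self) -> None:
        if abs(self.c_delta - (self.integral_term + self.track_end_term)) > 1e-12 * max(
            1.0, abs(self.c_delta)
        ):
            raise ValueError("c_delta must equal integral_term + track_end_term")


def cema_integrand(
    spectrum: FluenceSpectrum, stopping: StoppingPowerTable
) -> np.ndarray:
    """Per-bin restricted-cema density PhiE_i * (S_Delta/rho)(E_i) [unit of
    PhiE times MeV cm^2/g]; stopping powers at bin centres (log-log
    interpolated)."""
    if spectrum.bin_edges[0] < stopping.delta - 1e-12:
        raise ValueError("spectrum contains bins below Delta")
    s = stopping.interp_restricted_total(spectrum.bin_centers)
    return spectrum.fluence * s


def restricted_cema(
    spectrum: FluenceSpectrum,
    stopping: StoppingPowerTable,
    track_end_term: float,
    track_end_rel_unc: float = 0.0,
    integral_rel_unc: float | None = None,
) -> CemaResult:
    """Restricted cema from a spectral fluence, the restricted total mass
    stopping power at each bin centre, and the directly tallied track-end
    term.

    When the engine's per-history cema-integral tally is available, pass its
    relative uncertainty as ``integral_rel_unc``; otherwise per-bin
    uncertainties are combined assuming independence between bins, which
    underestimates the variance because one electron populates many adjacent
    bins."""
    dens = cema_integrand(spectrum, stopping)
    dw = spectrum.bin_width
    integral = float(np.sum(dens) * dw)
    if integral_rel_unc is not None:
        var = (integral * integral_rel_unc) ** 2
    else:
        var = float(np.sum((dens * dw * spectrum.rel_uncertainty) ** 2))
    var += (track_end_term * track_end_rel_unc) ** 2
    c = integral + track_end_term
    rel = math.sqrt(var) / abs(c) if c != 0.0 else 0.0
    return CemaResult(c, integral, track_end_term, rel, stopping.delta, dw)


def track_end_from_dose(
    dose: float, spectrum: FluenceSpectrum, stopping: StoppingPowerTable
) -> float:
    """Dose-difference estimate of the track-end term,
    TE_Delta ~ D - sum_i PhiE_i (S_Delta/rho)_i dW (may be negative within
    noise; returned as computed)."""
    integral = float(np.sum(cema_integrand(spectrum, stopping)) * spectrum.bin_width)
    return dose - integral


@dataclass(frozen=True)
class EfficiencyReport:
    quantity: str
    cpu_time: float
    relative_variance: float
    efficiency: float
    gain: float = 1.0


def efficiency(cpu_time: float, relative_variance: float, quantity: str = "dose") -> EfficiencyReport:
    """Figure of merit eps = 1 / (T sigma^2); invariant under changes of the
    number of histories, improved only by genuine variance reduction."""
    if cpu_time <= 0:
        raise ValueError("cpu_time must be > 0")
    if relative_variance <= 0:
        raise ValueError(
            "zero relative variance: deterministic tally, efficiency undefined"
        )
    return EfficiencyReport(quantity, cpu_time, relative_variance, 1.0 / (cpu_time * relative_variance))


def relative_gain(eps_vrt: EfficiencyReport, eps_ref: EfficiencyReport) -> float:
    return eps_vrt.efficiency / eps_ref.efficiency


def denoise_spectrum(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average over ``window`` bins, averaging over the available
    window at the edges; preserves the spectrum integral exactly for
    interior-dominated spectra in the sense of a normalized convolution."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def locate_edges(
    energies: np.ndarray,
    values: np.ndarray,
    n_edges: int = 1,
    e_min: float | None = None,
    e_max: float | None = None,
    min_separation: float = 0.05,
    smooth_window: int = 2,
) -> list[float]:
    """Locate spectral (Compton) edges as the steepest falling gradients of
    the smoothed spectrum, reported at the midpoint of the falling bin pair.

    Repeatedly takes the most negative finite difference within
    [e_min, e_max], masking ``min_separation`` around each find.  Returns
    edge energies sorted descending.
    """
    e = np.asarray(energies, dtype=float)
    v = denoise_spectrum(np.asarray(values, dtype=float), smooth_window)
    grad = np.diff(v)
    mid = 0.5 * (e[:-1] + e[1:])
    mask = np.ones_like(grad, dtype=bool)
    if e_min is not None:
        mask &= mid >= e_min
    if e_max is not None:
        mask &= mid <= e_max
    edges: list[float] = []
    work = grad.copy()
    for _ in range(n_edges):
        work_m = np.where(mask, work, np.inf)
        i = int(np.argmin(work_m))
        if not np.isfinite(work_m[i]) or work_m[i] >= 0:
            break
        edges.append(float(mid[i]))
        mask &= np.abs(mid - mid[i]) > min_separation
    return sorted(edges, reverse=True)


def locate_compton_edges(
    energies: np.ndarray,
    values: np.ndarray,
    photon_lines: np.ndarray,
    line_intensities: np.ndarray,
    n_edges: int,
    smooth_window: int = 2,
    window_half: float = 0.06,
    cluster_tol: float = 0.05,
) -> list[float]:
    """Locate the Compton edges of a line-source electron spectrum.

    The photon line energies (a property of the source, not of the answer)
    fix search windows around each kinematic edge 2E^2/(m_e c^2 + 2E); lines
    whose edges fall within ``cluster_tol`` are merged (intensity-weighted).
    Within each window the edge is the steepest falling finite difference of
    the smoothed spectrum, reported at the midpoint of the falling bin pair
    -- so a simulation with displaced or washed-out edges reports a
    displaced energy.  Returns the ``n_edges`` strongest clusters' edge
    positions, sorted descending.
    """
    from .constants import ELECTRON_REST_MEV as MEC2

    e = np.asarray(energies, dtype=float)
    sm = denoise_spectrum(np.asarray(values, dtype=float), smooth_window)
    grad = np.diff(sm)
    mid = 0.5 * (e[:-1] + e[1:])
    t_edges = sorted(
        zip(
            [2.0 * x * x / (MEC2 + 2.0 * x) for x in np.asarray(photon_lines, float)],
            np.asarray(line_intensities, float),
        )
    )
    clusters: list[tuple[list[float], list[float]]] = []
    for t, i in t_edges:
        if clusters and t - clusters[-1][0][-1] < cluster_tol:
            clusters[-1][0].append(t)
            clusters[-1][1].append(i)
        else:
            clusters.append(([t], [i]))
    ranked = sorted(
        ((sum(i), float(np.average(t, weights=i))) for t, i in clusters), reverse=True
    )
    centers = sorted((t for _, t in ranked[:n_edges]), reverse=True)
    out: list[float] = []
    for t in centers:
        sel = (mid >= t - window_half) & (mid <= t + window_half)
        if not sel.any():
            continue
        gg = np.where(sel, grad, np.inf)
        out.append(float(mid[int(np.argmin(gg))]))
    return out
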