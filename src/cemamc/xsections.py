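"""Photon interaction coefficients and Compton kinematics.

The engine models three photon interactions in the 1 keV - 50 MeV window:

* incoherent (Compton) scattering off free electrons at rest, with the exact
  Klein-Nishina cross section;
* photoelectric absorption, via a compact power-law fit in photon energy and
  atomic number (no atomic relaxation: the full photon energy goes to the
  photoelectron);
* electron-positron pair production, via a Bethe-Heitler-shaped threshold fit
  in Z^2.

Rayleigh scattering, triplet production and bound-Compton corrections are
deliberately absent.  Attenuation coefficients are linear (1/cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    CLASSICAL_ELECTRON_RADIUS_CM,
    ELECTRON_REST_MEV as MEC2,
    PAIR_THRESHOLD_MEV,
    THOMSON_CROSS_SECTION_CM2,
)
from .materials import Material

__all__ = [
    "klein_nishina_total_cross_section",
    "klein_nishina_dcs",
    "compton_mu",
    "photoelectric_mu",
    "pair_mu",
    "total_attenuation",
    "sample_interaction_type",
    "sample_compton",
    "compton_edge",
    "CrossSectionSet",
    "E_MIN",
    "E_MAX",
]

E_MIN = 1e-3
E_MAX = 50.0

# photoelectric fit: tau/rho = C_PE * sum_i w_i Z_i^PE_ZEXP / A_i * E^-PE_EEXP
# [cm^2/g], calibrated to liquid water at 10 keV (~4.9 cm^2/g)
C_PE = 7.33e-9
PE_ZEXP = 4.3
PE_EEXP = 3.1

# pair fit: kappa/rho = C_PP * sum_i w_i Z_i^2 / A_i * (1-E_th/E)^3
#   * ln(1 + (E-E_th)/1.2)  [cm^2/g]
# calibrated to liquid water (nuclear pair + triplet) at 10 MeV (~8.3e-3
# cm^2/g) with the threshold shape matched near 2 MeV (~3.7e-4 cm^2/g)
C_PP = 1.46e-3


def klein_nishina_total_cross_section(energy: float) -> float:
    """Total Klein-Nishina cross section per free electron [cm^2].

    Approaches the Thomson value 0.6652 barn as E -> 0.
    """
    k = energy / MEC2
    if k < 1e-3:
        # low-energy series (the closed form cancels catastrophically here);
        # sigma/sigma_T = 1 - 2k + 26/5 k^2 - 133/10 k^3 + O(k^4)
        return THOMSON_CROSS_SECTION_CM2 * (1.0 - 2.0 * k + 5.2 * k * k - 13.3 * k**3)
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    t1 = (1.0 + k) / (k * k) * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - math.log(1.0 + 2.0 * k) / k)
    t2 = math.log(1.0 + 2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * math.pi * re2 * (t1 + t2 - t3)


def klein_nishina_dcs(energy: float, cos_theta: float) -> float:
    """Klein-Nishina d(sigma)/d(Omega) per electron [cm^2/sr] at photon
    scattering angle theta."""
    k = energy / MEC2
    eps = 1.0 / (1.0 + k * (1.0 - cos_theta))  # E'/E
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    sin2 = 1.0 - cos_theta * cos_theta
    return 0.5 * re2 * eps * eps * (eps + 1.0 / eps - sin2)


def _check_energy(energy: float) -> None:
    if not (E_MIN <= energy <= E_MAX):
        raise ValueError(f"photon energy {energy} MeV outside supported range [{E_MIN}, {E_MAX}]")


def compton_mu(material: Material, energy: float) -> float:
    """Linear Compton attenuation coefficient [1/cm]."""
    _check_energy(energy)
    return klein_nishina_total_cross_section(energy) * material.electron_density_per_cm3


def photoelectric_mu(material: Material, energy: float) -> float:
    """Linear photoelectric attenuation coefficient [1/cm] (power-law fit)."""
    _check_energy(energy)
    zfac = sum(e.mass_fraction * e.Z**PE_ZEXP / e.A for e in material.composition)
    return C_PE * zfac * energy ** (-PE_EEXP) * material.mass_density


def pair_mu(material: Material, energy: float) -> float:
    """Linear pair-production attenuation coefficient [1/cm]; zero below the
    1.022 MeV threshold."""
    _check_energy(energy)
    if energy <= PAIR_THRESHOLD_MEV:
        return 0.0
    zfac = sum(e.mass_fraction * e.Z**2 / e.A for e in material.composition)
    shape = (1.0 - PAIR_THRESHOLD_MEV / energy) ** 3 * math.log1p(
        (energy - PAIR_THRESHOLD_MEV) / 1.2
    )
    return C_PP * zfac * shape * material.mass_density


def total_attenuation(material: Material, energy: float) -> float:
    """Total linear attenuation coefficient mu [1/cm]: Compton +
    photoelectric + pair."""
    return compton_mu(material, energy) + photoelectric_mu(material, energy) + pair_mu(
        material, energy
    )


def sample_interaction_type(material: Material, energy: float, u: float) -> str:
    """Map a uniform deviate ``u`` in [0, 1) onto an interaction kind with
    probabilities proportional to the component coefficients."""
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    mc = compton_mu(material, energy)
    mp = photoelectric_mu(material, energy)
    mpair = pair_mu(material, energy)
    x = u * (mc + mp + mpair)
    if x < mc:
        return "compton"
    if x < mc + mp:
        return "photoelectric"
    return "pair"


def compton_edge(energy: float) -> float:
    """Maximum Compton electron energy 2E^2/(m_e c^2 + 2E) [MeV]."""
    return 2.0 * energy * energy / (MEC2 + 2.0 * energy)


def sample_compton(energy: float, rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Sample a Compton scatter off a free electron at rest.

    Uses the standard two-branch composition-rejection sampler for the
    Klein-Nishina energy distribution.

    Returns
    -------
    (E_scattered, cos_theta_photon, T_electron, cos_theta_electron)
        with exact energy conservation ``E = E_scattered + T_electron``.
    """
    if not (isinstance(energy, (int, float)) and math.isfinite(energy) and energy > 0):
        raise ValueError(f"invalid photon energy {energy!r}")
    k = energy / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = math.log(1.0 / eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = eps_min * math.exp(a1 * rng.random())
        else:
            eps = math.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * rng.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            break
    cos_th = 1.0 - t
    e_sc = eps * energy
    t_el = energy - e_sc
    if t_el > 0.0:
        p_el = math.sqrt(t_el * (t_el + 2.0 * MEC2))
        cos_el = (energy - e_sc * cos_th) / p_el
        cos_el = min(1.0, max(-1.0, cos_el))
    else:
        cos_el = 1.0
    return e_sc, cos_th, t_el, cos_el


@dataclass(frozen=True)
class CrossSectionSet:
    """Component and total attenuation coefficients for one material on a
    log-spaced photon energy grid [MeV]; all coefficients in 1/cm."""

    material: Material
    energy_grid: np.ndarray
    compton: np.ndarray
    photoelectric: np.ndarray
    pair: np.ndarray

    @classmethod
    def build(
        cls, material: Material, e_min: float = E_MIN, e_max: float = E_MAX, n: int = 400
    ) -> "CrossSectionSet":
        grid = np.geomspace(e_min, e_max, n)
        co = np.array([compton_mu(material, float(e)) for e in grid])
        pe = np.array([photoelectric_mu(material, float(e)) for e in grid])
        pp = np.array([pair_mu(material, float(e)) for e in grid])
        return cls(material, grid, co, pe, pp)

    @property
    def total(self) -> np.ndarray:
        return self.compton + self.photoelectric + self.pair
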