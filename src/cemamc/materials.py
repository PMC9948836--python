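"""Material definitions for the transport engine.

A :class:`Material` carries a mass density, an elemental composition by mass
fraction, and the mean excitation energy (I-value) used by the stopping-power
model.  Four common dosimetry media are built in (liquid water, dry air near
sea level, PMMA and graphite); arbitrary media can be declared in the run
configuration by composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import AVOGADRO

__all__ = ["Element", "Material", "water", "air", "pmma", "graphite", "MATERIALS"]

#: symbol -> (atomic number Z, standard atomic weight A [g/mol])
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "F": (9, 18.998),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "Ar": (18, 39.948),
    "Ca": (20, 40.078),
    "Cu": (29, 63.546),
}


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float
    mass_fraction: float


@dataclass(frozen=True)
class Material:
    """A homogeneous medium.

    Parameters
    ----------
    name:
        Identifier used in configurations and reports.
    mass_density:
        Density rho [g/cm^3].
    composition:
        ``(element symbol, mass fraction)`` pairs; fractions must sum to 1.
    mean_excitation_energy_ev:
        Mean excitation energy I [eV] entering the Bethe stopping-power
        logarithm.
    """

    name: str
    mass_density: float
    composition: tuple[Element, ...]
    mean_excitation_energy_ev: float

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError(f"mass_density must be > 0, got {self.mass_density}")
        total = sum(e.mass_fraction for e in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total!r}, expected 1"
            )
        if self.mean_excitation_energy_ev <= 0:
            raise ValueError("mean_excitation_energy_ev must be > 0")

    @classmethod
    def from_composition(
        cls,
        name: str,
        mass_density: float,
        composition: dict[str, float] | list[tuple[str, float]],
        mean_excitation_energy_ev: float,
    ) -> "Material":
        items = composition.items() if isinstance(composition, dict) else composition
        elems = []
        for sym, frac in items:
            if sym not in ELEMENTS:
                raise KeyError(f"unknown element symbol {sym!r}")
            Z, A = ELEMENTS[sym]
            elems.append(Element(sym, Z, A, float(frac)))
        return cls(name, float(mass_density), tuple(elems), float(mean_excitation_energy_ev))

    @property
    def z_over_a(self) -> float:
        """Mass-fraction weighted <Z/A> [mol/g]."""
        return sum(e.mass_fraction * e.Z / e.A for e in self.composition)

    @property
    def electron_density_per_g(self) -> float:
        """Electrons per gram, N_A * <Z/A>."""
        return AVOGADRO * self.z_over_a

    @property
    def electron_density_per_cm3(self) -> float:
        return self.electron_density_per_g * self.mass_density

    @property
    def radiation_length_g_cm2(self) -> float:
        """Approximate radiation length X0 [g/cm^2] (Tsai-style fit,
        composition-weighted by 1/X0); used only for the Highland
        multiple-scattering angle."""
        import math

        inv = 0.0
        for e in self.composition:
            x0_el = 716.4 * e.A / (e.Z * (e.Z + 1) * math.log(287.0 / math.sqrt(e.Z)))
            inv += e.mass_fraction / x0_el
        return 1.0 / inv

    @property
    def radiation_length_cm(self) -> float:
        return self.radiation_length_g_cm2 / self.mass_density


def water() -> Material:
    return Material.from_composition(
        "water", 1.0, {"H": 0.111894, "O": 0.888106}, 78.0
    )


def air() -> Material:
    return Material.from_composition(
        "air",
        1.20479e-3,
        {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828},
        85.7,
    )


def pmma() -> Material:
    return Material.from_composition(
        "pmma", 1.190, {"H": 0.080538, "C": 0.599848, "O": 0.319614}, 74.0
    )


def graphite() -> Material:
    return Material.from_composition("graphite", 1.700, {"C": 1.0}, 81.0)


MATERIALS: dict[str, Material] = {
    m.name: m for m in (water(), air(), pmma(), graphite())
}
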