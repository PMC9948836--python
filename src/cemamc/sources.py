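"""Primary photon sources: tabulated spectra and the two source shapes.

Two spectrum file dialects are supported:

* EGSnrc-style ``.spectrum``: a title line, then ``N, E_low, mode``, then N
  lines of ``upper_edge, value``.  Mode 0 means counts per bin, mode 1 counts
  per MeV (converted by multiplying by the bin width), and mode 2 -- an
  extension of this reader -- means discrete lines given as
  ``energy, intensity`` (``E_low`` is ignored).
* CSV with header ``energy_mev,probability``.  Discrete by default; an
  optional leading comment ``# mode=histogram lowest=<E>`` declares the rows
  to be histogram upper edges above the given lowest edge.

The two source shapes are a collimated point source (ideal pyramid
collimation to a square field defined at the 100 cm reference plane) and an
isotropic point source immersed at the phantom centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectrumTable",
    "SourceConfig",
    "read_spectrum",
    "write_spectrum",
    "sample_primary",
    "normalization_factor",
    "co60_lines",
    "ir192_lines",
    "mv6_histogram",
]


class SpectrumParseError(ValueError):
    """Raised on malformed spectrum files; the message names the line."""


@dataclass(frozen=True)
class SpectrumTable:
    """Tabulated photon spectrum.

    ``mode="discrete"``: ``energies`` are line energies with ``probabilities``
    per line.  ``mode="histogram"``: ``edges`` are N+1 ascending bin edges and
    ``probabilities`` N per-bin probabilities (counts per bin, not per MeV).
    Probabilities are normalized to sum to 1.
    """

    mode: str
    probabilities: np.ndarray
    energies: np.ndarray | None = None
    edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("negative probabilities")
        if p.sum() <= 0:
            raise ValueError("spectrum has zero total intensity")
        object.__setattr__(self, "probabilities", p / p.sum())
        if self.mode == "discrete":
            e = np.asarray(self.energies, dtype=float)
            if np.any(np.diff(e) <= 0):
                raise ValueError("line energies must be strictly increasing")
            object.__setattr__(self, "energies", e)
        elif self.mode == "histogram":
            e = np.asarray(self.edges, dtype=float)
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if len(e) != len(p) + 1:
                raise ValueError("need N+1 edges for N bins")
            object.__setattr__(self, "edges", e)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def max_energy(self) -> float:
        return float(self.energies[-1] if self.mode == "discrete" else self.edges[-1])

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probabilities)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` photon energies [MeV]."""
        idx = np.searchsorted(self.cdf, rng.random(n), side="right")
        idx = np.minimum(idx, len(self.probabilities) - 1)
        if self.mode == "discrete":
            return self.energies[idx]
        lo = self.edges[idx]
        hi = self.edges[idx + 1]
        return lo + rng.random(n) * (hi - lo)

    def mean_energy(self) -> float:
        if self.mode == "discrete":
            return float(np.sum(self.energies * self.probabilities))
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(np.sum(mid * self.probabilities))


def _parse_float_pair(line: str, path: str, lineno: int) -> tuple[float, float]:
    parts = line.replace(",", " ").split()
    if len(parts) < 2:
        raise SpectrumParseError(f"{path}:{lineno}: expected two numbers, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise SpectrumParseError(f"{path}:{lineno}: {exc}") from exc


def read_spectrum(path: str | Path, dialect: str | None = None) -> SpectrumTable:
    """Read a spectrum file; ``dialect`` is ``"egsnrc_spectrum"`` or ``"csv"``
    (inferred from the suffix when omitted)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "egsnrc_spectrum"
    text = path.read_text().splitlines()
    if dialect == "egsnrc_spectrum":
        return _read_egsnrc(text, str(path))
    if dialect == "csv":
        return _read_csv(text, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_egsnrc(lines: list[str], path: str) -> SpectrumTable:
    body = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if len(body) < 2:
        raise SpectrumParseError(f"{path}: truncated file")
    # body[0] is the title line
    lineno, header = body[1]
    parts = header.replace(",", " ").split()
    if len(parts) < 3:
        raise SpectrumParseError(f"{path}:{lineno}: expected 'N, E_low, mode'")
    try:
        n, e_low, mode = int(float(parts[0])), float(parts[1]), int(float(parts[2]))
    except ValueError as exc:
        raise SpectrumParseError(f"{path}:{lineno}: {exc}") from exc
    rows = body[2:]
    if len(rows) < n:
        raise SpectrumParseError(
            f"{path}: truncated file: header promises {n} rows, found {len(rows)}"
        )
    upper = np.empty(n)
    val = np.empty(n)
    for k in range(n):
        lineno, ln = rows[k]
        upper[k], val[k] = _parse_float_pair(ln, path, lineno)
        if val[k] < 0:
            raise SpectrumParseError(f"{path}:{lineno}: negative probability")
    if mode == 2:
        return SpectrumTable("discrete", val, energies=upper)
    if np.any(np.diff(np.concatenate([[e_low], upper])) <= 0):
        raise SpectrumParseError(f"{path}: non-monotone bin edges")
    edges = np.concatenate([[e_low], upper])
    if mode == 1:  # counts per MeV -> counts per bin
        val = val * np.diff(edges)
    elif mode != 0:
        raise SpectrumParseError(f"{path}: unknown mode flag {mode}")
    return SpectrumTable("histogram", val, edges=edges)


def _read_csv(lines: list[str], path: str) -> SpectrumTable:
    mode = "discrete"
    lowest = None
    data_lines: list[tuple[int, str]] = []
    header_seen = False
    for i, raw in enumerate(lines):
        ln = raw.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "mode=histogram" in ln:
                mode = "histogram"
                for tok in ln.replace("#", " ").split():
                    if tok.startswith("lowest="):
                        lowest = float(tok.split("=", 1)[1])
            continue
        if not header_seen:
            if ln.lower().replace(" ", "") != "energy_mev,probability":
                raise SpectrumParseError(
                    f"{path}:{i + 1}: expected header 'energy_mev,probability'"
                )
            header_seen = True
            continue
        data_lines.append((i + 1, ln))
    if not data_lines:
        raise SpectrumParseError(f"{path}: no data rows")
    e = np.empty(len(data_lines))
    p = np.empty(len(data_lines))
    for k, (lineno, ln) in enumerate(data_lines):
        e[k], p[k] = _parse_float_pair(ln, path, lineno)
        if p[k] < 0:
            raise SpectrumParseError(f"{path}:{lineno}: negative probability")
    if mode == "histogram":
        if lowest is None:
            raise SpectrumParseError(f"{path}: histogram CSV needs '# mode=histogram lowest=<E>'")
        edges = np.concatenate([[lowest], e])
        if np.any(np.diff(edges) <= 0):
            raise SpectrumParseError(f"{path}: non-monotone bin edges")
        return SpectrumTable("histogram", p, edges=edges)
    if np.any(np.diff(e) <= 0):
        raise SpectrumParseError(f"{path}: non-monotone line energies")
    return SpectrumTable("discrete", p, energies=e)


def write_spectrum(table: SpectrumTable, path: str | Path, dialect: str, title: str = "spectrum") -> None:
    path = Path(path)
    lines: list[str] = []
    if dialect == "egsnrc_spectrum":
        lines.append(title)
        if table.mode == "discrete":
            lines.append(f"{len(table.probabilities)}, {table.energies[0]:.6g}, 2")
            for e, p in zip(table.energies, table.probabilities):
                lines.append(f"{e:.6g}, {p:.8g}")
        else:
            lines.append(f"{len(table.probabilities)}, {table.edges[0]:.6g}, 0")
            for e, p in zip(table.edges[1:], table.probabilities):
                lines.append(f"{e:.6g}, {p:.8g}")
    elif dialect == "csv":
        if table.mode == "histogram":
            lines.append(f"# mode=histogram lowest={table.edges[0]:.6g}")
            lines.append("energy_mev,probability")
            for e, p in zip(table.edges[1:], table.probabilities):
                lines.append(f"{e:.6g},{p:.8g}")
        else:
            lines.append("energy_mev,probability")
            for e, p in zip(table.energies, table.probabilities):
                lines.append(f"{e:.6g},{p:.8g}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# built-in fixture spectra
# ---------------------------------------------------------------------------


def co60_lines() -> SpectrumTable:
    """Co-60: the two gamma lines at 1.17 and 1.33 MeV, equal weights."""
    return SpectrumTable("discrete", np.array([0.5, 0.5]), energies=np.array([1.1732, 1.3325]))


def ir192_lines() -> SpectrumTable:
    """Ir-192: seven principal gamma lines with approximate emission
    intensities (per decay); all below the pair threshold."""
    e = np.array([0.2960, 0.3085, 0.3165, 0.4681, 0.5885, 0.6044, 0.6125])
    p = np.array([0.287, 0.297, 0.829, 0.478, 0.045, 0.082, 0.053])
    return SpectrumTable("discrete", p, energies=e)


def mv6_histogram() -> SpectrumTable:
    """Simplified 6 MV bremsstrahlung shape: thin-target (E0 - E)/E weighting
    with a 0.25 MeV low-energy cutoff emulating flattening-filter hardening,
    binned at 0.25 MeV up to the 6 MeV endpoint."""
    edges = np.arange(0.25, 6.0 + 1e-9, 0.25)
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = (6.0 - mid) / mid
    return SpectrumTable("histogram", w, edges=edges)


FIXTURES = {"co60": co60_lines, "ir192": ir192_lines, "mv6": mv6_histogram}


# ---------------------------------------------------------------------------
# source configurations and sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceConfig:
    """A photon point source.

    ``collimated_point``: source on the z axis at ``ssd`` upstream of the
    phantom entrance face, ideally collimated to a square
    ``field_size x field_size`` cm^2 defined at the reference plane 100 cm
    from the source.  ``isotropic_point``: source at ``position`` (default
    the phantom centre) emitting uniformly over 4 pi.
    """

    kind: str
    spectrum: SpectrumTable
    ssd: float = 95.0
    field_size: float = 4.0
    reference_distance: float = 100.0
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phantom_half: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("collimated_point", "isotropic_point"):
            raise ValueError(f"unknown source kind {self.kind!r}")

    @property
    def source_position(self) -> tuple[float, float, float]:
        if self.kind == "collimated_point":
            return (0.0, 0.0, -self.phantom_half - self.ssd)
        return self.position

    @property
    def field_area(self) -> float:
        """Field area [cm^2] at the reference plane."""
        return self.field_size**2


def sample_primary(cfg: SourceConfig, rng: np.random.Generator):
    """Sample one primary photon: (energy, position, direction, weight).

    Collimated sources emit uniformly per solid angle into the pyramid
    subtended by the field at the reference plane (rejection on the cos^3
    factor of the plane parametrization); isotropic sources emit uniformly
    over the sphere.
    """
    energy = float(cfg.spectrum.sample(rng, 1)[0])
    pos = np.array(cfg.source_position, dtype=float)
    if cfg.kind == "isotropic_point":
        w = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - w * w))
        d = np.array([s * math.cos(phi), s * math.sin(phi), w])
        return energy, pos, d, 1.0
    half_field = cfg.field_size / 2.0
    dref = cfg.reference_distance
    while True:
        x = (2.0 * rng.random() - 1.0) * half_field
        y = (2.0 * rng.random() - 1.0) * half_field
        r2 = x * x + y * y + dref * dref
        cos3 = (dref / math.sqrt(r2)) ** 3
        if rng.random() <= cos3:
            break
    d = np.array([x, y, dref]) / math.sqrt(r2)
    return energy, pos, d, 1.0


def normalization_factor(cfg: SourceConfig, n_histories: int) -> tuple[float, str, str]:
    """The divisor converting raw tallies to the reporting convention.

    Collimated external beams are normalized per incident photon fluence at
    the reference plane: divisor = N / A_field [cm^-2], so spectral fluence
    carries MeV^-1 and dose Gy cm^2.  The immersed isotropic source is
    normalized per initial particle: divisor = N, spectra in MeV^-1 cm^-2 and
    dose in Gy.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be > 0")
    if cfg.kind == "collimated_point":
        return n_histories / cfg.field_area, "MeV^-1", "Gy cm^2"
    return float(n_histories), "MeV^-1 cm^-2", "Gy"
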