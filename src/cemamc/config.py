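"""Run configuration: a strict YAML schema that round-trips losslessly.

Example::

    run:
      preset: external_disc        # geometry preset
      spectrum: co60               # fixture name or a spectrum file path
      source: collimated_point
      xcse_factor: 256
      shell_r: 0.75
      n_histories: 200000
      seed: 1
      output_dir: out
      transport:
        delta: 0.010
        pcut: 0.010
        estepe: 0.25

Unknown keys anywhere are rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import PRESETS
from .sources import FIXTURES, SpectrumTable, read_spectrum
from .transport import TransportOptions

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_TRANSPORT_KEYS = {
    "delta", "pcut", "estepe", "xcse_enabled", "rr_enabled",
    "mscat_enabled", "score_fluence", "bin_width", "max_substeps",
}
_RUN_KEYS = {
    "preset", "spectrum", "source", "xcse_factor", "shell_r", "depth",
    "phantom_side", "field_size", "ssd", "n_histories", "seed",
    "output_dir", "transport", "materials",
}
_MATERIAL_KEYS = {"name", "density", "composition", "i_value"}


@dataclass
class RunConfig:
    preset: str
    spectrum: str
    source: str
    xcse_factor: float = 1.0
    shell_r: float = 0.0
    depth: float = 5.0
    phantom_side: float = 30.0
    field_size: float = 4.0
    ssd: float = 95.0
    n_histories: int = 100_000
    seed: int = 1
    output_dir: str = "out"
    transport: TransportOptions = field(default_factory=TransportOptions)
    #: extra media declared by composition: [{name, density,
    #: composition: {symbol: mass fraction}, i_value}, ...]; registered into
    #: the material registry on load
    materials: tuple = ()

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.source not in ("collimated_point", "isotropic_point"):
            raise ConfigError(f"unknown source kind {self.source!r}")
        if self.n_histories <= 0:
            raise ConfigError("n_histories must be > 0")

    def spectrum_table(self) -> SpectrumTable:
        if self.spectrum in FIXTURES:
            return FIXTURES[self.spectrum]()
        return read_spectrum(self.spectrum)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transport"] = asdict(self.transport)
        d["materials"] = [dict(items) for items in self.materials]
        if not d["materials"]:
            del d["materials"]
        return {"run": d}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if set(data) != {"run"}:
            raise ConfigError(f"top level must be a single 'run' mapping, got {sorted(data)}")
        run = dict(data["run"])
        unknown = set(run) - _RUN_KEYS
        if unknown:
            raise ConfigError(f"unknown run key(s): {sorted(unknown)}")
        topt = run.pop("transport", {})
        unknown = set(topt) - _TRANSPORT_KEYS
        if unknown:
            raise ConfigError(f"unknown transport key(s): {sorted(unknown)}")
        mats = run.pop("materials", [])
        from .materials import MATERIALS, Material

        declared = []
        for m in mats:
            unknown = set(m) - _MATERIAL_KEYS
            if unknown:
                raise ConfigError(f"unknown material key(s): {sorted(unknown)}")
            try:
                mat = Material.from_composition(
                    m["name"], m["density"], m["composition"], m["i_value"]
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"material {m.get('name', '?')!r}: {exc}") from exc
            MATERIALS[mat.name] = mat
            declared.append(tuple(sorted(m.items(), key=str)))
        try:
            options = TransportOptions(**topt)
            return cls(transport=options, materials=tuple(declared), **run)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    return RunConfig.from_dict(data)
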