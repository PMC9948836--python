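"""Intermediate phase-space scoring (IPSS).

A recording run (``run_simulation(..., ipss_box=(lo, hi))``) captures every
particle entering an axis-aligned box once, at the entry point, and suspends
it there; particles born inside the box during recording are captured at
their birth point.  The captured set can then be replayed against several
detector variants that are identical outside the box, yielding one tally set
per variant from a single upstream simulation -- the standard trick for
computing detector perturbation chains (water voxel -> air voxel -> bare
cavity -> full chamber) in one run.

Replay uses a fresh random stream per (run seed, history id, variant index),
so variant estimates are statistically independent downstream of the box;
history ids are preserved for correct history-by-history uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernel as K
from .geometry import GeometryModel
from .transport import (
    CompiledModel,
    RawTallies,
    RunResult,
    TransportOptions,
    _alloc_tallies,
)

__all__ = ["PhaseSpace", "replay", "validate_variant"]

_DTYPE = np.dtype(
    [
        ("kind", np.int8),
        ("energy", np.float64),
        ("x", np.float64),
        ("y", np.float64),
        ("z", np.float64),
        ("u", np.float64),
        ("v", np.float64),
        ("w", np.float64),
        ("weight", np.float64),
        ("history", np.int64),
    ]
)


@dataclass
class PhaseSpace:
    """Recorded particle states on the IPSS box surface."""

    kind: np.ndarray
    energy: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    weight: np.ndarray
    history: np.ndarray
    box_lo: np.ndarray
    box_hi: np.ndarray
    n_histories: int
    seed: int

    def __len__(self) -> int:
        return len(self.energy)

    def to_structured(self) -> np.ndarray:
        arr = np.empty(len(self), dtype=_DTYPE)
        arr["kind"] = self.kind
        arr["energy"] = self.energy
        arr["x"], arr["y"], arr["z"] = self.x, self.y, self.z
        arr["u"], arr["v"], arr["w"] = self.u, self.v, self.w
        arr["weight"] = self.weight
        arr["history"] = self.history
        return arr

    def save(self, path: str | Path) -> None:
        """Flat binary file: a structured array plus box/run metadata."""
        np.savez(
            path,
            records=self.to_structured(),
            box_lo=self.box_lo,
            box_hi=self.box_hi,
            n_histories=self.n_histories,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhaseSpace":
        with np.load(path) as f:
            rec = f["records"]
            return cls(
                kind=rec["kind"].astype(np.int64),
                energy=rec["energy"].copy(),
                x=rec["x"].copy(), y=rec["y"].copy(), z=rec["z"].copy(),
                u=rec["u"].copy(), v=rec["v"].copy(), w=rec["w"].copy(),
                weight=rec["weight"].copy(),
                history=rec["history"].copy(),
                box_lo=f["box_lo"].copy(),
                box_hi=f["box_hi"].copy(),
                n_histories=int(f["n_histories"]),
                seed=int(f["seed"]),
            )


def validate_variant(recording: GeometryModel, variant: GeometryModel, box_lo, box_hi) -> None:
    """Variants must be identical to the recording geometry outside the box
    and must keep all differing bodies inside it."""
    lo = np.asarray(box_lo, dtype=float)
    hi = np.asarray(box_hi, dtype=float)
    if recording.phantom_half_size != variant.phantom_half_size:
        raise ValueError("variant phantom differs from the recording geometry")

    def outside(b):
        c = np.array(b.center)
        blo = c - np.array([b.radius, b.radius, b.half_height])
        bhi = c + np.array([b.radius, b.radius, b.half_height])
        return np.any(blo < lo - 1e-12) or np.any(bhi > hi + 1e-12)

    rec_out = [(b.center, b.radius, b.half_height, b.region.material.name)
               for b in recording.bodies if outside(b)]
    var_out = [(b.center, b.radius, b.half_height, b.region.material.name)
               for b in variant.bodies if outside(b)]
    if rec_out != var_out:
        raise ValueError(
            "variant geometry differs outside the phase-space box; "
            "IPSS replay would be biased"
        )


def replay(
    ps: PhaseSpace,
    variant: GeometryModel,
    source,
    options: TransportOptions,
    *,
    recording_geometry: GeometryModel | None = None,
    variant_index: int = 1,
) -> RunResult:
    """Transport all recorded particles through a detector variant.

    ``source`` is needed only for material/binning metadata (the spectrum
    defines the fluence bin range); primaries are the records themselves.
    """
    if recording_geometry is not None:
        validate_variant(recording_geometry, variant, ps.box_lo, ps.box_hi)
    model = CompiledModel(variant, source, options)
    t = _alloc_tallies(model.n_regions, model.n_bins)
    import time

    t0 = time.process_time()
    code = K.replay_batch(
        len(ps),
        np.asarray(ps.kind, dtype=np.int64),
        ps.energy, ps.x, ps.y, ps.z, ps.u, ps.v, ps.w, ps.weight,
        np.asarray(ps.history, dtype=np.int64),
        np.uint64(ps.seed),
        np.uint64(variant_index),
        model.geom_tuple,
        model.mats_tuple,
        model.opt_tuple(),
        t["dose_acc"], t["dose_sq"], t["dose_buf"],
        t["te_acc"], t["te_sq"], t["te_buf"],
        t["flu_acc"], t["flu_sq"], t["flu_buf"],
        t["touched"], t["ntouched"], t["sites"],
        t["fsum_acc"], t["fsum_sq"], t["fsum_buf"],
        t["csum_acc"], t["csum_sq"], t["csum_buf"],
        model.cema_weights, t["aud"],
    )
    cpu = time.process_time() - t0
    if code != 0:
        raise RuntimeError("particle stack overflow during replay")
    tallies = RawTallies(
        ps.n_histories,
        t["dose_acc"], t["dose_sq"], t["te_acc"], t["te_sq"],
        t["flu_acc"], t["flu_sq"], t["sites"], t["aud"],
        t["fsum_acc"], t["fsum_sq"], t["csum_acc"], t["csum_sq"],
    )
    return RunResult(model, tallies, cpu, ps.seed)
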