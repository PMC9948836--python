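"""Monte Carlo engine orchestration.

This module turns a :class:`~cemamc.geometry.GeometryModel` plus a
:class:`~cemamc.sources.SourceConfig` into the flat array representation the
compiled kernels consume, runs histories, and returns raw tallies.

Physics summary of the engine:

* analog photon transport (Compton / photoelectric / pair) with optional
  photon cross-section enhancement (XCSE): inside regions with enhancement
  factor b > 1, free paths are sampled with b*mu and each interaction site
  produces an interacting copy of weight w/b while the original photon
  continues with weight w(1 - 1/b); scattered photons of weight w/b play
  Russian roulette with survival 1/b and are restored to analog weight;
* condensed-history electron/positron transport: continuous losses from the
  restricted (Delta) collision plus radiative stopping power, discrete
  Moller knock-ons above Delta, single-Gaussian (Highland) multiple
  scattering per step, region-based kinetic-energy cutoffs, local deposition
  plus track-end tallying below the cutoff, and positron annihilation at
  rest into two opposed 511 keV photons.

All scoring is passive: attaching or detaching fluence tallies does not
change the random-number sequence, so dose tallies are bit-identical either
way.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .geometry import GeometryModel
from .materials import Material
from .sources import SourceConfig, normalization_factor
from .stopping import RangeTable, StoppingPowerTable
from .xsections import CrossSectionSet

__all__ = [
    "TransportOptions",
    "Particle",
    "CompiledModel",
    "RawTallies",
    "RunResult",
    "run_simulation",
    "russian_roulette",
    "xcse_split_weights",
]

PH_EMIN, PH_EMAX, PH_N = 1e-3, 50.0, 600
EL_EMIN, EL_EMAX, EL_N = 1e-3, 20.0, 640


@dataclass(frozen=True)
class TransportOptions:
    """Transport parameters (defaults follow standard small-cavity practice:
    Delta = PCUT = 10 keV kinetic, ESTEPE = 0.25)."""

    delta: float = 0.010
    pcut: float = 0.010
    estepe: float = 0.25
    xcse_enabled: bool = True
    rr_enabled: bool = True
    mscat_enabled: bool = True
    score_fluence: bool = True
    bin_width: float = 0.005
    max_substeps: int = 10_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.estepe <= 0.5:
            raise ValueError("estepe must be in (0, 0.5]")
        if self.delta <= 0 or self.pcut <= 0:
            raise ValueError("delta and pcut must be > 0")


@dataclass
class Particle:
    """A transportable particle (public-facing record type)."""

    kind: str
    kinetic_energy: float
    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float = 1.0
    region: int = 1
    history: int = 0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        d = np.asarray(self.direction, dtype=float)
        if abs(float(d @ d) - 1.0) > 1e-10:
            raise ValueError("direction must be unit length")


def russian_roulette(particle: Particle, survival_probability: float, rng) -> Particle | None:
    """Play Russian roulette: survive with probability p and weight /= p."""
    if not 0.0 < survival_probability <= 1.0:
        raise ValueError("survival probability must be in (0, 1]")
    if survival_probability >= 1.0 or rng.random() < survival_probability:
        return Particle(
            particle.kind,
            particle.kinetic_energy,
            particle.position,
            particle.direction,
            particle.weight / survival_probability,
            particle.region,
            particle.history,
        )
    return None


def xcse_split_weights(weight: float, b: float) -> tuple[float, float]:
    """Weight algebra of an XCSE split: (interacting copy, surviving photon).

    The two parts sum to the original weight exactly.
    """
    if b <= 1.0:
        raise ValueError("enhancement factor b must be > 1")
    wi = weight / b
    return wi, weight - wi


class CompiledModel:
    """Flat-array representation of geometry + materials + source for the
    compiled kernels."""

    def __init__(
        self,
        geometry: GeometryModel,
        source: SourceConfig,
        options: TransportOptions,
    ) -> None:
        self.geometry = geometry
        self.source_config = source
        self.options = options

        # --- material tables -------------------------------------------------
        mats: list[Material] = []
        mat_index: dict[str, int] = {}
        for reg in geometry.regions:
            if reg.material.name not in mat_index:
                mat_index[reg.material.name] = len(mats)
                mats.append(reg.material)
        self.materials = mats
        nmat = len(mats)

        ph_grid = np.geomspace(PH_EMIN, PH_EMAX, PH_N)
        mu_tot = np.empty((nmat, PH_N))
        mu_c = np.empty((nmat, PH_N))
        mu_p = np.empty((nmat, PH_N))
        mu_pp = np.empty((nmat, PH_N))
        el_grid = np.geomspace(EL_EMIN, EL_EMAX, EL_N)
        ln_scont = np.empty((nmat, EL_N))
        ln_range = np.empty((nmat, EL_N))
        sig_hard = np.empty((nmat, EL_N))
        x0cm = np.empty(nmat)
        self.range_tables: list[RangeTable] = []
        self.stopping_tables: list[StoppingPowerTable] = []
        from .stopping import hard_moller_cross_section

        for i, m in enumerate(mats):
            xsec = CrossSectionSet.build(m, PH_EMIN, PH_EMAX, PH_N)
            mu_c[i] = xsec.compton
            mu_p[i] = xsec.photoelectric
            mu_pp[i] = xsec.pair
            mu_tot[i] = xsec.total
            spt = StoppingPowerTable.build(m, options.delta, EL_EMIN, EL_EMAX, EL_N)
            # continuous (restricted collision + radiative) linear stopping
            # power interpolated onto the kernel grid
            s_cont = np.exp(
                np.interp(np.log(el_grid), np.log(spt.energy_grid), np.log(spt.restricted_total))
            ) * m.mass_density
            rt_src = RangeTable.build(spt)
            r = np.array([rt_src.range_of(float(e)) for e in el_grid])
            ln_scont[i] = np.log(s_cont)
            ln_range[i] = np.log(r)
            sig_hard[i] = np.array(
                [hard_moller_cross_section(m, float(e), options.delta) for e in el_grid]
            )
            x0cm[i] = m.radiation_length_cm
            self.range_tables.append(RangeTable(m, el_grid, r))
            self.stopping_tables.append(spt)

        self.mats_tuple = (
            math.log(PH_EMIN),
            math.log(ph_grid[1] / ph_grid[0]),
            mu_tot,
            mu_c,
            mu_p,
            mu_pp,
            math.log(EL_EMIN),
            math.log(el_grid[1] / el_grid[0]),
            np.log(el_grid),
            ln_scont,
            ln_range,
            sig_hard,
            x0cm,
        )

        # --- geometry arrays -------------------------------------------------
        nb = len(geometry.bodies)
        cyl = np.zeros((nb, 5))
        cylreg = np.zeros(nb, dtype=np.int64)
        for i, b in enumerate(geometry.bodies):
            cyl[i, 0:3] = b.center
            cyl[i, 3] = b.radius
            cyl[i, 4] = b.half_height
            cylreg[i] = 2 + i
        half = np.asarray(geometry.phantom_half_size, dtype=float)
        nreg = geometry.n_regions
        matidx = np.zeros(nreg, dtype=np.int64)
        bfac = np.ones(nreg)
        ecut = np.full(nreg, options.delta)
        iscav = np.zeros(nreg, dtype=np.int64)
        for reg in geometry.regions:
            matidx[reg.id] = mat_index[reg.material.name]
            bfac[reg.id] = reg.xcse_factor
            ecut[reg.id] = max(reg.ecut_kinetic, options.delta)
            iscav[reg.id] = 1 if reg.is_scoring_cavity else 0
        self.geom_tuple = (cyl, cylreg, half, matidx, bfac, ecut, iscav)
        self.n_regions = nreg
        self.cavity_regions = [r.id for r in geometry.regions if r.is_scoring_cavity]

        # --- source arrays ---------------------------------------------------
        spec = source.spectrum
        cdf = spec.cdf
        if spec.mode == "discrete":
            disc, evals, edges = 1, spec.energies, np.zeros(2)
        else:
            disc, evals, edges = 0, np.zeros(2), spec.edges
        sx, sy, sz = source.source_position
        kind = 0 if source.kind == "collimated_point" else 1
        self.src_tuple = (
            kind,
            float(sx),
            float(sy),
            float(sz),
            source.field_size / 2.0,
            float(source.reference_distance),
            disc,
            np.asarray(cdf, dtype=float),
            np.asarray(evals, dtype=float),
            np.asarray(edges, dtype=float),
        )

        # --- binning ---------------------------------------------------------
        emax = spec.max_energy
        self.bin_width = options.bin_width
        self.n_bins = max(1, int(math.ceil((emax - options.delta) / options.bin_width)))
        self.bin_edges = options.delta + options.bin_width * np.arange(self.n_bins + 1)
        # restricted total stopping power of the cavity material at bin
        # centres: the weights of the per-history cema-integral tally
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        if self.cavity_regions:
            cav_mat = int(matidx[self.cavity_regions[0]])
            self.cema_weights = np.asarray(
                self.stopping_tables[cav_mat].interp_restricted_total(centers), dtype=float
            )
        else:
            self.cema_weights = np.zeros(self.n_bins)

    def opt_tuple(self, score_fluence: bool | None = None) -> tuple:
        o = self.options
        sf = o.score_fluence if score_fluence is None else score_fluence
        return (
            o.delta,
            o.pcut,
            o.estepe,
            1 if o.xcse_enabled else 0,
            1 if o.rr_enabled else 0,
            1 if o.mscat_enabled else 0,
            1 if sf else 0,
            self.bin_width,
            self.n_bins,
        )

    def cavity_volume(self) -> float:
        v = 0.0
        for i, b in enumerate(self.geometry.bodies):
            if b.region.is_scoring_cavity:
                v += math.pi * b.radius**2 * 2.0 * b.half_height
                # subtract nested later bodies (e.g. central electrode)
                for c in self.geometry.bodies[i + 1 :]:
                    if (
                        c.radius <= b.radius
                        and abs(c.center[2] - b.center[2]) + c.half_height <= b.half_height + 1e-12
                    ):
                        v -= math.pi * c.radius**2 * 2.0 * c.half_height
        return v

    def cavity_mass(self) -> float:
        for b in self.geometry.bodies:
            if b.region.is_scoring_cavity:
                return self.cavity_volume() * b.region.material.mass_density
        raise ValueError("geometry has no scoring cavity")


@dataclass
class RawTallies:
    """Raw per-run accumulators (sums over histories and of squared
    per-history totals), in MeV and MeV*cm units, unnormalized."""

    n_histories: int
    dose_acc: np.ndarray
    dose_sq: np.ndarray
    te_acc: np.ndarray
    te_sq: np.ndarray
    flu_acc: np.ndarray
    flu_sq: np.ndarray
    sites: np.ndarray
    audit: np.ndarray
    # per-history scalar sums: total cavity track length and the
    # stopping-power-weighted (cema integral) track length, indexed
    # [electron, positron, combined]
    fsum_acc: np.ndarray = None
    fsum_sq: np.ndarray = None
    csum_acc: np.ndarray = None
    csum_sq: np.ndarray = None


@dataclass
class RunResult:
    model: CompiledModel
    tallies: RawTallies
    cpu_time: float
    seed: int
    phase_space: "object | None" = None

    @property
    def audit(self) -> dict[str, float]:
        a = self.tallies.audit
        return {
            "emitted": a[K.AUD_EMITTED],
            "deposited": a[K.AUD_DEPOSITED],
            "escaped": a[K.AUD_ESCAPED],
            "rr_killed": a[K.AUD_RR_KILLED],
            "rr_boost": a[K.AUD_RR_BOOST],
            "mass_sink": a[K.AUD_MASS_SINK],
            "mass_source": a[K.AUD_MASS_SOURCE],
            "discarded_below_pcut": a[K.AUD_SUBPCUT],
            "max_history_imbalance": a[K.AUD_MAX_IMBALANCE],
            "primary_uncollided": a[K.AUD_PRIMARY_UNCOLLIDED],
        }


def _alloc_tallies(nreg: int, nbins: int):
    return dict(
        dose_acc=np.zeros(nreg),
        dose_sq=np.zeros(nreg),
        dose_buf=np.zeros(nreg),
        te_acc=np.zeros(nreg),
        te_sq=np.zeros(nreg),
        te_buf=np.zeros(nreg),
        flu_acc=np.zeros((2, nbins)),
        flu_sq=np.zeros((2, nbins)),
        flu_buf=np.zeros((2, nbins)),
        touched=np.zeros(2 * nbins, dtype=np.int64),
        ntouched=np.zeros(1, dtype=np.int64),
        sites=np.zeros(nreg, dtype=np.int64),
        fsum_acc=np.zeros(3),
        fsum_sq=np.zeros(3),
        fsum_buf=np.zeros(3),
        csum_acc=np.zeros(3),
        csum_sq=np.zeros(3),
        csum_buf=np.zeros(3),
        aud=np.zeros(K.AUD_SIZE),
    )


def _inert_ipss():
    lo = np.zeros(3)
    hi = np.zeros(3)
    di = np.zeros(1, dtype=np.int64)
    df = np.zeros(1)
    err = np.zeros(1, dtype=np.int64)
    return (0, lo, hi, di, df, df, df, df, df, df, df, df, di, di, err)


def run_simulation(
    geometry: GeometryModel,
    source: SourceConfig,
    options: TransportOptions,
    n_histories: int,
    seed: int,
    *,
    score_fluence: bool | None = None,
    ipss_box: tuple[np.ndarray, np.ndarray] | None = None,
    record_capacity: int | None = None,
    variant: int = 0,
    hist_offset: int = 0,
) -> RunResult:
    """Run ``n_histories`` primary histories and return raw tallies.

    With ``ipss_box=(lo, hi)`` the run records every particle entering the
    axis-aligned box once and suspends it there (phase-space recording
    pass); the records are attached to the result as a
    :class:`~cemamc.phase_space.PhaseSpace`.
    """
    model = CompiledModel(geometry, source, options)
    t = _alloc_tallies(model.n_regions, model.n_bins)
    if ipss_box is not None:
        from .phase_space import PhaseSpace

        cap = record_capacity or max(4 * n_histories, 1000)
        lo = np.asarray(ipss_box[0], dtype=float)
        hi = np.asarray(ipss_box[1], dtype=float)
        rkind = np.zeros(cap, dtype=np.int64)
        re_ = np.zeros(cap)
        rx, ry, rz = np.zeros(cap), np.zeros(cap), np.zeros(cap)
        ru, rv, rw = np.zeros(cap), np.zeros(cap), np.zeros(cap)
        rwt = np.zeros(cap)
        rhist = np.zeros(cap, dtype=np.int64)
        rcount = np.zeros(1, dtype=np.int64)
        err = np.zeros(1, dtype=np.int64)
        ipss = (1, lo, hi, rkind, re_, rx, ry, rz, ru, rv, rw, rwt, rhist, rcount, err)
    else:
        ipss = _inert_ipss()
    t0 = time.process_time()
    code = K.run_batch(
        n_histories,
        hist_offset,
        np.uint64(seed),
        np.uint64(variant),
        model.src_tuple,
        model.geom_tuple,
        model.mats_tuple,
        model.opt_tuple(score_fluence),
        t["dose_acc"], t["dose_sq"], t["dose_buf"],
        t["te_acc"], t["te_sq"], t["te_buf"],
        t["flu_acc"], t["flu_sq"], t["flu_buf"],
        t["touched"], t["ntouched"], t["sites"],
        t["fsum_acc"], t["fsum_sq"], t["fsum_buf"],
        t["csum_acc"], t["csum_sq"], t["csum_buf"],
        model.cema_weights, t["aud"], ipss,
    )
    cpu = time.process_time() - t0
    if code == 1:
        raise RuntimeError(
            "particle stack overflow: weight/splitting misconfiguration "
            "(XCSE factor too large for the stack guard?)"
        )
    if code == 2:
        raise RuntimeError("phase-space record buffer full; raise record_capacity")
    tallies = RawTallies(
        n_histories,
        t["dose_acc"], t["dose_sq"], t["te_acc"], t["te_sq"],
        t["flu_acc"], t["flu_sq"], t["sites"], t["aud"],
        t["fsum_acc"], t["fsum_sq"], t["csum_acc"], t["csum_sq"],
    )
    result = RunResult(model, tallies, cpu, seed)
    if ipss_box is not None:
        from .phase_space import PhaseSpace

        n = int(ipss[13][0])
        result.phase_space = PhaseSpace(
            kind=ipss[3][:n].copy(),
            energy=ipss[4][:n].copy(),
            x=ipss[5][:n].copy(), y=ipss[6][:n].copy(), z=ipss[7][:n].copy(),
            u=ipss[8][:n].copy(), v=ipss[9][:n].copy(), w=ipss[10][:n].copy(),
            weight=ipss[11][:n].copy(),
            history=ipss[12][:n].copy(),
            box_lo=lo.copy(), box_hi=hi.copy(),
            n_histories=n_histories,
            seed=seed,
        )
    return result
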