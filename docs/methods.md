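# Methods

This note documents the physics model, the estimators, the variance
reduction, the numerical choices, and the limits of what the test suite can
demonstrate.

## Transport model

**Photons** undergo three interactions between 1 keV and 50 MeV:

* *Compton scattering* off free electrons at rest, with the exact
  Klein–Nishina differential cross section (two-branch composition–
  rejection sampling).  No binding, no Doppler broadening: the scattered
  electron energy therefore has a sharp kinematic maximum
  $T_{max} = 2E^2/(m_ec^2+2E)$ — the Compton edge the benchmarks look for.
* *Photoelectric absorption*, with a compact power-law fit
  $\tau/\rho \propto \langle Z^{4.3}/A\rangle\,E^{-3.1}$ normalized to
  liquid water at 10 keV (≈4.9 cm²/g).  No atomic relaxation: the full
  photon energy becomes photoelectron kinetic energy, emitted forward.
* *Pair production* above 1.022 MeV, with a Bethe–Heitler-shaped threshold
  fit $\kappa/\rho \propto \langle Z^2/A\rangle(1-E_{th}/E)^3
  \ln(1+(E-E_{th})/1.2)$ normalized to water near 10 MeV (≈8.3×10⁻³ cm²/g)
  with the threshold behaviour matched near 2 MeV (≈3.7×10⁻⁴ cm²/g).  The
  available kinetic energy is split uniformly between the pair, both
  emitted forward.

Rayleigh scattering, triplet production, photonuclear reactions and bound-
Compton corrections are deliberately absent.  Below about 50 keV the total
attenuation is therefore a few percent low relative to full-physics
libraries; all consistency properties tested here are internal and do not
depend on that fidelity.

**Electrons and positrons** are transported with a class-II condensed-
history scheme:

* Continuous energy loss at the *restricted* collision stopping power
  (Berger–Seltzer/Møller closed form with the restriction function
  $G^-(\tau,\eta)$, verified in the tests against direct quadrature of the
  Møller spectrum to 10⁻⁶) plus the radiative stopping power (compact fit
  ∝ ⟨Z(Z+1)/A⟩(T+m_ec²), water-calibrated at 1 MeV).  Radiative losses are
  deposited continuously and locally; no bremsstrahlung photons are
  created.  A Sternheimer-recipe density-effect correction is applied by
  default and can be switched off.
* Discrete Møller knock-ons for transfers above Δ (rejection sampling
  against a 1/ε² envelope), with exact two-body kinematics for both the
  knock-on and the deflected primary.  Positrons use the same sampler
  (no Bhabha refinement) and annihilate at rest into two opposed 511 keV
  photons.
* One Gaussian (Highland) multiple-scattering deflection per condensed
  step, on by default, toggleable.
* Steps are limited by the region boundary, by a maximum fractional energy
  loss ESTEPE, by the residual path to the cutoff, and by the sampled
  distance to the next hard collision (cross section frozen at the step's
  start energy — a standard approximation whose error is bounded by the
  ESTEPE limit).  Energy–path conversions use a per-material CSDA range
  table against the continuous (restricted total) stopping power; the
  forward and inverse mappings share the same piecewise log-log relation
  and are therefore exact inverses of each other.
* When the kinetic energy falls below the region cutoff (kinetic ECUT,
  ≥ Δ; both default to 10 keV) the remainder is deposited locally **and**
  recorded in the track-end tally.

Everything outside the phantom is vacuum; the phantom is convex, so charged
particles that leave never return and photons travel force-free until they
re-enter or escape.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| Δ (`delta`) | 0.010 MeV | charged-particle production/tracking threshold; also the lower edge of the fluence binning |
| PCUT (`pcut`) | 0.010 MeV | photon cutoff; lower-energy photons deposit locally |
| ESTEPE (`estepe`) | 0.25 | maximum fractional continuous energy loss per condensed step |
| `bin_width` | 0.005 MeV | fluence/cema spectral bin width |
| XCSE factor b | preset-dependent | cross-section multiplication in enhancement regions |
| shell radius r | preset-dependent | thickness of the water shell around the detector in which XCSE is on |

The benchmark presets use the optimum (b, r) combinations reported for the
corresponding full-scale setups: Co-60 water disc (256, 0.75 cm), chamber
(512, 0.5 cm); 6 MV disc (64, 1 cm); Ir-192 immersed disc (512, 0.25 cm),
chamber (1024, 0).  Default history counts (2×10⁵ line sources, 5×10⁵ for
6 MV) were chosen so each benchmark finishes in well under a minute of
transport time on one core with cavity-dose uncertainties of a few
percent; at these sizes the spectral bins near weak lines still carry
10–30% noise, which is the regime the windowed edge locator (below) is
designed for.

## Estimators

* **Fluence**: track-length estimation; every charged-particle step inside
  a scoring cavity contributes its length, apportioned over the energy bins
  it traverses in proportion to the CSDA path per bin
  (dℓ = dE/(ρS(E))), so a step's contributions sum to its exact length.
  This removes the constant-stopping-power-per-step approximation that
  plain bin-of-the-midpoint scoring makes, which matters only in the first
  bin above Δ where S varies steeply.
* **Dose**: all continuous losses, sub-threshold deposits and sub-PCUT
  photon absorptions, per region.
* **Restricted cema**: $C_\Delta = \sum_i \bar\Phi_{E,i}(S_\Delta/\rho)_i\,
  dW + TE_\Delta$ with the restricted **total** (collision + radiative)
  stopping power of the cavity medium at bin centres (log-log
  interpolation), starting at the first bin above Δ.  Because the engine
  also deposits radiative losses continuously, $C_\Delta = D$ holds in
  charged-particle equilibrium by construction — that equality, and the
  agreement of the direct track-end tally with the dose-difference estimate
  $TE_\Delta \approx D-\sum_i\bar\Phi_{E,i}(S_\Delta/\rho)_i dW$, are the
  consistency properties the acceptance suite checks.
* **Uncertainties**: history-by-history second moments for every tally.
  The kernel additionally accumulates, per history and species, the total
  cavity track length and its stopping-power-weighted version, so the
  uncertainties of the fluence integral and of the cema sum include the
  full within-history correlation between bins.  Per-bin uncertainties in
  the exported spectra are per-bin only; combining them across bins as if
  independent underestimates integral errors by a large factor — use the
  scalar tallies instead.
* **Efficiency**: ε = 1/(Tσ²) with T the process CPU time of the transport
  loop (table building and I/O excluded); gains are always quoted against
  an analog run of the same configuration at equal histories.

## Variance reduction

XCSE samples photon free paths with bμ inside enhancement regions
(consistently re-sampled across region boundaries via mean-free-path
bookkeeping, which is exact for exponential transport).  At each enhanced
site the interaction kind is sampled from the *true* component cross
sections; charged secondaries receive weight w/b, the original photon
continues with weight w(1−1/b), and the scattered photon (weight w/b)
survives Russian roulette with probability 1/b, restored to analog weight
w.  Weight is conserved exactly at every split; unbiasedness is verified
against analog runs at b ∈ {2, 16, 64, 256} for dose, fluence integral and
cema on a fattened scoring disc (the 0.1 cm preset scores essentially no
analog events at desk scale, which would make the comparison vacuous).
The per-history energy ledger (emitted + rest-mass sources + roulette
boosts = deposited + escaped + roulette kills + rest-mass sinks) closes to
~10⁻¹⁴ relative in every configuration, with and without XCSE.

IPSS records each particle entering a user-defined box once, at the entry
surface (particles born inside during recording are captured at birth), and
replays the set against detector variants that are identical outside the
box.  Replay seeds a fresh stream per (run seed, history id, variant), so
variant estimates are independent downstream of the box; history ids are
preserved for the uncertainty estimator.  Whether sharing post-box random
numbers across variants (which would correlate the estimates) is preferable
is left open; independent streams are the simpler, defensible choice.

## Random numbers and determinism

Each history uses its own xoroshiro128+ stream seeded by mixing
(run seed, history id, variant index) through splitmix64.  Consequences:
runs are bit-reproducible, chunkable and restartable; scoring is passive
(fluence tallies attached or not, the dose tallies are bit-identical); and
replay streams are well-defined.  All samplers consume from the single
per-history stream in a fixed call order.

## Edge location

At desk-scale statistics a global steepest-descent search over the whole
spectrum is dominated by per-bin noise on the slowing-down continuum.  The
locator therefore derives search windows (±0.06 MeV) from the *source line
energies* — inputs of the simulation, not results — via the kinematic edge
formula, merging lines whose edges lie within 0.05 MeV (intensity-weighted
centres), and reports the steepest falling finite difference of the
2-bin-smoothed spectrum inside each window, at the midpoint of the falling
bin pair.  A simulation with displaced or washed-out edges reports a wrong
energy, so the check keeps its power; edges more than the window half-width
away from the kinematic position are not found at all, which also fails the
check.

## Synthetic spectra

The bundled sources emulate the qualitative structure of the literature
spectra they stand in for: Co-60 as two equal lines (1.1732, 1.3325 MeV);
Ir-192 as its seven principal gamma lines with approximate per-decay
intensities (all below the pair threshold); 6 MV as a thin-target-shaped
histogram (E₀−E)/E with a 0.25 MeV cutoff and 6 MeV endpoint.  They
reproduce line positions and endpoints — which is what the edge and
positron-share measurements depend on — but not the detailed fluence
weighting of a clinical accelerator spectrum; absolute doses per fluence
are therefore engine-specific numbers, not literature reproductions.

## Numerical choices

* Tables: photon coefficients on a 600-point log grid (1 keV–50 MeV),
  electron quantities on a 640-point log grid (1 keV–20 MeV); linear
  interpolation in ln E for cross sections, log-log for stopping powers and
  ranges.
* Boundaries: crossings resolved by a 10⁻⁹ cm push-past; overlapping
  bodies resolved by list order (later wins), with presets built
  innermost-last.
* Møller sampling envelope bound 2 + g²/4 (provably ≥ the rejection
  function on [Δ/E, ½]).
* De-noising: renormalized moving average (2 bins; 5 for the 6 MV
  spectrum).  It preserves constants exactly everywhere and the integral
  exactly for spectra vanishing within a window of the array ends — true of
  physical spectra, which vanish at Δ and at the kinematic endpoint.
* Degenerate inputs: zero-length steps score nothing; spectra with all
  mass in one bin, single-line sources, and cavities containing nested
  bodies (electrode subtracted from cavity volume/mass) are handled
  explicitly.

## Known limitations

* Photon physics fidelity: no Rayleigh/bound-Compton/relaxations; analytic
  photoelectric and pair fits are 10–40% off full libraries in places.
  Internal consistency (C_Δ = D, unbiasedness, determinism, kinematics) is
  unaffected; absolute doses are not library-grade.
* Radiative losses deposit locally; in reality bremsstrahlung photons
  transport energy away (≲1% effect in water below Co-60 energies, a few
  percent at 6 MV).
* Positrons annihilate only at rest; in-flight annihilation is neglected.
* Hard-collision distances are sampled at the step's start energy.
* The "thimble chamber" is a generic simplified model (air cavity r = 0.1,
  length 0.5 cm; PMMA wall 0.06 cm; graphite electrode r = 0.015 cm; PMMA
  stem), not any specific commercial chamber; chamber results are
  illustrative of the machinery, not of a particular instrument.
* The 6 MV positron-share estimate rests on a handful of positron cavity
  crossings per 5×10⁵ histories; its per-run scatter (±0.3–0.4 percentage
  points) is reported alongside the value and accounted for in the test.
* Passing the suite demonstrates the estimators and the variance-reduction
  machinery are correct and self-consistent at desk scale; it does not
  validate the engine against measured data or full-physics codes.
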