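"""Physical constants (CODATA 2018) in the unit system used throughout:
energies in MeV, lengths in cm, masses in g."""

ELECTRON_REST_MEV = 0.51099895000
"""Electron rest energy m_e c^2 [MeV]."""

CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
"""Classical electron radius r_e [cm]."""

AVOGADRO = 6.02214076e23
"""Avogadro constant [1/mol]."""

THOMSON_CROSS_SECTION_CM2 = 0.66524587321e-24
"""Thomson cross section 8*pi*r_e^2/3 [cm^2] (= 0.6652 barn)."""

GRAY_PER_MEV_PER_G = 1.602176634e-10
"""Unit conversion: 1 MeV/g = 1.602176634e-10 Gy."""

TWO_PI_RE2_MEC2 = 2.0 * 3.141592653589793 * CLASSICAL_ELECTRON_RADIUS_CM**2 * ELECTRON_REST_MEV
"""2*pi*r_e^2*m_e c^2 [MeV cm^2 per electron]; the Moller/Berger-Seltzer prefactor."""

PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV
"""Photon energy threshold for electron-positron pair production [MeV]."""
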