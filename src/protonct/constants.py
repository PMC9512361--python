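"""Physical and elemental constants used throughout the package.

Elemental mean excitation energies follow the ICRU 37 recommendations;
atomic masses are standard atomic weights (g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float  # g/mol
    I: float  # mean excitation energy, eV


#: Elements that occur in the packaged tissue and plug compositions.
ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008, 19.2),
        Element("C", 6, 12.011, 78.0),
        Element("N", 7, 14.007, 82.0),
        Element("O", 8, 15.999, 95.0),
        Element("F", 9, 18.998, 115.0),
        Element("Na", 11, 22.990, 149.0),
        Element("Mg", 12, 24.305, 156.0),
        Element("Al", 13, 26.982, 166.0),
        Element("Si", 14, 28.085, 173.0),
        Element("P", 15, 30.974, 173.0),
        Element("S", 16, 32.06, 180.0),
        Element("Cl", 17, 35.45, 174.0),
        Element("Ar", 18, 39.948, 188.0),
        Element("K", 19, 39.098, 190.0),
        Element("Ca", 20, 40.078, 191.0),
        Element("Fe", 26, 55.845, 286.0),
        Element("I", 53, 126.904, 491.0),
    ]
}

#: Classical electron radius, cm.
R_ELECTRON_CM = 2.8179403262e-13
#: Electron rest energy, MeV.
ME_C2_MEV = 0.511
#: Proton rest energy, MeV.
PROTON_REST_MEV = 938.272
#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23
#: Electron density of liquid water, electrons/cm^3 (rho = 1 g/cm^3).
N_E_WATER_CM3 = 3.3428e23
#: Default mean excitation energy of water, eV.
I_WATER_EV = 75.0
#: Bethe-Bloch prefactor for water as used in the stopping-power ratio, MeV/cm.
K0_MEV_CM = 0.17045
#: Default proton kinetic energy for RSP evaluation, MeV.
DEFAULT_PROTON_ENERGY_MEV = 200.0
#: Reference linear attenuation coefficient of water at 60 keV, 1/cm
#: (NIST XCOM mass attenuation 0.2059 cm^2/g at unit density); anchors the
#: photoelectric constant of the two-process attenuation model.
MU_WATER_60KEV_CM = 0.2059
#: Exponent of Z in the photoelectric cross-section per atom (per electron
#: the model carries Zeff^(PE_EXPONENT-1)).
PE_EXPONENT = 4.0
#: Default exponent of the power-law (Mayneord) effective atomic number.
ZEFF_EXPONENT = 3.31
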