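"""Materials: elemental compositions and derived radiological parameters.

A material is described either by its elemental composition and mass density
(reference human tissues, for which relative electron density ``rho_e``,
effective atomic number ``z_eff`` and mean excitation energy ``i_mean`` are
computed), or by vendor-tabulated ``rho_e``/``z_eff`` (tissue-substitute
calibration plugs, whose values are taken verbatim from the packaged table
and never recomputed).

The proton relative stopping power (RSP) at a given kinetic energy follows
the Bethe-Bloch ratio

    RSP = rho_e * L(I) / L(I_water),
    L(I) = ln(2 me c^2 beta^2 / (I (1 - beta^2))) - beta^2,

without shell or Barkas corrections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_PROTON_ENERGY_MEV,
    ELEMENTS,
    I_WATER_EV,
    K0_MEV_CM,
    ME_C2_MEV,
    N_AVOGADRO,
    N_E_WATER_CM3,
    PROTON_REST_MEV,
    R_ELECTRON_CM,
    ZEFF_EXPONENT,
)

log = logging.getLogger(__name__)

__all__ = [
    "ElementalComposition",
    "TissueMaterial",
    "StoppingPowerParams",
    "WATER_COMPOSITION",
    "relative_electron_density",
    "effective_atomic_number",
    "mean_excitation_energy",
    "rsp_bethe_bloch",
    "beta_from_kinetic_energy",
    "k0_from_constants",
    "i_from_zeff",
    "water_material",
    "wax_material",
    "pmma_material",
    "air_material",
    "load_material_table",
    "save_material_table",
    "load_calibration_plugs",
    "load_icrp_tissues",
]


class CompositionError(ValueError):
    """Invalid or unnormalized elemental composition."""


@dataclass(frozen=True)
class ElementalComposition:
    """Mass-fraction composition; entries are (symbol, Z, A, w, I_elem)."""

    entries: tuple[tuple[str, int, float, float, float], ...]

    @classmethod
    def from_fractions(cls, fractions: dict[str, float]) -> "ElementalComposition":
        entries = []
        for sym, w in fractions.items():
            if sym not in ELEMENTS:
                raise CompositionError(f"unknown element symbol {sym!r}")
            if w < 0:
                raise CompositionError(f"negative mass fraction for {sym}")
            if w > 0:
                e = ELEMENTS[sym]
                entries.append((sym, e.Z, e.A, float(w), e.I))
        if not entries:
            raise CompositionError("empty composition")
        return cls(tuple(entries))

    def validate(self) -> None:
        if not self.entries:
            raise CompositionError("empty composition")
        for sym, Z, A, w, I_elem in self.entries:
            if Z <= 0 or A <= 0 or I_elem <= 0:
                raise CompositionError(f"non-positive Z/A/I for {sym}")
            if w < 0:
                raise CompositionError(f"negative mass fraction for {sym}")

    @property
    def total_mass_fraction(self) -> float:
        return float(sum(w for *_, w, _I in self.entries))

    @property
    def is_normalized(self) -> bool:
        return abs(self.total_mass_fraction - 1.0) <= 1e-6

    def normalized(self) -> "ElementalComposition":
        self.validate()
        tot = self.total_mass_fraction
        if tot <= 0:
            raise CompositionError("zero total mass fraction")
        return ElementalComposition(
            tuple((s, Z, A, w / tot, I) for s, Z, A, w, I in self.entries)
        )

    def _require_normalized(self) -> None:
        self.validate()
        if not self.is_normalized:
            raise CompositionError(
                f"composition not normalized (sum = {self.total_mass_fraction:.8f}); "
                "call .normalized() first"
            )

    @property
    def electrons_per_gram(self) -> float:
        """N_A * sum_i w_i Z_i / A_i, electrons per gram."""
        self._require_normalized()
        return N_AVOGADRO * sum(w * Z / A for _s, Z, A, w, _I in self.entries)

    def electron_fractions(self) -> list[tuple[str, int, float, float]]:
        """Per element: (symbol, Z, lambda_i, I_elem) with lambda the electron fraction."""
        self._require_normalized()
        za = [(s, Z, w * Z / A, I) for s, Z, A, w, I in self.entries]
        tot = sum(x[2] for x in za)
        return [(s, Z, f / tot, I) for s, Z, f, I in za]

    def as_dict(self) -> dict[str, float]:
        return {s: w for s, _Z, _A, w, _I in self.entries}


#: Liquid water (H 11.19 %, O 88.81 % by mass).
WATER_COMPOSITION = ElementalComposition.from_fractions({"H": 0.1119, "O": 0.8881}).normalized()

_WATER_EPG = WATER_COMPOSITION.electrons_per_gram


def relative_electron_density(comp: ElementalComposition, mass_density: float) -> float:
    """Electron density relative to water at 1 g/cm^3: rho * (Ne/g) / (Ne/g)_water."""
    if mass_density <= 0:
        raise ValueError("mass_density must be positive")
    return mass_density * comp.electrons_per_gram / _WATER_EPG


def effective_atomic_number(comp: ElementalComposition, exponent: float = ZEFF_EXPONENT) -> float:
    """Power-law effective atomic number (sum_i lambda_i Z_i^m)^(1/m)."""
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    lams = comp.electron_fractions()
    return float(sum(lam * Z**exponent for _s, Z, lam, _I in lams) ** (1.0 / exponent))


def mean_excitation_energy(comp: ElementalComposition) -> float:
    """Bragg-additivity mean excitation energy: exp(sum_i lambda_i ln I_i), eV."""
    lams = comp.electron_fractions()
    return float(math.exp(sum(lam * math.log(I) for _s, _Z, lam, I in lams)))


def beta_from_kinetic_energy(kinetic_energy_mev: float, rest_energy_mev: float = PROTON_REST_MEV) -> float:
    """Relativistic speed beta = sqrt(1 - (1 + T/E0)^-2)."""
    if kinetic_energy_mev < 0:
        raise ValueError("kinetic energy must be non-negative")
    if rest_energy_mev <= 0:
        raise ValueError("rest energy must be positive")
    gamma = 1.0 + kinetic_energy_mev / rest_energy_mev
    return math.sqrt(1.0 - gamma**-2)


def k0_from_constants() -> float:
    """Bethe-Bloch water prefactor 4 pi re^2 me c^2 n_e,water, MeV/cm."""
    return 4.0 * math.pi * R_ELECTRON_CM**2 * ME_C2_MEV * N_E_WATER_CM3


@dataclass(frozen=True)
class StoppingPowerParams:
    """Parameters of the Bethe-Bloch stopping-power ratio for protons."""

    k0: float = K0_MEV_CM  # MeV/cm
    z_charge: int = 1
    me_c2: float = ME_C2_MEV  # MeV
    kinetic_energy: float = DEFAULT_PROTON_ENERGY_MEV  # MeV
    beta: float | None = None  # derived from kinetic_energy when None
    i_water_ev: float = I_WATER_EV

    def resolved_beta(self) -> float:
        b = self.beta if self.beta is not None else beta_from_kinetic_energy(self.kinetic_energy)
        if not 0.0 < b < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {b}")
        return b


@dataclass
class TissueMaterial:
    """A material with the radiological parameters downstream equations consume."""

    name: str
    mass_density: float | None = None  # g/cm^3
    composition: ElementalComposition | None = None
    rho_e: float | None = None  # relative electron density
    z_eff: float | None = None
    z_eff_uncertainty: float | None = None
    i_mean: float | None = None  # eV
    rsp: float | None = None

    def __post_init__(self) -> None:
        if self.rho_e is not None and self.rho_e <= 0:
            raise ValueError(f"{self.name}: rho_e must be positive")
        if self.z_eff is not None and self.z_eff < 1:
            raise ValueError(f"{self.name}: z_eff must be >= 1")
        if self.i_mean is not None and self.i_mean <= 0:
            raise ValueError(f"{self.name}: i_mean must be positive")

    @classmethod
    def from_composition(
        cls,
        name: str,
        mass_density: float,
        composition: ElementalComposition,
        zeff_exponent: float = ZEFF_EXPONENT,
    ) -> "TissueMaterial":
        comp = composition.normalized()
        return cls(
            name=name,
            mass_density=mass_density,
            composition=comp,
            rho_e=relative_electron_density(comp, mass_density),
            z_eff=effective_atomic_number(comp, zeff_exponent),
            i_mean=mean_excitation_energy(comp),
        )


def rsp_bethe_bloch(mat: TissueMaterial, params: StoppingPowerParams | None = None) -> float:
    """Proton RSP = rho_e * L(I)/L(I_water); stores the result on the material."""
    params = params or StoppingPowerParams()
    if mat.rho_e is None or mat.i_mean is None:
        raise ValueError(f"{mat.name}: rho_e and i_mean must be set for RSP")
    if mat.i_mean <= 0:
        raise ValueError("mean excitation energy must be positive")
    beta = params.resolved_beta()
    b2 = beta * beta

    def stopping_log(i_ev: float) -> float:
        arg = 2.0 * params.me_c2 * 1e6 * b2 / (i_ev * (1.0 - b2))
        return math.log(arg) - b2

    mat.rsp = mat.rho_e * stopping_log(mat.i_mean) / stopping_log(params.i_water_ev)
    return mat.rsp


# --- Zeff -> I fallback -----------------------------------------------------

_I_FROM_ZEFF_ANCHORS: list[tuple[float, float]] | None = None


def i_from_zeff(z_eff: float) -> float:
    """Mean excitation energy from Zeff by log-linear interpolation.

    Anchors are (Zeff, I) pairs computed from the packaged reference-tissue
    compositions, so the mapping is consistent with Bragg additivity over
    the tissue range; outside the range the nearest anchor is held.
    """
    global _I_FROM_ZEFF_ANCHORS
    if _I_FROM_ZEFF_ANCHORS is None:
        tissues = load_icrp_tissues()
        pairs = sorted((t.z_eff, t.i_mean) for t in tissues)
        # average I over near-duplicate Zeff to keep the abscissa strictly increasing
        merged: list[tuple[float, float]] = []
        for z, i in pairs:
            if merged and z - merged[-1][0] < 1e-3:
                z0, i0 = merged[-1]
                merged[-1] = ((z0 + z) / 2, (i0 + i) / 2)
            else:
                merged.append((z, i))
        _I_FROM_ZEFF_ANCHORS = merged
    zs = np.array([p[0] for p in _I_FROM_ZEFF_ANCHORS])
    lis = np.log([p[1] for p in _I_FROM_ZEFF_ANCHORS])
    return float(np.exp(np.interp(z_eff, zs, lis)))


# --- Stock materials --------------------------------------------------------

def water_material(mass_density: float = 1.0) -> TissueMaterial:
    m = TissueMaterial.from_composition("water", mass_density, WATER_COMPOSITION)
    m.i_mean = I_WATER_EV
    if mass_density == 1.0:
        m.rho_e = 1.0
    rsp_bethe_bloch(m)
    return m


def wax_material(rho_e: float = 0.96) -> TissueMaterial:
    """Machinable-wax stand-in: CH2 hydrocarbon scaled to the requested rho_e."""
    comp = ElementalComposition.from_fractions({"H": 0.1437, "C": 0.8563}).normalized()
    density = rho_e / relative_electron_density(comp, 1.0)
    m = TissueMaterial.from_composition("wax", density, comp)
    rsp_bethe_bloch(m)
    return m


def pmma_material(mass_density: float = 1.19) -> TissueMaterial:
    comp = ElementalComposition.from_fractions(
        {"H": 0.0805, "C": 0.5998, "O": 0.3196}
    ).normalized()
    m = TissueMaterial.from_composition("pmma", mass_density, comp)
    rsp_bethe_bloch(m)
    return m


def air_material() -> TissueMaterial:
    comp = ElementalComposition.from_fractions(
        {"N": 0.7552, "O": 0.2318, "Ar": 0.0128, "C": 0.0002}
    ).normalized()
    m = TissueMaterial.from_composition("air", 0.0012, comp)
    rsp_bethe_bloch(m)
    return m


def aluminum_material(mass_density: float = 2.699) -> TissueMaterial:
    return TissueMaterial.from_composition(
        "aluminum", mass_density, ElementalComposition.from_fractions({"Al": 1.0})
    )


# --- Material tables (CSV) --------------------------------------------------

def _parse_composition(text: str) -> ElementalComposition | None:
    if not isinstance(text, str) or not text.strip():
        return None
    fractions: dict[str, float] = {}
    for token in text.split():
        sym, _, frac = token.partition(":")
        fractions[sym] = float(frac)
    return ElementalComposition.from_fractions(fractions).normalized()


def load_material_table(path_or_buf, zeff_exponent: float = ZEFF_EXPONENT) -> list[TissueMaterial]:
    """Read a material table CSV: name, density, rho_e, z_eff[, z_eff_unc], composition.

    rho_e/z_eff left blank are computed from the composition; i_mean comes from
    the composition when present, otherwise from the Zeff->I fallback.
    """
    df = pd.read_csv(path_or_buf)
    mats: list[TissueMaterial] = []
    for row in df.itertuples(index=False):
        comp = _parse_composition(getattr(row, "composition", ""))
        density = getattr(row, "density", None)
        density = None if pd.isna(density) else float(density)
        rho_e = getattr(row, "rho_e", None)
        z_eff = getattr(row, "z_eff", None)
        unc = getattr(row, "z_eff_unc", None)
        rho_e = None if pd.isna(rho_e) else float(rho_e)
        z_eff = None if pd.isna(z_eff) else float(z_eff)
        unc = None if unc is None or pd.isna(unc) else float(unc)
        if comp is not None:
            if rho_e is None:
                if density is None:
                    raise ValueError(f"{row.name}: need density to compute rho_e")
                rho_e = relative_electron_density(comp, density)
            if z_eff is None:
                z_eff = effective_atomic_number(comp, zeff_exponent)
            i_mean = mean_excitation_energy(comp)
        else:
            if rho_e is None or z_eff is None:
                raise ValueError(f"{row.name}: composition or (rho_e, z_eff) required")
            i_mean = None
        mats.append(
            TissueMaterial(
                name=str(row.name),
                mass_density=density,
                composition=comp,
                rho_e=rho_e,
                z_eff=z_eff,
                z_eff_uncertainty=unc,
                i_mean=i_mean,
            )
        )
    return mats


def save_material_table(mats: Iterable[TissueMaterial], path) -> None:
    rows = []
    for m in mats:
        comp = (
            " ".join(f"{s}:{w:.6f}" for s, w in m.composition.as_dict().items())
            if m.composition is not None
            else ""
        )
        rows.append(
            {
                "name": m.name,
                "density": m.mass_density,
                "rho_e": m.rho_e,
                "z_eff": m.z_eff,
                "z_eff_unc": m.z_eff_uncertainty,
                "composition": comp,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _data_path(fname: str):
    return resources.files("protonct.data").joinpath(fname)


def load_calibration_plugs(path=None) -> list[TissueMaterial]:
    """The 13 tissue-substitute calibration plugs.

    Vendor rho_e and Bourque-style Zeff (with uncertainty) are tabulated and
    used verbatim; the packaged mixture compositions feed only the mean
    excitation energy for the plug RSP.
    """
    with resources.as_file(_data_path("calibration_plugs.csv")) as p:
        mats = load_material_table(path or p)
    params = StoppingPowerParams()
    for m in mats:
        if m.i_mean is None:
            m.i_mean = i_from_zeff(m.z_eff)
        rsp_bethe_bloch(m, params)
    return mats


def load_icrp_tissues(path=None, zeff_exponent: float = ZEFF_EXPONENT) -> list[TissueMaterial]:
    """The packaged 33 reference human tissues with computed rho_e, Zeff, I, RSP."""
    with resources.as_file(_data_path("icrp_tissues.csv")) as p:
        mats = load_material_table(path or p, zeff_exponent=zeff_exponent)
    params = StoppingPowerParams()
    for m in mats:
        rsp_bethe_bloch(m, params)
    return mats
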