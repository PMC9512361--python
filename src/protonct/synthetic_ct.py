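"""Synthetic polychromatic CT: phantoms, acquisition, reconstruction, corrections.

The scanner stand-in works in parallel-beam geometry.  For every axial slice
the forward model computes per-energy line integrals of the linear attenuation
coefficient, sums the transmitted spectrum, and takes the negative log; images
are reconstructed by Ram-Lak filtered back projection.  Beam hardening arises
naturally from the polychromatic sum.  Three generic corrections emulate the
roles their clinical counterparts play:

* water linearization -- remaps each projection through the inverse of the
  simulated polychromatic water response (removes cupping in water-like media,
  on by default as on clinical scanners);
* an iterative two-material (water/bone) correction -- segments bone, forward
  projects it, replaces each ray's measured projection with the ideal
  monochromatic one implied by the water/bone estimate, and repeats;
* dual-energy basis decomposition -- per-voxel photoelectric/Compton solve
  from two scans, used both for pseudo-monochromatic synthesis at a target
  energy and for direct (rho_e, Zeff) recovery.

Attenuation follows a two-process model per electron,

    mu(E) = rho_e * n_e,water * (a_pe * Zeff^(n-1) / E^3 + sigma_KN(E)),

with the photoelectric constant anchored to the reference water attenuation
at 60 keV and sigma_KN the Klein-Nishina cross-section.  Coherent scatter is
neglected; the artifacts of interest do not depend on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .constants import ME_C2_MEV, MU_WATER_60KEV_CM, N_E_WATER_CM3, PE_EXPONENT, R_ELECTRON_CM
from .materials import (
    TissueMaterial,
    air_material,
    aluminum_material,
    effective_atomic_number,
    WATER_COMPOSITION,
    load_calibration_plugs,
    load_icrp_tissues,
    water_material,
    wax_material,
)

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "VoxelPhantom",
    "CTImage",
    "make_kvp_spectrum",
    "attenuation_mu",
    "klein_nishina_cross_section",
    "simulate_scan",
    "water_linearization",
    "ibhc_emulate",
    "pseudo_mono_image",
    "rho_z_decompose",
    "rho_z_to_rsp",
    "make_cupping_phantoms",
    "make_streak_phantom",
    "make_head_phantom",
    "make_calibration_phantom",
    "write_nifti",
]

SCAN_FOV_MM = 500.0  # hard field-of-view bound
_TRANSPARENT_RHO_E = 0.005  # materials below this are treated as vacuum


class FieldOfViewError(ValueError):
    """Phantom does not fit in the scan field of view."""


class ConditioningError(RuntimeError):
    """Dual-energy basis matrix is too ill-conditioned to invert."""


# --- spectra ----------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """Normalized photon-fluence spectrum on a 1-keV grid."""

    label: str
    energies: tuple[float, ...]  # keV, strictly increasing, > 10
    weights: tuple[float, ...]  # fluence fractions, sum to 1

    def __post_init__(self) -> None:
        e = np.asarray(self.energies)
        w = np.asarray(self.weights)
        if len(e) != len(w) or len(e) == 0:
            raise ValueError("energies and weights must be equal-length, nonempty")
        if np.any(np.diff(e) <= 0) or e[0] <= 10:
            raise ValueError("energies must be strictly increasing and > 10 keV")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean energy, keV (the effective energy used here)."""
        return float(np.dot(self.energies, self.weights))

    @property
    def is_monochromatic(self) -> bool:
        return len(self.energies) == 1

    @classmethod
    def monochromatic(cls, energy_kev: float, label: str | None = None) -> "Spectrum":
        return cls(label or f"mono{energy_kev:g}keV", (float(energy_kev),), (1.0,))

    def _key(self):
        return (self.label, len(self.energies), round(self.mean_energy, 9))


def make_kvp_spectrum(kvp: float, filtration_mm_al: float = 2.5) -> Spectrum:
    """Kramers bremsstrahlung at the given tube potential, aluminum-filtered.

    Photon fluence per 1-keV bin follows (kvp - E)/E, attenuated by the
    stated aluminum filtration; the mean energy increases with both kvp and
    filtration.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError("kvp must be in [40, 150]")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    e = np.arange(16.0, kvp + 0.5, 1.0)
    e = e[e < kvp + 1e-9]
    w = (kvp - e) / e
    w[w < 0] = 0.0
    al = aluminum_material()
    mu_al = attenuation_mu(al, e)
    w = w * np.exp(-mu_al * filtration_mm_al / 10.0)
    keep = w > 1e-8 * w.max()
    e, w = e[keep], w[keep]
    w = w / w.sum()
    return Spectrum(f"{kvp:g}kVp", tuple(e), tuple(w))


# --- attenuation model ------------------------------------------------------

def klein_nishina_cross_section(energy_kev) -> np.ndarray:
    """Total Klein-Nishina cross-section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / (ME_C2_MEV * 1e3)
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * math.pi * R_ELECTRON_CM**2 * (t1 + t2 - t3)


ZEFF_WATER = effective_atomic_number(WATER_COMPOSITION)

#: Photoelectric constant, anchored so water's mu at 60 keV matches the
#: packaged reference value.
A_PE = (MU_WATER_60KEV_CM / N_E_WATER_CM3 - float(klein_nishina_cross_section(60.0))) * (
    60.0**3
) / ZEFF_WATER ** (PE_EXPONENT - 1.0)


def attenuation_mu(mat: TissueMaterial, energy_kev) -> np.ndarray | float:
    """Linear attenuation coefficient of a material, 1/cm, for E in [10, 200] keV."""
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < 10.0) or np.any(e > 200.0):
        raise ValueError("energy outside the model's [10, 200] keV validity range")
    if mat.rho_e is None or mat.z_eff is None:
        raise ValueError(f"{mat.name}: rho_e and z_eff required")
    mu = mat.rho_e * N_E_WATER_CM3 * (
        A_PE * mat.z_eff ** (PE_EXPONENT - 1.0) / e**3 + klein_nishina_cross_section(e)
    )
    return float(mu) if np.isscalar(energy_kev) else mu


def mu_water(energy_kev) -> np.ndarray | float:
    return attenuation_mu(_WATER, energy_kev)


_WATER = water_material()


# --- phantoms ---------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """Labeled voxel grid (z, y, x) with a label -> material map."""

    labels: np.ndarray  # int, (nz, ny, nx)
    materials: dict[int, TissueMaterial]
    voxel_size: tuple[float, float, float]  # (dz, dy, dx), mm
    ap_mm: float
    lat_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material: {sorted(missing)}")


@dataclass
class CTImage:
    """Reconstructed HU volume tagged with its generating technique."""

    hu: np.ndarray  # (nz, ny, nx)
    voxel_size: tuple[float, float, float]
    technique_id: str
    corrections: frozenset[str] = frozenset()
    spectrum: Spectrum | None = None
    meta: dict = field(default_factory=dict)
    sim: "_SimContext | None" = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU volume contains non-finite values")


@dataclass
class _SimContext:
    """Geometry and projection data kept for projection-space corrections."""

    phantom: VoxelPhantom
    theta: np.ndarray
    px_cm: float
    projections: list[np.ndarray]  # per slice, linearized domain
    mu_w_ref: float
    mu_hat_w: float
    e_ref: float
    n_angles: int
    linearized: bool


def _circle_mask(n: int, px_mm: float, ap_mm: float, lat_mm: float, cy=0.0, cx=0.0) -> np.ndarray:
    c = (n - 1) / 2.0
    yy = (np.arange(n) - c)[:, None] * px_mm - cy
    xx = (np.arange(n) - c)[None, :] * px_mm - cx
    return (yy / (ap_mm / 2.0)) ** 2 + (xx / (lat_mm / 2.0)) ** 2 <= 1.0


def _disk(n: int, px_mm: float, cy: float, cx: float, radius_mm: float) -> np.ndarray:
    c = (n - 1) / 2.0
    yy = (np.arange(n) - c)[:, None] * px_mm - cy
    xx = (np.arange(n) - c)[None, :] * px_mm - cx
    return yy**2 + xx**2 <= radius_mm**2


def _pixel_size_for(extent_mm: float, grid_n: int, margin: float = 1.12) -> float:
    return extent_mm * margin / grid_n


def make_cupping_phantoms(
    diameters_cm: tuple[float, ...] = (13.5, 17.8, 26.9),
    insert: TissueMaterial | None = None,
    extended_deff_cm: float | None = 30.2,
    insert_diameter_mm: float = 28.0,
    grid_n: int = 128,
    nz: int = 4,
    slice_mm: float = 1.0,
    wax: TissueMaterial | None = None,
) -> list[VoxelPhantom]:
    """Wax cylinders with a central cortical-bone insert, plus the laterally
    extended variant whose effective diameter sqrt(AP*LAT) hits the target."""
    wax = wax or wax_material()
    if insert is None:
        insert = [m for m in load_calibration_plugs() if m.name.startswith("SB3")][0]
    specs = [(d * 10.0, d * 10.0) for d in diameters_cm]
    if extended_deff_cm is not None:
        ap = max(diameters_cm) * 10.0
        lat = (extended_deff_cm * 10.0) ** 2 / ap
        specs.append((ap, lat))
    phantoms = []
    for ap_mm, lat_mm in specs:
        if insert_diameter_mm > min(ap_mm, lat_mm):
            raise ValueError("insert larger than phantom")
        px = _pixel_size_for(max(ap_mm, lat_mm), grid_n)
        body = _circle_mask(grid_n, px, ap_mm, lat_mm)
        hole = _disk(grid_n, px, 0.0, 0.0, insert_diameter_mm / 2.0)
        sl = np.zeros((grid_n, grid_n), dtype=np.int8)
        sl[body] = 1
        sl[hole] = 2
        labels = np.broadcast_to(sl, (nz, grid_n, grid_n)).copy()
        phantoms.append(
            VoxelPhantom(
                labels=labels,
                materials={0: air_material(), 1: wax, 2: insert},
                voxel_size=(slice_mm, px, px),
                ap_mm=ap_mm,
                lat_mm=lat_mm,
                meta={"insert_center_mm": (0.0, 0.0), "insert_diameter_mm": insert_diameter_mm},
            )
        )
    return phantoms


def make_streak_phantom(
    grid_n: int = 128,
    region_len_mm: float = 70.0,
    slice_mm: float = 2.0,
    hole_diameter_mm: float = 28.0,
    hole_gap_mm: float = 15.0,
) -> VoxelPhantom:
    """Three-hole wax slab; region 1 (artifact-free) has wax plugs around the
    central solid-water plug, region 2 has cortical-bone plugs around it."""
    wax = wax_material()
    plugs = load_calibration_plugs()
    solid_water = [m for m in plugs if m.name == "CT solid water"][0]
    bone = [m for m in plugs if m.name.startswith("SB3")][0]
    lat_mm, ap_mm = 330.0, 120.0
    px = _pixel_size_for(lat_mm, grid_n)
    spacing = hole_diameter_mm + hole_gap_mm  # center-to-center
    body = np.zeros((grid_n, grid_n), dtype=np.int8)
    c = (grid_n - 1) / 2.0
    yy = (np.arange(grid_n) - c)[:, None] * px
    xx = (np.arange(grid_n) - c)[None, :] * px
    body[(np.abs(yy) <= ap_mm / 2.0) & (np.abs(xx) <= lat_mm / 2.0)] = 1
    center = _disk(grid_n, px, 0.0, 0.0, hole_diameter_mm / 2.0)
    left = _disk(grid_n, px, 0.0, -spacing, hole_diameter_mm / 2.0)
    right = _disk(grid_n, px, 0.0, spacing, hole_diameter_mm / 2.0)
    sl_r1 = body.copy()
    sl_r1[center] = 2  # outer holes carry wax plugs: same label as body
    sl_r2 = body.copy()
    sl_r2[center] = 2
    sl_r2[left] = 3
    sl_r2[right] = 3
    n_per = max(1, int(round(region_len_mm / slice_mm)))
    labels = np.concatenate(
        [
            np.broadcast_to(sl_r1, (n_per, grid_n, grid_n)),
            np.broadcast_to(sl_r2, (n_per, grid_n, grid_n)),
        ]
    ).copy()
    return VoxelPhantom(
        labels=labels,
        materials={0: air_material(), 1: wax, 2: solid_water, 3: bone},
        voxel_size=(slice_mm, px, px),
        ap_mm=ap_mm,
        lat_mm=lat_mm,
        meta={
            "plug_spacing_mm": spacing,
            "hole_diameter_mm": hole_diameter_mm,
            "region1_slices": (0, n_per),
            "region2_slices": (n_per, 2 * n_per),
        },
    )


def make_head_phantom(
    grid_n: int = 128,
    ap_mm: float = 190.0,
    lat_mm: float = 150.0,
    nz: int = 12,
    slice_mm: float = 2.0,
    skull_thickness_mm: float = 7.0,
) -> VoxelPhantom:
    """Simplified digital head: soft-tissue ellipse, skull shell, brain, and
    two dense petrous bone blocks flanking the brain on the lateral axis."""
    tissues = {t.name: t for t in load_icrp_tissues()}
    soft = tissues["muscle_skeletal"]
    skull = tissues["cranium"]
    brain = tissues["brain"]
    petrous = tissues["cortical_bone"]
    px = _pixel_size_for(max(ap_mm, lat_mm), grid_n)
    outer = _circle_mask(grid_n, px, ap_mm, lat_mm)
    inner = _circle_mask(grid_n, px, ap_mm - 2 * skull_thickness_mm, lat_mm - 2 * skull_thickness_mm)
    brain_reg = _circle_mask(
        grid_n, px, ap_mm - 2 * skull_thickness_mm - 10, lat_mm - 2 * skull_thickness_mm - 10
    )
    sl = np.zeros((grid_n, grid_n), dtype=np.int8)
    sl[outer] = 1
    sl[outer & ~inner] = 2
    sl[brain_reg] = 3
    # petrous blocks: rectangles at mid-height, left and right of the brain
    c = (grid_n - 1) / 2.0
    yy = (np.arange(grid_n) - c)[:, None] * px
    xx = (np.arange(grid_n) - c)[None, :] * px
    half_w, half_h = 14.0, 9.0
    x0 = lat_mm / 2.0 - skull_thickness_mm - half_w - 8.0
    for sgn in (-1, 1):
        block = (np.abs(yy) <= half_h) & (np.abs(xx - sgn * x0) <= half_w)
        sl[block & inner] = 4
    labels = np.broadcast_to(sl, (nz, grid_n, grid_n)).copy()
    petrous_rows = np.where(np.any(sl == 4, axis=1))[0]
    return VoxelPhantom(
        labels=labels,
        materials={0: air_material(), 1: soft, 2: skull, 3: brain, 4: petrous},
        voxel_size=(slice_mm, px, px),
        ap_mm=ap_mm,
        lat_mm=lat_mm,
        meta={
            "petrous_row_range": (int(petrous_rows.min()), int(petrous_rows.max())),
            "petrous_x_mm": x0,
        },
    )


def make_calibration_phantom(
    diameter_cm: float,
    plugs: list[TissueMaterial] | None = None,
    plug_diameter_mm: float = 28.0,
    grid_n: int = 128,
    nz: int = 2,
    slice_mm: float = 1.0,
) -> VoxelPhantom:
    """Water-filled calibration cylinder with the tissue-substitute plugs
    arranged as one central plug plus an evenly spaced ring."""
    plugs = plugs if plugs is not None else load_calibration_plugs()
    d_mm = diameter_cm * 10.0
    px = _pixel_size_for(d_mm, grid_n)
    body = _circle_mask(grid_n, px, d_mm, d_mm)
    sl = np.zeros((grid_n, grid_n), dtype=np.int16)
    sl[body] = 1
    materials = {0: air_material(), 1: water_material()}
    n_ring = len(plugs) - 1
    ring_r = d_mm / 2.0 - plug_diameter_mm / 2.0 - 0.12 * d_mm / 2.0
    centers = [(0.0, 0.0)]
    for i in range(n_ring):
        ang = 2 * math.pi * i / n_ring
        centers.append((ring_r * math.sin(ang), ring_r * math.cos(ang)))
    plug_centers = {}
    for k, (plug, (cy, cx)) in enumerate(zip(plugs, centers), start=2):
        sl[_disk(grid_n, px, cy, cx, plug_diameter_mm / 2.0)] = k
        materials[k] = plug
        plug_centers[plug.name] = (cy, cx)
    labels = np.broadcast_to(sl, (nz, grid_n, grid_n)).copy()
    return VoxelPhantom(
        labels=labels,
        materials=materials,
        voxel_size=(slice_mm, px, px),
        ap_mm=d_mm,
        lat_mm=d_mm,
        meta={"plug_centers_mm": plug_centers, "plug_diameter_mm": plug_diameter_mm},
    )


# --- water linearization ----------------------------------------------------

_WL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, float, float]] = {}

#: Water path length defining the beam-hardened effective energy, cm.  HU
#: scales on clinical scanners are calibrated in a water phantom of roughly
#: this size, so the reference energy of the linearized domain (and of the
#: corrections built on it) is the energy whose water attenuation matches
#: the polychromatic response over this path.
EFFECTIVE_ENERGY_WATER_CM = 20.0


def effective_energy(spec: Spectrum) -> float:
    """Beam-hardened effective energy of a spectrum, keV."""
    return _wl_table(spec)[3]


def _wl_table(spec: Spectrum) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(water lengths cm, polychromatic projections, mu_w at E_eff, E_eff keV)."""
    key = spec._key()
    if key not in _WL_CACHE:
        lengths = np.linspace(0.0, 64.0, 513)
        mu_w = np.asarray(mu_water(np.asarray(spec.energies)))
        w = np.asarray(spec.weights)
        p = -np.log(np.exp(-np.outer(lengths, mu_w)) @ w)
        if spec.is_monochromatic:
            e_eff = float(spec.energies[0])
        else:
            # energy whose water mu matches the hardened response over the
            # reference path
            i_ref = int(np.argmin(np.abs(lengths - EFFECTIVE_ENERGY_WATER_CM)))
            mu_eff = p[i_ref] / lengths[i_ref]
            e_grid = np.linspace(15.0, 200.0, 742)
            mu_grid = np.asarray(mu_water(e_grid))
            e_eff = float(np.interp(-mu_eff, -mu_grid, e_grid))  # mu decreasing
        _WL_CACHE[key] = (lengths, p, float(mu_water(e_eff)), e_eff)
    return _WL_CACHE[key]


def water_linearization(projections: np.ndarray, spec: Spectrum) -> np.ndarray:
    """Remap polychromatic projections so water paths become linear in length.

    Output is in the linearized domain mu_w(E_ref) * L_weq, with E_ref the
    spectrum's fluence-weighted mean energy.  Projections beyond the
    precomputed water-path table are extrapolated linearly.
    """
    lengths, p_tab, mu_w_ref, _e_eff = _wl_table(spec)
    p = np.asarray(projections, dtype=float)
    l_weq = np.interp(p, p_tab, lengths)
    over = p > p_tab[-1]
    if np.any(over):
        slope = (lengths[-1] - lengths[-2]) / (p_tab[-1] - p_tab[-2])
        l_weq = np.where(over, lengths[-1] + (p - p_tab[-1]) * slope, l_weq)
        log.warning("water_linearization: %d projection(s) beyond table, extrapolated", int(over.sum()))
    return mu_w_ref * l_weq


# --- scanning ---------------------------------------------------------------

_WATER_CAL_CACHE: dict[tuple, float] = {}


def _water_calibration_mu(
    spec: Spectrum, linearize: bool, n_angles: int, grid_n: int, px_cm: float
) -> float:
    """Mean reconstructed mu in the core of a same-technique water scan."""
    key = (spec._key(), linearize, n_angles, grid_n, round(px_cm, 8))
    if key not in _WATER_CAL_CACHE:
        d_mm = min(200.0, 0.8 * grid_n * px_cm * 10.0)
        ph = VoxelPhantom(
            labels=_circle_mask(grid_n, px_cm * 10.0, d_mm, d_mm)[None].astype(np.int8),
            materials={0: air_material(), 1: water_material()},
            voxel_size=(1.0, px_cm * 10.0, px_cm * 10.0),
            ap_mm=d_mm,
            lat_mm=d_mm,
        )
        img = simulate_scan(ph, spec, n_angles=n_angles, linearize=linearize, _normalize=False)
        core = _disk(grid_n, px_cm * 10.0, 0.0, 0.0, d_mm / 8.0)
        _WATER_CAL_CACHE[key] = float(img.hu[0][core].mean())  # holds mu, not HU
    return _WATER_CAL_CACHE[key]


def simulate_scan(
    ph: VoxelPhantom,
    spec: Spectrum,
    n_angles: int = 180,
    noise_seed: int | None = None,
    noise_level: float = 0.0,
    linearize: bool = True,
    _normalize: bool = True,
) -> CTImage:
    """Polychromatic parallel-beam scan with filtered back projection.

    Per energy bin the detected signal is sum_E w(E) exp(-int mu dl); the
    post-log projections optionally receive seeded Gaussian noise with
    standard deviation noise_level * exp(p/2) (Poisson-like growth with
    attenuation), are water-linearized unless disabled, and are reconstructed
    slice by slice.  HU are formed against a cached same-technique
    water-calibration scan.
    """
    dz, dy, dx = ph.voxel_size
    if abs(dy - dx) > 1e-9:
        raise ValueError("in-plane voxels must be square")
    n = ph.labels.shape[1]
    if ph.labels.shape[2] != n:
        raise ValueError("in-plane grid must be square")
    if max(ph.ap_mm, ph.lat_mm) > SCAN_FOV_MM + 1e-6:
        raise FieldOfViewError(
            f"phantom extent {max(ph.ap_mm, ph.lat_mm):.0f} mm exceeds the {SCAN_FOV_MM:.0f} mm FOV"
        )
    px_cm = dx / 10.0
    # truncation check: body must fit the reconstruction circle
    body = ph.labels.max(axis=0) > 0
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rmax = np.sqrt(((yy - c) ** 2 + (xx - c) ** 2))[body].max() if body.any() else 0.0
    if rmax > n / 2.0:
        raise FieldOfViewError("phantom exceeds the reconstruction circle (truncation)")

    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    energies = np.asarray(spec.energies)
    weights = np.asarray(spec.weights)
    mu_by_label = {
        lab: np.asarray(attenuation_mu(mat, energies))
        for lab, mat in ph.materials.items()
        if mat.rho_e is not None and mat.rho_e >= _TRANSPARENT_RHO_E
    }

    nz = ph.labels.shape[0]
    flat = ph.labels.reshape(nz, -1)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    clean: list[np.ndarray] = []
    for row in uniq:
        sl = row.reshape(n, n)
        T = None
        for lab, mu in mu_by_label.items():
            mask = sl == lab
            if not mask.any():
                continue
            L = radon(mask.astype(float), theta=theta, circle=True) * px_cm
            contrib = L[:, :, None] * mu[None, None, :]
            T = contrib if T is None else T + contrib
        if T is None:
            p = np.zeros((n, n_angles))
        else:
            p = -np.log(np.clip(np.exp(-T) @ weights, 1e-12, None))
        clean.append(p)

    rng = np.random.default_rng(noise_seed) if noise_level > 0 else None
    _, _, mu_w_ref, e_eff = _wl_table(spec)
    mu_hat_w = (
        _water_calibration_mu(spec, linearize, n_angles, n, px_cm) if _normalize else None
    )

    def _recon(p: np.ndarray) -> np.ndarray:
        if linearize:
            p = water_linearization(p, spec)
        return iradon(p, theta=theta, circle=True, filter_name="ramp") / px_cm

    vol = np.empty((nz, n, n))
    proj_per_slice: list[np.ndarray] = [None] * nz  # type: ignore[list-item]
    if rng is None:
        recon_u = []
        proj_u = []
        for p in clean:
            pl = water_linearization(p, spec) if linearize else p
            proj_u.append(pl)
            recon_u.append(iradon(pl, theta=theta, circle=True, filter_name="ramp") / px_cm)
        for iz in range(nz):
            vol[iz] = recon_u[inv[iz]]
            proj_per_slice[iz] = proj_u[inv[iz]]
    else:
        for iz in range(nz):
            p = clean[inv[iz]]
            p = p + rng.normal(size=p.shape) * noise_level * np.exp(p / 2.0)
            pl = water_linearization(p, spec) if linearize else p
            proj_per_slice[iz] = pl
            vol[iz] = iradon(pl, theta=theta, circle=True, filter_name="ramp") / px_cm

    if _normalize:
        hu = 1000.0 * (vol - mu_hat_w) / mu_hat_w
    else:
        hu = vol  # raw mu, used internally by the water-calibration scan
    corrections = frozenset({"water_linearized"} if linearize else set())
    return CTImage(
        hu=hu,
        voxel_size=ph.voxel_size,
        technique_id=spec.label,
        corrections=corrections,
        spectrum=spec,
        meta={"e_ref_kev": e_eff, "noise_level": noise_level, "noise_seed": noise_seed},
        sim=_SimContext(
            phantom=ph,
            theta=theta,
            px_cm=px_cm,
            projections=proj_per_slice,
            mu_w_ref=mu_w_ref,
            mu_hat_w=mu_hat_w if mu_hat_w is not None else mu_w_ref,
            e_ref=e_eff,
            n_angles=n_angles,
            linearized=linearize,
        ),
    )


# --- iterative two-material beam-hardening correction -----------------------

def ibhc_emulate(
    img: CTImage,
    projections: list[np.ndarray] | None = None,
    bone_threshold: float = 300.0,
    n_iter: int = 2,
    bone_material: TissueMaterial | None = None,
) -> CTImage:
    """Iterative water/bone correction in projection space.

    Each pass segments bone above the HU threshold, forward projects the bone
    component, estimates per ray the hardening error the known spectrum
    produces for that water/bone split, replaces the measured projection by
    the ideal monochromatic one, reconstructs, and re-segments.  Returns the
    input unchanged (logged) when no voxel exceeds the threshold.
    """
    if img.sim is None:
        raise ValueError("ibhc_emulate needs an image produced by simulate_scan")
    sim = img.sim
    spec = img.spectrum
    assert spec is not None
    if bone_material is None:
        candidates = [m for m in sim.phantom.materials.values() if (m.rho_e or 0) > 1.2]
        if candidates:
            bone_material = max(candidates, key=lambda m: m.rho_e)
        else:
            bone_material = [m for m in load_calibration_plugs() if m.name.startswith("SB3")][0]
    if not np.any(img.hu > bone_threshold):
        log.info("ibhc_emulate: no voxels above %.0f HU; returning input unchanged", bone_threshold)
        return img

    energies = np.asarray(spec.energies)
    weights = np.asarray(spec.weights)
    mu_w_e = np.asarray(mu_water(energies))
    mu_b_e = np.asarray(attenuation_mu(bone_material, energies))
    mu_w_ref = sim.mu_w_ref
    mu_b_ref = float(attenuation_mu(bone_material, sim.e_ref))
    hu_b_ref = 1000.0 * (mu_b_ref - mu_w_ref) / mu_w_ref  # reference bone HU at E_ref
    px_cm = sim.px_cm
    theta = sim.theta
    projs = projections if projections is not None else sim.projections

    hu = img.hu.copy()
    out_projs: list[np.ndarray] = list(projs)
    for _ in range(n_iter):
        new_hu = np.empty_like(hu)
        for iz in range(hu.shape[0]):
            l_weq = projs[iz] / mu_w_ref
            bone_mask = hu[iz] > bone_threshold
            if not bone_mask.any():
                new_hu[iz] = hu[iz]
                continue
            # fractional bone-equivalent density: segmented voxels carry the
            # reference bone attenuation scaled by their HU excess over water
            b_map = np.where(bone_mask, np.clip(hu[iz], 0.0, None) / hu_b_ref, 0.0)
            l_b = radon(b_map, theta=theta, circle=True) * px_cm
            l_w0 = np.clip(l_weq - l_b * (mu_b_ref / mu_w_ref), 0.0, None)
            # what the linearized scanner would report for this (water, bone) split
            t = np.einsum("da,e->dae", l_w0, mu_w_e) + np.einsum("da,e->dae", l_b, mu_b_e)
            p_model = -np.log(np.clip(np.exp(-t) @ weights, 1e-12, None))
            l_weq_model = water_linearization(p_model, spec) / mu_w_ref
            l_w = np.clip(l_w0 + (l_weq - l_weq_model), 0.0, None)
            p_corr = mu_w_ref * l_w + mu_b_ref * l_b
            out_projs[iz] = p_corr
            mu_hat = iradon(p_corr, theta=theta, circle=True, filter_name="ramp") / px_cm
            new_hu[iz] = 1000.0 * (mu_hat - sim.mu_hat_w) / sim.mu_hat_w
        hu = new_hu
    new_sim = _SimContext(
        phantom=sim.phantom,
        theta=sim.theta,
        px_cm=sim.px_cm,
        projections=out_projs,
        mu_w_ref=sim.mu_w_ref,
        mu_hat_w=sim.mu_hat_w,
        e_ref=sim.e_ref,
        n_angles=sim.n_angles,
        linearized=sim.linearized,
    )
    return CTImage(
        hu=hu,
        voxel_size=img.voxel_size,
        technique_id=img.technique_id,
        corrections=img.corrections | {"ibhc_emulated"},
        spectrum=spec,
        meta=dict(img.meta),
        sim=new_sim,
    )


# --- dual-energy: basis decomposition, pseudo-mono, rho/z -------------------

_E0 = 60.0  # keV, scaling energy for the basis functions


def _basis(e_kev):
    f_pe = (_E0 / np.asarray(e_kev, dtype=float)) ** 3
    f_kn = klein_nishina_cross_section(e_kev) / klein_nishina_cross_section(_E0)
    return f_pe, f_kn


def _decompose(img_low: CTImage, img_high: CTImage) -> tuple[np.ndarray, np.ndarray, float, float]:
    if img_low.hu.shape != img_high.hu.shape:
        raise ValueError("images must be geometrically identical")
    e1 = img_low.meta.get("e_ref_kev") or effective_energy(img_low.spectrum)
    e2 = img_high.meta.get("e_ref_kev") or effective_energy(img_high.spectrum)
    f1p, f1c = _basis(e1)
    f2p, f2c = _basis(e2)
    det = f1p * f2c - f2p * f1c
    if abs(det) < 1e-3 * max(abs(f1p * f2c), abs(f2p * f1c), 1e-30):
        raise ConditioningError(f"spectra too similar (E_ref {e1:.1f} vs {e2:.1f} keV)")
    mu1 = float(mu_water(e1)) * (1.0 + img_low.hu / 1000.0)
    mu2 = float(mu_water(e2)) * (1.0 + img_high.hu / 1000.0)
    p_map = (mu1 * f2c - mu2 * f1c) / det
    c_map = (f1p * mu2 - f2p * mu1) / det
    return p_map, c_map, e1, e2


def pseudo_mono_image(img_low: CTImage, img_high: CTImage, target_kev: float) -> CTImage:
    """Synthesize a pseudo-monochromatic image from a dual-energy pair.

    Solves the two-basis (photoelectric/Compton) system per voxel at the two
    spectra's effective energies, evaluates mu at the target energy, and
    converts to HU at that energy.
    """
    e1 = img_low.meta.get("e_ref_kev") or effective_energy(img_low.spectrum)
    e2 = img_high.meta.get("e_ref_kev") or effective_energy(img_high.spectrum)
    if abs(e1 - e2) < 1e-9:
        # degenerate pair of identical effective energies: only the identity
        # synthesis (target at that same energy) is defined
        if abs(float(target_kev) - e1) < 1e-9:
            return CTImage(
                hu=img_low.hu.copy(),
                voxel_size=img_low.voxel_size,
                technique_id=f"mono{target_kev:g}keV",
                corrections=img_low.corrections | {"pseudo_mono"},
                spectrum=None,
                meta={"e_ref_kev": float(target_kev), "pair": (img_low.technique_id, img_high.technique_id)},
            )
        raise ConditioningError("identical effective energies; cannot extrapolate")
    p_map, c_map, _e1, _e2 = _decompose(img_low, img_high)
    ftp, ftc = _basis(target_kev)
    mu_t = p_map * ftp + c_map * ftc
    mu_wt = float(mu_water(target_kev))
    hu_t = 1000.0 * (mu_t - mu_wt) / mu_wt
    return CTImage(
        hu=hu_t,
        voxel_size=img_low.voxel_size,
        technique_id=f"mono{target_kev:g}keV",
        corrections=(img_low.corrections & img_high.corrections) | {"pseudo_mono"},
        spectrum=None,
        meta={
            "e_ref_kev": float(target_kev),
            "pair": (img_low.technique_id, img_high.technique_id),
        },
        sim=None,
    )


def rho_z_decompose(img_low: CTImage, img_high: CTImage) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (rho_e, Zeff) from a dual-energy pair via the two-process model.

    Voxels with non-physical solutions (rho_e <= 0) are masked as NaN and
    counted in the log.
    """
    p_map, c_map, _e1, _e2 = _decompose(img_low, img_high)
    # Compton coefficient: C * sigma_KN(E)/sigma_KN(E0) = rho_e n_e,w sigma_KN(E)
    rho_e = c_map / (N_E_WATER_CM3 * float(klein_nishina_cross_section(_E0)))
    bad = rho_e <= 0
    pe_phys = p_map * _E0**3  # rho_e n_ew a_pe Zeff^(n-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zeff = (pe_phys / (rho_e * N_E_WATER_CM3 * A_PE)) ** (1.0 / (PE_EXPONENT - 1.0))
    bad |= ~np.isfinite(zeff)
    if bad.any():
        log.warning("rho_z_decompose: masked %d non-physical voxel(s)", int(bad.sum()))
    rho_e = np.where(bad, np.nan, rho_e)
    zeff = np.where(bad, np.nan, zeff)
    return rho_e, zeff


def rho_z_to_rsp(rho_e: np.ndarray, zeff: np.ndarray) -> np.ndarray:
    """RSP map from decomposed (rho_e, Zeff) via the Zeff->I mapping and the
    Bethe-Bloch ratio at the default proton energy."""
    from .materials import StoppingPowerParams

    params = StoppingPowerParams()
    beta = params.resolved_beta()
    b2 = beta * beta

    def logterm(i_ev):
        return np.log(2.0 * params.me_c2 * 1e6 * b2 / (i_ev * (1.0 - b2))) - b2

    zs = np.clip(np.nan_to_num(zeff, nan=7.5), 1.1, 60.0)
    i_map = _i_from_zeff_arr(np.asarray(zs))
    rsp = rho_e * logterm(i_map) / logterm(params.i_water_ev)
    return np.where(np.isfinite(rsp), rsp, np.nan)


def _i_from_zeff_arr(z: np.ndarray) -> np.ndarray:
    from . import materials as _m

    _m.i_from_zeff(7.5)  # ensure anchors built
    anchors = _m._I_FROM_ZEFF_ANCHORS
    zs = np.array([p[0] for p in anchors])
    lis = np.log([p[1] for p in anchors])
    return np.exp(np.interp(z, zs, lis))


# --- I/O --------------------------------------------------------------------

def write_nifti(img: CTImage, path) -> None:
    """Write the HU volume as NIfTI with the voxel size in the affine."""
    import nibabel as nib

    dz, dy, dx = img.voxel_size
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(np.transpose(img.hu, (2, 1, 0)).astype(np.float32), affine), str(path))
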