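"""Shared fixtures.

Heavy simulator products (calibrations, streak-phantom scans) are
session-scoped so the physics checks and the acceptance suite reuse one
set of reconstructions.  Desk-scale defaults: 128^2 grid, 180 angles.
"""

from __future__ import annotations

import numpy as np
import pytest

from protonct import bha_analysis as bha
from protonct import cli_io
from protonct import synthetic_ct as sct
from protonct.materials import (
    StoppingPowerParams,
    load_calibration_plugs,
    load_icrp_tissues,
)

GRID = 128
ANGLES = 180


@pytest.fixture(scope="session")
def plugs():
    return load_calibration_plugs()


@pytest.fixture(scope="session")
def tissues():
    return load_icrp_tissues()


@pytest.fixture(scope="session")
def params():
    return StoppingPowerParams()


@pytest.fixture(scope="session")
def spectra():
    return {t: cli_io.get_spectrum(t) for t in ("80kVp", "120kVp", "140kVp")}


@pytest.fixture(scope="session")
def streak_phantom():
    # reduced axial extent: two unique slice patterns are what matters
    return sct.make_streak_phantom(grid_n=GRID, region_len_mm=20.0, slice_mm=10.0)


@pytest.fixture(scope="session")
def streak_scans(streak_phantom):
    """Noiseless streak-phantom scans per SECT technique, +/- iBHC."""
    out = {}
    for tech in ("80kVp", "120kVp", "140kVp"):
        img = cli_io.acquire(streak_phantom, tech, n_angles=ANGLES)
        out[(tech, False)] = img
        out[(tech, True)] = sct.ibhc_emulate(img)
    return out


@pytest.fixture(scope="session")
def streak_rois(streak_phantom, streak_scans):
    img = streak_scans[("80kVp", False)]
    return cli_io.streak_rois(img, streak_phantom, length_mm=18.0)


def streak_delta(img, rois):
    r1, r2 = rois
    return bha.region_delta(img, r1, r2)[0]


@pytest.fixture(scope="session")
def calibrations():
    """80 kVp calibrations for both phantom sizes and BHC states."""
    out = {}
    for phantom_cm in (33.0, 20.0):
        for ibhc in (False, True):
            out[(phantom_cm, ibhc)] = cli_io.calibrate_technique(
                "80kVp", phantom_cm, ibhc, grid_n=GRID, n_angles=ANGLES
            )
    return out


@pytest.fixture(scope="session")
def cupping_series():
    """Noiseless bone-insert HU over the diameter series per technique/state."""
    phantoms = sct.make_cupping_phantoms(grid_n=GRID, nz=1)
    out = {}
    for tech in ("80kVp", "120kVp", "140kVp"):
        for ibhc in (False, True):
            pts = []
            for ph in phantoms:
                img = cli_io.acquire(ph, tech, ibhc=ibhc, n_angles=ANGLES)
                roi = bha.cylinder_roi(img, (0.0, 0.0), ph.meta["insert_diameter_mm"] / 2.0)
                deff = bha.effective_diameter(ph.ap_mm / 10.0, ph.lat_mm / 10.0)
                pts.append((deff, bha.roi_stats(img, roi)[0]))
            out[(tech, ibhc)] = pts
    return out


@pytest.fixture(scope="session")
def water_cylinder():
    """20-cm water cylinder phantom on the default grid."""
    from protonct.materials import air_material, water_material

    px = sct._pixel_size_for(200.0, GRID)
    labels = sct._circle_mask(GRID, px, 200.0, 200.0)[None].astype(np.int8)
    return sct.VoxelPhantom(
        labels=labels,
        materials={0: air_material(), 1: water_material()},
        voxel_size=(1.0, px, px),
        ap_mm=200.0,
        lat_mm=200.0,
    )


def center_edge_means(img):
    c = bha.cylinder_roi(img, (0.0, 0.0), 25.0, contraction_mm=0.0)
    e = bha.cylinder_roi(img, (0.0, 85.0), 12.0, contraction_mm=0.0)
    (mc, sc_, _), (me, se, _) = bha.roi_stats(img, c), bha.roi_stats(img, e)
    return mc, me, sc_, se
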