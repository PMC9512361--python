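"""Water-equivalent thickness: HU -> RSP maps and axis-aligned projections.

WET along a ray is the line integral of RSP in mm of water; for an
axis-aligned projection it reduces to a sum of voxel RSP times the voxel
size along the ray.  The 90-degree projection integrates along the lateral
(x) axis; 0 degrees integrates along the anterior-posterior (y) axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stoich_calibration import CalibrationCurve, hu_to_rsp
from .synthetic_ct import CTImage

log = logging.getLogger(__name__)

__all__ = ["RSPMap", "WETMap", "rsp_map", "wet_projection", "delta_wet", "save_wet_csv"]


@dataclass
class RSPMap:
    rsp: np.ndarray  # (nz, ny, nx), dimensionless
    voxel_size: tuple[float, float, float]  # mm
    curve_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.rsp < 0):
            raise ValueError("RSP map must be non-negative")


@dataclass
class WETMap:
    wet: np.ndarray  # 2-D, mm
    angle_deg: float
    voxel_size: tuple[float, float]  # mm along the two remaining axes
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wet.ndim != 2:
            raise ValueError("WET map must be 2-D")
        if np.any(self.wet < -1e-9):
            raise ValueError("WET must be non-negative")


def rsp_map(image: CTImage, curve: CalibrationCurve) -> RSPMap:
    """Voxel-wise HU -> RSP; negative interpolants are clamped to 0 (counted)."""
    rsp = hu_to_rsp(curve, image.hu)
    n_neg = int(np.sum(rsp < 0))
    if n_neg:
        log.warning("rsp_map: clamped %d negative voxel(s)", n_neg)
    rsp = np.maximum(rsp, 0.0)
    return RSPMap(rsp=rsp, voxel_size=image.voxel_size, curve_id=curve.fit.technique_id)


def wet_projection(m: RSPMap, angle_deg: float = 90.0) -> WETMap:
    """Sum RSP along an axis-aligned ray; 90 degrees = lateral (x) axis.

    Returns WET(slice, row) in mm: shape (nz, ny) for 90 degrees and
    (nz, nx) for 0 degrees.
    """
    dz, dy, dx = m.voxel_size
    if angle_deg == 90.0:
        wet = m.rsp.sum(axis=2) * dx
        vox = (dz, dy)
    elif angle_deg == 0.0:
        wet = m.rsp.sum(axis=1) * dy
        vox = (dz, dx)
    else:
        raise ValueError("only axis-aligned angles (0, 90) are supported")
    return WETMap(wet=wet, angle_deg=angle_deg, voxel_size=vox, meta={"curve_id": m.curve_id})


def delta_wet(
    a: WETMap, b: WETMap, roi2d: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Elementwise a - b, its ROI mean, and a 1-mm-bin histogram over the ROI."""
    if a.wet.shape != b.wet.shape or a.angle_deg != b.angle_deg:
        raise ValueError("WET maps must share shape and angle")
    d = a.wet - b.wet
    roi = roi2d if roi2d is not None else np.ones_like(d, dtype=bool)
    if roi.shape != d.shape:
        raise ValueError("ROI shape mismatch")
    vals = d[roi]
    mean = float(vals.mean())
    lo = np.floor(vals.min())
    hi = np.ceil(vals.max()) + 1
    counts, edges = np.histogram(vals, bins=np.arange(lo, hi + 1, 1.0))
    hist = np.column_stack([edges[:-1], counts])
    return d, mean, hist


def save_wet_csv(m: WETMap, path) -> None:
    pd.DataFrame(m.wet).to_csv(path, index=False, header=False)
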