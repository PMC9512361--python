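"""Artifact metrics: ROIs with physical contraction, size trends, region deltas.

ROI contours are contracted to avoid plug/phantom interface voxels.  The
contraction is diametral: a 28-mm plug with the default 2-mm contraction
yields a 26-mm-diameter cylindrical ROI (a 1-mm radial margin), and the ROI
length is shortened by the same amount split over both ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stoich_calibration import CalibrationCurve, hu_to_rsp
from .synthetic_ct import CTImage

log = logging.getLogger(__name__)

__all__ = [
    "ROI",
    "TrendResult",
    "cylinder_roi",
    "roi_stats",
    "effective_diameter",
    "cupping_trend",
    "region_delta",
    "mean_ci_halfwidth",
]


@dataclass
class ROI:
    mask: np.ndarray  # bool, aligned to an image volume
    contraction_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} empty after contraction")


@dataclass
class TrendResult:
    slope: float
    intercept: float
    pearson_r: float
    n: int
    unit: str = "HU/cm"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")


def cylinder_roi(
    image: CTImage,
    center_mm: tuple[float, float],
    radius_mm: float,
    length_mm: float | None = None,
    contraction_mm: float = 2.0,
    z_center_mm: float | None = None,
    label: str = "",
) -> ROI:
    """Axial cylindrical ROI; erosion is Euclidean in physical millimetres.

    ``center_mm`` is (y, x) relative to the slice center; the ROI spans the
    whole z extent unless ``length_mm`` is given (centered on ``z_center_mm``,
    default mid-volume).
    """
    nz, ny, nx = image.hu.shape
    dz, dy, dx = image.voxel_size
    r_eff = radius_mm - contraction_mm / 2.0
    if r_eff <= 0:
        raise ValueError("contraction removes the whole ROI radius")
    cy, cx = center_mm
    yy = (np.arange(ny) - (ny - 1) / 2.0) * dy - cy
    xx = (np.arange(nx) - (nx - 1) / 2.0) * dx - cx
    disk = yy[:, None] ** 2 + xx[None, :] ** 2 <= r_eff**2
    if length_mm is None:
        zsel = np.ones(nz, dtype=bool)
    else:
        l_eff = length_mm - contraction_mm
        if l_eff <= 0:
            raise ValueError("contraction removes the whole ROI length")
        zc = z_center_mm if z_center_mm is not None else nz / 2.0 * dz
        zpos = (np.arange(nz) + 0.5) * dz  # slice centers
        zsel = np.abs(zpos - zc) <= l_eff / 2.0
    mask = np.zeros((nz, ny, nx), dtype=bool)
    mask[zsel] = disk
    return ROI(mask=mask, contraction_mm=contraction_mm, label=label)


def roi_stats(image: CTImage, roi: ROI) -> tuple[float, float, np.ndarray]:
    """Mean, population sd, and a 1-HU-bin histogram over the masked voxels.

    The histogram rows are (bin left edge, count).
    """
    if roi.mask.shape != image.hu.shape:
        raise ValueError("ROI not aligned to image")
    vals = image.hu[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    lo = math.floor(vals.min())
    hi = math.ceil(vals.max()) + 1
    counts, edges = np.histogram(vals, bins=np.arange(lo, hi + 1, 1.0))
    hist = np.column_stack([edges[:-1], counts])
    return mean, sd, hist


def effective_diameter(ap_cm: float, lat_cm: float) -> float:
    """d_eff = sqrt(AP * LAT), cm."""
    if ap_cm <= 0 or lat_cm <= 0:
        raise ValueError("dimensions must be positive")
    return math.sqrt(ap_cm * lat_cm)


def cupping_trend(series: list[tuple[float, float]], unit: str = "HU/cm") -> TrendResult:
    """OLS line and Pearson r of a (d_eff, value) series."""
    if len(series) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in series], dtype=float)
    y = np.array([p[1] for p in series], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:
        return TrendResult(0.0, float(y[0]), 0.0, len(x), unit=unit, degenerate=True)
    slope, intercept = np.polyfit(x, y, 1)
    r = float(stats.pearsonr(x, y).statistic)
    return TrendResult(float(slope), float(intercept), r, len(x), unit=unit)


def region_delta(
    image: CTImage, roi1: ROI, roi2: ROI, curve: CalibrationCurve | None = None
) -> tuple[float, float]:
    """(dHU, dRSP%) between artifact-free region 1 and artifact region 2.

    dHU = mean1 - mean2; dRSP% uses region 1 (artifact-free) as denominator.
    Without a curve, dRSP% is NaN.
    """
    m1, _, _ = roi_stats(image, roi1)
    m2, _, _ = roi_stats(image, roi2)
    dhu = m1 - m2
    if curve is None:
        return dhu, float("nan")
    r1 = hu_to_rsp(curve, m1)
    r2 = hu_to_rsp(curve, m2)
    drsp = 100.0 * (r1 - r2) / r1 if r1 != 0 else float("nan")
    return dhu, drsp


def mean_ci_halfwidth(values, confidence: float = 0.95) -> float:
    """t-distribution half-width of the CI of the mean over scan repeats."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 repeats")
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return float(tcrit * v.std(ddof=1) / math.sqrt(n))
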