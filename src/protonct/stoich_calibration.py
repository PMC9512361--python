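"""Stoichiometric HU-to-RSP calibration.

The CT number model is U = (HU + 1000)/1000 = rho_e * f(Zeff), with f a
power series in the effective atomic number fitted by least squares to
tissue-substitute plug readings for one scan technique.  The fitted model
is then evaluated for a set of reference human tissues to produce the
(model HU, Bethe-Bloch RSP) knot sequence that converts any measured HU
into proton relative stopping power by piecewise-linear interpolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import StoppingPowerParams, TissueMaterial, rsp_bethe_bloch

log = logging.getLogger(__name__)

__all__ = [
    "PlugReading",
    "CalibrationFit",
    "CalibrationCurve",
    "model_u",
    "model_hu",
    "fit_ean_function",
    "build_calibration_curve",
    "hu_to_rsp",
    "save_curve_json",
    "load_curve_json",
    "save_curve_csv",
    "load_plug_readings_csv",
]

#: Default polynomial degree M-1 of the Zeff power series.
DEFAULT_DEGREE = 5

AIR_HU = -1000.0


class SingularFitError(RuntimeError):
    """Design matrix is rank deficient (too few distinct Zeff values)."""


@dataclass(frozen=True)
class PlugReading:
    """Measured (or simulated) mean plug HU for one technique."""

    plug: TissueMaterial
    mean_hu: float
    sd_hu: float = 0.0
    technique_id: str = ""

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")


@dataclass
class CalibrationFit:
    technique_id: str
    degree: int
    coeffs: list[float]  # b_m, m = 1..M, multiplying Zeff^(m-1)
    residual_rms: float = 0.0  # HU

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if len(self.coeffs) != self.degree + 1:
            raise ValueError("len(coeffs) must equal degree + 1")


@dataclass
class CalibrationCurve:
    fit: CalibrationFit
    knots: list[tuple[float, float]]  # (model HU, RSP), sorted by HU
    energy_mev: float

    def __post_init__(self) -> None:
        hus = [h for h, _ in self.knots]
        if any(b <= a for a, b in zip(hus, hus[1:])):
            raise ValueError("knots must be strictly sorted by model HU")
        if any(r <= 0 for _, r in self.knots):
            raise ValueError("knot RSP must be positive")


def _ean_poly(z_eff, coeffs) -> np.ndarray:
    z = np.asarray(z_eff, dtype=float)
    return sum(b * z**m for m, b in enumerate(coeffs))


def model_u(rho_e, z_eff, fit: CalibrationFit):
    """U = rho_e * sum_m b_m Zeff^(m-1)."""
    return np.asarray(rho_e, dtype=float) * _ean_poly(z_eff, fit.coeffs)


def model_hu(rho_e, z_eff, fit: CalibrationFit):
    """Model CT number, HU = 1000 U - 1000."""
    return 1000.0 * model_u(rho_e, z_eff, fit) - 1000.0


def fit_ean_function(
    readings: list[PlugReading],
    degree: int = DEFAULT_DEGREE,
    weighted: bool = False,
    technique_id: str | None = None,
) -> CalibrationFit:
    """Least-squares fit of the Zeff power series to plug readings.

    Minimizes sum_i (U_obs,i - rho_e,i f(Zeff,i))^2 over the M = degree+1
    coefficients; optionally weighted by 1/sd_hu^2.
    """
    if len(readings) <= degree + 1:
        raise ValueError("need more readings than coefficients")
    rho = np.array([r.plug.rho_e for r in readings])
    zef = np.array([r.plug.z_eff for r in readings])
    if any(v is None for v in rho) or any(v is None for v in zef):
        raise ValueError("every plug needs rho_e and z_eff")
    u_obs = (np.array([r.mean_hu for r in readings]) + 1000.0) / 1000.0
    X = rho[:, None] * zef[:, None] ** np.arange(degree + 1)[None, :]
    y = u_obs
    if weighted:
        sd = np.array([max(r.sd_hu, 1e-6) for r in readings])
        X = X / sd[:, None]
        y = y / sd
    coeffs, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise SingularFitError(
            f"rank-deficient fit (rank {rank} < {degree + 1}); too few distinct Zeff"
        )
    tid = technique_id if technique_id is not None else (readings[0].technique_id or "")
    fit = CalibrationFit(technique_id=tid, degree=degree, coeffs=[float(c) for c in coeffs])
    pred_hu = model_hu(rho, zef, fit)
    obs_hu = 1000.0 * u_obs - 1000.0
    fit.residual_rms = float(np.sqrt(np.mean((pred_hu - obs_hu) ** 2)))
    return fit


def build_calibration_curve(
    fit: CalibrationFit,
    tissues: list[TissueMaterial],
    params: StoppingPowerParams | None = None,
    merge_tol_hu: float = 0.0,
) -> CalibrationCurve:
    """Evaluate the fitted model and Bethe-Bloch RSP per tissue and sort by HU.

    Knots closer than ``merge_tol_hu`` are merged by averaging RSP (default 0:
    only exact ties are offending and raise, naming the tissues involved).
    """
    params = params or StoppingPowerParams()
    pairs = []
    for t in tissues:
        if t.rho_e is None or t.z_eff is None or t.i_mean is None:
            raise ValueError(f"{t.name}: rho_e, z_eff, i_mean required")
        hu = float(model_hu(t.rho_e, t.z_eff, fit))
        rsp = rsp_bethe_bloch(t, params)
        pairs.append((hu, rsp, t.name))
    pairs.sort(key=lambda p: p[0])
    knots: list[tuple[float, float]] = []
    names: list[list[str]] = []
    for hu, rsp, name in pairs:
        if knots and merge_tol_hu > 0 and hu - knots[-1][0] <= merge_tol_hu:
            h0, r0 = knots[-1]
            k = len(names[-1])
            knots[-1] = ((h0 * k + hu) / (k + 1), (r0 * k + rsp) / (k + 1))
            names[-1].append(name)
        else:
            knots.append((hu, rsp))
            names.append([name])
    hus = [h for h, _ in knots]
    dup = [
        names[i][0] + ", " + names[i + 1][0]
        for i in range(len(hus) - 1)
        if hus[i + 1] <= hus[i]
    ]
    if dup:
        raise ValueError(f"duplicate model HU after tie resolution: {dup}")
    merged = [", ".join(ns) for ns in names if len(ns) > 1]
    if merged:
        log.info("merged calibration knots: %s", "; ".join(merged))
    return CalibrationCurve(fit=fit, knots=knots, energy_mev=params.kinetic_energy)


def hu_to_rsp(curve: CalibrationCurve, hu) -> np.ndarray | float:
    """Piecewise-linear HU -> RSP through the tissue knots.

    Below the first knot the curve runs linearly to the air point
    (-1000 HU, RSP 0); above the last knot the final (bone) segment is
    extrapolated linearly.  Negative results are clamped to zero.
    """
    if len(curve.knots) < 2:
        raise ValueError("curve needs at least 2 knots")
    xs = np.array([k[0] for k in curve.knots])
    ys = np.array([k[1] for k in curve.knots])
    if xs[0] > AIR_HU:
        xs = np.concatenate([[AIR_HU], xs])
        ys = np.concatenate([[0.0], ys])
    h = np.asarray(hu, dtype=float)
    out = np.interp(h, xs, ys)
    # linear extrapolation beyond the endpoints on the terminal segments
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    out = np.where(h > xs[-1], ys[-1] + (h - xs[-1]) * hi_slope, out)
    out = np.where(h < xs[0], ys[0] + (h - xs[0]) * lo_slope, out)
    n_neg = int(np.sum(out < 0))
    if n_neg:
        log.warning("hu_to_rsp: clamped %d negative RSP value(s) to 0", n_neg)
        out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(hu) else out


# --- serialization ----------------------------------------------------------

def save_curve_json(curve: CalibrationCurve, path) -> None:
    obj = {
        "technique_id": curve.fit.technique_id,
        "degree": curve.fit.degree,
        "coefficients": curve.fit.coeffs,
        "residual_rms_hu": curve.fit.residual_rms,
        "energy_mev": curve.energy_mev,
        "knots": [[h, r] for h, r in curve.knots],
    }
    with open(path, "w") as f:
        json.dump(obj, f, indent=1)


def load_curve_json(path) -> CalibrationCurve:
    with open(path) as f:
        obj = json.load(f)
    fit = CalibrationFit(
        technique_id=obj["technique_id"],
        degree=obj["degree"],
        coeffs=list(obj["coefficients"]),
        residual_rms=obj.get("residual_rms_hu", 0.0),
    )
    return CalibrationCurve(
        fit=fit,
        knots=[(float(h), float(r)) for h, r in obj["knots"]],
        energy_mev=obj["energy_mev"],
    )


def save_curve_csv(curve: CalibrationCurve, path) -> None:
    pd.DataFrame(curve.knots, columns=["hu", "rsp"]).to_csv(path, index=False)


def load_plug_readings_csv(path, plugs: list[TissueMaterial], technique_id: str = "") -> list[PlugReading]:
    """Import externally measured plug readings (plug_name, mean_hu, sd_hu)."""
    df = pd.read_csv(path)
    by_name = {m.name: m for m in plugs}
    readings = []
    for row in df.itertuples(index=False):
        name = str(row.plug_name)
        if name not in by_name:
            raise KeyError(f"unknown plug {name!r}")
        readings.append(
            PlugReading(
                plug=by_name[name],
                mean_hu=float(row.mean_hu),
                sd_hu=float(getattr(row, "sd_hu", 0.0)),
                technique_id=technique_id,
            )
        )
    return readings
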