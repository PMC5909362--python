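"""Estimation of the tube-output line, tube yields and mu_en from
measurement series.

Two fits characterise a beam for one anode-filter combination:

* kerma line — air kerma per mAs at zero phantom thickness is regressed
  on kVp (ordinary least squares), giving the slope ``alpha`` and
  intercept ``beta`` with their standard errors;
* exponential attenuation — beam intensity under increasing depths of
  solid water is fitted to ``I(x) = I0 * exp(-mu_en * x)``, giving the
  effective energy-absorption coefficient per kVp setting.  The
  per-combination average of those coefficients is what the dose model
  uses by default.

Replicate measurements at identical settings are averaged before
fitting (the measurement protocol repeats each point five times), with a
pooled mode available.  Fits are unweighted: the protocol supplies no
per-point sigmas.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dosimetry import DosimetryError, MammodoseWarning

__all__ = [
    "KermaCalibrationPoint",
    "AttenuationPoint",
    "FitResult",
    "fit_kerma_line",
    "fit_attenuation",
    "average_mu_en",
    "tube_yield",
    "read_kerma_csv",
    "read_attenuation_csv",
]


class CalibrationError(DosimetryError):
    """Measurement series unusable for the requested fit."""


@dataclass(frozen=True)
class KermaCalibrationPoint:
    """One air-kerma measurement at zero phantom thickness."""

    kvp: float
    mas: float
    kerma: float
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.kerma <= 0:
            raise CalibrationError("measured kerma must be positive")
        if self.mas <= 0:
            raise CalibrationError("mAs must be positive")


@dataclass(frozen=True)
class AttenuationPoint:
    """One beam-intensity measurement under ``depth_cm`` of solid water."""

    depth_cm: float
    intensity: float
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.depth_cm < 0:
            raise CalibrationError("depth must be non-negative")
        if self.intensity <= 0:
            raise CalibrationError("intensity must be positive")


@dataclass(frozen=True)
class FitResult:
    """Least-squares estimates with 1-sigma standard errors.

    ``r_squared`` is computed in the space of the measured quantity
    (kerma/mAs for the line fit, intensity for the attenuation fit).
    ``covariance`` carries off-diagonal fit covariances when available.
    """

    estimates: Mapping[str, float]
    sigmas: Mapping[str, float]
    r_squared: float
    n_points: int
    residuals: tuple[float, ...] = ()
    covariance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigmas.values()):
            raise CalibrationError("standard errors must be non-negative")
        if self.n_points < len(self.estimates):
            raise CalibrationError("fewer points than parameters")

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "sigmas": dict(self.sigmas),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "residuals": list(self.residuals),
            "covariance": dict(self.covariance),
        }


def _average_replicates(
    keys: Sequence[tuple], values: Sequence[float]
) -> tuple[list[tuple], list[float]]:
    """Average values sharing the same design key, preserving key order."""
    order: list[tuple] = []
    groups: dict[tuple, list[float]] = {}
    for key, value in zip(keys, values):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(value)
    return order, [float(np.mean(groups[k])) for k in order]


def fit_kerma_line(
    points: Iterable[KermaCalibrationPoint],
    averaging: str = "replicates_first",
) -> FitResult:
    """OLS of kerma/mAs against kVp: estimates ``alpha`` (slope) and
    ``beta`` (intercept).

    With ``averaging="replicates_first"`` (measurement-protocol
    behaviour) replicates at identical (kVp, mAs) are averaged before
    the regression; ``"pooled"`` fits every point.  R^2 is the squared
    correlation of the regression.
    """
    points = list(points)
    if averaging not in ("replicates_first", "pooled"):
        raise CalibrationError(f"unknown averaging mode {averaging!r}")
    if averaging == "replicates_first":
        keys, y = _average_replicates(
            [(p.kvp, p.mas) for p in points], [p.kerma / p.mas for p in points]
        )
        x = [k[0] for k in keys]
    else:
        x = [p.kvp for p in points]
        y = [p.kerma / p.mas for p in points]
    if len(set(x)) < 2:
        raise CalibrationError(
            "kerma-line fit needs at least two distinct kVp values"
        )
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    res = stats.linregress(x_arr, y_arr)
    fitted = res.slope * x_arr + res.intercept
    residuals = y_arr - fitted
    # OLS covariance of (slope, intercept): cov = -xbar * se_slope^2
    cov_ab = -float(np.mean(x_arr)) * res.stderr**2
    return FitResult(
        estimates={"alpha": float(res.slope), "beta": float(res.intercept)},
        sigmas={"alpha": float(res.stderr), "beta": float(res.intercept_stderr)},
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        residuals=tuple(float(r) for r in residuals),
        covariance={"alpha_beta": cov_ab},
    )


def _loglinear_attenuation(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, np.log(y))
    i0 = math.exp(res.intercept)
    return {
        "I0": i0,
        "mu_en": -res.slope,
        "I0_sigma": i0 * res.intercept_stderr,
        "mu_en_sigma": res.stderr,
    }


def fit_attenuation(
    points: Iterable[AttenuationPoint],
    method: str = "nonlinear",
    averaging: str = "replicates_first",
) -> FitResult:
    """Fit ``I(x) = I0 * exp(-mu_en * x)`` to a transmission series.

    ``method="nonlinear"`` (default) runs intensity-space least squares
    initialised from the log-linear closed form — unbiased under
    additive intensity noise.  ``method="loglinear"`` returns the
    log-space OLS solution directly (fast, diagnostic).  R^2 is always
    computed in intensity space.
    """
    points = list(points)
    if method not in ("nonlinear", "loglinear"):
        raise CalibrationError(f"unknown attenuation fit method {method!r}")
    if averaging == "replicates_first":
        keys, y = _average_replicates(
            [(p.depth_cm,) for p in points], [p.intensity for p in points]
        )
        x = [k[0] for k in keys]
    else:
        x = [p.depth_cm for p in points]
        y = [p.intensity for p in points]
    if len(points) < 3 or len(set(x)) < 2:
        raise CalibrationError(
            "attenuation fit needs >= 3 points spanning >= 2 distinct depths"
        )
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)

    start = _loglinear_attenuation(x_arr, y_arr)
    if method == "loglinear":
        i0, mu = start["I0"], start["mu_en"]
        sig_i0, sig_mu = start["I0_sigma"], start["mu_en_sigma"]
        cov = {}
    else:
        popt, pcov = optimize.curve_fit(
            lambda x, i0, mu: i0 * np.exp(-mu * x),
            x_arr,
            y_arr,
            p0=[start["I0"], start["mu_en"]],
            maxfev=10000,
        )
        i0, mu = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        sig_i0, sig_mu = float(perr[0]), float(perr[1])
        if not np.isfinite(sig_i0):  # exact fit: zero residual variance
            sig_i0 = 0.0
        if not np.isfinite(sig_mu):
            sig_mu = 0.0
        cov = {"I0_mu_en": float(pcov[0, 1]) if np.isfinite(pcov[0, 1]) else 0.0}

    fitted = i0 * np.exp(-mu * x_arr)
    residuals = y_arr - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y_arr - y_arr.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return FitResult(
        estimates={"I0": i0, "mu_en": mu},
        sigmas={"I0": sig_i0, "mu_en": sig_mu},
        r_squared=min(r_squared, 1.0),
        n_points=len(x),
        residuals=tuple(float(r) for r in residuals),
        covariance=cov,
    )


def average_mu_en(
    per_kvp: Mapping[float, tuple[float, float] | float],
) -> tuple[float, float]:
    """Unweighted mean of per-kVp mu_en values for one combination.

    The attached sigma is ``max(mean of per-kVp sigmas, SD/sqrt(n))`` —
    the per-fit error floor or the spread of the mean, whichever
    dominates.  Values may be bare floats (sigma 0) or (value, sigma).
    """
    if not per_kvp:
        raise CalibrationError("empty per-kVp mu_en map")
    values, sigmas = [], []
    for entry in per_kvp.values():
        if isinstance(entry, (tuple, list)):
            values.append(float(entry[0]))
            sigmas.append(float(entry[1]))
        else:
            values.append(float(entry))
            sigmas.append(0.0)
    mean = float(np.mean(values))
    n = len(values)
    sem = float(np.std(values, ddof=1)) / math.sqrt(n) if n > 1 else 0.0
    return mean, max(float(np.mean(sigmas)), sem)


def tube_yield(
    points: Iterable[KermaCalibrationPoint],
    reference_kvp: float | None = None,
) -> tuple[float, float]:
    """Tube yield Y (mGy/mAs) at the reference kVp: mean of kerma/mAs
    across replicate measurements, with the sample SD as 1-sigma.

    All points must share one kVp (the reference); pass ``reference_kvp``
    to additionally assert which one.
    """
    points = list(points)
    if not points:
        raise CalibrationError("no measurements for tube yield")
    kvps = {p.kvp for p in points}
    if len(kvps) > 1:
        raise CalibrationError(
            f"tube yield measurements mix kVp values: {sorted(kvps)}"
        )
    if reference_kvp is not None and kvps != {reference_kvp}:
        raise CalibrationError(
            f"tube yield measured at {kvps.pop()} kVp, expected {reference_kvp}"
        )
    ratios = [p.kerma / p.mas for p in points]
    if len(ratios) == 1:
        _warnings.warn(
            "single yield measurement: standard deviation reported as 0",
            MammodoseWarning,
            stacklevel=2,
        )
        return float(ratios[0]), 0.0
    return float(np.mean(ratios)), float(np.std(ratios, ddof=1))


# ----------------------------------------------------------------------
# Measurement CSV formats (UTF-8, dot decimal, header required)
# ----------------------------------------------------------------------

def read_kerma_csv(path) -> dict[str, list[KermaCalibrationPoint]]:
    """Read kerma calibration measurements grouped by combination.

    Columns: combination, kvp, mas, kerma_mgy, replicate (optional).
    """
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"combination", "kvp", "mas", "kerma_mgy"}
    missing = required - set(frame.columns)
    if missing:
        raise CalibrationError(
            f"kerma CSV missing columns: {', '.join(sorted(missing))}"
        )
    groups: dict[str, list[KermaCalibrationPoint]] = {}
    for _, row in frame.iterrows():
        rep = row.get("replicate")
        groups.setdefault(str(row["combination"]), []).append(
            KermaCalibrationPoint(
                kvp=float(row["kvp"]),
                mas=float(row["mas"]),
                kerma=float(row["kerma_mgy"]),
                replicate_id=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    return groups


def read_attenuation_csv(path) -> dict[tuple[str, float], list[AttenuationPoint]]:
    """Read transmission measurements grouped by (combination, kVp).

    Columns: combination, kvp, depth_cm, intensity_mgy, replicate
    (optional).
    """
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"combination", "kvp", "depth_cm", "intensity_mgy"}
    missing = required - set(frame.columns)
    if missing:
        raise CalibrationError(
            f"attenuation CSV missing columns: {', '.join(sorted(missing))}"
        )
    groups: dict[tuple[str, float], list[AttenuationPoint]] = {}
    for _, row in frame.iterrows():
        rep = row.get("replicate")
        key = (str(row["combination"]), float(row["kvp"]))
        groups.setdefault(key, []).append(
            AttenuationPoint(
                depth_cm=float(row["depth_cm"]),
                intensity=float(row["intensity_mgy"]),
                replicate_id=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    return groups
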