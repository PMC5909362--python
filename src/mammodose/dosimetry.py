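"""Closed-form evaluation of incident air kerma and the 2ABD dose index.

The average absorbed breast dose (2ABD) is the depth average of the
absorbed dose in a compressed breast of thickness ``d`` irradiated by a
mammographic beam.  With an effective exponential energy-absorption
coefficient ``mu_en`` for water-equivalent soft tissue, the depth average
of ``k_ai * exp(-mu_en * x)`` over ``[0, d]`` has the closed form

    2ABD = k_ai * (1 - exp(-mu_en * d)) / (mu_en * d)

where ``k_ai`` is the incident air kerma at the upper breast surface.
``k_ai`` itself is reconstructed from acquisition parameters: within the
mammographic tube-voltage range the kerma per mAs at the image plane is
linear in kVp, so

    k_ai = (Y_tb / Y_0) * (alpha * kVp + beta) * mAs * (FID / (FID - d))**2

with ``alpha``/``beta`` fitted on a reference tube of yield ``Y_0``,
``Y_tb`` the yield of the clinical tube (both at the same reference kVp),
and the inverse-square factor moving the reference point from the image
plane to the breast entrance surface at ``FID - d``.

Units used throughout the package: cm, mGy, kVp, mAs, cm^-1, mm Al.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping

logger = logging.getLogger("mammodose")

# ----------------------------------------------------------------------
# Package-wide constants
# ----------------------------------------------------------------------

#: mu_en * d below this uses the 3-term series of (1 - exp(-u)) / u.
SMALL_ARGUMENT_THRESHOLD = 1e-6

#: kVp at which tube yields are defined unless a calibration overrides it.
DEFAULT_REFERENCE_KVP = 28.0

#: Calibrated kVp interval of the linear kerma model.
DEFAULT_KVP_VALIDITY = (22.0, 34.0)

#: Breast-thickness uncertainty quoted by device technical manuals (cm).
DEFAULT_THICKNESS_SIGMA_CM = 0.5

#: Anode-filter combinations with bundled calibrations.
SUPPORTED_COMBINATIONS = ("Mo-Mo", "Mo-Rh", "Rh-Rh", "W-Rh", "W-Ag")


class MammodoseError(Exception):
    """Base class for all package errors."""


class DosimetryError(MammodoseError, ValueError):
    """Invalid physics input (negative thickness, non-positive kerma, ...)."""


class ConfigurationError(MammodoseError, ValueError):
    """Missing or inconsistent configuration (tables, modes, registries)."""


class MammodoseWarning(UserWarning):
    """Base class for package warnings."""


class KvpRangeWarning(MammodoseWarning):
    """Tube voltage outside the calibrated linearity interval."""


class UnknownCombinationWarning(MammodoseWarning):
    """Anode-filter combination without a bundled calibration."""


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------

_MATERIAL_ALIASES = {
    "mo": "Mo",
    "molybdenum": "Mo",
    "rh": "Rh",
    "rhodium": "Rh",
    "w": "W",
    "tungsten": "W",
    "ag": "Ag",
    "silver": "Ag",
    "al": "Al",
    "aluminum": "Al",
    "aluminium": "Al",
}


def _normalise_material(text: str) -> str:
    key = text.strip().lower()
    if not key:
        raise DosimetryError("empty material label")
    return _MATERIAL_ALIASES.get(key, text.strip().capitalize())


@dataclass(frozen=True)
class AnodeFilterCombination:
    """X-ray target and filtration materials defining the beam spectrum.

    Materials are normalised to element symbols at construction
    (``MOLYBDENUM`` -> ``Mo``), so equality and hashing are effectively
    case-insensitive on the canonical ``Anode-Filter`` form.  Unknown
    materials remain representable; :attr:`is_supported` flags whether a
    bundled calibration exists for the combination.
    """

    anode: str
    filter: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "anode", _normalise_material(self.anode))
        object.__setattr__(self, "filter", _normalise_material(self.filter))

    @property
    def canonical(self) -> str:
        return f"{self.anode}-{self.filter}"

    @property
    def is_supported(self) -> bool:
        return self.canonical in SUPPORTED_COMBINATIONS

    @classmethod
    def from_string(cls, text: str) -> "AnodeFilterCombination":
        parts = text.split("-")
        if len(parts) != 2:
            raise DosimetryError(
                f"combination {text!r} is not of the form 'Anode-Filter'"
            )
        return cls(parts[0], parts[1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical


@dataclass(frozen=True)
class TubeCalibration:
    """Per anode-filter physics constants of the reference tube.

    ``alpha``/``beta`` are the slope (mGy mAs^-1 kVp^-1) and intercept
    (mGy mAs^-1) of the kerma-per-mAs line; ``y0`` the measured reference
    yield at ``reference_kvp`` (mGy mAs^-1, zero phantom thickness);
    ``mu_en`` the combination-average energy-absorption coefficient
    (cm^-1), optionally backed by a per-kVp table.
    """

    combination: AnodeFilterCombination
    alpha: float
    beta: float
    y0: float
    mu_en: float
    alpha_sigma: float = 0.0
    beta_sigma: float = 0.0
    y0_sigma: float = 0.0
    mu_en_sigma: float = 0.0
    reference_kvp: float = DEFAULT_REFERENCE_KVP
    mu_en_by_kvp: Mapping[float, tuple[float, float]] | None = None
    kvp_validity: tuple[float, float] = DEFAULT_KVP_VALIDITY

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DosimetryError("alpha must be positive")
        if self.y0 <= 0:
            raise DosimetryError("Y0 must be positive")
        if self.mu_en <= 0:
            raise DosimetryError("mu_en must be positive")
        if self.alpha * self.reference_kvp + self.beta <= 0:
            raise DosimetryError(
                "kerma line is non-positive at the reference kVp"
            )
        for name in ("alpha_sigma", "beta_sigma", "y0_sigma", "mu_en_sigma"):
            if getattr(self, name) < 0:
                raise DosimetryError(f"{name} must be non-negative")

    def line_value(self, kvp: float) -> float:
        """Kerma per mAs predicted by the fitted line at ``kvp``."""
        return self.alpha * kvp + self.beta

    def mu_en_at(self, kvp: float) -> tuple[float, float]:
        """Interpolate ``mu_en`` (value, sigma) linearly in kVp.

        Clamped at the table ends; requires :attr:`mu_en_by_kvp`.
        """
        if not self.mu_en_by_kvp:
            raise ConfigurationError(
                f"no per-kVp mu_en table for {self.combination.canonical}"
            )
        kvps = sorted(self.mu_en_by_kvp)
        values = [self.mu_en_by_kvp[k][0] for k in kvps]
        sigmas = [self.mu_en_by_kvp[k][1] for k in kvps]
        return _interp_clamped(kvp, kvps, values), _interp_clamped(kvp, kvps, sigmas)

    def to_dict(self) -> dict:
        out = {
            "combination": self.combination.canonical,
            "alpha": self.alpha,
            "alpha_sigma": self.alpha_sigma,
            "beta": self.beta,
            "beta_sigma": self.beta_sigma,
            "Y0": self.y0,
            "Y0_sigma": self.y0_sigma,
            "reference_kvp": self.reference_kvp,
            "mu_en": self.mu_en,
            "mu_en_sigma": self.mu_en_sigma,
            "kvp_validity": list(self.kvp_validity),
        }
        if self.mu_en_by_kvp:
            out["mu_en_by_kvp"] = {
                str(k): list(v) for k, v in sorted(self.mu_en_by_kvp.items())
            }
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "TubeCalibration":
        by_kvp = data.get("mu_en_by_kvp")
        return cls(
            combination=AnodeFilterCombination.from_string(data["combination"]),
            alpha=float(data["alpha"]),
            alpha_sigma=float(data.get("alpha_sigma", 0.0)),
            beta=float(data["beta"]),
            beta_sigma=float(data.get("beta_sigma", 0.0)),
            y0=float(data["Y0"]),
            y0_sigma=float(data.get("Y0_sigma", 0.0)),
            reference_kvp=float(data.get("reference_kvp", DEFAULT_REFERENCE_KVP)),
            mu_en=float(data["mu_en"]),
            mu_en_sigma=float(data.get("mu_en_sigma", 0.0)),
            mu_en_by_kvp=(
                {float(k): (float(v[0]), float(v[1])) for k, v in by_kvp.items()}
                if by_kvp
                else None
            ),
            kvp_validity=tuple(data.get("kvp_validity", DEFAULT_KVP_VALIDITY)),
        )


def _interp_clamped(x: float, xs: list[float], ys: list[float]) -> float:
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(1, len(xs)):
        if x <= xs[i]:
            t = (x - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + t * (ys[i] - ys[i - 1])
    return ys[-1]  # pragma: no cover


@dataclass(frozen=True)
class DeviceProfile:
    """Geometry and per-combination output of one mammography unit.

    ``yields`` maps canonical combination strings to ``(Y_tb, sigma)`` in
    mGy mAs^-1 at the reference kVp.
    """

    device_id: str
    fid_cm: float
    yields: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fid_cm <= 0:
            raise DosimetryError("FID must be positive")
        for combo, (y, sigma) in self.yields.items():
            if y <= 0:
                raise DosimetryError(f"Y_tb for {combo} must be positive")
            if sigma < 0:
                raise DosimetryError(f"Y_tb sigma for {combo} must be >= 0")

    def yield_for(self, combination: AnodeFilterCombination) -> tuple[float, float]:
        key = combination.canonical
        if key not in self.yields:
            raise DosimetryError(
                f"device {self.device_id!r} has no tube yield for {key}"
            )
        return self.yields[key]

    def to_dict(self) -> dict:
        return {
            "FID_cm": self.fid_cm,
            "yields": {
                combo: {"Y": y, "sigma": s}
                for combo, (y, s) in sorted(self.yields.items())
            },
        }

    @classmethod
    def from_dict(cls, device_id: str, data: Mapping) -> "DeviceProfile":
        return cls(
            device_id=device_id,
            fid_cm=float(data["FID_cm"]),
            yields={
                combo: (float(entry["Y"]), float(entry.get("sigma", 0.0)))
                for combo, entry in data.get("yields", {}).items()
            },
        )


@dataclass(frozen=True)
class ExamRecord:
    """Acquisition parameters of one mammographic exposure."""

    exam_id: str
    combination: AnodeFilterCombination
    kvp: float
    mas: float
    thickness_cm: float
    device_id: str = ""
    thickness_sigma_cm: float = DEFAULT_THICKNESS_SIGMA_CM
    age_years: float | None = None
    glandularity_pct: float | None = None
    hvl_mmal: float | None = None

    def __post_init__(self) -> None:
        if self.kvp <= 0:
            raise DosimetryError(f"exam {self.exam_id}: kVp must be positive")
        if self.mas <= 0:
            raise DosimetryError(f"exam {self.exam_id}: mAs must be positive")
        if self.thickness_cm < 0:
            raise DosimetryError(
                f"exam {self.exam_id}: thickness must be non-negative"
            )
        if self.thickness_sigma_cm < 0:
            raise DosimetryError(
                f"exam {self.exam_id}: thickness sigma must be >= 0"
            )
        if self.hvl_mmal is not None and self.hvl_mmal <= 0:
            raise DosimetryError(f"exam {self.exam_id}: HVL must be positive")


@dataclass(frozen=True)
class KermaResult:
    """Incident air kerma with its multiplicative component breakdown.

    ``components`` holds ``yield_ratio`` (Y_tb/Y_0), ``line_mas``
    ((alpha*kVp+beta)*mAs, mGy) and ``inverse_square``; their product
    reconstructs ``k_ai`` exactly.
    """

    k_ai: float
    sigma: float
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.k_ai <= 0:
            raise DosimetryError("incident air kerma must be positive")
        product = 1.0
        for value in self.components.values():
            product *= value
        if abs(product - self.k_ai) > 1e-12 * self.k_ai:
            raise DosimetryError(
                "kerma component product does not reconstruct k_ai"
            )


@dataclass(frozen=True)
class DoseResult:
    """2ABD with its kerma and optional reference AGD values (all mGy)."""

    two_abd: float
    sigma: float
    k_ai: KermaResult
    agd_dance: tuple[float, float] | None = None
    agd_wu: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.two_abd <= self.k_ai.k_ai * (1 + 1e-12):
            raise DosimetryError("2ABD must satisfy 0 < 2ABD <= k_ai")
        if self.sigma < 0:
            raise DosimetryError("sigma must be non-negative")


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def attenuation_integral_factor(mu_en: float, d: float) -> float:
    """Depth-average transmission factor ``(1 - exp(-mu_en*d)) / (mu_en*d)``.

    This is the ratio of 2ABD to the incident air kerma: the mean of
    ``exp(-mu_en*x)`` over depths ``x`` in ``[0, d]``.  Continuous at
    ``mu_en*d -> 0`` (series branch), strictly decreasing in ``mu_en*d``
    and always in ``(0, 1]``.

    Parameters
    ----------
    mu_en : float
        Energy absorption coefficient, cm^-1, >= 0.
    d : float
        Breast thickness, cm, >= 0.
    """
    if mu_en < 0 or d < 0:
        raise DosimetryError("mu_en and d must be non-negative")
    u = mu_en * d
    if u < SMALL_ARGUMENT_THRESHOLD:
        # 3-term series: error < u**3/24 < 1e-19 below the threshold
        return 1.0 - u / 2.0 + u * u / 6.0
    return -math.expm1(-u) / u


def inverse_square_factor(fid_cm: float, d_cm: float) -> float:
    """Inverse-square correction ``(FID / (FID - d))**2`` from the image
    plane to the breast entrance surface.

    Requires ``0 <= d < FID``; equals 1 at ``d = 0``.
    """
    if fid_cm <= 0:
        raise DosimetryError("FID must be positive")
    if d_cm < 0:
        raise DosimetryError("thickness must be non-negative")
    if d_cm >= fid_cm:
        raise DosimetryError(
            f"breast thicker than focus distance (d={d_cm} cm >= FID={fid_cm} cm)"
        )
    ratio = fid_cm / (fid_cm - d_cm)
    return ratio * ratio


def two_abd_value(
    alpha: float,
    beta: float,
    y0: float,
    ytb: float,
    kvp: float,
    mas: float,
    d: float,
    fid: float,
    mu_en: float,
) -> float:
    """Raw 2ABD from scalar inputs; shared by propagation and its
    finite-difference oracle."""
    line = alpha * kvp + beta
    if line <= 0:
        raise DosimetryError(f"non-positive kerma line value {line:.4g}")
    k = (ytb / y0) * line * mas * inverse_square_factor(fid, d)
    return k * attenuation_integral_factor(mu_en, d)


def incident_air_kerma(
    cal: TubeCalibration,
    device: DeviceProfile,
    exam: ExamRecord,
    sigma: float | None = None,
) -> KermaResult:
    """Reconstruct the incident air kerma of one exposure.

    ``k_ai = (Y_tb/Y_0) * (alpha*kVp + beta) * mAs * (FID/(FID-d))**2``.
    A kVp outside the calibration's validity interval triggers a
    :class:`KvpRangeWarning` and proceeds (extrapolation is the user's
    informed choice).  When ``sigma`` is None the 1-sigma uncertainty is
    propagated with the default budget of the calibration and device.
    """
    if exam.combination != cal.combination:
        raise DosimetryError(
            f"exam combination {exam.combination.canonical} does not match "
            f"calibration {cal.combination.canonical}"
        )
    ytb, _ = device.yield_for(exam.combination)
    line = cal.line_value(exam.kvp)
    if line <= 0:
        raise DosimetryError(
            f"kerma line (alpha*kVp+beta) non-positive at {exam.kvp} kVp "
            f"for {cal.combination.canonical}: {line:.4g} mGy/mAs"
        )
    lo, hi = cal.kvp_validity
    if not lo <= exam.kvp <= hi:
        _warnings.warn(
            f"exam {exam.exam_id}: {exam.kvp} kVp outside calibrated "
            f"interval [{lo}, {hi}]; extrapolating the kerma line",
            KvpRangeWarning,
            stacklevel=2,
        )
    components = {
        "yield_ratio": ytb / cal.y0,
        "line_mas": line * exam.mas,
        "inverse_square": inverse_square_factor(device.fid_cm, exam.thickness_cm),
    }
    k_ai = components["yield_ratio"] * components["line_mas"] * components["inverse_square"]
    if sigma is None:
        from .uncertainty import UncertaintyBudget, propagate_2abd

        budget = UncertaintyBudget.from_sources(cal, device, exam)
        sigma = propagate_2abd(cal, device, exam, budget).kerma_sigma_abs
    return KermaResult(k_ai=k_ai, sigma=sigma, components=components)


def average_breast_dose(
    cal: TubeCalibration,
    device: DeviceProfile,
    exam: ExamRecord,
    mu_en_mode: str = "average",
    budget=None,
) -> DoseResult:
    """Compute 2ABD for one exposure with propagated 1-sigma uncertainty.

    ``mu_en_mode`` selects the combination-average coefficient
    (``"average"``, default: the per-kVp variation of the depth-averaged
    dose is negligible over the calibrated range) or linear interpolation
    of the per-kVp table (``"per_kvp"``, clamped at the table ends).
    ``budget`` overrides the default uncertainty budget (see
    :mod:`mammodose.uncertainty`).
    """
    if mu_en_mode not in ("average", "per_kvp"):
        raise ConfigurationError(f"unknown mu_en mode {mu_en_mode!r}")
    if mu_en_mode == "per_kvp":
        mu_en, mu_sigma = cal.mu_en_at(exam.kvp)
    else:
        mu_en, mu_sigma = cal.mu_en, cal.mu_en_sigma

    from .uncertainty import UncertaintyBudget, propagate_2abd

    if budget is None:
        budget = UncertaintyBudget.from_sources(cal, device, exam, mu_en_sigma=mu_sigma)
    prop = propagate_2abd(cal, device, exam, budget, mu_en=mu_en)

    kerma = incident_air_kerma(cal, device, exam, sigma=prop.kerma_sigma_abs)
    factor = attenuation_integral_factor(mu_en, exam.thickness_cm)
    return DoseResult(
        two_abd=kerma.k_ai * factor,
        sigma=prop.sigma_abs,
        k_ai=kerma,
    )
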