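"""First-order propagation of input uncertainties through the 2ABD model.

The dose is a product ``D = (Y_tb/Y_0) * (alpha*kVp + beta) * mAs * S(d) * f(mu*d)``
with ``S`` the inverse-square factor and ``f(u) = (1 - e^-u)/u``, so the
partial derivatives are analytic.  The 1-sigma uncertainty is assembled
by the classical delta method: per-input contributions summed in
quadrature, plus an optional alpha-beta covariance cross term.  mAs is
treated as exact (it is a set value, not a measurement); kVp and FID
default to exact as well but can be overridden in the budget.

Reference AGD values carry a flat 20% relative uncertainty, the accepted
overall error of the conversion-factor formalisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dosimetry import (
    DEFAULT_THICKNESS_SIGMA_CM,
    DeviceProfile,
    DosimetryError,
    ExamRecord,
    TubeCalibration,
    attenuation_integral_factor,
    inverse_square_factor,
    two_abd_value,
)

#: Flat relative uncertainty of conversion-factor AGD estimates.
AGD_RELATIVE_SIGMA = 0.20

#: Input names, in the order partial derivatives are reported.
BUDGET_INPUTS = ("alpha", "beta", "y0", "ytb", "kvp", "d", "fid", "mu_en")


@dataclass(frozen=True)
class UncertaintyBudget:
    """1-sigma input uncertainties entering the 2ABD propagation.

    All sigmas in the unit of the corresponding input (mGy mAs^-1 kVp^-1,
    mGy mAs^-1, kVp, cm, cm^-1).  ``alpha_beta_cov`` (mGy^2 mAs^-2 kVp^-1)
    adds the fit covariance cross term when the line fit supplies it.
    """

    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0
    sigma_y0: float = 0.0
    sigma_ytb: float = 0.0
    sigma_kvp: float = 0.0
    sigma_d: float = DEFAULT_THICKNESS_SIGMA_CM
    sigma_fid: float = 0.0
    sigma_mu_en: float = 0.0
    alpha_beta_cov: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "sigma_alpha",
            "sigma_beta",
            "sigma_y0",
            "sigma_ytb",
            "sigma_kvp",
            "sigma_d",
            "sigma_fid",
            "sigma_mu_en",
        ):
            if getattr(self, name) < 0:
                raise DosimetryError(f"{name} must be non-negative")
        if self.alpha_beta_cov is not None:
            # |rho| <= 1 given the marginal sigmas
            bound = self.sigma_alpha * self.sigma_beta
            if abs(self.alpha_beta_cov) > bound * (1 + 1e-9):
                raise DosimetryError(
                    "alpha-beta covariance inconsistent with marginal sigmas"
                )

    def sigma(self, name: str) -> float:
        return getattr(self, f"sigma_{name}")

    @classmethod
    def from_sources(
        cls,
        cal: TubeCalibration,
        device: DeviceProfile,
        exam: ExamRecord,
        mu_en_sigma: float | None = None,
    ) -> "UncertaintyBudget":
        """Default budget: fit sigmas from the calibration, yield sigma
        from the device registry, thickness sigma from the exam record
        (0.5 cm unless overridden); kVp and FID exact."""
        _, ytb_sigma = device.yield_for(exam.combination)
        return cls(
            sigma_alpha=cal.alpha_sigma,
            sigma_beta=cal.beta_sigma,
            sigma_y0=cal.y0_sigma,
            sigma_ytb=ytb_sigma,
            sigma_kvp=0.0,
            sigma_d=exam.thickness_sigma_cm,
            sigma_fid=0.0,
            sigma_mu_en=cal.mu_en_sigma if mu_en_sigma is None else mu_en_sigma,
        )

    def to_dict(self) -> dict:
        out = {f"sigma_{name}": self.sigma(name) for name in BUDGET_INPUTS}
        if self.alpha_beta_cov is not None:
            out["alpha_beta_cov"] = self.alpha_beta_cov
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "UncertaintyBudget":
        kwargs = {k: float(v) for k, v in data.items() if k.startswith("sigma_")}
        if "alpha_beta_cov" in data and data["alpha_beta_cov"] is not None:
            kwargs["alpha_beta_cov"] = float(data["alpha_beta_cov"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PropagationResult:
    """Absolute and relative 1-sigma on 2ABD, plus the kerma-only sigma
    and the per-input absolute contributions (quadrature summands)."""

    sigma_abs: float
    sigma_rel: float
    kerma_sigma_abs: float
    contributions: dict[str, float]


def _dlnf_du(u: float) -> float:
    """d/du of log((1 - e^-u)/u) = 1/(e^u - 1) - 1/u."""
    if u < 1e-4:
        # Laurent series; error < u^3/720
        return -0.5 + u / 12.0
    return 1.0 / math.expm1(u) - 1.0 / u


def _partials(
    alpha: float,
    beta: float,
    y0: float,
    ytb: float,
    kvp: float,
    mas: float,
    d: float,
    fid: float,
    mu_en: float,
) -> tuple[float, float, dict[str, float], dict[str, float]]:
    """Return (dose, kerma, dose partials, kerma partials) per input."""
    line = alpha * kvp + beta
    if line <= 0:
        raise DosimetryError(f"non-positive kerma line value {line:.4g}")
    kerma = (ytb / y0) * line * mas * inverse_square_factor(fid, d)
    factor = attenuation_integral_factor(mu_en, d)
    dose = kerma * factor

    u = mu_en * d
    dlnf = _dlnf_du(u)
    # log-derivatives of the kerma w.r.t. each input
    k_log = {
        "alpha": kvp / line,
        "beta": 1.0 / line,
        "y0": -1.0 / y0,
        "ytb": 1.0 / ytb,
        "kvp": alpha / line,
        "d": 2.0 / (fid - d),
        "fid": 2.0 / fid - 2.0 / (fid - d),
        "mu_en": 0.0,
    }
    d_log = dict(k_log)
    d_log["mu_en"] = d * dlnf
    d_log["d"] = k_log["d"] + mu_en * dlnf

    dose_partials = {name: dose * d_log[name] for name in BUDGET_INPUTS}
    kerma_partials = {name: kerma * k_log[name] for name in BUDGET_INPUTS}
    return dose, kerma, dose_partials, kerma_partials


def _inputs_from(
    cal: TubeCalibration,
    device: DeviceProfile,
    exam: ExamRecord,
    mu_en: float | None,
) -> dict[str, float]:
    ytb, _ = device.yield_for(exam.combination)
    return {
        "alpha": cal.alpha,
        "beta": cal.beta,
        "y0": cal.y0,
        "ytb": ytb,
        "kvp": exam.kvp,
        "mas": exam.mas,
        "d": exam.thickness_cm,
        "fid": device.fid_cm,
        "mu_en": cal.mu_en if mu_en is None else mu_en,
    }


def propagate_2abd(
    cal: TubeCalibration,
    device: DeviceProfile,
    exam: ExamRecord,
    budget: UncertaintyBudget | None = None,
    mu_en: float | None = None,
) -> PropagationResult:
    """Delta-method 1-sigma of 2ABD from analytic partial derivatives.

    ``mu_en`` overrides the calibration-average coefficient (used by the
    per-kVp mode).  With ``budget`` omitted the default budget of the
    calibration, device and exam is used.
    """
    if budget is None:
        budget = UncertaintyBudget.from_sources(cal, device, exam)
    x = _inputs_from(cal, device, exam, mu_en)
    dose, kerma, dp, kp = _partials(**x)

    var = 0.0
    kvar = 0.0
    contributions = {}
    for name in BUDGET_INPUTS:
        contrib = dp[name] * budget.sigma(name)
        contributions[name] = abs(contrib)
        var += contrib * contrib
        kc = kp[name] * budget.sigma(name)
        kvar += kc * kc
    if budget.alpha_beta_cov is not None:
        var += 2.0 * dp["alpha"] * dp["beta"] * budget.alpha_beta_cov
        kvar += 2.0 * kp["alpha"] * kp["beta"] * budget.alpha_beta_cov
    sigma = math.sqrt(max(var, 0.0))
    return PropagationResult(
        sigma_abs=sigma,
        sigma_rel=sigma / dose,
        kerma_sigma_abs=math.sqrt(max(kvar, 0.0)),
        contributions=contributions,
    )


def finite_difference_check(
    cal: TubeCalibration,
    device: DeviceProfile,
    exam: ExamRecord,
    budget: UncertaintyBudget | None = None,
    mu_en: float | None = None,
    rel_step: float = 1e-5,
) -> float:
    """Rebuild sigma(2ABD) with central finite differences and return the
    relative discrepancy against the analytic result.

    Verification oracle for the analytic partials: each partial is
    replaced by ``(D(x+h) - D(x-h)) / 2h`` with ``h`` a 1e-5 relative
    step, and the quadrature sum is recomputed.  Returns 0 when both
    sigmas vanish.
    """
    if budget is None:
        budget = UncertaintyBudget.from_sources(cal, device, exam)
    x = _inputs_from(cal, device, exam, mu_en)
    analytic = propagate_2abd(cal, device, exam, budget, mu_en=mu_en)

    def value(**overrides: float) -> float:
        xs = dict(x)
        xs.update(overrides)
        return two_abd_value(**xs)

    var = 0.0
    partials = {}
    for name in BUDGET_INPUTS:
        h = rel_step * max(abs(x[name]), 1e-3)
        partial = (value(**{name: x[name] + h}) - value(**{name: x[name] - h})) / (2 * h)
        partials[name] = partial
        contrib = partial * budget.sigma(name)
        var += contrib * contrib
    if budget.alpha_beta_cov is not None:
        var += 2.0 * partials["alpha"] * partials["beta"] * budget.alpha_beta_cov
    sigma_fd = math.sqrt(max(var, 0.0))
    if analytic.sigma_abs == 0.0 and sigma_fd == 0.0:
        return 0.0
    return abs(sigma_fd - analytic.sigma_abs) / max(analytic.sigma_abs, sigma_fd)


def agd_sigma(agd_value: float) -> float:
    """Flat 20% 1-sigma attached to conversion-factor AGD estimates."""
    if agd_value < 0:
        raise DosimetryError("AGD must be non-negative")
    return AGD_RELATIVE_SIGMA * agd_value
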