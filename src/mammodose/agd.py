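"""Reference-standard average glandular dose (AGD) from conversion
factors, for comparison against 2ABD.

Two formalisms are supported, both multiplying the incident air kerma by
tabulated Monte-Carlo conversion factors indexed on beam quality (HVL,
mm Al) and compressed breast thickness (cm):

* Dance: ``AGD = k_ai * g * c * s`` — ``g`` converts kerma to AGD for a
  50%-glandular standard breast, ``c`` corrects for breast composition
  (age- or glandularity-stratified, values within [0.885, 1.306]), ``s``
  is a flat per-spectrum factor;
* Wu: ``AGD = k_ai * D_gN`` with the normalised average glandular dose.

The published factor grids are third-party data and are NOT bundled:
this module supplies the grid container, CSV format and bilinear
interpolation contract, and the tests exercise it on synthetic tables.
AGD uncertainties use the flat 20% rule (see :mod:`mammodose.uncertainty`).
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dosimetry import (
    AnodeFilterCombination,
    ConfigurationError,
    DosimetryError,
    KermaResult,
    MammodoseWarning,
)
from .uncertainty import agd_sigma

DANCE_C_RANGE = (0.885, 1.306)

#: c-table age strata of the Dance formalism.
AGE_STRATA = ("40-49", "50-64")


class TableLookupError(ConfigurationError):
    """Coefficient lookup outside the tabulated grid."""


class ClampWarning(MammodoseWarning):
    """Out-of-grid coefficient query clamped to the table boundary."""


@dataclass
class CoefficientTable:
    """Rectangular (HVL x thickness) conversion-factor grid.

    ``values[i, j]`` is the factor at ``hvl_grid[i]`` mm Al and
    ``thickness_grid[j]`` cm.  Interpolation between nodes is bilinear
    and exact at the nodes; queries outside the grid either raise or,
    with ``clamp=True``, are clamped to the boundary with a warning.
    """

    name: str
    hvl_grid: np.ndarray
    thickness_grid: np.ndarray
    values: np.ndarray
    stratum: str | None = None
    combination: AnodeFilterCombination | None = None
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.hvl_grid = np.asarray(self.hvl_grid, dtype=float)
        self.thickness_grid = np.asarray(self.thickness_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for grid, label in ((self.hvl_grid, "HVL"), (self.thickness_grid, "thickness")):
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise ConfigurationError(
                    f"{label} grid must be 1-D, length >= 2, strictly increasing"
                )
        if self.values.shape != (len(self.hvl_grid), len(self.thickness_grid)):
            raise ConfigurationError(
                "coefficient matrix shape does not match the grids"
            )
        if np.any(self.values <= 0):
            raise ConfigurationError("coefficients must be positive")
        if self.name == "dance_c":
            lo, hi = DANCE_C_RANGE
            if np.any(self.values < lo) or np.any(self.values > hi):
                raise ConfigurationError(
                    f"dance_c values must lie within [{lo}, {hi}]"
                )
        self._interp = RegularGridInterpolator(
            (self.hvl_grid, self.thickness_grid), self.values, method="linear"
        )

    def interpolate(self, hvl: float, thickness: float, clamp: bool = False) -> float:
        """Bilinear coefficient at (``hvl`` mm Al, ``thickness`` cm)."""
        h, t = float(hvl), float(thickness)
        h_lo, h_hi = self.hvl_grid[0], self.hvl_grid[-1]
        t_lo, t_hi = self.thickness_grid[0], self.thickness_grid[-1]
        outside = not (h_lo <= h <= h_hi and t_lo <= t <= t_hi)
        if outside:
            if not clamp:
                raise TableLookupError(
                    f"query (HVL={h}, d={t}) outside {self.name} grid "
                    f"[{h_lo}, {h_hi}] x [{t_lo}, {t_hi}]"
                )
            _warnings.warn(
                f"{self.name}: query (HVL={h}, d={t}) clamped to grid boundary",
                ClampWarning,
                stacklevel=2,
            )
            h = min(max(h, h_lo), h_hi)
            t = min(max(t, t_lo), t_hi)
        return float(self._interp((h, t)))

    # -- CSV grid format: first row = thickness grid (cm), first column =
    #    HVL grid (mm Al), body = coefficients; sidecar JSON declares
    #    name / stratum / combination. ---------------------------------

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        frame = pd.DataFrame(
            self.values, index=self.hvl_grid, columns=self.thickness_grid
        )
        frame.index.name = "hvl_mmal"
        frame.to_csv(path)
        if sidecar:
            meta = {
                "name": self.name,
                "stratum": self.stratum,
                "combination": self.combination.canonical if self.combination else None,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=1) + "\n"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        combo = meta.get("combination")
        return cls(
            name=meta.get("name", path.stem),
            hvl_grid=frame.index.to_numpy(dtype=float),
            thickness_grid=np.array([float(c) for c in frame.columns]),
            values=frame.to_numpy(dtype=float),
            stratum=meta.get("stratum"),
            combination=AnodeFilterCombination.from_string(combo) if combo else None,
        )


@dataclass(frozen=True)
class SFactorMap:
    """Flat spectrum factor ``s`` per anode-filter combination."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.factors.values()):
            raise ConfigurationError("all s factors must be positive")

    def for_combination(self, combination: AnodeFilterCombination) -> float:
        key = combination.canonical
        if key not in self.factors:
            raise ConfigurationError(f"no s factor for {key}")
        return self.factors[key]

    @classmethod
    def from_json(cls, path: str | Path) -> "SFactorMap":
        data = json.loads(Path(path).read_text())
        return cls({k: float(v) for k, v in data.items()})


def interpolate_coefficient(
    table: CoefficientTable, hvl: float, thickness: float, clamp: bool = False
) -> float:
    """Functional form of :meth:`CoefficientTable.interpolate`."""
    return table.interpolate(hvl, thickness, clamp=clamp)


def _kerma_value(k_ai: KermaResult | float) -> float:
    return k_ai.k_ai if isinstance(k_ai, KermaResult) else float(k_ai)


def dance_agd(
    k_ai: KermaResult | float, g: float, c: float, s: float
) -> tuple[float, float]:
    """AGD = k_ai * g * c * s with its flat 20% 1-sigma."""
    if g <= 0 or c <= 0 or s <= 0:
        raise DosimetryError("Dance factors g, c, s must all be positive")
    agd = _kerma_value(k_ai) * g * c * s
    return agd, agd_sigma(agd)


def wu_agd(k_ai: KermaResult | float, dgn: float) -> tuple[float, float]:
    """AGD = k_ai * D_gN with its flat 20% 1-sigma."""
    if dgn <= 0:
        raise DosimetryError("D_gN must be positive")
    agd = _kerma_value(k_ai) * dgn
    return agd, agd_sigma(agd)


def select_c_stratum(
    age_years: float | None = None,
    glandularity_pct: float | None = None,
    glandularity_bins: Mapping[str, tuple[float, float]] | None = None,
) -> str:
    """Pick the c-table stratum for a patient.

    Explicit glandularity together with a glandularity-binned table
    overrides age.  Ages inside 40-49 or 50-64 map directly; ages
    outside both ranges map to the nearest group with a warning.
    """
    if glandularity_pct is not None and glandularity_bins:
        for label, (lo, hi) in glandularity_bins.items():
            if lo <= glandularity_pct <= hi:
                return label
        raise ConfigurationError(
            f"glandularity {glandularity_pct}% falls in no declared bin"
        )
    if age_years is None:
        raise ConfigurationError(
            "stratified c table needs patient age or glandularity"
        )
    if 40 <= age_years <= 49:
        return AGE_STRATA[0]
    if 50 <= age_years <= 64:
        return AGE_STRATA[1]
    nearest = AGE_STRATA[0] if age_years < 49.5 else AGE_STRATA[1]
    _warnings.warn(
        f"age {age_years} outside the tabulated ranges 40-49/50-64; "
        f"using nearest group {nearest}",
        MammodoseWarning,
        stacklevel=2,
    )
    return nearest
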