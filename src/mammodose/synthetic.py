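"""Seeded generators for every input the toolkit consumes.

Emulates the measurement designs behind the calibration procedures —
kerma measured over kVp 22-34 and mAs 10-100 with five replicates per
setting, transmission measured under 0-5.5 cm of solid water — plus
clinical exam cohorts with parameters in the ranges seen in practice
(kVp 25-30, mAs 18-114, thickness 2-7 cm, the five standard
anode-filter combinations), and minimal header-only DICOM fixtures.

Default noise is multiplicative Gaussian with a 1% sigma, the
repeatability scale of solid-state mammography dosimeters.  Every
generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .calibration import AttenuationPoint, KermaCalibrationPoint
from .dosimetry import (
    AnodeFilterCombination,
    DeviceProfile,
    DosimetryError,
    ExamRecord,
)

#: Digital Mammography X-Ray Image Storage (for presentation)
_MAMMO_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.1.2"

_DICOM_MATERIAL = {"Mo": "MOLYBDENUM", "Rh": "RHODIUM", "W": "TUNGSTEN", "Ag": "SILVER"}

#: typical measured HVL (mm Al) per combination, used by the cohort generator
_TYPICAL_HVL = {"Mo-Mo": 0.30, "Mo-Rh": 0.43, "Rh-Rh": 0.47, "W-Rh": 0.54, "W-Ag": 0.62}

#: reference-tube beam intensity I0 (mGy at 40 mAs) per combination and
#: kVp — the generating truth for simulated transmission series
REFERENCE_I0 = {
    "Mo-Mo": {22: 1.45, 24: 2.05, 26: 2.77, 28: 3.55, 30: 4.41},
    "Mo-Rh": {24: 1.59, 26: 2.22, 28: 2.88, 30: 3.62, 32: 4.39},
    "Rh-Rh": {26: 2.08, 28: 2.69, 30: 3.39, 32: 4.1, 34: 4.9},
    "W-Rh": {26: 1.02, 28: 1.25, 30: 1.46, 32: 1.68, 34: 1.90},
    "W-Ag": {26: 1.25, 28: 1.59, 30: 1.90, 32: 2.21, 34: 2.52},
}

DEFAULT_KVP_GRID = tuple(float(k) for k in range(22, 35))
DEFAULT_MAS_GRID = (10.0, 40.0, 100.0)
DEFAULT_DEPTH_GRID = tuple(0.5 * i for i in range(12))  # 0.0 .. 5.5 cm


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed and noise model shared by all generators.

    ``noise_model``: ``"none"``, ``"gaussian_relative"`` (sigma as a
    fraction of the true value) or ``"gaussian_absolute"`` (sigma in the
    measurement unit).
    """

    seed: int = 0
    noise_model: str = "gaussian_relative"
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian_relative", "gaussian_absolute"):
            raise DosimetryError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise DosimetryError("noise sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy(rng: np.random.Generator, spec: GeneratorSpec, true_value: float) -> float:
    """One noisy measurement; redrawn (up to 100 times) to stay positive."""
    if spec.noise_model == "none" or spec.noise_sigma == 0.0:
        return true_value
    scale = (
        spec.noise_sigma * true_value
        if spec.noise_model == "gaussian_relative"
        else spec.noise_sigma
    )
    for _ in range(100):
        value = true_value + rng.normal(0.0, scale)
        if value > 0:
            return value
    raise DosimetryError("noise model cannot produce a positive measurement")


def generate_kerma_calibration(
    alpha: float,
    beta: float,
    spec: GeneratorSpec | None = None,
    kvp_values: Sequence[float] = DEFAULT_KVP_GRID,
    mas_values: Sequence[float] = DEFAULT_MAS_GRID,
    replicates: int = 5,
) -> list[KermaCalibrationPoint]:
    """Kerma measurements at zero phantom thickness from a linear truth.

    ``kerma = (alpha*kVp + beta) * mAs`` plus noise; raises if the line
    is non-positive anywhere on the design grid.
    """
    spec = spec or GeneratorSpec()
    rng = spec.rng()
    points = []
    for kvp in kvp_values:
        line = alpha * kvp + beta
        if line <= 0:
            raise DosimetryError(
                f"kerma line non-positive at {kvp} kVp (value {line:.4g}); "
                "design grid extends below the line's root"
            )
        for mas in mas_values:
            for rep in range(replicates):
                points.append(
                    KermaCalibrationPoint(
                        kvp=float(kvp),
                        mas=float(mas),
                        kerma=_noisy(rng, spec, line * mas),
                        replicate_id=rep,
                    )
                )
    return points


def generate_attenuation_series(
    i0: float,
    mu_en: float,
    spec: GeneratorSpec | None = None,
    depths: Sequence[float] = DEFAULT_DEPTH_GRID,
    replicates: int = 1,
) -> list[AttenuationPoint]:
    """Transmission series ``I = I0 * exp(-mu_en * x)`` plus noise."""
    if i0 <= 0 or mu_en < 0:
        raise DosimetryError("I0 must be positive and mu_en non-negative")
    if any(x < 0 for x in depths):
        raise DosimetryError("depths must be non-negative")
    spec = spec or GeneratorSpec()
    rng = spec.rng()
    points = []
    for x in depths:
        truth = i0 * float(np.exp(-mu_en * x))
        for rep in range(replicates):
            points.append(
                AttenuationPoint(
                    depth_cm=float(x),
                    intensity=_noisy(rng, spec, truth),
                    replicate_id=rep,
                )
            )
    return points


def generate_exam_cohort(
    n: int,
    registry: Mapping[str, DeviceProfile],
    spec: GeneratorSpec | None = None,
    kvp_range: tuple[int, int] = (25, 30),
    mas_range: tuple[int, int] = (18, 114),
    thickness_range_cm: tuple[float, float] = (2.0, 7.0),
) -> list[ExamRecord]:
    """Sample ``n`` clinical exposures across the registry's devices.

    Combinations are drawn from those with a registered yield; kVp and
    mAs are integers (as set on real units), thickness is rounded to
    millimetres, ages span the screening range 40-64, and HVL is the
    combination-typical value with a small jitter.
    """
    if n < 1:
        raise DosimetryError("cohort size must be >= 1")
    if not registry:
        raise DosimetryError("empty device registry")
    spec = spec or GeneratorSpec()
    rng = spec.rng()
    choices = [
        (device_id, combo)
        for device_id, device in sorted(registry.items())
        for combo in sorted(device.yields)
    ]
    records = []
    for i in range(n):
        device_id, combo = choices[int(rng.integers(len(choices)))]
        device = registry[device_id]
        d_hi = min(thickness_range_cm[1], device.fid_cm - 1.0)
        thickness = round(float(rng.uniform(thickness_range_cm[0], d_hi)), 1)
        hvl = _TYPICAL_HVL.get(combo, 0.45) + round(float(rng.uniform(-0.02, 0.02)), 3)
        records.append(
            ExamRecord(
                exam_id=f"exam-{i + 1:04d}",
                combination=AnodeFilterCombination.from_string(combo),
                kvp=float(rng.integers(kvp_range[0], kvp_range[1] + 1)),
                mas=float(rng.integers(mas_range[0], mas_range[1] + 1)),
                thickness_cm=thickness,
                device_id=device_id,
                age_years=float(rng.integers(40, 65)),
                glandularity_pct=float(rng.integers(10, 101)),
                hvl_mmal=round(hvl, 3),
            )
        )
    return records


def write_dicom_fixture(
    record: ExamRecord,
    path: str | Path,
    spec: GeneratorSpec | None = None,
    station_name: str | None = None,
) -> Path:
    """Write a minimal header-only Part-10 DICOM file for one exam.

    Synthetic fixture: carries exactly the acquisition attributes the
    header reader consumes (no pixel data).  UIDs are derived
    deterministically from the exam id and seed.
    """
    spec = spec or GeneratorSpec()
    path = Path(path)
    uid = generate_uid(entropy_srcs=[record.exam_id, str(spec.seed)])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _MAMMO_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _MAMMO_SOP_CLASS
    ds.SOPInstanceUID = uid
    ds.Modality = "MG"
    ds.PatientID = record.exam_id
    ds.PatientName = record.exam_id
    if record.age_years is not None:
        ds.PatientAge = f"{int(record.age_years):03d}Y"
    # StationName is VR SH (16 chars max); long device ids go in the
    # model name, which the header reader also matches against
    label = station_name or record.device_id
    ds.StationName = label[:16]
    ds.ManufacturerModelName = label
    ds.KVP = str(record.kvp)
    ds.Exposure = str(int(round(record.mas)))
    ds.ExposureInuAs = str(int(round(record.mas * 1000)))
    ds.AnodeTargetMaterial = _DICOM_MATERIAL.get(
        record.combination.anode, record.combination.anode.upper()
    )
    ds.FilterMaterial = _DICOM_MATERIAL.get(
        record.combination.filter, record.combination.filter.upper()
    )
    ds.BodyPartThickness = str(round(record.thickness_cm * 10.0, 6))
    ds.save_as(path, enforce_file_format=True)
    return path


def write_dicom_cohort(
    records: Iterable[ExamRecord],
    directory: str | Path,
    spec: GeneratorSpec | None = None,
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_dicom_fixture(record, directory / f"{record.exam_id}.dcm", spec)
        for record in records
    ]


def synthetic_coefficient_table(
    name: str = "wu_dgn",
    hvl_grid: Sequence[float] = (0.30, 0.40, 0.50, 0.60),
    thickness_grid: Sequence[float] = (2.0, 4.0, 6.0, 8.0),
    fn=None,
    stratum: str | None = None,
    combination: str | None = None,
):
    """Small synthetic conversion-factor grid for tests and examples.

    ``fn(hvl, thickness)`` supplies node values (default: a smooth
    positive surface roughly shaped like published factor tables).
    Labelled synthetic: it stands in for third-party literature grids
    that are not redistributed.
    """
    from .agd import CoefficientTable

    if fn is None:
        fn = lambda h, t: 0.6 * h / (0.1 + 0.05 * t) * 0.25 + 0.1  # noqa: E731
    h = np.asarray(hvl_grid, dtype=float)
    t = np.asarray(thickness_grid, dtype=float)
    values = np.array([[float(fn(hi, tj)) for tj in t] for hi in h])
    return CoefficientTable(
        name=name,
        hvl_grid=h,
        thickness_grid=t,
        values=values,
        stratum=stratum,
        combination=(
            AnodeFilterCombination.from_string(combination) if combination else None
        ),
    )
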