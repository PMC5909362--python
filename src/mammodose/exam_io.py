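"""Build exam records from DICOM headers or CSV batches.

Every acquisition parameter the dose model needs is written by the
mammography unit into the image header: tube voltage (0018,0060),
exposure (0018,1152) or exposure-in-uAs (0018,1153), anode target
material (0018,1191), filter material (0018,7050) and compressed breast
thickness (0018,11A0).  This module normalises them to package units
(mm -> cm, uAs -> mAs), maps vendor material spellings to element
symbols and resolves the device against a registry, recording the
provenance of every field.

FID is never taken from headers: the stored source-to-detector distance
need not coincide with the calibrated FID definition, so it is only
cross-checked against the registry with a warning on mismatch.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pydicom

from .dosimetry import (
    AnodeFilterCombination,
    DEFAULT_THICKNESS_SIGMA_CM,
    DeviceProfile,
    DosimetryError,
    ExamRecord,
    MammodoseWarning,
    UnknownCombinationWarning,
)

#: keyword -> (tag string, mandatory)
DICOM_FIELDS = {
    "KVP": ("(0018,0060)", True),
    "Exposure": ("(0018,1152)", False),
    "ExposureInuAs": ("(0018,1153)", False),
    "AnodeTargetMaterial": ("(0018,1191)", True),
    "FilterMaterial": ("(0018,7050)", True),
    "BodyPartThickness": ("(0018,11A0)", True),
    "DistanceSourceToDetector": ("(0018,1110)", False),
    "StationName": ("(0008,1010)", False),
    "ManufacturerModelName": ("(0008,1090)", False),
    "PatientAge": ("(0010,1010)", False),
}

CSV_REQUIRED_COLUMNS = (
    "exam_id",
    "combination",
    "kvp",
    "mas",
    "thickness_cm",
    "device_id",
)
CSV_OPTIONAL_COLUMNS = (
    "thickness_sigma_cm",
    "age_years",
    "glandularity_pct",
    "hvl_mmal",
)

#: tolerated relative disagreement between (0018,1152) and (0018,1153)/1000
MAS_CONSISTENCY_TOL = 0.01


class ExtractionError(DosimetryError):
    """Mandatory acquisition fields missing or unusable."""


class ExtractionWarning(MammodoseWarning):
    """Non-fatal header anomaly (missing optional field, inconsistency)."""


@dataclass
class HeaderExtraction:
    """Raw extracted values with per-field provenance and warnings."""

    values: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        _warnings.warn(message, ExtractionWarning, stacklevel=3)


def map_anode_filter(anode_text: str, filter_text: str) -> AnodeFilterCombination:
    """Normalise vendor material spellings to a canonical combination.

    ``MOLYBDENUM/Mo``, ``RHODIUM/Rh``, ``TUNGSTEN/W`` and ``SILVER/Ag``
    (case-insensitive) map to element symbols; other materials stay
    representable but raise an :class:`UnknownCombinationWarning` since
    no bundled calibration exists for them.
    """
    if not anode_text or not anode_text.strip():
        raise ExtractionError("empty anode material")
    if not filter_text or not filter_text.strip():
        raise ExtractionError("empty filter material")
    combo = AnodeFilterCombination(anode_text, filter_text)
    if not combo.is_supported:
        _warnings.warn(
            f"anode-filter combination {combo.canonical} has no bundled "
            "calibration",
            UnknownCombinationWarning,
            stacklevel=2,
        )
    return combo


def _parse_age(text: str) -> float | None:
    """DICOM AS value '061Y' -> 61.0 (months/weeks/days scaled)."""
    text = str(text).strip()
    if not text:
        return None
    unit = text[-1].upper()
    try:
        number = float(text[:-1] if unit in "YMWD" else text)
    except ValueError:
        return None
    scale = {"Y": 1.0, "M": 1 / 12.0, "W": 1 / 52.0, "D": 1 / 365.25}.get(unit, 1.0)
    return number * scale


def read_exam_dicom(
    path: str | Path,
    registry: Mapping[str, DeviceProfile] | None = None,
    exam_id: str | None = None,
) -> tuple[ExamRecord, HeaderExtraction]:
    """Read one exposure's acquisition parameters from a DICOM header.

    Pixel data are never loaded.  mAs is taken from (0018,1152),
    falling back to (0018,1153)/1000; when both are present and disagree
    by more than 1% a warning is recorded.  Thickness is converted
    mm -> cm, with the manual-quoted 0.5 cm sigma attached.  The device
    is resolved by station name or model against ``registry``.

    Returns the exam record and the extraction report (values,
    provenance, warnings).  Missing mandatory attributes raise an
    :class:`ExtractionError` naming the absent tags.
    """
    path = Path(path)
    ds = pydicom.dcmread(path, stop_before_pixels=True)
    report = HeaderExtraction()

    missing = []
    for keyword, (tag, mandatory) in DICOM_FIELDS.items():
        value = ds.get(keyword)
        if value is not None and str(value) != "":
            report.values[keyword] = value
            report.provenance[keyword] = "dicom_tag"
        elif mandatory:
            missing.append(f"{tag} {keyword}")

    exposure = report.values.get("Exposure")
    exposure_uas = report.values.get("ExposureInuAs")
    if exposure is None and exposure_uas is None:
        missing.append("(0018,1152) Exposure / (0018,1153) ExposureInuAs")
    if missing:
        raise ExtractionError(
            f"{path.name}: missing mandatory DICOM attributes: " + "; ".join(missing)
        )

    if exposure is not None:
        mas = float(exposure)
        report.provenance["mas"] = "dicom_tag:(0018,1152)"
        if exposure_uas is not None:
            alt = float(exposure_uas) / 1000.0
            if alt > 0 and not math.isclose(mas, alt, rel_tol=MAS_CONSISTENCY_TOL):
                report.warn(
                    f"{path.name}: (0018,1152)={mas} mAs disagrees with "
                    f"(0018,1153)/1000={alt} mAs"
                )
    else:
        mas = float(exposure_uas) / 1000.0
        report.provenance["mas"] = "dicom_tag:(0018,1153)"

    combo = map_anode_filter(
        str(report.values["AnodeTargetMaterial"]),
        str(report.values["FilterMaterial"]),
    )
    thickness_cm = float(report.values["BodyPartThickness"]) / 10.0
    report.provenance["thickness_sigma_cm"] = "default"

    device_id, device = _resolve_device(report, registry, path.name)
    if device is not None and "DistanceSourceToDetector" in report.values:
        sdd_cm = float(report.values["DistanceSourceToDetector"]) / 10.0
        if abs(sdd_cm - device.fid_cm) > 1.0:
            report.warn(
                f"{path.name}: header source-to-detector distance "
                f"{sdd_cm:.1f} cm differs from registry FID {device.fid_cm:.1f} cm"
            )

    age = None
    if "PatientAge" in report.values:
        age = _parse_age(report.values["PatientAge"])

    record = ExamRecord(
        exam_id=exam_id or path.stem,
        combination=combo,
        kvp=float(report.values["KVP"]),
        mas=mas,
        thickness_cm=thickness_cm,
        thickness_sigma_cm=DEFAULT_THICKNESS_SIGMA_CM,
        device_id=device_id,
        age_years=age,
    )
    return record, report


def _resolve_device(
    report: HeaderExtraction,
    registry: Mapping[str, DeviceProfile] | None,
    source: str,
) -> tuple[str, DeviceProfile | None]:
    candidates = [
        str(report.values.get(k, "")).strip()
        for k in ("StationName", "ManufacturerModelName")
    ]
    candidates = [c for c in candidates if c]
    if registry:
        lowered = {k.lower(): k for k in registry}
        for candidate in candidates:
            key = lowered.get(candidate.lower())
            if key is not None:
                report.provenance["device_id"] = "registry"
                return key, registry[key]
        report.warn(
            f"{source}: no registry device matches station/model "
            f"{candidates or ['<absent>']}"
        )
    device_id = candidates[0] if candidates else "unknown"
    report.provenance["device_id"] = "dicom_tag" if candidates else "default"
    return device_id, None


class RowError(DosimetryError):
    """A CSV exam row failed validation; names the line and column."""


def read_exam_csv(
    path: str | Path,
    registry: Mapping[str, DeviceProfile] | None = None,
) -> list[ExamRecord]:
    """Read an exam batch CSV (one exposure per row, units cm/mGy).

    Required columns: exam_id, combination, kvp, mas, thickness_cm,
    device_id; optional: thickness_sigma_cm, age_years,
    glandularity_pct, hvl_mmal.  Row failures raise :class:`RowError`
    with the 1-based file line number and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ExtractionError(
            f"{path.name}: missing required columns: {', '.join(missing)}"
        )
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        records.append(_record_from_row(row, line, path.name))
    if registry is not None:
        for record in records:
            if record.device_id not in registry:
                _warnings.warn(
                    f"{path.name}: exam {record.exam_id} references unknown "
                    f"device {record.device_id!r}",
                    ExtractionWarning,
                    stacklevel=2,
                )
    return records


def _record_from_row(row: pd.Series, line: int, source: str) -> ExamRecord:
    def number(column: str, optional: bool = False) -> float | None:
        raw = row.get(column)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw) == "":
            if optional:
                return None
            raise RowError(f"{source} line {line}: missing value in {column!r}")
        try:
            return float(raw)
        except ValueError:
            raise RowError(
                f"{source} line {line}: unparseable number {raw!r} in {column!r}"
            ) from None

    try:
        combo = AnodeFilterCombination.from_string(str(row["combination"]))
        sigma = number("thickness_sigma_cm", optional=True)
        return ExamRecord(
            exam_id=str(row["exam_id"]),
            combination=combo,
            kvp=number("kvp"),
            mas=number("mas"),
            thickness_cm=number("thickness_cm"),
            thickness_sigma_cm=DEFAULT_THICKNESS_SIGMA_CM if sigma is None else sigma,
            device_id=str(row["device_id"]),
            age_years=number("age_years", optional=True),
            glandularity_pct=number("glandularity_pct", optional=True),
            hvl_mmal=number("hvl_mmal", optional=True),
        )
    except RowError:
        raise
    except DosimetryError as exc:
        raise RowError(f"{source} line {line}: {exc}") from exc


def write_exam_csv(records: Iterable[ExamRecord], path: str | Path) -> None:
    """Write exams in the canonical batch CSV schema (round-trips with
    :func:`read_exam_csv`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "exam_id": r.exam_id,
                "combination": r.combination.canonical,
                "kvp": r.kvp,
                "mas": r.mas,
                "thickness_cm": r.thickness_cm,
                "device_id": r.device_id,
                "thickness_sigma_cm": r.thickness_sigma_cm,
                "age_years": r.age_years,
                "glandularity_pct": r.glandularity_pct,
                "hvl_mmal": r.hvl_mmal,
            }
        )
    columns = list(CSV_REQUIRED_COLUMNS) + list(CSV_OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
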