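"""Bundled reference constants and registry/config file loading.

The package ships the measured physics constants of the two reference
units (kerma-line parameters, reference yields and energy-absorption
coefficients for the five standard anode-filter combinations) plus a
matching device registry and the default uncertainty budget.  User
files in the same JSON/YAML formats override them on the command line.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .dosimetry import (
    AnodeFilterCombination,
    ConfigurationError,
    DeviceProfile,
    TubeCalibration,
)


def _data_text(name: str) -> str:
    return resources.files("mammodose").joinpath("data", name).read_text()


def load_calibrations(path: str | Path | None = None) -> dict[str, TubeCalibration]:
    """Load tube calibrations keyed by canonical combination.

    ``path`` may point to a user JSON file (a list of calibration
    objects); with ``None`` the bundled reference constants are used.
    """
    text = Path(path).read_text() if path is not None else _data_text("tube_calibrations.json")
    entries = json.loads(text)
    if not isinstance(entries, list):
        entries = [entries]
    cals = {}
    for entry in entries:
        cal = TubeCalibration.from_dict(entry)
        cals[cal.combination.canonical] = cal
    return cals


def calibration_for(
    combination: AnodeFilterCombination | str,
    calibrations: Mapping[str, TubeCalibration] | None = None,
) -> TubeCalibration:
    if isinstance(combination, str):
        combination = AnodeFilterCombination.from_string(combination)
    calibrations = calibrations or load_calibrations()
    try:
        return calibrations[combination.canonical]
    except KeyError:
        raise ConfigurationError(
            f"no calibration for combination {combination.canonical}"
        ) from None


def load_registry(path: str | Path | None = None) -> dict[str, DeviceProfile]:
    """Load the device registry (YAML or JSON): device_id ->
    {FID_cm, yields: {combo: {Y, sigma}}}."""
    if path is None:
        data = json.loads(_data_text("device_registry.json"))
    else:
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix.lower() in (".yml", ".yaml")
            else json.loads(text)
        )
    if not isinstance(data, dict):
        raise ConfigurationError("device registry must map device ids to profiles")
    return {
        device_id: DeviceProfile.from_dict(device_id, entry)
        for device_id, entry in data.items()
    }


def load_default_budget_config() -> dict:
    """Fixed sigmas of the bundled default budget (thickness, FID, kVp)."""
    return json.loads(_data_text("default_budget.json"))


def save_calibrations(
    calibrations: Mapping[str, TubeCalibration], path: str | Path
) -> None:
    payload = [calibrations[key].to_dict() for key in sorted(calibrations)]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
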