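import pytest

import mammodose as md

#: Clinical exposures on the GE reference unit (FID 63.5 cm, Y_tb = Y_0):
#: (exam_id, combination, thickness cm, kVp, mAs, HVL mm Al, age, reported 2ABD mGy)
REFERENCE_COHORT = [
    ("p1", "Mo-Mo", 2.0, 25, 32, 0.30, 61, 1.0),
    ("p2", "Mo-Mo", 3.0, 26, 36, 0.30, 55, 1.0),
    ("p3", "Mo-Mo", 2.4, 27, 18, 0.31, 43, 0.6),
    ("p4", "Mo-Rh", 3.0, 26, 43, 0.42, 60, 0.9),
    ("p5", "Mo-Rh", 4.0, 27, 50, 0.43, 48, 1.1),
    ("p6", "Mo-Rh", 4.0, 28, 54, 0.44, 51, 1.3),
    ("p7", "Rh-Rh", 5.0, 28, 48, 0.45, 63, 1.1),
    ("p8", "Rh-Rh", 5.0, 29, 58, 0.47, 59, 1.4),
    ("p9", "Rh-Rh", 6.0, 29, 73, 0.47, 45, 1.6),
    ("p10", "Rh-Rh", 6.0, 30, 63, 0.48, 57, 1.5),
    ("p11", "Rh-Rh", 7.0, 30, 75, 0.48, 60, 1.6),
]


@pytest.fixture(scope="session")
def calibrations():
    return md.load_calibrations()


@pytest.fixture(scope="session")
def registry():
    return md.load_registry()


@pytest.fixture(scope="session")
def reference_device(registry):
    return registry["reference-ge-senographe-ds"]


def make_exam(combo, d, kvp, mas, device_id="reference-ge-senographe-ds", **kw):
    return md.ExamRecord(
        exam_id=kw.pop("exam_id", "exam"),
        combination=md.AnodeFilterCombination.from_string(combo),
        kvp=kvp,
        mas=mas,
        thickness_cm=d,
        device_id=device_id,
        **kw,
    )
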