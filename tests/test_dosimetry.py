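"""Core closed-form dose model: attenuation factor, inverse square,
incident kerma and 2ABD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import simpson

import mammodose as md
from mammodose.dosimetry import SMALL_ARGUMENT_THRESHOLD

from conftest import make_exam


class TestAttenuationIntegralFactor:
    @pytest.mark.parametrize(
        "mu, d, expected",
        [
            (0.0, 3.0, 1.0),  # zero-attenuation limit
            (0.68, 5.0, 0.284302),  # (1 - e^-3.4) / 3.4
            (0.91, 2.0, 0.460425),  # (1 - e^-1.82) / 1.82
            (0.5, 0.0, 1.0),  # thin-breast limit
        ],
    )
    def test_reference_values(self, mu, d, expected):
        assert md.attenuation_integral_factor(mu, d) == pytest.approx(
            expected, abs=5e-7
        )

    def test_negative_arguments_rejected(self):
        with pytest.raises(md.DosimetryError):
            md.attenuation_integral_factor(-0.1, 2.0)
        with pytest.raises(md.DosimetryError):
            md.attenuation_integral_factor(0.5, -1.0)

    def test_matches_defining_integral(self):
        """The factor is the depth average of exp(-mu*x): it must agree
        with a numeric quadrature of the defining integral."""
        for mu in np.arange(0.1, 1.21, 0.1):
            for d in np.arange(0.5, 8.01, 0.75):
                x = np.linspace(0.0, d, 10_001)
                oracle = simpson(np.exp(-mu * x), x=x) / d
                factor = md.attenuation_integral_factor(mu, d)
                assert factor == pytest.approx(oracle, rel=1e-8)

    def test_series_and_exact_branch_agree_at_threshold(self):
        u = SMALL_ARGUMENT_THRESHOLD
        series = 1.0 - u / 2.0 + u * u / 6.0
        exact = -math.expm1(-u) / u
        assert series == pytest.approx(exact, rel=1e-10)
        # the implementation is continuous across the switch
        below = md.attenuation_integral_factor(u * (1 - 1e-9), 1.0)
        above = md.attenuation_integral_factor(u * (1 + 1e-9), 1.0)
        assert below == pytest.approx(above, rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        u1=st.floats(min_value=1e-8, max_value=20.0),
        u2=st.floats(min_value=1e-8, max_value=20.0),
    )
    def test_strictly_decreasing_and_bounded(self, u1, u2):
        f1 = md.attenuation_integral_factor(u1, 1.0)
        f2 = md.attenuation_integral_factor(u2, 1.0)
        assert 0.0 < f1 <= 1.0
        if u1 < u2:
            assert f1 > f2
        elif u1 > u2:
            assert f1 < f2


class TestInverseSquareFactor:
    @pytest.mark.parametrize(
        "fid, d, expected",
        [(63.5, 0.0, 1.0), (63.5, 5.0, 1.178245)],
    )
    def test_reference_values(self, fid, d, expected):
        assert md.inverse_square_factor(fid, d) == pytest.approx(expected, abs=1e-6)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(md.DosimetryError, match="thicker than"):
            md.inverse_square_factor(64.0, 64.0)

    def test_strictly_increasing_in_thickness(self):
        values = [md.inverse_square_factor(63.5, d) for d in np.linspace(0, 20, 30)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestIncidentAirKerma:
    def test_all_correction_factors_unity(self, calibrations, reference_device):
        """With Y_tb = Y_0, mAs = 1 and d = 0 the kerma is the line value."""
        cal = calibrations["Mo-Mo"]
        exam = make_exam("Mo-Mo", 0.0, 28, 1)
        result = md.incident_air_kerma(cal, reference_device, exam)
        assert result.k_ai == pytest.approx(cal.line_value(28), rel=1e-12)

    def test_component_product_reconstructs_kerma(self, calibrations, reference_device):
        exam = make_exam("Rh-Rh", 5.0, 29, 50)
        result = md.incident_air_kerma(calibrations["Rh-Rh"], reference_device, exam)
        product = math.prod(result.components.values())
        assert product == pytest.approx(result.k_ai, rel=1e-13)
        assert set(result.components) == {"yield_ratio", "line_mas", "inverse_square"}

    def test_kerma_increasing_in_thickness(self, calibrations, reference_device):
        cal = calibrations["Mo-Rh"]
        kermas = [
            md.incident_air_kerma(
                cal, reference_device, make_exam("Mo-Rh", d, 28, 40)
            ).k_ai
            for d in np.linspace(0, 8, 9)
        ]
        assert all(b > a for a, b in zip(kermas, kermas[1:]))

    def test_out_of_range_kvp_warns_but_computes(self, calibrations, reference_device):
        exam = make_exam("Mo-Mo", 2.0, 36, 10)
        with pytest.warns(md.KvpRangeWarning):
            result = md.incident_air_kerma(calibrations["Mo-Mo"], reference_device, exam)
        assert result.k_ai > 0

    def test_kvp_below_line_root_rejected(self, calibrations, reference_device):
        # the Mo-Mo line crosses zero near 18.7 kVp
        exam = make_exam("Mo-Mo", 2.0, 18, 10)
        with pytest.raises(md.DosimetryError, match="line"):
            md.incident_air_kerma(calibrations["Mo-Mo"], reference_device, exam)

    def test_missing_yield_rejected(self, calibrations, reference_device):
        exam = make_exam("W-Rh", 2.0, 28, 10)
        with pytest.raises(md.DosimetryError, match="yield"):
            md.incident_air_kerma(calibrations["W-Rh"], reference_device, exam)


class TestAverageBreastDose:
    def test_dose_is_kerma_times_factor(self, calibrations, reference_device):
        exam = make_exam("Rh-Rh", 5.0, 28, 48)
        cal = calibrations["Rh-Rh"]
        result = md.average_breast_dose(cal, reference_device, exam)
        factor = md.attenuation_integral_factor(cal.mu_en, 5.0)
        assert result.two_abd == pytest.approx(result.k_ai.k_ai * factor, rel=1e-12)

    def test_zero_thickness_dose_equals_kerma(self, calibrations, reference_device):
        exam = make_exam("Mo-Mo", 0.0, 28, 20)
        result = md.average_breast_dose(calibrations["Mo-Mo"], reference_device, exam)
        assert result.two_abd == result.k_ai.k_ai

    def test_dose_decreasing_in_mu_en(self, calibrations, reference_device):
        """At fixed kVp/mAs the depth-averaged dose falls as the beam
        becomes more strongly absorbed."""
        cal = calibrations["Mo-Mo"]
        exam = make_exam("Mo-Mo", 4.0, 27, 40)
        doses = []
        for mu in np.linspace(0.4, 1.2, 9):
            modified = md.TubeCalibration(
                combination=cal.combination,
                alpha=cal.alpha,
                beta=cal.beta,
                y0=cal.y0,
                mu_en=float(mu),
            )
            doses.append(
                md.average_breast_dose(modified, reference_device, exam).two_abd
            )
        assert all(b < a for a, b in zip(doses, doses[1:]))

    def test_per_kvp_mode_interpolates(self, calibrations, reference_device):
        cal = calibrations["Mo-Mo"]
        # midpoint of the 22 and 24 kVp table entries
        mu, _ = cal.mu_en_at(23.0)
        assert mu == pytest.approx((1.04 + 0.95) / 2)
        assert cal.mu_en_at(20.0)[0] == pytest.approx(1.04)  # clamped low
        assert cal.mu_en_at(35.0)[0] == pytest.approx(0.81)  # clamped high
        exam = make_exam("Mo-Mo", 3.0, 23, 40)
        by_kvp = md.average_breast_dose(
            cal, reference_device, exam, mu_en_mode="per_kvp"
        )
        expected = by_kvp.k_ai.k_ai * md.attenuation_integral_factor(mu, 3.0)
        assert by_kvp.two_abd == pytest.approx(expected, rel=1e-12)

    def test_per_kvp_mode_requires_table(self, reference_device):
        bare = md.TubeCalibration(
            combination=md.AnodeFilterCombination("Mo", "Mo"),
            alpha=0.00997,
            beta=-0.186,
            y0=0.0938,
            mu_en=0.91,
        )
        exam = make_exam("Mo-Mo", 3.0, 26, 40)
        with pytest.raises(md.ConfigurationError):
            md.average_breast_dose(
                bare, reference_device, exam, mu_en_mode="per_kvp"
            )


class TestCombination:
    def test_canonical_form_case_insensitive(self):
        assert md.AnodeFilterCombination("MO", "rh") == md.AnodeFilterCombination(
            "Mo", "Rh"
        )
        assert md.AnodeFilterCombination("tungsten", "SILVER").canonical == "W-Ag"

    def test_unknown_material_representable(self):
        combo = md.AnodeFilterCombination("W", "Al")
        assert combo.canonical == "W-Al"
        assert not combo.is_supported
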