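"""Kerma-line and exponential-attenuation estimators."""

import math

import numpy as np
import pytest

import mammodose as md
from mammodose.calibration import read_attenuation_csv, read_kerma_csv
from mammodose.synthetic import GeneratorSpec


def line_points(alpha, beta, kvps, mas=40.0):
    return [
        md.KermaCalibrationPoint(kvp=k, mas=mas, kerma=(alpha * k + beta) * mas)
        for k in kvps
    ]


class TestKermaLineFit:
    def test_noiseless_recovery(self):
        """A noiseless linear series returns the generating slope and
        intercept to at least 6 significant digits."""
        alpha, beta = 0.00997, -0.186
        fit = md.fit_kerma_line(line_points(alpha, beta, range(22, 35)))
        assert fit.estimates["alpha"] == pytest.approx(alpha, rel=1e-9)
        assert fit.estimates["beta"] == pytest.approx(beta, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_point_line(self):
        y1, y2 = 0.05, 0.14
        points = [
            md.KermaCalibrationPoint(kvp=22, mas=1, kerma=y1),
            md.KermaCalibrationPoint(kvp=34, mas=1, kerma=y2),
        ]
        fit = md.fit_kerma_line(points)
        slope = (y2 - y1) / 12
        assert fit.estimates["alpha"] == pytest.approx(slope, rel=1e-12)
        assert fit.estimates["beta"] == pytest.approx(y1 - 22 * slope, rel=1e-12)

    def test_replicates_averaged_before_fit(self):
        # an outlier replicate shifts the mean, not the point count
        points = line_points(0.01, -0.18, [22, 26, 30, 34])
        points += [
            md.KermaCalibrationPoint(kvp=22, mas=40.0, kerma=points[0].kerma * 1.1)
        ]
        averaged = md.fit_kerma_line(points, averaging="replicates_first")
        pooled = md.fit_kerma_line(points, averaging="pooled")
        assert averaged.n_points == 4
        assert pooled.n_points == 5
        assert averaged.estimates["alpha"] != pooled.estimates["alpha"]

    def test_residuals_orthogonal_to_design(self):
        """OLS residuals are orthogonal to the constant and kVp regressors."""
        rng = np.random.default_rng(7)
        points = [
            md.KermaCalibrationPoint(
                kvp=k, mas=40.0, kerma=(0.008 * k - 0.1) * 40 * (1 + rng.normal(0, 0.02))
            )
            for k in range(22, 35)
        ]
        fit = md.fit_kerma_line(points)
        residuals = np.array(fit.residuals)
        kvps = np.arange(22, 35, dtype=float)
        assert abs(residuals.sum()) < 1e-8
        assert abs((residuals * kvps).sum()) < 1e-8

    def test_mean_alpha_recovered_under_noise(self):
        """Monte Carlo over seeds: 13 kVp levels x 3 replicates at 1%
        relative noise recover the slope within 1% in the mean."""
        alpha, beta = 0.00997, -0.186
        estimates = []
        for seed in range(200):
            spec = GeneratorSpec(seed=seed, noise_sigma=0.01)
            points = md.generate_kerma_calibration(
                alpha, beta, spec, mas_values=(40.0,), replicates=3
            )
            estimates.append(md.fit_kerma_line(points).estimates["alpha"])
        assert np.mean(estimates) == pytest.approx(alpha, rel=0.01)

    def test_single_kvp_rejected(self):
        with pytest.raises(md.CalibrationError, match="distinct kVp"):
            md.fit_kerma_line(line_points(0.01, -0.18, [28, 28, 28]))


def exp_points(i0, mu, depths):
    return [
        md.AttenuationPoint(depth_cm=x, intensity=i0 * math.exp(-mu * x))
        for x in depths
    ]


class TestAttenuationFit:
    @pytest.mark.parametrize("method", ["nonlinear", "loglinear"])
    def test_noiseless_recovery(self, method):
        fit = md.fit_attenuation(exp_points(2.08, 0.76, range(6)), method=method)
        assert fit.estimates["I0"] == pytest.approx(2.08, rel=1e-9)
        assert fit.estimates["mu_en"] == pytest.approx(0.76, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_point_closed_form(self):
        i0, mu = 3.0, 0.6
        points = exp_points(i0, mu, [0.0, 1.0]) + exp_points(i0, mu, [0.5])
        fit = md.fit_attenuation(points)
        assert fit.estimates["mu_en"] == pytest.approx(
            math.log(points[0].intensity / points[1].intensity), rel=1e-9
        )

    def test_mean_mu_recovered_under_noise(self):
        """100 seeded series at 1% multiplicative noise recover mu_en
        within 2% in the mean."""
        truth = 0.68
        estimates = []
        for seed in range(100):
            spec = GeneratorSpec(seed=seed, noise_sigma=0.01)
            points = md.generate_attenuation_series(2.08, truth, spec)
            estimates.append(md.fit_attenuation(points).estimates["mu_en"])
        assert np.mean(estimates) == pytest.approx(truth, rel=0.02)

    def test_loglinear_close_to_nonlinear_at_low_noise(self):
        """The two estimators differ only through their error weighting,
        so their disagreement on mu_en shrinks proportionally with the
        measurement noise: every series agrees within 0.5% at 0.1%
        noise, and the mean disagreement stays below the noise sigma at
        1% noise."""
        def deviations(noise):
            out = []
            for seed in range(50):
                spec = GeneratorSpec(seed=1000 + seed, noise_sigma=noise)
                points = md.generate_attenuation_series(2.5, 0.7, spec)
                nl = md.fit_attenuation(points, method="nonlinear")
                ll = md.fit_attenuation(points, method="loglinear")
                out.append(
                    abs(nl.estimates["mu_en"] - ll.estimates["mu_en"])
                    / nl.estimates["mu_en"]
                )
            return out

        assert max(deviations(0.001)) < 0.005
        assert np.mean(deviations(0.01)) < 0.01

    def test_bias_shrinks_with_noise(self):
        """Estimator bias stays below the noise scale at three levels."""
        truth = 0.7
        for noise in (0.005, 0.01, 0.02):
            estimates = []
            for seed in range(60):
                spec = GeneratorSpec(seed=seed, noise_sigma=noise)
                points = md.generate_attenuation_series(2.0, truth, spec, replicates=3)
                estimates.append(md.fit_attenuation(points).estimates["mu_en"])
            assert abs(np.mean(estimates) - truth) / truth < noise

    def test_degenerate_series_rejected(self):
        with pytest.raises(md.CalibrationError):
            md.fit_attenuation(exp_points(2.0, 0.7, [1.0, 1.0, 1.0]))
        with pytest.raises(md.CalibrationError):
            md.fit_attenuation(exp_points(2.0, 0.7, [0.0, 1.0]))


class TestAverageMuEn:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ({22: 1.04, 24: 0.95, 26: 0.89, 28: 0.84, 30: 0.81}, 0.91),
            ({26: 0.58, 28: 0.55, 30: 0.52, 32: 0.50, 34: 0.48}, 0.53),
            ({28: 0.70}, 0.70),
        ],
    )
    def test_mean_of_per_kvp_values(self, values, expected):
        mean, _ = md.average_mu_en(values)
        assert round(mean, 2) == pytest.approx(expected)

    def test_sigma_is_error_floor_or_spread(self):
        # identical sigmas dominate a tight spread
        mean, sigma = md.average_mu_en({26: (0.76, 0.04), 28: (0.75, 0.04)})
        assert sigma == pytest.approx(0.04)
        # a wide spread dominates tiny per-fit sigmas
        _, sigma = md.average_mu_en({26: (1.0, 0.001), 28: (0.6, 0.001)})
        assert sigma > 0.1

    def test_empty_map_rejected(self):
        with pytest.raises(md.CalibrationError):
            md.average_mu_en({})


class TestTubeYield:
    def test_zero_variance_replicates(self):
        points = [
            md.KermaCalibrationPoint(kvp=28, mas=1.0, kerma=0.0938) for _ in range(5)
        ]
        y, sigma = md.tube_yield(points, reference_kvp=28)
        assert y == pytest.approx(0.0938)
        assert sigma == 0.0

    def test_mean_and_sample_sd(self):
        points = [
            md.KermaCalibrationPoint(kvp=28, mas=1.0, kerma=k)
            for k in (0.093, 0.094, 0.095)
        ]
        y, sigma = md.tube_yield(points)
        assert y == pytest.approx(0.094)
        assert sigma == pytest.approx(0.001)

    def test_error_cases(self):
        with pytest.raises(md.CalibrationError):
            md.tube_yield([])
        mixed = [
            md.KermaCalibrationPoint(kvp=26, mas=1.0, kerma=0.07),
            md.KermaCalibrationPoint(kvp=28, mas=1.0, kerma=0.09),
        ]
        with pytest.raises(md.CalibrationError, match="mix"):
            md.tube_yield(mixed)
        single = [md.KermaCalibrationPoint(kvp=28, mas=1.0, kerma=0.09)]
        with pytest.warns(md.MammodoseWarning):
            _, sigma = md.tube_yield(single)
        assert sigma == 0.0


class TestMeasurementCsv:
    def test_round_trip_groups(self, tmp_path):
        import pandas as pd

        kerma = tmp_path / "kerma.csv"
        pd.DataFrame(
            {
                "combination": ["Mo-Mo", "Mo-Mo", "Rh-Rh"],
                "kvp": [26, 28, 28],
                "mas": [40, 40, 40],
                "kerma_mgy": [2.0, 2.5, 2.2],
                "replicate": [0, 0, 0],
            }
        ).to_csv(kerma, index=False)
        groups = read_kerma_csv(kerma)
        assert sorted(groups) == ["Mo-Mo", "Rh-Rh"]
        assert len(groups["Mo-Mo"]) == 2

        atten = tmp_path / "atten.csv"
        pd.DataFrame(
            {
                "combination": ["Rh-Rh"] * 3,
                "kvp": [28] * 3,
                "depth_cm": [0.0, 1.0, 2.0],
                "intensity_mgy": [2.0, 1.0, 0.5],
            }
        ).to_csv(atten, index=False)
        agroups = read_attenuation_csv(atten)
        assert list(agroups) == [("Rh-Rh", 28.0)]

    def test_missing_column_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("combination,kvp\nMo-Mo,28\n")
        with pytest.raises(md.CalibrationError, match="kerma_mgy"):
            read_kerma_csv(bad)
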