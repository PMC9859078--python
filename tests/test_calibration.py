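import numpy as np
import pytest
from scipy import stats

from strvarqc import (
    LogPoint,
    VarianceType,
    empirical_band,
    fit_poly4,
    fit_polynomial,
    jarque_bera,
    load_calibration,
    predict,
    predict_upper,
    save_calibration,
    reference_band,
    REFERENCE_COEFFICIENTS,
)
from strvarqc.reference import DEFAULT_PRIORS

ALLELE = VarianceType.ALLELE


def make_points(x, y, vt=ALLELE):
    return [LogPoint(float(a), float(b), vt) for a, b in zip(x, y)]


def normal_equations(x, y, degree=4):
    """Brute-force OLS oracle: solve X'X b = X'y directly."""
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def poly_eval(coeffs, x):
    return sum(c * x**k for k, c in enumerate(coeffs))


class TestFit:
    def test_noiseless_recovery_of_reference_coefficients(self):
        coeffs = REFERENCE_COEFFICIENTS[ALLELE]
        x = np.linspace(1.5, 4.0, 25)
        y = [poly_eval(coeffs, xi) for xi in x]
        model = fit_poly4(make_points(x, y))
        assert np.allclose(model.coefficients, coeffs, atol=1e-8)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-8)
        assert model.x_range == (1.5, 4.0)

    def test_constant_response_degenerate_fit(self):
        x = np.linspace(1.0, 4.0, 10)
        with pytest.warns(UserWarning, match="zero total variance"):
            model = fit_poly4(make_points(x, np.full(10, 2.5)))
        assert model.coefficients[0] == pytest.approx(2.5, abs=1e-8)
        assert np.allclose(model.coefficients[1:], 0.0, atol=1e-8)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert model.r_squared == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [9, 20, 50])
    def test_matches_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1.0, 4.0, n)
        y = rng.normal(0.0, 1.0, n) + 0.5 * x
        model = fit_poly4(make_points(x, y))
        assert np.allclose(model.coefficients, normal_equations(x, y), atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 60
        x = rng.uniform(1.5, 4.0, n)
        y = rng.normal(0.0, 0.2, n) + 0.1 * x**2
        model = fit_poly4(make_points(x, y))
        resid = y - np.array([predict(model, xi, warn_extrapolation=False) for xi in x])
        X = np.vander(x, 5, increasing=True)
        scale = np.abs(y).max()
        assert np.all(np.abs(X.T @ resid) <= 1e-8 * n * max(scale, 1.0))
        assert abs(resid.sum()) <= 1e-8 * n * max(scale, 1.0)

    def test_r_squared_nondecreasing_with_degree(self, rng):
        x = rng.uniform(1.0, 4.0, 40)
        y = rng.normal(0.0, 0.3, 40) + np.sin(x)
        pts = make_points(x, y)
        r3 = fit_polynomial(pts, degree=3).r_squared
        r4 = fit_polynomial(pts, degree=4).r_squared
        assert r4 >= r3 - 1e-12

    def test_too_few_distinct_x_rejected(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        y = np.arange(12.0)
        with pytest.raises(ValueError, match="distinct x"):
            fit_poly4(make_points(x, y))

    def test_too_few_points_rejected(self):
        x = np.linspace(1, 4, 6)
        with pytest.raises(ValueError, match="at least 7 points"):
            fit_poly4(make_points(x, x))

    def test_coefficient_cis_cover_truth_and_sd_recovered(self):
        # moderate replication; the full 200-replicate check runs in acceptance
        coeffs = REFERENCE_COEFFICIENTS[ALLELE]
        sd_true = 0.0927
        hits = np.zeros(5)
        sd_ok = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(1.5, 4.2, 500)
            y = [poly_eval(coeffs, xi) + rng.normal(0, sd_true) for xi in x]
            m = fit_poly4(make_points(x, y))
            for k, (lo, hi) in enumerate(m.coef_ci99):
                hits[k] += lo <= coeffs[k] <= hi
            sd_ok += abs(m.residual_sd - sd_true) / sd_true < 0.10
        assert (hits / reps >= 0.9).all()
        assert sd_ok / reps >= 0.95


class TestPredict:
    def test_intercept_at_x_zero(self, bands):
        for vt, band in bands.items():
            assert predict(band.model, 0.0, warn_extrapolation=False) == (
                REFERENCE_COEFFICIENTS[vt][0]
            )

    def test_matches_independent_horner_oracle(self, bands):
        model = bands[ALLELE].model
        # np.polyval as the independent evaluator (descending coefficients)
        for x in (0.0, 1.7, 3.0, 4.1):
            expected = np.polyval(list(reversed(model.coefficients)), x)
            assert predict(model, x, warn_extrapolation=False) == pytest.approx(
                expected, abs=1e-12
            )
        assert predict(model, 3.0, warn_extrapolation=False) == pytest.approx(0.5593, abs=1e-10)

    def test_extrapolation_warns(self, bands):
        with pytest.warns(UserWarning, match="extrapolating"):
            predict(bands[ALLELE].model, 5.0)

    def test_upper_band_adds_offset(self, bands):
        band = bands[ALLELE]
        x = 3.0
        assert predict_upper(band, x, warn_extrapolation=False) == pytest.approx(
            predict(band.model, x, warn_extrapolation=False) + band.offset, abs=1e-14
        )


class TestEmpiricalBand:
    @pytest.mark.parametrize(
        "vt, offset",
        [
            (ALLELE, 0.2156),
            (VarianceType.REVERSE_STUTTER, 0.2755),
            (VarianceType.FORWARD_STUTTER, 0.1779),
        ],
    )
    def test_reference_offsets_reproduce(self, vt, offset):
        assert reference_band(vt).offset == pytest.approx(offset, abs=1e-12)

    def test_zero_residual_sd_gives_zero_offset(self):
        x = np.linspace(1, 4, 10)
        model = fit_poly4(make_points(x, [poly_eval((1, 1, 0, 0, 0), xi) for xi in x]))
        band = empirical_band(model)
        assert band.offset == pytest.approx(0.0, abs=1e-8)
        assert predict_upper(band, 2.0, warn_extrapolation=False) == pytest.approx(
            predict(model, 2.0, warn_extrapolation=False), abs=1e-8
        )

    def test_nonpositive_z_rejected(self, bands):
        with pytest.raises(ValueError, match="z must be > 0"):
            empirical_band(bands[ALLELE].model, z=0.0)


class TestJarqueBera:
    def test_hand_computed_three_point_case(self):
        # S = 0, K = 1.5, n = 3 -> JB = (3/6)*(0 + (1.5-3)^2/4) = 0.28125
        stat, p = jarque_bera([-1.0, 0.0, 1.0])
        assert stat == pytest.approx(0.28125, abs=1e-12)
        assert 0 < p < 1

    def test_zero_for_zero_skew_kurtosis_three(self):
        # symmetric sample {±1 x4, ±a} with a^2 = 6 + 5*sqrt(2) has K = 3 exactly
        a = np.sqrt(6 + 5 * np.sqrt(2))
        sample = [1.0] * 4 + [-1.0] * 4 + [a, -a]
        stat, p = jarque_bera(sample)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            jarque_bera([2.0, 2.0, 2.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_implementation(self, seed):
        r = np.random.default_rng(seed).gamma(2.0, size=200)
        stat, p = jarque_bera(r)
        ref = stats.jarque_bera(r)
        assert stat == pytest.approx(float(ref.statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-8)

    def test_asymptotic_size_under_normality(self):
        # 1%-level test rejects a truly normal sample rarely
        rejections = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed).normal(size=10_000)
            _, p = jarque_bera(r)
            rejections += p <= 0.01
        assert (reps - rejections) / reps >= 0.99


class TestArtifactRoundTrip:
    def test_save_load_identity(self, tmp_path, rng):
        x = rng.uniform(1.5, 4.0, 80)
        bands = {}
        for vt in VarianceType:
            y = rng.normal(0, 0.1, 80) + 0.3 * x
            bands[vt] = empirical_band(fit_poly4(make_points(x, y, vt)))
        path = tmp_path / "calibration.json"
        save_calibration(bands, DEFAULT_PRIORS, path)
        loaded_bands, loaded_priors = load_calibration(path)
        for vt in VarianceType:
            assert loaded_bands[vt].model == bands[vt].model
            assert loaded_bands[vt].z == bands[vt].z
            assert loaded_priors[vt] == DEFAULT_PRIORS[vt]
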