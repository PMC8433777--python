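import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hasec import (
    fit_concentration_curve,
    fit_mw_curve,
    kav_theoretical,
    mw_from_kav,
    predict_concentration,
    t_test_coefficients,
)
from hasec.calibration import LinearFit
from hasec.errors import (
    BelowBlankWarning,
    DomainError,
    ExtrapolationWarning,
    NonInvertibleError,
    SingularDesignError,
)

CONCS = np.array([100.0, 250.0, 400.0, 550.0, 700.0, 850.0, 1000.0])


def line_fit(slope, intercept, curve_kind="molecular_weight", x_min=8.0, x_max=15.0):
    return LinearFit(
        slope=slope, intercept=intercept, n=4, r2=1.0, adj_r2=1.0, pearson_r=-1.0,
        residual_sd=0.0, se_slope=0.0, se_intercept=0.0, curve_kind=curve_kind,
        x_min=x_min, x_max=x_max,
    )


class TestConcentrationCurve:
    def test_recovers_noiseless_line_exactly(self):
        # the 0.011 MDa standard's analytical curve
        areas = 186.46 * CONCS + 2191.2
        fit = fit_concentration_curve(list(zip(CONCS, areas)))
        assert fit.slope == pytest.approx(186.46, abs=1e-9)
        assert fit.intercept == pytest.approx(2191.2, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_identity_line(self):
        fit = fit_concentration_curve([(1, 1), (2, 2), (3, 3)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        y = 150.0 * CONCS + 500.0 + rng.normal(0, 800.0, CONCS.size)
        fit = fit_concentration_curve(list(zip(CONCS, y)))
        # independent oracle: solve the normal equations directly
        X = np.column_stack([CONCS, np.ones_like(CONCS)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], rel=1e-10)
        assert fit.intercept == pytest.approx(beta[1], rel=1e-10)

    def test_diagnostics_consistency(self):
        rng = np.random.default_rng(7)
        y = 150.0 * CONCS + rng.normal(0, 500.0, CONCS.size)
        fit = fit_concentration_curve(list(zip(CONCS, y)))
        assert 0 <= fit.r2 <= 1
        assert fit.adj_r2 <= fit.r2
        assert fit.pearson_r**2 == pytest.approx(fit.r2, abs=1e-12)

    def test_singular_design_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_concentration_curve([(5, 1), (5, 2), (5, 3)])

    @given(k=st.floats(0.1, 100.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_equivariance_of_prediction(self, k):
        # scaling all areas by k scales the coefficients but not predictions
        areas = 186.46 * CONCS + 2191.2
        f1 = fit_concentration_curve(list(zip(CONCS, areas)))
        f2 = fit_concentration_curve(list(zip(CONCS, k * areas)))
        assert f2.slope == pytest.approx(k * f1.slope, rel=1e-9)
        a = 50_000.0
        assert predict_concentration(k * a, f2) == pytest.approx(
            predict_concentration(a, f1), rel=1e-9
        )


class TestTTests:
    def test_collinear_slope_infinitely_significant(self):
        fit = fit_concentration_curve([(1, 2), (2, 4), (3, 6), (4, 8)])
        t_s, p_s, _, _ = t_test_coefficients(fit)
        assert p_s < 1e-10

    def test_symmetric_data_gives_zero_intercept_t(self):
        rng = np.random.default_rng(3)
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = 2 * x + rng.normal(0, 0.5, 5)
        y = y - y.mean()  # centred response + symmetric x => intercept exactly 0
        fit = fit_concentration_curve(list(zip(x, y)))
        _, _, t_i, p_i = t_test_coefficients(fit)
        assert t_i == pytest.approx(0.0, abs=1e-9)
        assert p_i == pytest.approx(1.0, abs=1e-9)

    def test_null_rejection_rate_calibrated(self):
        # pure-noise slopes: two-sided test at alpha=0.05 rejects ~5% of the time
        rng = np.random.default_rng(2024)
        x = np.arange(7.0)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(0, 1, 7)
            _, p_s, _, _ = t_test_coefficients(
                fit_concentration_curve(list(zip(x, y)))
            )
            rejections += p_s < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


class TestPredictConcentration:
    def test_blank_area_maps_to_zero(self):
        fit = fit_concentration_curve(
            list(zip(CONCS, 186.46 * CONCS + 2191.2))
        )
        assert predict_concentration(2191.2, fit) == pytest.approx(0.0, abs=1e-9)

    def test_inverts_printed_curve_at_600(self):
        fit = fit_concentration_curve(
            list(zip(CONCS, 186.46 * CONCS + 2191.2))
        )
        assert predict_concentration(114_067.2, fit) == pytest.approx(600.0, abs=1e-9)

    @given(c=st.floats(0.0, 2000.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_round_trip(self, c):
        fit = fit_concentration_curve(
            list(zip(CONCS, 186.46 * CONCS + 2191.2))
        )
        assert predict_concentration(fit.slope * c + fit.intercept, fit) == (
            pytest.approx(c, abs=1e-9)
        )

    def test_below_blank_flagged(self):
        fit = fit_concentration_curve(
            list(zip(CONCS, 186.46 * CONCS + 2191.2))
        )
        with pytest.warns(BelowBlankWarning):
            assert predict_concentration(0.0, fit) < 0

    def test_zero_slope_not_invertible(self):
        fit = line_fit(0.0, 5.0, curve_kind="concentration")
        with pytest.raises(NonInvertibleError):
            predict_concentration(10.0, fit)


class TestMwCurve:
    def test_two_standards_interpolating_line(self):
        fit = fit_mw_curve([(1e4, 0.8), (1e6, 0.2)])
        assert fit.predict(np.log(1e4)) == pytest.approx(0.8)
        assert fit.predict(np.log(1e6)) == pytest.approx(0.2)
        assert fit.r2 == 1.0

    def test_recovers_simulated_kav_law(self, make_spec, mw_fit):
        spec = make_spec()
        assert mw_fit.slope == pytest.approx(spec.kav_slope, abs=1e-9)
        assert mw_fit.intercept == pytest.approx(spec.kav_intercept, abs=1e-9)

    def test_slope_negative_for_sec_ordering(self, mw_fit):
        assert mw_fit.slope < 0

    def test_non_positive_mw_rejected(self):
        with pytest.raises(DomainError):
            fit_mw_curve([(0.0, 0.5), (1e5, 0.3)])


class TestKavMwTransforms:
    @pytest.mark.parametrize("mw", [1e4, 1e6])
    def test_round_trip(self, mw_fit, mw):
        assert mw_from_kav(kav_theoretical(mw, mw_fit), mw_fit) == pytest.approx(
            mw, rel=1e-12
        )

    def test_hand_arithmetic(self):
        fit = line_fit(-0.1, 1.5, x_min=0.0, x_max=20.0)
        assert kav_theoretical(float(np.exp(10.0)), fit) == pytest.approx(0.5)

    def test_extrapolation_warns(self, mw_fit):
        with pytest.warns(ExtrapolationWarning):
            kav_theoretical(5e6, mw_fit)  # above the 2.2 MDa standard
        with pytest.warns(ExtrapolationWarning):
            mw_from_kav(0.99, mw_fit)

    def test_largest_standard_reproduced_on_perfect_fit(self, make_spec, mw_fit):
        spec = make_spec()
        mw_top = 2.2e6
        k_obs = spec.kav_slope * np.log(mw_top) + spec.kav_intercept
        assert kav_theoretical(mw_top, mw_fit) == pytest.approx(k_obs, abs=1e-12)
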