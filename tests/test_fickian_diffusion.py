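"""Crank sphere-diffusion series, De fitting, and the residual bootstrap."""

import numpy as np
import pytest

from sonoextract import (
    ExtractionCurve,
    FitError,
    ValidationError,
    bootstrap_de,
    crank_y,
    fit_de,
    pso_predict,
    unaccomplished_ratio,
)

RADIUS = 1.25e-4
TIMES_S = np.arange(10.0, 90, 10) * 60.0


class TestCrankSeries:
    def test_basel_normalization_at_t0(self):
        # (6/pi^2) * sum_{1..10} n^-2 = 0.9421; -> 1 as n_terms grows
        assert crank_y(1e-12, RADIUS, 0.0, n_terms=10) == pytest.approx(0.9421, abs=5e-5)
        assert crank_y(1e-12, RADIUS, 0.0, n_terms=100000) == pytest.approx(1.0, abs=1e-4)

    def test_t0_value_increases_with_truncation(self):
        values = [crank_y(1e-12, RADIUS, 0.0, n) for n in (1, 2, 5, 10, 20, 50)]
        assert values == sorted(values)
        assert all(v < 1.0 for v in values)

    def test_hand_summed_value_at_moderate_fourier_number(self):
        # De = 12.690e-13, t = 3000 s -> Fo ~ 0.244; only n=1 contributes
        y = crank_y(12.690e-13, RADIUS, 3000.0, n_terms=10)
        assert y == pytest.approx(0.0549, abs=1e-4)

    def test_monotone_non_increasing_in_time_and_de(self):
        y_t = crank_y(1e-12, RADIUS, TIMES_S, n_terms=10)
        assert np.all(np.diff(y_t) < 0)
        y_de = [crank_y(de, RADIUS, 1800.0, 10) for de in (5e-13, 1e-12, 2e-12)]
        assert y_de == sorted(y_de, reverse=True)

    def test_truncation_error_bound_beyond_small_fourier_numbers(self):
        """|y(n=10) - y(n=20)| < 1e-6 whenever De t / R^2 >= 0.01."""
        for de in (8.728e-13, 12.690e-13):
            t = np.linspace(0.01 * RADIUS**2 / de, 5000.0, 50)
            gap = np.abs(
                crank_y(de, RADIUS, t, n_terms=10) - crank_y(de, RADIUS, t, n_terms=20)
            )
            assert gap.max() < 1e-6

    def test_domain_validation(self):
        with pytest.raises(ValidationError):
            crank_y(-1e-12, RADIUS, 100.0, 10)
        with pytest.raises(ValidationError):
            crank_y(1e-12, RADIUS, 100.0, 0)


class TestUnaccomplishedRatio:
    def test_arithmetic(self):
        curve = ExtractionCurve(
            times=[10.0, 20.0], concentrations=[0.0, 75.0], temperature=30.0
        )
        t_s, y = unaccomplished_ratio(curve, c_inf=100.0, c0=0.0)
        assert list(t_s) == [600.0, 1200.0]
        assert list(y) == [1.0, 0.25]

    def test_equilibrium_point_maps_to_zero(self):
        curve = ExtractionCurve(times=[10.0], concentrations=[100.0], temperature=30.0)
        _, y = unaccomplished_ratio(curve, c_inf=100.0)
        assert y[0] == 0.0

    def test_invalid_c_inf_rejected(self):
        curve = ExtractionCurve(times=[10.0], concentrations=[1.0], temperature=30.0)
        with pytest.raises(ValidationError):
            unaccomplished_ratio(curve, c_inf=0.0)

    def test_points_above_c_inf_dropped_with_warning(self):
        curve = ExtractionCurve(
            times=[10.0, 20.0, 30.0], concentrations=[50.0, 105.0, 90.0], temperature=30.0
        )
        with pytest.warns(UserWarning, match="dropped"):
            t_s, y = unaccomplished_ratio(curve, c_inf=100.0)
        assert t_s.size == 2


class TestFitDe:
    def test_noise_free_self_consistency(self):
        y = crank_y(1e-12, RADIUS, TIMES_S, n_terms=10)
        fit = fit_de((TIMES_S, y), radius=RADIUS, n_terms=10)
        assert fit.de == pytest.approx(1e-12, rel=1e-6)
        assert fit.quality.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_truncation_study_one_term_biased_ten_vs_twenty_coincide(self):
        y = crank_y(1e-12, RADIUS, TIMES_S, n_terms=50)
        de_1 = fit_de((TIMES_S, y), radius=RADIUS, n_terms=1).de
        de_10 = fit_de((TIMES_S, y), radius=RADIUS, n_terms=10).de
        de_20 = fit_de((TIMES_S, y), radius=RADIUS, n_terms=20).de
        assert de_10 == pytest.approx(de_20, rel=1e-6)
        assert de_1 < de_10  # one-term fit biased low
        assert abs(de_1 - 1e-12) / 1e-12 > 1e-3

    def test_y_above_one_rejected_with_warning(self):
        y = crank_y(1e-12, RADIUS, TIMES_S, n_terms=10)
        y[0] = 1.2
        with pytest.warns(UserWarning, match="rejected"):
            fit = fit_de((TIMES_S, y), radius=RADIUS, n_terms=10)
        assert fit.times_seconds.size == TIMES_S.size - 1

    def test_all_equal_y_rejected(self):
        with pytest.raises(ValidationError):
            fit_de((TIMES_S, np.full(8, 0.5)), radius=RADIUS, n_terms=10)

    def test_agrees_with_grid_search_oracle(self):
        """kappa-reparameterized optimizer matches a brute-force De grid."""
        rng = np.random.default_rng(5)
        y = np.clip(
            crank_y(1e-12, RADIUS, TIMES_S, 10) + rng.normal(0, 0.01, 8), 1e-9, 1.0
        )
        fit = fit_de((TIMES_S, y), radius=RADIUS, n_terms=10)
        grid = np.linspace(0.5e-12, 2e-12, 1000)
        sse = [np.sum((crank_y(de, RADIUS, TIMES_S, 10) - y) ** 2) for de in grid]
        best = grid[int(np.argmin(sse))]
        assert fit.de == pytest.approx(best, abs=2 * (grid[1] - grid[0]))

    def test_radius_time_similarity_scaling(self):
        """Halving R with De fixed is equivalent to rescaling time by 4."""
        y_full = crank_y(1e-12, RADIUS, TIMES_S, 10)
        y_half = crank_y(1e-12, RADIUS / 2, TIMES_S / 4, 10)
        np.testing.assert_allclose(y_full, y_half, rtol=1e-12)


class TestBootstrapDe:
    def _fit(self, sigma=0.01, seed=11):
        rng = np.random.default_rng(seed)
        y = np.clip(
            crank_y(1e-12, RADIUS, TIMES_S, 10) + rng.normal(0, sigma, 8), 1e-9, 1.0
        )
        return fit_de((TIMES_S, y), radius=RADIUS, n_terms=10)

    def test_degenerate_zero_residual_case(self):
        y = crank_y(1e-12, RADIUS, TIMES_S, n_terms=10)
        fit = fit_de((TIMES_S, y), radius=RADIUS, n_terms=10)
        boot = bootstrap_de(fit, n_iterations=100, seed=0)
        assert boot.standard_error == pytest.approx(0.0, abs=1e-20)
        assert boot.ci_low == pytest.approx(fit.de, rel=1e-6)
        assert boot.ci_high == pytest.approx(fit.de, rel=1e-6)

    def test_seeded_reproducibility_is_exact(self):
        fit = self._fit()
        b1 = bootstrap_de(fit, n_iterations=200, seed=123)
        b2 = bootstrap_de(fit, n_iterations=200, seed=123)
        np.testing.assert_array_equal(b1.distribution, b2.distribution)
        assert b1.ci_low == b2.ci_low and b1.ci_high == b2.ci_high

    def test_distribution_length_and_percentile_bracketing(self):
        fit = self._fit()
        boot = bootstrap_de(fit, n_iterations=300, seed=7)
        assert boot.distribution.size == 300
        median = np.median(boot.distribution[~np.isnan(boot.distribution)])
        assert boot.ci_low <= median <= boot.ci_high

    def test_standard_error_scales_with_noise(self):
        ses = []
        for sigma in (0.005, 0.01, 0.02):
            boot = bootstrap_de(self._fit(sigma=sigma), n_iterations=300, seed=9)
            ses.append(boot.standard_error)
        assert ses[0] < ses[1] < ses[2]

    def test_refit_required_before_bootstrap(self):
        from sonoextract.core_data import FitQuality
        from sonoextract.fickian_diffusion import DiffusionFit

        bare = DiffusionFit(
            de=1e-12,
            n_terms=10,
            radius=RADIUS,
            quality=FitQuality(1.0, 0.0, 0.0, 8),
            c_inf=None,
            c0=0.0,
            y_series=np.zeros(8),
        )
        with pytest.raises(ValidationError):
            bootstrap_de(bare, n_iterations=10, seed=0)


def test_pipeline_transform_from_pso_curve():
    """A PSO-generated concentration curve maps into a fittable y-series."""
    t = np.arange(10.0, 90, 10)
    curve = ExtractionCurve(
        times=t, concentrations=pso_predict(159.15, 12.3074e-4, t), temperature=50.0
    )
    t_s, y = unaccomplished_ratio(curve, c_inf=159.15)
    fit = fit_de((t_s, y), radius=RADIUS, n_terms=10)
    assert 0 < fit.de < 1e-10  # plausible diffusivity scale for plant tissue
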