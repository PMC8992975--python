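"""Distance-density fitting, AICc selection and area correction."""

import math

import numpy as np
import pytest
from scipy import stats

from batmort.distance import (
    DistanceFit,
    DistanceSample,
    InsufficientDataError,
    UnreliableFitError,
    area_correction,
    area_correction_from_params,
    bootstrap_area_correction,
    density_cdf,
    frozen_distribution,
    pool_samples,
    select_distance_model,
    twl_fit,
)
from batmort.geometry import SquarePlot
from batmort.simulate import sample_observed_distances


class TestDensityCdf:
    @pytest.mark.parametrize("family, shape, scale", [
        ("gamma", 2.0, 10.0),
        ("gompertz", 0.07, 0.01),
        ("rayleigh", None, 20.0),
        ("truncated_normal", 30.0, 15.0),
        ("weibull", 1.8, 30.0),
    ])
    def test_support_starts_at_zero_and_reaches_one(self, family, shape, scale):
        assert density_cdf(family, shape, scale, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert density_cdf(family, shape, scale, 1e5) == pytest.approx(1.0, abs=1e-6)
        x = np.linspace(0, 200, 101)
        vals = density_cdf(family, shape, scale, x)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_gompertz_small_shape_approaches_exponential(self):
        lam = 0.05
        x = np.array([1.0, 10.0, 40.0])
        got = density_cdf("gompertz", 1e-8, lam, x)
        assert np.allclose(got, 1 - np.exp(-lam * x), atol=1e-6)

    def test_gompertz_hazard_parametrization(self):
        # published control fit: F(40) under hazard lam*exp(b x)
        b, lam = 0.0728, 0.0094
        closed = 1 - math.exp(-(lam / b) * math.expm1(b * 40.0))
        assert density_cdf("gompertz", b, lam, 40.0) == pytest.approx(closed, abs=1e-12)
        assert closed == pytest.approx(0.89416, abs=1e-4)
        # numeric integration of the density as an independent check
        from scipy.integrate import quad
        val, _ = quad(frozen_distribution("gompertz", (b, lam)).pdf, 0, 40)
        assert val == pytest.approx(closed, abs=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            density_cdf("gompertz", -0.1, 0.01, 10.0)
        with pytest.raises(ValueError):
            density_cdf("nosuch", 1.0, 1.0, 10.0)


class TestTwlFit:
    def test_weights_collapse_to_unweighted_mle(self):
        """With every distance inside the fully searched radius and no
        truncation, TWL equals the ordinary MLE (scipy's gamma fit)."""
        rng = np.random.default_rng(0)
        d = stats.gamma(a=3.0, scale=5.0).rvs(400, random_state=rng)
        big = SquarePlot(10_000.0)  # psi == 1, tau effectively infinite
        fit = twl_fit(DistanceSample(tuple(d), "x"), "gamma", big)
        a_mle, _, scale_mle = stats.gamma.fit(d, floc=0)
        assert fit.params[0] == pytest.approx(a_mle, rel=2e-3)
        assert fit.params[1] == pytest.approx(scale_mle, rel=2e-3)

    def test_gompertz_parameter_recovery(self, plot):
        """Thinned, truncated draws from a known Gompertz recover the
        parameters within 25% relative error."""
        rng = np.random.default_rng(3)
        truth = (0.0589, 0.0066)
        d = sample_observed_distances("gompertz", truth, plot, 500, rng)
        fit = twl_fit(DistanceSample(tuple(d), "sim"), "gompertz", plot)
        assert fit.reliable
        assert fit.params[0] == pytest.approx(truth[0], rel=0.25)
        assert fit.params[1] == pytest.approx(truth[1], rel=0.25)

    def test_mass_increasing_to_bound_is_unreliable(self, plot):
        """A sample whose density rises to the truncation radius (mode not
        captured by the plot) must be flagged unreliable."""
        rng = np.random.default_rng(4)
        # true mode far beyond the corner radius
        d = sample_observed_distances("gompertz", (0.05, 0.0005), plot, 40, rng)
        fit = twl_fit(DistanceSample(tuple(d), "timr-like"), "gompertz", plot)
        assert not fit.reliable

    def test_insufficient_data(self, plot):
        with pytest.raises(InsufficientDataError):
            twl_fit(DistanceSample((10.0, 20.0, 30.0), "tiny"), "gompertz", plot)

    def test_distances_beyond_truncation_rejected(self, plot):
        with pytest.raises(ValueError):
            twl_fit(DistanceSample(tuple([10.0] * 10 + [60.0]), "bad"), "rayleigh", plot)

    def test_aicc_uses_raw_sample_size(self, plot):
        rng = np.random.default_rng(5)
        d = sample_observed_distances("rayleigh", (15.0,), plot, 30, rng)
        fit = twl_fit(DistanceSample(tuple(d), "r"), "rayleigh", plot)
        k, n = 1, 30
        assert fit.aicc == pytest.approx(
            -2 * fit.log_likelihood + 2 * k + 2 * k * (k + 1) / (n - k - 1))


class TestSelection:
    def _fit(self, family, aicc, n_params=2, reliable=True):
        return DistanceFit(family=family, params=(1.0,) * n_params,
                           log_likelihood=0.0, aicc=aicc, n=50, mode_m=20.0,
                           reliable=reliable)

    def test_argmin(self):
        fits = [self._fit("gamma", 100.0), self._fit("weibull", 98.5),
                self._fit("rayleigh", 103.2, n_params=1)]
        assert select_distance_model(fits).family == "weibull"

    def test_single_fit(self):
        f = self._fit("gamma", 50.0)
        assert select_distance_model([f]) is f

    def test_tie_breaks(self):
        # equal AICc and parameter count: alphabetically first family
        fits = [self._fit("weibull", 100.0), self._fit("gamma", 100.0)]
        assert select_distance_model(fits).family == "gamma"
        # fewer parameters wins an AICc tie
        fits = [self._fit("gamma", 100.0), self._fit("rayleigh", 100.0, n_params=1)]
        assert select_distance_model(fits).family == "rayleigh"

    def test_all_unreliable_raises_with_pooling_guidance(self):
        fits = [self._fit("gamma", 100.0, reliable=False)]
        with pytest.raises(UnreliableFitError, match="pool"):
            select_distance_model(fits)


class TestAreaCorrection:
    def test_all_mass_inside_searched_region(self, plot):
        ac = area_correction_from_params("rayleigh", (10.0,), plot)
        assert ac > 0.999

    def test_all_mass_beyond_corners(self, plot):
        ac = area_correction_from_params("truncated_normal", (500.0, 10.0), plot)
        assert ac == pytest.approx(0.0, abs=1e-6)

    def test_published_control_parameters(self, plot):
        """Annulus sum for the published control Gompertz fit, verified
        against a Monte-Carlo landing-point oracle."""
        ac = area_correction_from_params("gompertz", (0.0728, 0.0094), plot)
        assert ac == pytest.approx(0.9457, abs=2e-4)
        rng = np.random.default_rng(11)
        n = 200_000
        d = frozen_distribution("gompertz", (0.0728, 0.0094)).rvs(n, random_state=rng)
        theta = rng.uniform(0, 2 * np.pi, n)
        inside = (np.abs(d * np.cos(theta)) <= 40) & (np.abs(d * np.sin(theta)) <= 40)
        p_hat = inside.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        assert ac == pytest.approx(p_hat, abs=3 * se)

    def test_bounded_by_cdf_at_halfwidth_and_corner(self, plot):
        for family, params in [("gompertz", (0.0589, 0.0066)),
                               ("weibull", (2.0, 30.0)),
                               ("gamma", (3.0, 12.0))]:
            dist = frozen_distribution(family, params)
            ac = area_correction_from_params(family, params, plot)
            assert dist.cdf(40.0) - 1e-9 <= ac <= dist.cdf(plot.truncation_distance) + 1e-9

    def test_shifting_mass_outward_decreases_ac(self, plot):
        acs = [area_correction_from_params("truncated_normal", (mu, 12.0), plot)
               for mu in (10.0, 25.0, 40.0, 55.0)]
        assert all(a > b for a, b in zip(acs, acs[1:]))

    def test_unreliable_fit_refused_without_force(self, plot):
        fit = DistanceFit(family="gompertz", params=(0.05, 0.0005),
                          log_likelihood=0.0, aicc=0.0, n=30, mode_m=90.0,
                          reliable=False)
        with pytest.raises(UnreliableFitError):
            area_correction(fit, plot)
        assert area_correction(fit, plot, force=True) >= 0.0


class TestBootstrapAC:
    def test_degenerate_sample_gives_degenerate_ci(self, plot):
        d = (20.0,) * 25
        ac = bootstrap_area_correction(DistanceSample(d, "deg"), "rayleigh", plot,
                                       n_boot=50, seed=0)
        assert ac.ci_lower == pytest.approx(ac.estimate)
        assert ac.ci_upper == pytest.approx(ac.estimate)

    def test_percentile_ordering_and_determinism(self, plot):
        rng = np.random.default_rng(8)
        d = sample_observed_distances("gompertz", (0.0728, 0.0094), plot, 150, rng)
        sample = DistanceSample(tuple(d), "control-like")
        ac1 = bootstrap_area_correction(sample, "gompertz", plot, n_boot=100, seed=5)
        ac2 = bootstrap_area_correction(sample, "gompertz", plot, n_boot=100, seed=5)
        assert ac1 == ac2
        assert ac1.ci_lower <= ac1.estimate <= ac1.ci_upper
        assert ac1.ci_lower < ac1.ci_upper

    def test_ci_coverage_matches_simulation_study(self, plot):
        """Measured coverage of the 90% percentile interval at control-like
        sample sizes.

        The AC estimator is driven by the largest observed distances, which
        bootstrap resamples cannot exceed, so the percentile interval
        undercovers: a 200-dataset simulation study measures ~74% coverage
        at n=187 (a documented limitation of the published procedure).
        This pins that behaviour against regressions in either direction.
        """
        truth_params = (0.0728, 0.0094)
        true_ac = area_correction_from_params("gompertz", truth_params, plot)
        rng = np.random.default_rng(13)
        n_datasets, hits = 150, 0
        for _ in range(n_datasets):
            d = sample_observed_distances("gompertz", truth_params, plot, 187, rng)
            ac = bootstrap_area_correction(DistanceSample(tuple(d), "sim"),
                                           "gompertz", plot, n_boot=150,
                                           seed=rng)
            hits += ac.ci_lower <= true_ac <= ac.ci_upper
        assert 0.62 <= hits / n_datasets <= 0.86


class TestPooling:
    def test_pooled_sizes_add(self):
        woc = DistanceSample(tuple(np.linspace(5, 50, 78)), "WOC")
        timr = DistanceSample(tuple(np.linspace(30, 55, 31)), "TIMR")
        pooled = pool_samples([woc, timr], "TIMR + WOC")
        assert pooled.n == 109
        assert pooled.sources == ("WOC", "TIMR")

    def test_self_pool_doubles(self):
        s = DistanceSample((1.0, 2.0, 3.0), "x")
        assert pool_samples([s, s], "xx").n == 6

    def test_empty_second_sample(self):
        s = DistanceSample((1.0, 2.0), "x")
        empty = DistanceSample((), "y")
        assert pool_samples([s, empty], "x+y").distances == s.distances

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pool_samples([DistanceSample((1.0,), "x")], "x")
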