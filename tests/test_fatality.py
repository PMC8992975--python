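"""Detection probability g, Horvitz-Thompson adjustment, comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from batmort.detection import PersistenceTrialSet, SeefTrialSet
from batmort.distance import DistanceSample
from batmort.fatality import (
    StudyInputs,
    TreatmentInputs,
    bootstrap_fatality_ci,
    ci_overlap_distinct,
    detection_probability,
    estimate_fatalities,
    fatality_reduction,
    reduction_ratio,
)
from batmort.geometry import SquarePlot


def _ones(t):
    return np.ones_like(np.asarray(t, dtype=float))


class TestDetectionProbability:
    def test_certain_first_search(self):
        assert detection_probability(1.0, 0.5, _ones) == pytest.approx(1.0)

    def test_single_chance_when_k_zero(self):
        assert detection_probability(0.6, 0.0, _ones) == pytest.approx(0.6)

    def test_fixed_arrival_enumeration(self):
        """Two searches at ages 1 and 2 with S(t)=e^{-0.2t}:
        term-by-term sum 0.40937 + 0.13406."""
        g = detection_probability(0.5, 0.8, lambda t: np.exp(-0.2 * np.asarray(t)),
                                  search_offsets=[0.0, 1.0], arrival=1.0)
        assert g == pytest.approx(0.54343, abs=1e-5)

    def test_increasing_in_p_and_k(self):
        surv = stats.lognorm(s=1.85, scale=8.7).sf
        gs = [detection_probability(p, 0.67, surv) for p in (0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(gs, gs[1:]))
        gs = [detection_probability(0.6, k, surv) for k in (0.0, 0.4, 0.7, 1.0)]
        assert all(a < b for a, b in zip(gs, gs[1:]))

    def test_increasing_under_longer_persistence(self):
        g_short = detection_probability(0.6, 0.67, stats.expon(scale=2.0).sf)
        g_long = detection_probability(0.6, 0.67, stats.expon(scale=10.0).sf)
        assert g_long > g_short

    def test_matches_per_carcass_simulation(self):
        """Monte-Carlo oracle: simulate individual carcasses through the
        daily schedule and compare the empirical detection fraction."""
        p, k = 0.6, 0.67
        surv_dist = stats.lognorm(s=1.85, scale=8.7)
        g = detection_probability(p, k, surv_dist.sf, n_searches=60)
        rng = np.random.default_rng(17)
        n = 100_000
        arrival = rng.random(n)              # age at first search
        removal = surv_dist.rvs(n, random_state=rng)
        detected = np.zeros(n, dtype=bool)
        alive = np.ones(n, dtype=bool)
        for m in range(60):
            age = arrival + m
            at_risk = alive & ~detected & (removal > age)
            hit = at_risk & (rng.random(n) < p * k**m)
            detected |= hit
            alive &= removal > age
        p_hat = detected.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        assert g == pytest.approx(p_hat, abs=3 * se)

    def test_zero_detection_error(self):
        with pytest.raises(ValueError):
            detection_probability(0.0, 0.5, _ones)


class TestEstimate:
    def test_no_adjustment(self):
        est = estimate_fatalities(50, 1.0, 1.0, 10)
        assert est.m_per_turbine == pytest.approx(5.0)

    def test_half_detection(self):
        est = estimate_fatalities(31, 1.0, 0.5, 10)
        assert est.m_per_turbine == pytest.approx(6.2)

    def test_zero_count_boundary(self):
        est = estimate_fatalities(0, 0.8, 0.9, 10)
        assert est.m_per_turbine == 0.0

    def test_self_consistency_identity(self):
        """M_hat * n_turbines * g_total recovers the raw count exactly."""
        est = estimate_fatalities(187, 0.794, 0.92, 10, capacity_mw=1.65)
        assert est.m_per_turbine * 10 * est.g_total == pytest.approx(187.0, rel=1e-12)
        assert est.m_per_mw == pytest.approx(est.m_per_turbine / 1.65)
        assert est.m_per_turbine >= est.observed_per_turbine

    def test_zero_detection_rejected(self):
        with pytest.raises(ValueError):
            estimate_fatalities(10, 0.0, 1.0, 10)


class TestComparisons:
    def test_reduction_from_published_estimates(self):
        assert fatality_reduction(26.28, 14.12) == pytest.approx(0.4627, abs=1e-4)
        assert fatality_reduction(10.0, 10.0) == 0.0
        assert fatality_reduction(10.0, 15.0) == pytest.approx(-0.5)

    def test_reduction_needs_positive_control(self):
        with pytest.raises(ValueError):
            fatality_reduction(0.0, 1.0)

    def test_reduction_ratio(self):
        assert reduction_ratio(26.28, 6.62, 14.12) == pytest.approx(1.6168, abs=1e-3)
        assert reduction_ratio(10.0, 5.0, 5.0) == pytest.approx(1.0)
        assert reduction_ratio(10.0, 10.0, 5.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            reduction_ratio(10.0, 5.0, 10.0)

    @pytest.mark.parametrize("a, b, expected", [
        ((1.0, 2.0), (3.0, 4.0), True),
        ((1.0, 3.0), (2.0, 4.0), False),
        ((1.0, 2.0), (2.0, 3.0), False),  # touching endpoints overlap
    ])
    def test_ci_overlap_rule(self, a, b, expected):
        assert ci_overlap_distinct(a, b) is expected
        assert ci_overlap_distinct(b, a) is expected


def _study_inputs(plot, counts, distances, family="rayleigh",
                  seef=None, pers=None, pers_family="exponential"):
    seef = seef or SeefTrialSet((True,) * 20, (True,) * 20)
    pers = pers or PersistenceTrialSet((1.0,) * 12, (2.0,) * 12)
    return StudyInputs(
        treatments={"control": TreatmentInputs(counts, "control")},
        distance_samples={"control": (DistanceSample(distances, "control"), family)},
        seef_trials=seef,
        persistence_trials=pers,
        persistence_family=pers_family,
        k=0.67,
        plot=plot,
        n_searches=30,
    )


class TestBootstrap:
    def test_degenerate_inputs_zero_width_ci(self, plot):
        """All components exact and a single turbine count: the bootstrap
        cannot vary and the CI collapses to the point estimate."""
        inputs = _study_inputs(plot, counts=(12.0,), distances=(20.0,) * 25)
        boot = bootstrap_fatality_ci(inputs, n_boot=60, seed=1)
        lo, hi = boot.m_per_turbine_ci("control")
        assert lo == pytest.approx(hi, rel=1e-9)

    def test_deterministic_given_seed(self, plot):
        rng = np.random.default_rng(2)
        d = tuple(np.clip(rng.normal(22, 8, 60), 0.5, 39.0))
        counts = tuple(float(c) for c in rng.poisson(6, 10))
        seef = SeefTrialSet((True,) * 30, tuple(rng.random(30) < 0.6))
        pers = PersistenceTrialSet(tuple([0.0, 1.0, 2.0] * 10),
                                   tuple([1.0, 2.0, np.inf] * 10))
        inputs = _study_inputs(plot, counts, d, seef=seef, pers=pers)
        b1 = bootstrap_fatality_ci(inputs, n_boot=80, seed=9)
        b2 = bootstrap_fatality_ci(inputs, n_boot=80, seed=9)
        assert b1.m_per_turbine_ci("control") == b2.m_per_turbine_ci("control")

    def test_paired_reduction_ci_narrower_than_independent(self, plot):
        """Shared detection components cancel in paired replicates, so the
        reduction CI is narrower than an unpaired recombination."""
        rng = np.random.default_rng(3)
        d_c = tuple(np.clip(rng.normal(20, 7, 80), 0.5, 39.0))
        d_t = tuple(np.clip(rng.normal(24, 7, 50), 0.5, 39.0))
        seef = SeefTrialSet((True,) * 40, tuple(rng.random(40) < 0.6))
        pers = PersistenceTrialSet(tuple([0.0, 1.0, 2.0, 4.0] * 14),
                                   tuple([1.0, 2.0, 3.0, np.inf] * 14))
        inputs = StudyInputs(
            treatments={
                "control": TreatmentInputs(tuple(float(c) for c in rng.poisson(19, 10)), "control"),
                "WOC": TreatmentInputs(tuple(float(c) for c in rng.poisson(8, 10)), "WOC"),
            },
            distance_samples={
                "control": (DistanceSample(d_c, "control"), "rayleigh"),
                "WOC": (DistanceSample(d_t, "WOC"), "rayleigh"),
            },
            seef_trials=seef,
            persistence_trials=pers,
            persistence_family="lognormal",
            k=0.67,
            plot=plot,
            n_searches=30,
        )
        boot = bootstrap_fatality_ci(inputs, n_boot=400, seed=4)
        lo, hi = boot.reduction_ci("control", "WOC")
        paired_width = hi - lo
        rng2 = np.random.default_rng(5)
        c = boot.replicates["control"]
        t = rng2.permutation(boot.replicates["WOC"])
        ind = 1.0 - t / c
        ind_lo, ind_hi = np.quantile(ind, [0.05, 0.95])
        assert paired_width < (ind_hi - ind_lo)
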