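"""Detection-adjusted fatality estimation and treatment comparison.

A carcass is counted only if it (a) falls inside the searched plot, (b)
persists to at least one search, and (c) is found on one of the searches
while it persists.  The season-level probability of (b) and (c) for a
carcass in the searched area is

    g_search = sum_m P(persist to search m) * p k^{m-1}
                     * prod_{l<m} (1 - p k^{l-1}),

with persistence evaluated for an arrival uniform within the night,
P(persist to search m) = int_0^1 S(u + (m-1) I) du for daily interval I.
Multiplying by the area correction gives the total detection probability
g = g_search * AC, and the Horvitz-Thompson adjusted count is

    M_hat = C / (n_turbines * g).

Uncertainty comes from a paired nonparametric bootstrap that resamples
every estimated component at once: searcher-efficiency trials, persistence
trial carcasses, carcass distances (area correction) and per-turbine
carcass counts.  Treatments are compared on the same replicates, so the
reduction and ratio CIs respect the correlation induced by the shared
detection model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detection import (
    PersistenceFit,
    PersistenceFitError,
    PersistenceTrialSet,
    SeefEstimate,
    SeefTrialSet,
    estimate_seef,
    fit_persistence,
)
from .distance import (
    DistanceSample,
    FitError,
    InsufficientDataError,
    area_correction,
    twl_fit,
)
from .geometry import SquarePlot

__all__ = [
    "detection_probability",
    "FatalityEstimate",
    "estimate_fatalities",
    "fatality_reduction",
    "reduction_ratio",
    "ci_overlap_distinct",
    "StudyInputs",
    "TreatmentInputs",
    "FatalityBootstrap",
    "bootstrap_fatality_ci",
]


def detection_probability(
    p: float,
    k: float,
    survival,
    n_searches: int = 78,
    interval: float = 1.0,
    search_offsets=None,
    arrival: float | str = "uniform",
    nodes: int = 32,
    tol: float = 1e-10,
) -> float:
    """Season-level detection probability ``g_search`` within the plot.

    Parameters
    ----------
    p, k : float
        Searcher efficiency on the first exposure and its per-search decay.
    survival : callable
        Vectorised survival function ``S(t)`` of carcass persistence (days).
    n_searches, interval : int, float
        Number of equally spaced searches and their spacing in days;
        ignored when explicit ``search_offsets`` are given.
    search_offsets : array-like, optional
        Times of each search relative to the first search opportunity
        (offsets[0] == 0); gaps in the realized schedule lengthen the
        corresponding offsets.
    arrival : "uniform" or float
        "uniform" integrates the carcass age at first search over
        (0, interval]; a float fixes that age (used by enumeration tests).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= k <= 1.0):
        raise ValueError("p and k must lie in [0, 1]")
    if search_offsets is None:
        offsets = interval * np.arange(n_searches, dtype=float)
    else:
        offsets = np.asarray(search_offsets, dtype=float)
        if offsets.size == 0 or offsets[0] != 0.0 or np.any(np.diff(offsets) <= 0):
            raise ValueError("search_offsets must start at 0 and increase")
    m = offsets.size
    pm = p * k ** np.arange(m)
    miss = np.concatenate([[1.0], np.cumprod(1.0 - pm[:-1])])
    find = pm * miss  # P(found at search m | persisted to m)
    # drop negligible tail terms
    keep = np.nonzero(find >= tol)[0]
    if keep.size:
        last = keep[-1] + 1
        offsets, find = offsets[:last], find[:last]

    if arrival == "uniform":
        u, w = np.polynomial.legendre.leggauss(nodes)
        u = 0.5 * interval * (u + 1.0)
        w = 0.5 * interval * w / interval
        ages = u[:, None] + offsets[None, :]
        g = float(np.sum(w[:, None] * survival(ages) * find[None, :]))
    else:
        ages = float(arrival) + offsets
        g = float(np.sum(survival(ages) * find))
    if g <= 0.0:
        raise ValueError("detection probability is zero: no carcass could ever be found")
    return min(g, 1.0)


@dataclass(frozen=True)
class FatalityEstimate:
    """Adjusted fatality estimate for one treatment group."""

    treatment: str
    g_search: float
    g_total: float
    observed_per_turbine: float
    m_per_turbine: float
    m_per_mw: float
    m_per_turbine_ci: tuple[float, float] = (np.nan, np.nan)
    m_per_mw_ci: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not (0.0 < self.g_total <= 1.0):
            raise ValueError("g_total must lie in (0, 1]")


def estimate_fatalities(
    carcass_count: float,
    g_search: float,
    area_correction_value: float,
    n_turbines: int,
    capacity_mw: float = 1.65,
    treatment: str = "",
) -> FatalityEstimate:
    """Horvitz-Thompson adjusted fatalities per turbine and per MW."""
    g_total = g_search * area_correction_value
    if g_total <= 0.0:
        raise ValueError("g_search * area_correction must be positive")
    m = carcass_count / (n_turbines * g_total)
    return FatalityEstimate(
        treatment=treatment,
        g_search=g_search,
        g_total=g_total,
        observed_per_turbine=carcass_count / n_turbines,
        m_per_turbine=m,
        m_per_mw=m / capacity_mw,
    )


def fatality_reduction(m_control: float, m_treatment: float) -> float:
    """Proportional mortality reduction ``1 - M_t / M_c`` (negative values
    indicate increased mortality)."""
    if m_control <= 0:
        raise ValueError("control fatality rate must be positive")
    return 1.0 - m_treatment / m_control


def reduction_ratio(m_control: float, m_t1: float, m_t2: float) -> float:
    """Ratio of absolute reductions ``(M_c - M_t1) / (M_c - M_t2)``."""
    if m_control == m_t2:
        raise ValueError("reference treatment shows no reduction; ratio undefined")
    return (m_control - m_t1) / (m_control - m_t2)


def ci_overlap_distinct(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True iff two closed intervals do not overlap (touching endpoints
    count as overlapping)."""
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("intervals must be ordered")
    return max(lo_a, lo_b) > min(hi_a, hi_b)


# -- paired bootstrap over every estimated component ------------------------


@dataclass(frozen=True)
class TreatmentInputs:
    """Per-treatment observed data entering the estimator."""

    turbine_counts: tuple[float, ...]  # carcasses per turbine (inside plot)
    distance_key: str  # which distance sample supplies the area correction

    @property
    def n_turbines(self) -> int:
        return len(self.turbine_counts)

    @property
    def count(self) -> float:
        return float(sum(self.turbine_counts))


@dataclass(frozen=True)
class StudyInputs:
    """Everything the fatality estimator and its bootstrap consume."""

    treatments: dict[str, TreatmentInputs]
    distance_samples: dict[str, tuple[DistanceSample, str]]  # key -> (sample, family)
    seef_trials: SeefTrialSet
    persistence_trials: PersistenceTrialSet
    persistence_family: str
    k: float
    plot: SquarePlot
    capacity_mw: float = 1.65
    n_searches: int = 78
    interval: float = 1.0
    control: str = "control"


def _point_components(inputs: StudyInputs, ci_level: float):
    seef = estimate_seef(inputs.seef_trials, ci_level=ci_level, k=inputs.k)
    pers = fit_persistence(inputs.persistence_trials, inputs.persistence_family)
    acs = {}
    dist_fits = {}
    for key, (sample, family) in inputs.distance_samples.items():
        f = twl_fit(sample, family, inputs.plot)
        dist_fits[key] = f
        acs[key] = area_correction(f, inputs.plot, force=True)
    g = detection_probability(seef.p, inputs.k, pers.survival,
                              n_searches=inputs.n_searches, interval=inputs.interval)
    return seef, pers, dist_fits, acs, g


def point_estimates(inputs: StudyInputs, ci_level: float = 0.90) -> dict[str, FatalityEstimate]:
    """Point estimates for every treatment (no CIs)."""
    _, _, _, acs, g = _point_components(inputs, ci_level)
    out = {}
    for label, tr in inputs.treatments.items():
        out[label] = estimate_fatalities(
            tr.count, g, acs[tr.distance_key], tr.n_turbines,
            capacity_mw=inputs.capacity_mw, treatment=label,
        )
    return out


@dataclass(frozen=True)
class FatalityBootstrap:
    """Paired bootstrap replicates of per-turbine adjusted fatalities."""

    replicates: dict[str, np.ndarray]
    ci_level: float
    capacity_mw: float
    n_failed: int
    warnings: tuple[str, ...] = ()

    def _q(self, x: np.ndarray) -> tuple[float, float]:
        alpha = 1.0 - self.ci_level
        lo, hi = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)

    def m_per_turbine_ci(self, label: str) -> tuple[float, float]:
        return self._q(self.replicates[label])

    def m_per_mw_ci(self, label: str) -> tuple[float, float]:
        return self._q(self.replicates[label] / self.capacity_mw)

    def reduction_ci(self, control: str, treatment: str) -> tuple[float, float]:
        r = 1.0 - self.replicates[treatment] / self.replicates[control]
        return self._q(r)

    def ratio_ci(self, control: str, t1: str, t2: str) -> tuple[float, float]:
        c, a, b = (self.replicates[x] for x in (control, t1, t2))
        denom = c - b
        ok = denom != 0
        return self._q((c[ok] - a[ok]) / denom[ok])


def bootstrap_fatality_ci(
    inputs: StudyInputs,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int | np.random.Generator = 0,
) -> FatalityBootstrap:
    """Joint percentile bootstrap of all fatality estimates.

    Each replicate resamples (with replacement) the SEEF trial outcomes,
    the persistence trial carcasses, every distance sample, and the
    per-turbine carcass counts of every treatment, then recomputes all
    adjusted estimates on the same draw.  Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seef, pers, dist_fits, _, _ = _point_components(inputs, ci_level)

    found = np.asarray(inputs.seef_trials.found, dtype=bool)
    avail_found = found[np.asarray(inputs.seef_trials.available, dtype=bool)]
    n_seef = avail_found.size
    p_lo = np.asarray(inputs.persistence_trials.last_present_d, float)
    p_hi = np.asarray(inputs.persistence_trials.first_absent_d, float)
    n_pers = p_lo.size
    dist_arrays = {
        key: np.asarray(sample.distances, float)
        for key, (sample, _) in inputs.distance_samples.items()
    }
    counts = {lab: np.asarray(tr.turbine_counts, float) for lab, tr in inputs.treatments.items()}

    reps: dict[str, list[float]] = {lab: [] for lab in inputs.treatments}
    failed = 0
    for _ in range(n_boot):
        try:
            p_b = float(np.mean(avail_found[rng.integers(0, n_seef, n_seef)]))
            idx = rng.integers(0, n_pers, n_pers)
            pers_b = fit_persistence(
                PersistenceTrialSet(tuple(p_lo[idx]), tuple(p_hi[idx])),
                inputs.persistence_family, start=pers.params, quick=True,
            )
            if p_b <= 0.0:
                raise ValueError("resampled searcher efficiency is zero")
            g_b = detection_probability(p_b, inputs.k, pers_b.survival,
                                        n_searches=inputs.n_searches, interval=inputs.interval)
            ac_b = {}
            for key, (sample, family) in inputs.distance_samples.items():
                d = dist_arrays[key]
                boot = DistanceSample(tuple(d[rng.integers(0, d.size, d.size)]),
                                      sample.treatment_label)
                f_b = twl_fit(boot, family, inputs.plot, start=dist_fits[key].params, quick=True)
                if not f_b.reliable:
                    raise FitError("unreliable distance refit in replicate")
                ac_b[key] = area_correction(f_b, inputs.plot)
            m_b = {}
            for lab, tr in inputs.treatments.items():
                c = counts[lab]
                c_b = float(np.sum(c[rng.integers(0, c.size, c.size)]))
                g_total = g_b * ac_b[tr.distance_key]
                if g_total <= 0:
                    raise ValueError("zero detection probability in replicate")
                m_b[lab] = c_b / (tr.n_turbines * g_total)
        except (FitError, InsufficientDataError, PersistenceFitError, ValueError):
            failed += 1
            continue
        for lab, val in m_b.items():
            reps[lab].append(val)

    warnings: tuple[str, ...] = ()
    if n_boot and failed > 0.2 * n_boot:
        warnings = (f"{failed}/{n_boot} bootstrap replicates failed",)
    if failed == n_boot:
        raise FitError("all bootstrap replicates failed")
    return FatalityBootstrap(
        replicates={lab: np.asarray(v) for lab, v in reps.items()},
        ci_level=ci_level,
        capacity_mw=inputs.capacity_mw,
        n_failed=failed,
        warnings=warnings,
    )
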