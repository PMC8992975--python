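"""Searcher efficiency and carcass persistence.

Searcher efficiency (SEEF) is the probability ``p`` that a searcher finds a
carcass present in the searched area, estimated from single-search bias
trials as the proportion found among trial carcasses still available
(not scavenged) at the search.  Single-search trials cannot identify the
detection decay factor ``k`` (the multiplicative drop p, pk, pk^2, ... on
successive searches), so ``k`` is a required external input.

Carcass persistence is the time from arrival to removal by scavengers or
machinery, observed only through interval-censored trial check histories
(checked daily for 4 days, then on days 7, 10, 14, 20 and 30).  Four
survival families are fitted by interval-censored maximum likelihood and
compared by AICc.  The derived quantity ``r`` is the probability that a
carcass arriving uniformly within a search interval persists to the next
search, ``r = (1/I) * int_0^I S(u) du``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

from .util import aicc as _aicc

__all__ = [
    "PERSISTENCE_FAMILIES",
    "SeefTrialSet",
    "SeefEstimate",
    "PersistenceTrialSet",
    "PersistenceFit",
    "estimate_seef",
    "seef_at_search",
    "fit_persistence",
    "select_persistence_model",
    "persistence_distribution",
    "interval_availability",
    "PersistenceFitError",
]

PERSISTENCE_FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")

_N_PARAMS = {"exponential": 1, "weibull": 2, "lognormal": 2, "loglogistic": 2}


class PersistenceFitError(RuntimeError):
    """Persistence model could not be fitted."""


@dataclass(frozen=True)
class SeefTrialSet:
    """Outcomes of single-search searcher-efficiency trials.

    ``available`` marks carcasses not scavenged before the search (only
    these enter the estimate); ``found`` marks recovery by the searcher.
    """

    available: tuple[bool, ...]
    found: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.available) != len(self.found):
            raise ValueError("available and found must have equal length")
        if any(f and not a for a, f in zip(self.available, self.found)):
            raise ValueError("a carcass cannot be found if it was unavailable")

    @property
    def n_placed(self) -> int:
        return len(self.available)

    @property
    def n_available(self) -> int:
        return int(sum(self.available))

    @property
    def n_found(self) -> int:
        return int(sum(self.found))


@dataclass(frozen=True)
class SeefEstimate:
    p: float
    ci_lower: float
    ci_upper: float
    k: float
    n_available: int
    n_found: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.k <= 1.0):
            raise ValueError("p and k must lie in [0, 1]")
        if not (self.ci_lower <= self.p <= self.ci_upper):
            raise ValueError("CI must bracket p")


def estimate_seef(trials: SeefTrialSet, ci_level: float = 0.90, k: float = 0.67) -> SeefEstimate:
    """Proportion found among available, with a Wilson score CI.

    ``k`` is attached from configuration; it is not estimable from
    single-search trials.
    """
    n = trials.n_available
    if n == 0:
        raise ValueError("no trial carcasses were available to searchers")
    x = trials.n_found
    lo, hi = proportion_confint(x, n, alpha=1.0 - ci_level, method="wilson")
    return SeefEstimate(p=x / n, ci_lower=float(lo), ci_upper=float(hi),
                        k=k, n_available=n, n_found=x)


def seef_at_search(p: float, k: float, m: int) -> float:
    """Detection probability on the ``m``-th search a carcass is exposed to:
    ``p * k**(m-1)``."""
    if not (0.0 <= p <= 1.0 and 0.0 <= k <= 1.0):
        raise ValueError("p and k must lie in [0, 1]")
    if m < 1:
        raise ValueError("search index starts at 1")
    return p * k ** (m - 1)


@dataclass(frozen=True)
class PersistenceTrialSet:
    """Interval-censored removal times from carcass-persistence trials.

    Each carcass contributes an interval (last day seen present, first day
    seen absent]; carcasses still present at the final check are censored
    there (``first_absent_d = inf``).  A carcass never seen after placement
    has the interval (0, first check].
    """

    last_present_d: tuple[float, ...]
    first_absent_d: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = np.asarray(self.last_present_d, float)
        hi = np.asarray(self.first_absent_d, float)
        if lo.shape != hi.shape:
            raise ValueError("interval bounds must have equal length")
        if np.any(lo < 0) or np.any(lo >= hi):
            raise ValueError("need 0 <= last_present_d < first_absent_d")

    @property
    def n(self) -> int:
        return len(self.last_present_d)

    @property
    def n_censored(self) -> int:
        return int(np.sum(np.isinf(np.asarray(self.first_absent_d))))


@dataclass(frozen=True)
class PersistenceFit:
    family: str
    params: tuple[float, ...]
    log_likelihood: float
    aicc: float
    n: int
    median_days: float

    @property
    def n_params(self) -> int:
        return len(self.params)

    def distribution(self):
        return _frozen(self.family, self.params)

    def survival(self, t):
        return self.distribution().sf(t)


def _frozen(family: str, params: tuple[float, ...]):
    if family == "exponential":
        (rate,) = params
        return stats.expon(scale=1.0 / rate)
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min(c=shape, scale=scale)
    if family == "lognormal":
        mu, sigma = params
        return stats.lognorm(s=sigma, scale=math.exp(mu))
    if family == "loglogistic":
        shape, scale = params
        return stats.fisk(c=shape, scale=scale)
    raise ValueError(f"unknown persistence family {family!r}")


def persistence_distribution(family: str, params: tuple[float, ...]):
    """Frozen scipy distribution for a persistence family/parameter pair."""
    return _frozen(family, params)


def _to_params(family: str, z: np.ndarray) -> tuple[float, ...]:
    if family == "exponential":
        return (math.exp(z[0]),)
    if family == "lognormal":
        return (float(z[0]), math.exp(z[1]))
    return (math.exp(z[0]), math.exp(z[1]))


def _from_params(family: str, p: tuple[float, ...]) -> np.ndarray:
    if family == "exponential":
        return np.array([math.log(p[0])])
    if family == "lognormal":
        return np.array([p[0], math.log(p[1])])
    return np.array([math.log(p[0]), math.log(p[1])])


def _starts(family: str, lo: np.ndarray, hi: np.ndarray) -> list[tuple[float, ...]]:
    finite_hi = np.where(np.isinf(hi), lo, hi)
    mid = np.maximum(0.5 * (lo + finite_hi), 0.25)
    m = float(np.mean(mid))
    if family == "exponential":
        return [(f / m,) for f in (0.5, 1.0, 2.0)]
    if family == "lognormal":
        mu0 = math.log(max(np.median(mid), 0.25))
        return [(mu0, s) for s in (0.7, 1.2, 1.8, 2.5)]
    # weibull / loglogistic (shape, scale)
    return [(c, m) for c in (0.6, 1.0, 1.6, 2.5)]


def _interval_nll(family: str, lo_u: np.ndarray, hi_u: np.ndarray, lo_c: np.ndarray):
    """Closed-form interval-censored negative log-likelihood.

    Uses elementary survival functions (via scipy.special) instead of
    frozen distributions because the bootstrap refits this ~10^4 times.
    S(0) = 1 is handled explicitly for intervals starting at placement.
    """
    BAD = 1e12

    def make(sf):
        def nll(z):
            try:
                s_lo = sf(lo_u, z)
                s_hi = sf(hi_u, z)
                val = -float(np.sum(np.log(np.maximum(s_lo - s_hi, 1e-300))))
                if lo_c.size:
                    val -= float(np.sum(np.log(np.maximum(sf(lo_c, z), 1e-300))))
            except (ValueError, FloatingPointError, OverflowError):
                return BAD
            return val if np.isfinite(val) else BAD
        return nll

    if family == "exponential":
        def sf(t, z):
            rate = math.exp(z[0])
            with np.errstate(over="ignore", under="ignore"):
                return np.exp(-rate * t)
    elif family == "weibull":
        def sf(t, z):
            c, s = math.exp(z[0]), math.exp(z[1])
            if c > 1e3:
                raise OverflowError
            with np.errstate(over="ignore", under="ignore", divide="ignore"):
                return np.exp(-np.power(t / s, c))
    elif family == "lognormal":
        def sf(t, z):
            mu, sigma = float(z[0]), math.exp(z[1])
            with np.errstate(divide="ignore"):
                logt = np.log(np.maximum(t, 1e-300))
            out = special.ndtr(-(logt - mu) / sigma)
            return np.where(t <= 0, 1.0, out)
    elif family == "loglogistic":
        def sf(t, z):
            c, s = math.exp(z[0]), math.exp(z[1])
            if c > 1e3:
                raise OverflowError
            with np.errstate(over="ignore", divide="ignore"):
                return 1.0 / (1.0 + np.power(t / s, c))
    else:
        raise ValueError(f"unknown persistence family {family!r}")
    return make(sf)


def fit_persistence(
    trials: PersistenceTrialSet,
    family: str,
    start: tuple[float, ...] | None = None,
    quick: bool = False,
) -> PersistenceFit:
    """Interval-censored maximum-likelihood fit of one survival family.

    Maximises sum over removed carcasses of log[S(lo) - S(hi)] plus
    sum over censored carcasses of log S(t_cens).
    """
    if family not in PERSISTENCE_FAMILIES:
        raise ValueError(f"unknown persistence family {family!r}")
    lo = np.asarray(trials.last_present_d, float)
    hi = np.asarray(trials.first_absent_d, float)
    censored = np.isinf(hi)
    if censored.all():
        raise PersistenceFitError("all trial carcasses were censored; removal time unidentified")
    n = lo.size

    lo_u, hi_u = lo[~censored], hi[~censored]
    lo_c = lo[censored]
    nll = _interval_nll(family, lo_u, hi_u, lo_c)

    if quick and start is not None:
        starts = [tuple(start)]
        options = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 600}
    else:
        starts = _starts(family, lo, hi)
        if start is not None:
            starts = [tuple(start)] + starts
        options = {"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000}
    best = None
    for s0 in starts:
        res = optimize.minimize(nll, _from_params(family, s0), method="Nelder-Mead",
                                options=options)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e11:
        raise PersistenceFitError(f"{family} persistence fit did not converge")

    params = _to_params(family, best.x)
    loglik = -float(best.fun)
    k = _N_PARAMS[family]
    return PersistenceFit(
        family=family,
        params=tuple(float(p) for p in params),
        log_likelihood=loglik,
        aicc=_aicc(loglik, k, n),
        n=n,
        median_days=float(_frozen(family, params).median()),
    )


def select_persistence_model(fits: list[PersistenceFit]) -> PersistenceFit:
    """AICc-minimal fit; ties broken by parameter count then family name."""
    usable = [f for f in fits if np.isfinite(f.aicc)]
    if not usable:
        raise PersistenceFitError("no persistence fit has a finite AICc")
    return min(usable, key=lambda f: (f.aicc, f.n_params, f.family))


def interval_availability(fit: PersistenceFit, interval_days: float = 1.0) -> float:
    """Probability ``r`` of persisting from a uniform arrival to the next
    search: ``(1/I) * int_0^I S(u) du``."""
    if interval_days <= 0:
        raise ValueError("interval must be positive")
    sf = fit.survival
    val, _ = integrate.quad(sf, 0.0, interval_days, limit=200)
    return float(val / interval_days)
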