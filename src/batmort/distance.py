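"""Carcass fall-distance modelling.

Fits candidate distance-density families (gamma, Gompertz, Rayleigh,
truncated normal, Weibull) to right-truncated carcass distances by
truncated weighted likelihood (TWL), selects among them by AICc, and turns
the chosen density into an *area correction*: the fraction of all carcasses
expected to land inside the searched plot, obtained by summing the
predicted probability mass of each 1-m annulus times the searched fraction
of that annulus.

The TWL objective up-weights each observation by the inverse of its
inclusion probability (the searched fraction of the circle at its
distance), so carcasses found in the sparsely searched corners count for
more than carcasses found near the turbine:

    l(theta) = sum_i w_i * [log f(d_i; theta) - log F(tau; theta)],
    w_i ~ 1 / psi(d_i),  normalised so sum_i w_i = n.

Parametrizations
----------------
gamma(shape, scale) and weibull(shape, scale) are the standard scipy ones;
rayleigh has a single scale sigma; truncated_normal(mean, sd) is a normal
truncated to [0, inf); gompertz(shape b, scale lam) has hazard
h(x) = lam * exp(b x), so F(x) = 1 - exp(-(lam/b)(exp(b x) - 1)) and the
density mode sits at ln(b/lam)/b when b > lam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from .geometry import SquarePlot, annuli, annulus_searched_fraction, circle_inclusion_fraction
from .util import aicc as _aicc

__all__ = [
    "FAMILIES",
    "DistanceSample",
    "DistanceFit",
    "AreaCorrection",
    "frozen_distribution",
    "density_cdf",
    "twl_fit",
    "select_distance_model",
    "area_correction",
    "area_correction_from_params",
    "bootstrap_area_correction",
    "pool_samples",
    "InsufficientDataError",
    "FitError",
    "UnreliableFitError",
]

FAMILIES = ("gamma", "gompertz", "rayleigh", "truncated_normal", "weibull")

#: number of free parameters per family
N_PARAMS = {
    "gamma": 2,
    "gompertz": 2,
    "rayleigh": 1,
    "truncated_normal": 2,
    "weibull": 2,
}


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested family."""


class FitError(RuntimeError):
    """The optimiser failed to produce a usable fit."""


class UnreliableFitError(RuntimeError):
    """An unreliable fit was used where a reliable one is required."""


@dataclass(frozen=True)
class DistanceSample:
    """Right-truncated carcass distances (metres) for one treatment group."""

    distances: tuple[float, ...]
    treatment_label: str
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.size and d.min() < 0:
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "distances", tuple(float(x) for x in d))
        if not self.sources:
            object.__setattr__(self, "sources", (self.treatment_label,))

    @property
    def n(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class DistanceFit:
    """A fitted distance-density family with its selection statistics."""

    family: str
    params: tuple[float, ...]
    log_likelihood: float
    aicc: float
    n: int
    mode_m: float
    reliable: bool
    treatment_label: str = ""
    message: str = ""

    @property
    def shape(self) -> float:
        """First parameter (NaN for the one-parameter Rayleigh)."""
        return self.params[0] if len(self.params) == 2 else math.nan

    @property
    def scale(self) -> float:
        return self.params[-1]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def distribution(self):
        return frozen_distribution(self.family, self.params)


@dataclass(frozen=True)
class AreaCorrection:
    """Fraction of carcasses expected within the searched plot, with CI."""

    estimate: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int
    n_failed: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError(f"estimate must be in [0,1], got {self.estimate}")
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise ValueError("CI must bracket the estimate")


def frozen_distribution(family: str, params: tuple[float, ...]):
    """Frozen scipy distribution on [0, inf) for a family/parameter pair."""
    if family == "gamma":
        shape, scale = params
        return stats.gamma(a=shape, scale=scale)
    if family == "gompertz":
        b, lam = params
        # scipy's gompertz(c, scale=s) has F = 1 - exp(-c (e^{x/s} - 1));
        # c = lam/b, s = 1/b recovers the hazard form lam * e^{b x}.
        return stats.gompertz(c=lam / b, scale=1.0 / b)
    if family == "rayleigh":
        (sigma,) = params
        return stats.rayleigh(scale=sigma)
    if family == "truncated_normal":
        mean, sd = params
        return stats.truncnorm(a=(0.0 - mean) / sd, b=np.inf, loc=mean, scale=sd)
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min(c=shape, scale=scale)
    raise ValueError(f"unknown family {family!r}")


def _validate_params(family: str, params: tuple[float, ...]) -> None:
    if family not in N_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    if len(params) != N_PARAMS[family]:
        raise ValueError(f"{family} takes {N_PARAMS[family]} parameters, got {len(params)}")
    positive = params if family != "truncated_normal" else params[1:]
    if any(not np.isfinite(p) or p <= 0 for p in positive):
        raise ValueError(f"invalid parameters for {family}: {params}")


def density_cdf(family: str, shape: float | None, scale: float, x) -> float:
    """CDF ``F(x)`` of a distance-density family on [0, inf)."""
    params = (scale,) if family == "rayleigh" else (shape, scale)
    _validate_params(family, tuple(float(p) for p in params))
    if np.ndim(x) == 0 and x < 0:
        raise ValueError("x must be non-negative")
    val = frozen_distribution(family, params).cdf(x)
    return float(val) if np.ndim(x) == 0 else val


# -- parameter transforms: optimise on an unconstrained scale ---------------

def _to_params(family: str, z: np.ndarray) -> tuple[float, ...]:
    if family == "rayleigh":
        return (math.exp(z[0]),)
    if family == "truncated_normal":
        return (float(z[0]), math.exp(z[1]))
    return (math.exp(z[0]), math.exp(z[1]))


def _from_params(family: str, params: tuple[float, ...]) -> np.ndarray:
    if family == "rayleigh":
        return np.array([math.log(params[0])])
    if family == "truncated_normal":
        return np.array([params[0], math.log(params[1])])
    return np.array([math.log(params[0]), math.log(params[1])])


def _starting_points(family: str, d: np.ndarray) -> list[tuple[float, ...]]:
    """Five deterministic moment-based starts spanning plausible shapes."""
    m = float(np.mean(d))
    s = float(np.std(d)) or max(m, 1.0) * 0.25
    if family == "gamma":
        k0 = max((m / s) ** 2, 0.2)
        return [(k0 * f, m / (k0 * f)) for f in (0.4, 0.7, 1.0, 1.6, 2.5)]
    if family == "weibull":
        return [(c, m) for c in (0.8, 1.2, 1.8, 2.5, 3.5)]
    if family == "rayleigh":
        sig = m / math.sqrt(math.pi / 2.0)
        return [(sig * f,) for f in (0.5, 0.75, 1.0, 1.5, 2.25)]
    if family == "truncated_normal":
        return [(m * f, s * g) for f, g in ((0.5, 1.5), (0.8, 1.0), (1.0, 1.0), (1.2, 0.8), (1.5, 1.2))]
    if family == "gompertz":
        # starts with modes ln(b/lam)/b bracketing the sample mean
        out = []
        for b in (0.02, 0.04, 0.07, 0.1, 0.15):
            lam = b * math.exp(-b * m)  # mode at the sample mean
            out.append((b, max(lam, 1e-8)))
        return out
    raise ValueError(family)


def _twl_nll(family: str, d: np.ndarray, w: np.ndarray, tau: float):
    """Closed-form weighted truncated negative log-likelihood.

    Written out with scipy.special primitives rather than frozen
    distributions: the objective is evaluated ~10^2 times per fit and the
    bootstrap runs ~10^4 fits, so frozen-distribution overhead dominates
    otherwise.  Each closure returns a large penalty for invalid or
    non-finite parameter values.
    """
    log_d = np.log(np.maximum(d, 1e-300))
    sum_w = float(np.sum(w))
    BAD = 1e12

    if family == "gompertz":
        def nll(z):
            b, lam = math.exp(z[0]), math.exp(z[1])
            if b > 5.0 or b * tau > 500.0:
                return BAD
            with np.errstate(over="ignore"):
                logf = math.log(lam) + b * d - (lam / b) * np.expm1(b * d)
                ftau = -math.expm1(-(lam / b) * math.expm1(b * tau))
            if not ftau > 1e-9:  # essentially no mass inside the plot: degenerate
                return BAD
            val = -float(np.sum(w * logf)) + sum_w * math.log(ftau)
            return val if np.isfinite(val) else BAD
    elif family == "gamma":
        def nll(z):
            k, s = math.exp(z[0]), math.exp(z[1])
            if k > 1e4:
                return BAD
            logf = (k - 1.0) * log_d - d / s - k * math.log(s) - special.gammaln(k)
            ftau = special.gammainc(k, tau / s)
            if not ftau > 1e-9:  # essentially no mass inside the plot: degenerate
                return BAD
            val = -float(np.sum(w * logf)) + sum_w * math.log(ftau)
            return val if np.isfinite(val) else BAD
    elif family == "weibull":
        def nll(z):
            c, s = math.exp(z[0]), math.exp(z[1])
            if c > 1e3:
                return BAD
            with np.errstate(over="ignore"):
                logf = math.log(c) - math.log(s) + (c - 1.0) * (log_d - math.log(s)) - (d / s) ** c
            ftau = -math.expm1(-((tau / s) ** c)) if (tau / s) ** c < 500 else 1.0
            if not ftau > 1e-9:  # essentially no mass inside the plot: degenerate
                return BAD
            val = -float(np.sum(w * logf)) + sum_w * math.log(ftau)
            return val if np.isfinite(val) else BAD
    elif family == "rayleigh":
        def nll(z):
            sig = math.exp(z[0])
            logf = log_d - 2.0 * math.log(sig) - d**2 / (2.0 * sig**2)
            ftau = -math.expm1(-(tau**2) / (2.0 * sig**2))
            if not ftau > 1e-9:  # essentially no mass inside the plot: degenerate
                return BAD
            val = -float(np.sum(w * logf)) + sum_w * math.log(ftau)
            return val if np.isfinite(val) else BAD
    elif family == "truncated_normal":
        log_sqrt2pi = 0.5 * math.log(2.0 * math.pi)
        def nll(z):
            mu, sd = float(z[0]), math.exp(z[1])
            zlo = -mu / sd
            denom = special.ndtr(-zlo)  # P(X > 0) for the untruncated normal
            logf = -log_sqrt2pi - math.log(sd) - (d - mu) ** 2 / (2.0 * sd**2) - math.log(max(denom, 1e-300))
            ftau = (special.ndtr((tau - mu) / sd) - special.ndtr(zlo)) / max(denom, 1e-300)
            if not ftau > 1e-9:  # essentially no mass inside the plot: degenerate
                return BAD
            val = -float(np.sum(w * logf)) + sum_w * math.log(ftau)
            return val if np.isfinite(val) else BAD
    else:
        raise ValueError(f"unknown family {family!r}")
    return nll


def fitted_mode(family: str, params: tuple[float, ...], upper: float) -> float:
    """Mode of the fitted density, located on a fine grid over [0, upper]."""
    dist = frozen_distribution(family, params)
    x = np.linspace(0.0, upper, 4097)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        pdf = dist.pdf(x)
    pdf = np.nan_to_num(pdf, nan=0.0, posinf=0.0)
    return float(x[int(np.argmax(pdf))])


def twl_fit(
    sample: DistanceSample,
    family: str,
    plot: SquarePlot,
    weights: np.ndarray | None = None,
    start: tuple[float, ...] | None = None,
    mode_reliability_fraction: float = 0.95,
    quick: bool = False,
) -> DistanceFit:
    """Truncated weighted likelihood fit of one family to one sample.

    ``weights`` overrides the inclusion-probability weights (used by the
    bootstrap to reuse the point-estimate weights); ``start`` adds a warm
    start to the deterministic multi-start list; ``quick`` with a warm
    start skips the multi-start sweep (bootstrap refits).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    d = np.asarray(sample.distances, dtype=float)
    n = d.size
    k = N_PARAMS[family]
    if n < k + 2:
        raise InsufficientDataError(
            f"{family} needs at least {k + 2} observations, sample {sample.treatment_label!r} has {n}"
        )
    tau = plot.truncation_distance
    if d.max() >= tau:
        raise ValueError("all distances must lie strictly inside the truncation radius")

    if weights is None:
        psi = circle_inclusion_fraction(d, plot)
        w = 1.0 / np.maximum(psi, 1e-12)
    else:
        w = np.asarray(weights, dtype=float)
    w = w * (n / w.sum())

    nll = _twl_nll(family, d, w, tau)

    if quick and start is not None:
        starts = [tuple(start)]
        options = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 600}
    else:
        starts = _starting_points(family, d)
        if start is not None:
            starts = [tuple(start)] + starts
        options = {"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000}
    best = None
    for s0 in starts:
        try:
            z0 = _from_params(family, s0)
        except ValueError:
            continue
        res = optimize.minimize(nll, z0, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e11:
        raise FitError(f"TWL fit of {family} to {sample.treatment_label!r} did not converge")

    params = _to_params(family, best.x)
    loglik = -float(best.fun)
    mode = fitted_mode(family, params, upper=2.0 * tau)
    reliable = mode < mode_reliability_fraction * tau
    # degenerate fits: scale at an optimiser bound, or nearly all predicted
    # mass beyond the plot corners (the "implausibly low area correction"
    # failure of right-truncated samples that exclude the mode)
    ftau = float(frozen_distribution(family, params).cdf(tau))
    if params[-1] < 1e-6 or not np.isfinite(loglik) or not ftau >= 0.05:
        reliable = False
    return DistanceFit(
        family=family,
        params=tuple(float(p) for p in params),
        log_likelihood=loglik,
        aicc=_aicc(loglik, k, n),
        n=n,
        mode_m=mode,
        reliable=reliable,
        treatment_label=sample.treatment_label,
    )


def select_distance_model(fits: list[DistanceFit]) -> DistanceFit:
    """AICc-minimal reliable fit; ties broken by parameter count then name."""
    reliable = [f for f in fits if f.reliable and np.isfinite(f.aicc)]
    if not reliable:
        raise UnreliableFitError(
            "no reliable distance fit: the truncated data may not include the "
            "mode of the distribution; pool with another treatment's distances "
            "(pool_samples) and refit"
        )
    return min(reliable, key=lambda f: (f.aicc, f.n_params, f.family))


def area_correction_from_params(family: str, params: tuple[float, ...], plot: SquarePlot) -> float:
    """Annulus-sum area correction for an explicit family/parameter pair."""
    dist = frozen_distribution(family, params)
    bins = annuli(plot)
    edges = np.array([b[0] for b in bins] + [bins[-1][1]])
    cdf = dist.cdf(edges)
    fractions = np.array([annulus_searched_fraction(lo, hi, plot) for lo, hi in bins])
    return float(np.sum(np.diff(cdf) * fractions))


def area_correction(fit: DistanceFit, plot: SquarePlot, force: bool = False) -> float:
    """Annulus-sum area correction for a fitted distance density.

    Sum over 1-m annuli of (probability mass in annulus) x (searched
    fraction of annulus).  Lies in [F(a), F(tau)].
    """
    if not fit.reliable and not force:
        raise UnreliableFitError(
            f"fit of {fit.family} for {fit.treatment_label!r} is unreliable "
            "(mode at or beyond the truncation radius); pass force=True to "
            "compute anyway or pool samples and refit"
        )
    return area_correction_from_params(fit.family, fit.params, plot)


def bootstrap_area_correction(
    sample: DistanceSample,
    family: str,
    plot: SquarePlot,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int | np.random.Generator = 0,
) -> AreaCorrection:
    """Percentile bootstrap CI for the area correction.

    Resamples distances with replacement, refits the *same* family, and
    recomputes the area correction; replicates whose refit fails or is
    unreliable are dropped and counted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point_fit = twl_fit(sample, family, plot)
    point_ac = area_correction(point_fit, plot, force=True)

    d = np.asarray(sample.distances, dtype=float)
    n = d.size
    reps = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = DistanceSample(tuple(d[idx]), sample.treatment_label)
        try:
            f = twl_fit(boot, family, plot, start=point_fit.params, quick=True)
        except (FitError, InsufficientDataError, ValueError):
            failed += 1
            continue
        if not f.reliable:
            failed += 1
            continue
        reps.append(area_correction(f, plot, force=True))
    warnings = ()
    if n_boot and failed > 0.2 * n_boot:
        warnings = (f"{failed}/{n_boot} bootstrap replicates failed or were unreliable",)
    if reps:
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        lo, hi = min(lo, point_ac), max(hi, point_ac)
    else:
        lo = hi = point_ac
        warnings = warnings + ("all bootstrap replicates failed; CI degenerate",)
    return AreaCorrection(
        estimate=point_ac,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_bootstrap=len(reps),
        n_failed=failed,
        warnings=warnings,
    )


def pool_samples(samples: list[DistanceSample], label: str) -> DistanceSample:
    """Concatenate distance samples under a new label, keeping provenance."""
    if len(samples) < 2:
        raise ValueError("pooling needs at least two samples")
    distances: tuple[float, ...] = ()
    sources: tuple[str, ...] = ()
    for s in samples:
        distances += s.distances
        sources += s.sources
    return DistanceSample(distances, label, sources=sources)
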