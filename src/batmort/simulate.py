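"""Synthetic study generator with known ground truth.

Generates a complete curtailment study — true fatalities, carcass fall
positions, removal times, per-search detection outcomes, searcher
efficiency and persistence trials, and 10-minute turbine operation records
— from explicit parameters, so every stage of the estimation pipeline can
be checked against a recoverable truth.

The defaults emulate the 2015 Blue Sky Green Field study conditions: three
treatment groups of 10 turbines searched daily over a 78-night season on
80 m x 80 m plots; Gompertz fall-distance distributions with modes at
28.1 m (control), 37.2 m (WOC) and 47.2 m (TIMR); lognormal persistence
with median 8.7 d and log-sd 1.85 (giving a 94% daily persistence
probability); searcher efficiency 0.60 over 42 placed trial carcasses and
56 persistence trial carcasses checked on days 1-4, 7, 10, 14, 20, 30;
Weibull night winds with mean 5.7 m/s; and the WOC (< 4.5 m/s) and TIMR
(< 8.0 m/s with a bat call in the last 30 minutes) curtailment rules.

What the generator deliberately does not model: within-season arrival
pulses, carcass-level covariates, weather/phenology coupling of bat
activity, and facility layout or wake effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as gamma_fn

from .distance import area_correction_from_params, frozen_distribution
from .detection import persistence_distribution as _persistence_frozen
from .fatality import detection_probability
from .geometry import SquarePlot

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "simulate_ops",
           "sample_observed_distances"]


def sample_observed_distances(
    family: str,
    params: tuple[float, ...],
    plot: SquarePlot,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` observed carcass distances: falls with uniform direction,
    kept only when the landing point lies inside the square plot (which
    right-truncates at the corner radius and thins corner distances)."""
    dist = frozen_distribution(family, tuple(params))
    out: list[np.ndarray] = []
    have = 0
    while have < n:
        m = max(4 * (n - have), 64)
        d = dist.rvs(m, random_state=rng)
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        keep = (np.abs(d * np.cos(theta)) <= plot.half_width) & \
               (np.abs(d * np.sin(theta)) <= plot.half_width)
        kept = d[keep]
        out.append(kept)
        have += kept.size
    return np.concatenate(out)[:n]

_SPECIES = ("big brown bat", "eastern red bat", "hoary bat",
            "little brown bat", "silver-haired bat", "tri-colored bat")
_SPECIES_P = np.array([42, 62, 77, 47, 66, 2], dtype=float) / 296.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_turbines: int = 10
    season_nights: int = 78
    season_start: date = date(2015, 7, 15)
    half_width_m: float = 40.0
    # expected fatalities per turbine per season, by treatment
    fatality_rates: dict = field(default_factory=lambda: {
        "control": 26.28, "WOC": 14.12, "TIMR": 6.62,
    })
    # fall-distance family and parameters by treatment
    distance_models: dict = field(default_factory=lambda: {
        "control": ("gompertz", (0.0728, 0.0094)),
        "WOC": ("gompertz", (0.0589, 0.0066)),
        "TIMR": ("gompertz", (0.0441, 0.0055)),
    })
    persistence_family: str = "lognormal"
    persistence_params: tuple[float, ...] = (float(np.log(8.7)), 1.85)
    persistence_check_days: tuple[float, ...] = (1, 2, 3, 4, 7, 10, 14, 20, 30)
    seef_p: float = 0.60
    k: float = 0.67
    seef_available_prob: float = 0.95
    n_seef_trials: int = 42
    n_persistence_trials: int = 56
    missed_search_prob: float = 0.02
    # operations
    wind_mean_mps: float = 5.7
    wind_weibull_shape: float = 2.8
    turbine_wind_sd: float = 0.25
    cut_in_mps: float = 3.5
    rated_mps: float = 13.5
    rated_power_mw: float = 1.65
    woc_threshold_mps: float = 4.5
    timr_threshold_mps: float = 8.0
    bat_call_prob: float = 0.21
    bat_call_high_wind_factor: float = 0.3
    call_memory_bins: int = 3  # current bin plus previous two = 30 minutes
    price_per_mwh: float = 40.0

    def __post_init__(self) -> None:
        if not (0 <= self.seef_p <= 1 and 0 <= self.k <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(r < 0 for r in self.fatality_rates.values()):
            raise ValueError("fatality rates must be non-negative")
        if min(self.woc_threshold_mps, self.timr_threshold_mps) <= self.cut_in_mps:
            raise ValueError("curtailment thresholds must exceed the cut-in speed")
        for fam, params in self.distance_models.values():
            frozen_distribution(fam, tuple(params))  # validates

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(self.fatality_rates)

    @property
    def plot(self) -> SquarePlot:
        return SquarePlot(self.half_width_m)


@dataclass(frozen=True)
class SimulatedStudy:
    """All generated tables plus the ground-truth record."""

    carcasses: pd.DataFrame        # every true fatality, observed or not
    seef_trials: pd.DataFrame
    persistence_trials: pd.DataFrame
    ops: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def observed_carcasses(self) -> pd.DataFrame:
        """Pipeline-format carcass table: discovered carcasses only."""
        obs = self.carcasses[self.carcasses["observed"].astype(bool)].copy()
        cols = ["carcass_id", "turbine_id", "treatment", "date_found",
                "species", "distance_m", "scheduled_search", "inside_plot"]
        return obs[cols].reset_index(drop=True)


def _power_curve(v: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Cubic power curve: 0 below cut-in, rated at and above the rated speed."""
    v = np.asarray(v, dtype=float)
    ci3, r3 = cfg.cut_in_mps**3, cfg.rated_mps**3
    frac = np.clip((v**3 - ci3) / (r3 - ci3), 0.0, 1.0)
    return cfg.rated_power_mw * frac


def _simulate_carcasses(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    a = cfg.half_width_m
    pers = _persistence_frozen(cfg.persistence_family, cfg.persistence_params)
    rows = []
    cid = 0
    for treatment in cfg.treatments:
        rate = cfg.fatality_rates[treatment]
        family, params = cfg.distance_models[treatment]
        fall = frozen_distribution(family, tuple(params))
        for turbine in range(cfg.n_turbines):
            turbine_id = f"{treatment}-{turbine + 1:02d}"
            # realized search days for this turbine (2% of mornings missed)
            searched = rng.random(cfg.season_nights) >= cfg.missed_search_prob
            search_days = np.nonzero(searched)[0] + 1.0  # morning after night i
            n_fat = rng.poisson(rate)
            nights = rng.integers(0, cfg.season_nights, n_fat)
            arrivals = nights + rng.random(n_fat)
            distances = fall.rvs(n_fat, random_state=rng)
            angles = rng.uniform(0.0, 2.0 * np.pi, n_fat)
            removals = pers.rvs(n_fat, random_state=rng)
            for i in range(n_fat):
                cid += 1
                x, y = distances[i] * np.cos(angles[i]), distances[i] * np.sin(angles[i])
                inside = bool(abs(x) <= a and abs(y) <= a)
                observed, found_day = False, np.nan
                if inside:
                    opportunity = 0
                    for day in search_days[search_days > arrivals[i]]:
                        age = day - arrivals[i]
                        if age >= removals[i]:
                            break
                        opportunity += 1
                        if rng.random() < cfg.seef_p * cfg.k ** (opportunity - 1):
                            observed, found_day = True, day
                            break
                rows.append({
                    "carcass_id": f"C{cid:04d}",
                    "turbine_id": turbine_id,
                    "treatment": treatment,
                    "night": int(nights[i]),
                    "species": rng.choice(_SPECIES, p=_SPECIES_P),
                    "distance_m": float(distances[i]),
                    "angle_rad": float(angles[i]),
                    "inside_plot": inside,
                    "removal_days": float(removals[i]),
                    "observed": observed,
                    "date_found": (cfg.season_start + timedelta(days=float(found_day))
                                   if observed else pd.NaT),
                    "scheduled_search": observed,
                })
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=[
            "carcass_id", "turbine_id", "treatment", "night", "species",
            "distance_m", "angle_rad", "inside_plot", "removal_days",
            "observed", "date_found", "scheduled_search"])
    return df


def _simulate_seef_trials(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_seef_trials
    available = rng.random(n) < cfg.seef_available_prob
    found = available & (rng.random(n) < cfg.seef_p)
    days = np.sort(rng.integers(0, cfg.season_nights, n))
    return pd.DataFrame({
        "carcass_id": [f"S{i + 1:03d}" for i in range(n)],
        "date": [cfg.season_start + timedelta(days=int(d)) for d in days],
        "available": available,
        "found": found,
    })


def _simulate_persistence_trials(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    pers = _persistence_frozen(cfg.persistence_family, cfg.persistence_params)
    times = pers.rvs(cfg.n_persistence_trials, random_state=rng)
    checks = np.asarray(cfg.persistence_check_days, dtype=float)
    rows = []
    for i, t in enumerate(times):
        gone = checks[checks >= t]
        if gone.size:
            first_absent = float(gone[0])
            before = checks[checks < t]
            last_present = float(before[-1]) if before.size else 0.0
            censored = False
        else:
            last_present, first_absent, censored = float(checks[-1]), np.inf, True
        rows.append({
            "carcass_id": f"P{i + 1:03d}",
            "last_present_d": last_present,
            "first_absent_d": first_absent,
            "censored": censored,
        })
    return pd.DataFrame(rows)


def simulate_ops(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """10-minute in-window operation records for every study turbine.

    A facility-level wind draw is shared by all turbines (plus small
    per-turbine noise); curtailment flags follow each treatment's rule and
    energy comes from the cubic power curve.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scale = cfg.wind_mean_mps / gamma_fn(1.0 + 1.0 / cfg.wind_weibull_shape)

    bins_per_night = [72 if n < 48 else 78 for n in range(cfg.season_nights)]
    starts = []
    for night, nb in enumerate(bins_per_night):
        t0 = pd.Timestamp(cfg.season_start) + pd.Timedelta(days=night, hours=18)
        starts.append(t0 + pd.to_timedelta(np.arange(nb) * 10, unit="m"))
    timestamps = pd.DatetimeIndex(np.concatenate([s.values for s in starts]))
    n_bins = len(timestamps)

    wind = scale * rng.weibull(cfg.wind_weibull_shape, n_bins)
    call_p = np.where(wind < cfg.timr_threshold_mps,
                      cfg.bat_call_prob,
                      cfg.bat_call_prob * cfg.bat_call_high_wind_factor)
    calls = rng.random(n_bins) < call_p
    # a call is "active" for call_memory_bins bins, reset at each night start
    active = np.zeros(n_bins, dtype=bool)
    offset = 0
    for nb in bins_per_night:
        night_calls = calls[offset:offset + nb]
        act = np.zeros(nb, dtype=bool)
        for lag in range(cfg.call_memory_bins):
            act[lag:] |= night_calls[:nb - lag]
        active[offset:offset + nb] = act
        offset += nb

    frames = []
    for treatment in cfg.treatments:
        for turbine in range(cfg.n_turbines):
            w = np.clip(wind + rng.normal(0.0, cfg.turbine_wind_sd, n_bins), 0.0, None)
            if treatment == "WOC":
                curtailed = w < cfg.woc_threshold_mps
            elif treatment == "TIMR":
                curtailed = (w < cfg.timr_threshold_mps) & active
            else:
                curtailed = np.zeros(n_bins, dtype=bool)
            energy = np.where(curtailed, 0.0, _power_curve(w, cfg) / 6.0)
            frames.append(pd.DataFrame({
                "turbine_id": f"{treatment}-{turbine + 1:02d}",
                "treatment": treatment,
                "timestamp": timestamps,
                "wind_speed_mps": w,
                "in_treatment_window": True,
                "curtailed": curtailed,
                "energy_mwh": energy,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    r_carc, r_seef, r_pers, r_ops = rng.spawn(4)

    carcasses = _simulate_carcasses(cfg, r_carc)
    seef = _simulate_seef_trials(cfg, r_seef)
    pers_trials = _simulate_persistence_trials(cfg, r_pers)
    ops = simulate_ops(cfg, r_ops)

    plot = cfg.plot
    pers = _persistence_frozen(cfg.persistence_family, cfg.persistence_params)
    g_search = detection_probability(cfg.seef_p, cfg.k, pers.sf,
                                     n_searches=cfg.season_nights)
    truth: dict = {
        "g_search": g_search,
        "k": cfg.k,
        "seef_p": cfg.seef_p,
        "per_treatment": {},
    }
    for treatment in cfg.treatments:
        family, params = cfg.distance_models[treatment]
        ac = area_correction_from_params(family, tuple(params), plot)
        sub = carcasses[carcasses["treatment"] == treatment] if len(carcasses) else carcasses
        truth["per_treatment"][treatment] = {
            "rate_per_turbine": cfg.fatality_rates[treatment],
            "true_fatalities": int(len(sub)),
            "true_per_turbine": len(sub) / cfg.n_turbines,
            "area_correction": ac,
            "g_total": g_search * ac,
            "distance_family": family,
            "distance_params": tuple(params),
        }
    return SimulatedStudy(carcasses=carcasses, seef_trials=seef,
                          persistence_trials=pers_trials, ops=ops,
                          truth=truth, config=cfg)
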