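"""Input validation, configuration and table I/O for the pipeline.

All tables are plain UTF-8 comma-separated files with a header row and
ISO-8601 dates:

``carcasses.csv``
    carcass_id, turbine_id, treatment, date_found, species, distance_m,
    scheduled_search, inside_plot
``seef_trials.csv``
    carcass_id, date, available, found
``persistence_trials.csv``
    carcass_id, last_present_d, first_absent_d, censored
``ops.csv``
    turbine_id, treatment, timestamp, wind_speed_mps, in_treatment_window,
    curtailed, energy_mwh

Column-name aliases can be supplied in the run configuration to map a
foreign layout onto this schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import PERSISTENCE_FAMILIES, PersistenceTrialSet, SeefTrialSet
from .distance import FAMILIES, DistanceSample
from .geometry import SquarePlot

__all__ = ["RunConfig", "ValidationError", "ValidatedStudy", "validate_inputs", "load_tables"]

CARCASS_COLUMNS = ["carcass_id", "turbine_id", "treatment", "date_found",
                   "species", "distance_m", "scheduled_search", "inside_plot"]
SEEF_COLUMNS = ["carcass_id", "date", "available", "found"]
PERSISTENCE_COLUMNS = ["carcass_id", "last_present_d", "first_absent_d", "censored"]


class ValidationError(ValueError):
    """Raised when an input table violates the schema or value ranges."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    half_width_m: float = 40.0
    distance_families: tuple[str, ...] = FAMILIES
    persistence_families: tuple[str, ...] = PERSISTENCE_FAMILIES
    k: float = 0.67
    k_sensitivity: tuple[float, ...] = (0.5, 0.67, 0.8, 1.0)
    ci_level: float = 0.90
    n_boot: int = 1000
    seed: int = 0
    price_per_mwh: float = 40.0
    turbine_capacity_mw: float = 1.65
    control_treatment: str = "control"
    n_turbines_per_treatment: int = 10
    n_searches: int = 78
    search_interval_days: float = 1.0
    # treatments whose distance fit, when unreliable, is replaced by a fit
    # to the pooled distances of the listed treatments (the two curtailment
    # treatments pool with each other; control plots rarely fail because
    # their distance mode sits well inside the searched radius)
    pool_fallback: dict = field(default_factory=lambda: {
        "TIMR": ("WOC", "TIMR"), "WOC": ("WOC", "TIMR")})
    column_aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_boot < 0:
            raise ValueError("n_boot must be non-negative")
        if not (0.0 <= self.k <= 1.0):
            raise ValueError("k must lie in [0, 1]")

    @property
    def plot(self) -> SquarePlot:
        return SquarePlot(self.half_width_m)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("distance_families", "persistence_families", "k_sensitivity"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "pool_fallback" in raw:
            raw["pool_fallback"] = {k: tuple(v) for k, v in raw["pool_fallback"].items()}
        return cls(**raw)


@dataclass(frozen=True)
class ValidatedStudy:
    """Validated, estimation-ready views of the input tables."""

    carcasses: pd.DataFrame  # inside-plot carcasses only
    turbine_counts: dict[str, tuple[float, ...]]  # per treatment
    distance_samples: dict[str, DistanceSample]
    seef_trials: SeefTrialSet
    persistence_trials: PersistenceTrialSet
    ops: pd.DataFrame | None
    warnings: tuple[str, ...]


def _apply_aliases(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    return df.rename(columns={v: k for k, v in aliases.items()}) if aliases else df


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} is missing columns {missing}")


def validate_inputs(
    carcasses: pd.DataFrame,
    seef_trials: pd.DataFrame,
    persistence_trials: pd.DataFrame,
    config: RunConfig,
    ops: pd.DataFrame | None = None,
) -> ValidatedStudy:
    """Type/range-check input tables and build estimation-ready objects.

    Off-plot carcasses are excluded from estimation with a warning count;
    an inside-plot record at a distance beyond the corner radius, or a
    duplicated carcass id, is an error naming the offending rows.
    """
    warnings: list[str] = []
    tau = config.plot.truncation_distance

    carcasses = _apply_aliases(carcasses.copy(), config.column_aliases)
    _require(carcasses, CARCASS_COLUMNS, "carcasses")
    dup = carcasses["carcass_id"].duplicated()
    if dup.any():
        raise ValidationError(f"duplicate carcass_id at rows {list(carcasses.index[dup])}")
    inside = carcasses["inside_plot"].astype(bool)
    bad = inside & (carcasses["distance_m"].astype(float) >= tau)
    if bad.any():
        raise ValidationError(
            f"carcasses flagged inside_plot at distance >= {tau:.1f} m "
            f"(rows {list(carcasses.index[bad])})"
        )
    if carcasses["distance_m"].astype(float).lt(0).any():
        raise ValidationError("negative carcass distances")
    n_off = int((~inside).sum())
    if n_off:
        warnings.append(f"excluded {n_off} off-plot carcasses from estimation")
    used = carcasses[inside].copy()

    counts: dict[str, tuple[float, ...]] = {}
    samples: dict[str, DistanceSample] = {}
    for treatment, grp in used.groupby("treatment", sort=True):
        by_turbine = grp.groupby("turbine_id").size()
        n_t = max(config.n_turbines_per_treatment, by_turbine.size)
        vec = np.zeros(n_t)
        vec[: by_turbine.size] = by_turbine.to_numpy()
        counts[str(treatment)] = tuple(vec)
        samples[str(treatment)] = DistanceSample(
            tuple(grp["distance_m"].astype(float)), str(treatment))

    seef_trials = _apply_aliases(seef_trials.copy(), config.column_aliases)
    _require(seef_trials, SEEF_COLUMNS, "seef_trials")
    seef = SeefTrialSet(
        tuple(seef_trials["available"].astype(bool)),
        tuple(seef_trials["found"].astype(bool)),
    )

    persistence_trials = _apply_aliases(persistence_trials.copy(), config.column_aliases)
    _require(persistence_trials, PERSISTENCE_COLUMNS, "persistence_trials")
    hi = persistence_trials["first_absent_d"].astype(float).to_numpy()
    hi = np.where(persistence_trials["censored"].astype(bool), np.inf, hi)
    pers = PersistenceTrialSet(
        tuple(persistence_trials["last_present_d"].astype(float)),
        tuple(hi),
    )

    return ValidatedStudy(
        carcasses=used.reset_index(drop=True),
        turbine_counts=counts,
        distance_samples=samples,
        seef_trials=seef,
        persistence_trials=pers,
        ops=ops,
        warnings=tuple(warnings),
    )


def load_tables(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the pipeline CSVs from a directory (ops.csv optional)."""
    data_dir = Path(data_dir)
    out: dict[str, pd.DataFrame] = {}
    for name in ("carcasses", "seef_trials", "persistence_trials"):
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise ValidationError(f"missing input file {path}")
        out[name] = pd.read_csv(path)
    ops_path = data_dir / "ops.csv"
    out["ops"] = pd.read_csv(ops_path, parse_dates=["timestamp"]) if ops_path.exists() else None
    return out
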