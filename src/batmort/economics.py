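"""Curtailment time, energy and revenue accounting.

Summarises 10-minute turbine operation records per treatment group
(curtailed fraction of in-window bins, season energy per turbine, revenue
at a fixed market rate) and computes treatment-difference losses.  Revenue
is energy in MWh times the price per MWh; the published rate for the study
period is $40/MWh.  Monetary values are reported at cent precision with
half-even rounding; energies are kept at full precision internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

__all__ = [
    "OpsSummary",
    "CostComparison",
    "summarize_ops",
    "summaries_from_energy",
    "compare_treatments",
    "loss_ratio",
    "round_currency",
]

OPS_COLUMNS = [
    "turbine_id", "treatment", "timestamp", "wind_speed_mps",
    "in_treatment_window", "curtailed", "energy_mwh",
]


def round_currency(x: float) -> float:
    """Half-even rounding to cents."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class OpsSummary:
    treatment: str
    mean_wind_mps: float
    curtailed_fraction: float
    energy_mwh_per_turbine: float
    revenue_per_turbine: float
    price_per_mwh: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.curtailed_fraction <= 1.0):
            raise ValueError("curtailed_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CostComparison:
    pair: str
    energy_difference_mwh_per_turbine: float
    revenue_difference_per_turbine: float
    percent_loss: float  # proportion of reference energy


def summarize_ops(records: pd.DataFrame, price_per_mwh: float = 40.0) -> dict[str, OpsSummary]:
    """Per-treatment operation summary from 10-minute records.

    Curtailed fraction is computed over in-window bins only; energy is
    summed per turbine then averaged within treatment.
    """
    missing = [c for c in OPS_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"ops records missing columns: {missing}")
    out: dict[str, OpsSummary] = {}
    for treatment, grp in records.groupby("treatment", sort=True):
        in_window = grp[grp["in_treatment_window"].astype(bool)]
        if in_window.empty:
            raise ValueError(f"treatment {treatment!r} has no in-window bins")
        energy = float(grp.groupby("turbine_id")["energy_mwh"].sum().mean())
        out[str(treatment)] = OpsSummary(
            treatment=str(treatment),
            mean_wind_mps=float(in_window["wind_speed_mps"].mean()),
            curtailed_fraction=float(in_window["curtailed"].astype(bool).mean()),
            energy_mwh_per_turbine=energy,
            revenue_per_turbine=energy * price_per_mwh,
            price_per_mwh=price_per_mwh,
        )
    return out


def summaries_from_energy(
    energy_mwh: dict[str, float],
    price_per_mwh: float = 40.0,
    mean_wind: dict[str, float] | None = None,
    curtailed_fraction: dict[str, float] | None = None,
) -> dict[str, OpsSummary]:
    """Build summaries from per-treatment season energies (MWh/turbine),
    e.g. from a published production table."""
    out = {}
    for treatment, e in energy_mwh.items():
        out[treatment] = OpsSummary(
            treatment=treatment,
            mean_wind_mps=(mean_wind or {}).get(treatment, float("nan")),
            curtailed_fraction=(curtailed_fraction or {}).get(treatment, 0.0),
            energy_mwh_per_turbine=float(e),
            revenue_per_turbine=float(e) * price_per_mwh,
            price_per_mwh=price_per_mwh,
        )
    return out


def compare_treatments(ref: OpsSummary, alt: OpsSummary) -> CostComparison:
    """Loss of the alternative treatment relative to the reference."""
    if ref.price_per_mwh != alt.price_per_mwh:
        raise ValueError("summaries must share a price")
    if ref.energy_mwh_per_turbine == 0:
        raise ValueError("reference energy is zero; percent loss undefined")
    de = ref.energy_mwh_per_turbine - alt.energy_mwh_per_turbine
    return CostComparison(
        pair=f"{ref.treatment} vs. {alt.treatment}",
        energy_difference_mwh_per_turbine=de,
        revenue_difference_per_turbine=de * ref.price_per_mwh,
        percent_loss=de / ref.energy_mwh_per_turbine,
    )


def loss_ratio(comp_a: CostComparison, comp_b: CostComparison) -> float:
    """Ratio of revenue losses between two treatment comparisons."""
    if comp_b.revenue_difference_per_turbine == 0:
        raise ValueError("denominator comparison has zero revenue difference")
    return comp_a.revenue_difference_per_turbine / comp_b.revenue_difference_per_turbine
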