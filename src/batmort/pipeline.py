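"""End-to-end orchestration: detection models, distance/area correction
with pooling fallback, fatality estimation with a paired bootstrap,
treatment comparisons and operations economics, collected into a single
machine-readable report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import (
    estimate_seef,
    fit_persistence,
    interval_availability,
    select_persistence_model,
)
from .distance import (
    DistanceSample,
    FitError,
    InsufficientDataError,
    UnreliableFitError,
    area_correction,
    bootstrap_area_correction,
    pool_samples,
    select_distance_model,
    twl_fit,
)
from .economics import compare_treatments, loss_ratio, summarize_ops
from .fatality import (
    StudyInputs,
    TreatmentInputs,
    bootstrap_fatality_ci,
    detection_probability,
    estimate_fatalities,
    fatality_reduction,
    ci_overlap_distinct,
    reduction_ratio,
)
from .io import RunConfig, ValidatedStudy

__all__ = ["StudyReport", "run_pipeline"]


@dataclass(frozen=True)
class StudyReport:
    """All pipeline results plus provenance and accumulated warnings."""

    detection: dict
    distance: dict
    estimates: dict
    comparisons: dict
    operations: dict
    provenance: dict
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=_jsonable)

    def write(self, out_dir: str | Path) -> None:
        """Write report.json plus CSV tables mirroring the study's tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        tables = out / "tables"
        tables.mkdir(exist_ok=True)
        pd.DataFrame(self.distance["fits"]).to_csv(tables / "distance_fits.csv", index=False)
        pd.DataFrame(self.estimates["by_treatment"]).to_csv(tables / "fatality_estimates.csv", index=False)
        pd.DataFrame(self.comparisons["reductions"]).to_csv(tables / "reductions.csv", index=False)
        if self.operations:
            pd.DataFrame(self.operations["summaries"]).to_csv(tables / "ops_summaries.csv", index=False)
            pd.DataFrame(self.operations["losses"]).to_csv(tables / "power_losses.csv", index=False)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Timestamp):
        return x.isoformat()
    return str(x)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=_jsonable)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fit_distance_stage(study: ValidatedStudy, config: RunConfig, warnings: list[str]):
    """Per-treatment family fits with AICc selection and pooling fallback.

    Returns selected fits keyed by *distance sample key* and the mapping
    treatment -> key ('pooled:<members>' when the fallback engaged).
    """
    plot = config.plot
    selected: dict[str, dict] = {}
    assignment: dict[str, str] = {}
    fit_rows: list[dict] = []

    def fit_sample(sample: DistanceSample) -> tuple:
        fits = []
        for family in config.distance_families:
            try:
                f = twl_fit(sample, family, plot)
            except (FitError, InsufficientDataError) as err:
                warnings.append(f"{sample.treatment_label}: {family} fit failed ({err})")
                continue
            fits.append(f)
            fit_rows.append({
                "sample": sample.treatment_label, "n": f.n, "family": f.family,
                "shape": f.shape, "scale": f.scale, "aicc": f.aicc,
                "mode_m": f.mode_m, "reliable": f.reliable,
            })
        return fits

    for treatment, sample in study.distance_samples.items():
        fits = fit_sample(sample)
        try:
            best = select_distance_model(fits)
        except UnreliableFitError:
            # fall back to the configured pooled sample; if that also has no
            # reliable fit, pool across every treatment as a last resort
            members = config.pool_fallback.get(treatment)
            candidates = []
            if members:
                candidates.append(tuple(members))
            all_members = tuple(sorted(study.distance_samples))
            if all_members not in candidates:
                candidates.append(all_members)
            pooled_best = None
            for cand in candidates:
                key = "pooled:" + "+".join(cand)
                if key in selected:
                    pooled_best = selected[key]["fit"]
                    break
                pooled = pool_samples([study.distance_samples[m] for m in cand], key)
                try:
                    pooled_best = select_distance_model(fit_sample(pooled))
                except UnreliableFitError:
                    continue
                selected[key] = {"sample": pooled, "fit": pooled_best, "pooled": True}
                break
            if pooled_best is None:
                raise
            warnings.append(
                f"{treatment}: no reliable distance fit; using pooled sample {key}"
            )
            assignment[treatment] = key
            continue
        selected[treatment] = {"sample": sample, "fit": best, "pooled": False}
        assignment[treatment] = treatment
    return selected, assignment, fit_rows


def run_pipeline(study: ValidatedStudy, config: RunConfig) -> StudyReport:
    """Execute detection -> distance/area-correction -> fatality estimation
    -> comparisons -> operations economics; deterministic given the seed."""
    warnings = list(study.warnings)
    rng = np.random.default_rng(config.seed)
    seed_ac, seed_fat = (int(s.integers(0, 2**31 - 1)) for s in rng.spawn(2))

    # --- detection models --------------------------------------------------
    seef = estimate_seef(study.seef_trials, ci_level=config.ci_level, k=config.k)
    pers_fits = [fit_persistence(study.persistence_trials, fam)
                 for fam in config.persistence_families]
    pers = select_persistence_model(pers_fits)
    r_daily = interval_availability(pers, config.search_interval_days)
    g_search = detection_probability(
        seef.p, config.k, pers.survival,
        n_searches=config.n_searches, interval=config.search_interval_days)

    detection_report = {
        "seef": {"p": seef.p, "ci": (seef.ci_lower, seef.ci_upper),
                 "k": config.k, "n_available": seef.n_available, "n_found": seef.n_found},
        "persistence": {
            "family": pers.family, "params": pers.params, "aicc": pers.aicc,
            "median_days": pers.median_days, "r_daily": r_daily,
            "candidates": [{"family": f.family, "aicc": f.aicc,
                            "median_days": f.median_days} for f in pers_fits],
        },
        "g_search": g_search,
    }

    # --- distance fits and area corrections --------------------------------
    selected, assignment, fit_rows = _fit_distance_stage(study, config, warnings)
    ac_results: dict[str, dict] = {}
    for key, entry in selected.items():
        fit = entry["fit"]
        if config.n_boot > 0:
            ac = bootstrap_area_correction(
                entry["sample"], fit.family, config.plot,
                n_boot=config.n_boot, ci_level=config.ci_level, seed=seed_ac)
            warnings.extend(f"{key}: {w}" for w in ac.warnings)
            ac_results[key] = {"estimate": ac.estimate, "ci": (ac.ci_lower, ac.ci_upper),
                               "n_bootstrap": ac.n_bootstrap, "pooled": entry["pooled"]}
        else:
            est = area_correction(fit, config.plot, force=True)
            ac_results[key] = {"estimate": est, "ci": (np.nan, np.nan),
                               "n_bootstrap": 0, "pooled": entry["pooled"]}

    distance_report = {
        "fits": fit_rows,
        "selected": {key: {
            "family": e["fit"].family, "shape": e["fit"].shape, "scale": e["fit"].scale,
            "aicc": e["fit"].aicc, "n": e["fit"].n, "mode_m": e["fit"].mode_m,
            "pooled": e["pooled"],
        } for key, e in selected.items()},
        "area_correction": ac_results,
        "assignment": assignment,
    }

    # --- fatality estimates -------------------------------------------------
    inputs = StudyInputs(
        treatments={
            t: TreatmentInputs(study.turbine_counts[t], assignment[t])
            for t in study.turbine_counts
        },
        distance_samples={key: (e["sample"], e["fit"].family) for key, e in selected.items()},
        seef_trials=study.seef_trials,
        persistence_trials=study.persistence_trials,
        persistence_family=pers.family,
        k=config.k,
        plot=config.plot,
        capacity_mw=config.turbine_capacity_mw,
        n_searches=config.n_searches,
        interval=config.search_interval_days,
        control=config.control_treatment,
    )
    estimates: dict[str, dict] = {}
    point = {}
    for t, tr in inputs.treatments.items():
        est = estimate_fatalities(
            tr.count, g_search, ac_results[tr.distance_key]["estimate"],
            tr.n_turbines, capacity_mw=config.turbine_capacity_mw, treatment=t)
        point[t] = est
        estimates[t] = {
            "treatment": t,
            "observed_per_turbine": est.observed_per_turbine,
            "g_search": est.g_search, "g_total": est.g_total,
            "m_per_turbine": est.m_per_turbine, "m_per_mw": est.m_per_mw,
        }

    boot = None
    if config.n_boot > 0:
        boot = bootstrap_fatality_ci(inputs, n_boot=config.n_boot,
                                     ci_level=config.ci_level, seed=seed_fat)
        warnings.extend(boot.warnings)
        for t in estimates:
            estimates[t]["m_per_turbine_ci"] = boot.m_per_turbine_ci(t)
            estimates[t]["m_per_mw_ci"] = boot.m_per_mw_ci(t)

    # k-sensitivity sweep (point estimates only)
    sensitivity = []
    for k_alt in config.k_sensitivity:
        g_alt = detection_probability(seef.p, k_alt, pers.survival,
                                      n_searches=config.n_searches,
                                      interval=config.search_interval_days)
        for t, tr in inputs.treatments.items():
            m_alt = estimate_fatalities(
                tr.count, g_alt, ac_results[tr.distance_key]["estimate"],
                tr.n_turbines, capacity_mw=config.turbine_capacity_mw, treatment=t)
            sensitivity.append({"k": k_alt, "treatment": t,
                                "m_per_turbine": m_alt.m_per_turbine})

    # --- comparisons --------------------------------------------------------
    control = config.control_treatment
    others = [t for t in estimates if t != control]
    reductions = []
    for t in others:
        row = {
            "pair": f"{control} vs. {t}",
            "treatment": t,
            "reduction": fatality_reduction(point[control].m_per_turbine,
                                            point[t].m_per_turbine),
        }
        if boot is not None:
            row["ci"] = boot.reduction_ci(control, t)
            row["distinct_from_control"] = ci_overlap_distinct(
                boot.m_per_turbine_ci(control), boot.m_per_turbine_ci(t))
        reductions.append(row)
    ratios = []
    for t1 in others:
        for t2 in others:
            if t1 == t2:
                continue
            try:
                ratio = reduction_ratio(point[control].m_per_turbine,
                                        point[t1].m_per_turbine,
                                        point[t2].m_per_turbine)
            except ValueError:
                continue
            row = {"numerator": t1, "denominator": t2, "ratio": ratio}
            if boot is not None:
                row["ci"] = boot.ratio_ci(control, t1, t2)
            ratios.append(row)
    comparisons = {"reductions": reductions, "reduction_ratios": ratios,
                   "k_sensitivity": sensitivity}

    # --- operations economics ----------------------------------------------
    operations: dict = {}
    if study.ops is not None:
        summaries = summarize_ops(study.ops, price_per_mwh=config.price_per_mwh)
        losses = []
        comps = {}
        for t in others:
            comp = compare_treatments(summaries[control], summaries[t])
            comps[t] = comp
            losses.append({
                "pair": comp.pair,
                "energy_difference_mwh_per_turbine": comp.energy_difference_mwh_per_turbine,
                "revenue_difference_per_turbine": comp.revenue_difference_per_turbine,
                "percent_loss": comp.percent_loss,
            })
        ratio_rows = []
        for t1 in others:
            for t2 in others:
                if t1 != t2 and comps[t2].revenue_difference_per_turbine != 0:
                    ratio_rows.append({
                        "numerator": t1, "denominator": t2,
                        "loss_ratio": loss_ratio(comps[t1], comps[t2]),
                    })
        operations = {
            "summaries": [asdict(s) for s in summaries.values()],
            "losses": losses,
            "loss_ratios": ratio_rows,
        }

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_boot": config.n_boot,
        "ci_level": config.ci_level,
    }
    return StudyReport(
        detection=detection_report,
        distance=distance_report,
        estimates={"by_treatment": list(estimates.values()), "control": control},
        comparisons=comparisons,
        operations=operations,
        provenance=provenance,
        warnings=tuple(warnings),
    )
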