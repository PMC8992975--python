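# batmort

Detection-adjusted bat fatality estimation and curtailment cost-benefit
accounting for wind energy facilities.

Carcass counts under wind turbines wildly understate bat mortality:
searchers miss carcasses (searcher efficiency *p*, decaying as *p, pk,
pk², …* over repeated searches), scavengers remove them (persistence
survival *S(t)*), and many fall outside the searched plot entirely (area
correction, AC).  This package implements the full estimation chain for a
three-arm curtailment experiment — control turbines vs wind-speed-only
curtailment (WOC, feathered below 4.5 m/s) vs acoustic-informed
curtailment (TIMR, feathered below 8.0 m/s when a bat call occurred in the
last 30 minutes) — together with the energy and revenue cost of each
strategy.

The core estimator is a Horvitz–Thompson count adjustment

```
M̂ = C / (n_turbines · g_search · AC),
g_search = Σ_m P(persist to search m) · p k^(m−1) · Π_(l<m) (1 − p k^(l−1)),
```

with the area correction obtained by fitting carcass fall-distance
densities (gamma, Gompertz, Rayleigh, truncated normal, Weibull) to
right-truncated distances by **truncated weighted likelihood** — each
observation weighted by the inverse of the fraction of the circle at its
distance that lies inside the square 80 m × 80 m plot — selecting by AICc,
and summing predicted annulus mass × searched annulus fraction out to the
plot corner radius 40·√2 ≈ 56.6 m.  Persistence is fitted to
interval-censored trial check histories; uncertainty comes from a paired
nonparametric bootstrap over every estimated component.  A synthetic-study
generator with known ground truth (fall distances, removal times,
per-search detections, 10-minute turbine operations) stands in for field
data, so every stage is testable against a recoverable truth.

See `docs/methods.md` for the model, its assumptions and known
limitations (the TWL area correction is consistent but heavily skewed at
field sample sizes, and its bootstrap interval undercovers — both
documented and pinned by tests).

## Worked example

The analysis is organised as numbered drivers over the library:

```
python analysis/01_simulate_study.py      # synthetic study -> scratch/synthetic_study/
python analysis/02_detection_models.py    # p, persistence families, AICc, r
python analysis/03_distance_fits.py       # TWL fits, area corrections + bootstrap CIs
python analysis/04_fatality_estimates.py  # adjusted fatalities, reductions, k-sweep
python analysis/05_curtailment_economics.py
```

Step 02 prints, for the default synthetic study:

```
Searcher efficiency: p = 0.62 (90% CI 0.48-0.73, 24/39 found; k = 0.67 supplied)
Persistence: lognormal selected by AICc (median 7.0 d; daily availability r = 0.914)
```

i.e. searchers found 62% of available trial carcasses, and a carcass
arriving overnight has a ~91% chance of persisting to the next morning's
search.  Step 03 shows both the synthetic fits and what the published
Gompertz parameter sets imply:

```
control: gompertz (mode 26.5 m) AC = 0.954 (90% CI 0.929-0.975)
Area corrections implied by the published Gompertz fits:
  control: 0.946 (published 0.92)
  WOC: 0.760 (published 0.72)
```

— about 95% of carcasses at control turbines fall inside the plot, but
curtailed turbines throw carcasses further (higher collision wind speeds),
so their correction is smaller and far less certain.  In this particular
synthetic season the WOC distance sample is dragged outward by two
carcasses found near the plot corner (which carry TWL weights of 7–8), a
fragility of truncated-sample fitting that the study itself encountered
and that shows up here as wide bootstrap CIs and a warning about failed
replicates.  Step 05 recomputes the published season production table:

```
control vs. WOC: 32.3 MWh, $1,291.76 (5.3% of control energy)
control vs. TIMR: 89.8 MWh, $3,591.84 (14.8% of control energy)
TIMR losses are 2.78 times WOC losses per turbine
```

The acoustic-informed strategy roughly doubles the fatality reduction of
plain wind-speed curtailment, at about 2.8 times its revenue cost.

A thin CLI wraps the same pipeline: `batmort simulate`, `batmort
validate`, `batmort run` (see `batmort --help`).

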