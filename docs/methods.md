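# Methods

This package re-implements, as a tested pipeline, the estimation framework
of a controlled wind-turbine curtailment experiment: detection-adjusted
bat fatality estimation on square search plots, and energy/revenue
accounting for two curtailment strategies (wind-speed-only curtailment,
WOC, feathering below 4.5 m/s; and acoustic-informed curtailment, TIMR,
feathering below 8.0 m/s when a bat call was detected within the previous
30 minutes) against uncurtailed control turbines.  Because the original
field data are not redistributed with the package, a synthetic-study
generator with known ground truth stands in for them; the published
summary tables of the study are shipped as frozen constants for arithmetic
checks and worked examples.

## The estimator

A carcass produced at a turbine is observed only if it

1. falls inside the searched plot (area correction, AC),
2. persists to at least one search (carcass persistence, survival S(t)),
3. is found on a search while present (searcher efficiency p, decaying by
   a factor k on each successive search: p, pk, pk², …).

The per-carcass season-level detection probability inside the plot is

    g_search = Σ_m  P(persist to search m) · p k^{m−1} · Π_{l<m} (1 − p k^{l−1}),

with arrivals uniform within a night, so P(persist to search m) =
∫₀¹ S(u + (m−1)I) du for a daily interval I = 1 d.  The series is
truncated when terms fall below 1e−10; realized (gappy) search schedules
are handled by passing explicit search offsets.  The adjusted count is the
Horvitz–Thompson estimate

    M̂ = C / (n_turbines · g_search · AC),

which satisfies M̂ · n_turbines · g_total = C exactly.

### Searcher efficiency

p is the proportion of trial carcasses found among those still available
at the search, with a Wilson score interval (the Wilson interval is a
documented, swappable choice; the study does not state its CI method).
Single-search trials cannot identify k, so k is a required input, default
0.67, and every pipeline run reports a sensitivity sweep over
k ∈ {0.5, 0.67, 0.8, 1.0}.  Exposing the unidentifiable k is deliberate:
adjusted fatality levels move by roughly ±10% across this sweep while
treatment *ratios* are nearly invariant, because g_search is shared
between treatments and cancels.

### Carcass persistence

Removal times are observed only through interval-censored check histories
(daily for four days, then days 7, 10, 14, 20 and 30, censored at 30 d).
Four families — exponential, Weibull, lognormal, log-logistic — are fitted
by maximizing Σ_removed log[S(t_lo) − S(t_hi)] + Σ_censored log S(t_cens)
and compared by AICc (k parameters, n carcasses).  A carcass never seen
after placement contributes the interval (0, first check].  The likelihood
is written in closed form (scipy.special primitives) because the
downstream bootstrap refits it tens of thousands of times; the fits agree
with lifelines' interval-censoring fitter to ~1e−4, which the test suite
checks.  The derived availability r = (1/I)∫₀^I S(u) du is computed by
adaptive quadrature.

### Distance distributions and area correction

Observed carcass distances are right-truncated at the plot corner radius
τ = a√2 (56.57 m for a = 40 m half-width) and thinned beyond a because
only the plot corners are searched there.  Five families — gamma,
Gompertz, Rayleigh, truncated normal, Weibull — are fitted by truncated
weighted likelihood (TWL): each observation is weighted by the inverse of
its inclusion probability ψ(d) (the fraction of the circle of radius d
inside the square), weights normalized to sum to n, and the likelihood is
normalized by F(τ).  AICc (raw n) selects the family.  The Gompertz uses
the hazard parametrization h(x) = λe^{bx} (shape b, scale λ), which
places the printed parameter sets' modes at 28.1 / 37.2 / 47.2 m,
consistent with the study's distance histograms.

The area correction is the annulus sum Σ_i [F(i+1) − F(i)] · s_i over 1-m
annuli [i, i+1) (the last truncated at τ), where s_i is the searched
*area* fraction of the annulus.  Area fractions are the canonical choice
(the searched-fraction of an annulus is an area statement); the
circumference fraction ψ is retained for TWL weights, which apply at a
point distance.  The two differ by <0.001 in the resulting AC.

**Reliability.**  TWL fitting fails when the truncated sample does not
contain the distribution's mode.  A fit is flagged unreliable when its
mode is ≥ 0.95τ, when the fitted scale collapses to an optimizer bound,
or when the fitted family puts less than 5% of its mass inside τ (the
"implausibly low area correction" failure).  When no family fits a
treatment reliably, the pipeline pools that treatment's distances with its
partner curtailment treatment (configurable; default pools WOC and TIMR
with each other, the study's own remedy) and tags the result as pooled.

**Small-sample behaviour.**  The TWL/AC estimator is consistent (simulated
bias vanishes by n ≈ 2000) but strongly right-skewed at field sample
sizes: at n ≈ 90 from a Gompertz with mode 37 m, the AC estimate has
sd ≈ 0.2 and its median sits ≈ 0.06 above the truth, because low-AC fits
are exactly the ones the reliability rule rejects.  Consequently the
plain percentile bootstrap CI for AC (resampling distances, refitting the
selected family, dropping unreliable replicates) undercovers: measured
coverage of the nominal 90% interval is ≈ 75% at n = 187 in simulation.
This is a property of the published procedure, which the package
reproduces rather than repairs; the test suite pins the measured coverage,
and the limitation matters mostly for the curtailment treatments, whose
carcasses fall nearest the truncation radius.

### Uncertainty for fatality estimates

Fatality CIs come from a paired nonparametric bootstrap: each replicate
resamples the SEEF trial outcomes, the persistence trial carcasses (refit
of the selected family), every distance sample (TWL refit of the selected
family), and per-turbine carcass counts (resampling turbines with
replacement), then recomputes every treatment's M̂ and all comparisons on
the same draw.  Percentile intervals are taken over replicates; paired
resampling lets the shared detection components cancel in reductions, so
comparison CIs are narrower than an unpaired combination (tested).
Replicates whose refits fail or are unreliable are dropped and counted,
with a warning above 20%.  Treatments are "different" when their 90% CIs
do not overlap (closed intervals; touching endpoints overlap); no
multiple-testing adjustment is applied, matching the study's rule.
Degenerate inputs (a single turbine, identical trials and distances)
collapse the CI to a point, including for a zero carcass count.

### Economics

Per treatment: curtailed fraction of in-window 10-minute bins, season
energy summed per turbine then averaged, and revenue = energy × $40/MWh
(the study's phrasing is "$40/MW", but its revenue column equals energy in
MWh × 40, so the price is interpreted per MWh).  Treatment differences are
taken on full-precision energies; money is reported at cent precision with
half-even rounding.  The published production table rounds energy to
0.1 MWh but prints exact revenues, so full-precision energies are
recovered as revenue/40 when the table is used as input.  Computed from
those energies, the control-vs-TIMR revenue difference is $3,591.84; the
study's Table prints $3,597.84, which is inconsistent with its own
energies (89.8 MWh × $40), and the pipeline reports the computed value.

## Synthetic-study generator

Defaults are the study conditions: 3 × 10 turbines, 78 nights
(2015-07-15 to 2015-09-30), 80 m × 80 m plots, daily searches with 2% of
turbine-mornings missed; true fatality rates 26.28 / 14.12 / 6.62 per
turbine per season (the study's adjusted estimates), which reproduce
observed counts of the order 187 / 78 / 31 after detection losses;
Gompertz fall distances with the printed parameter sets (control and WOC)
and the printed pooled set for TIMR (mode 47.2 m, inside the plausible
25–50 m range); lognormal persistence with median 8.7 d; searcher
efficiency 0.60 (42 trial carcasses, 95% available) and k = 0.67; 56
persistence trial carcasses read through the check schedule.

Two generator parameters are calibrated rather than copied:

* persistence log-sd = 1.85, chosen so the daily availability r equals
  the study's 94%; this value also reproduces the printed 90% CI of the
  median (5.6, 13.3) d almost exactly at n = 56, whereas a narrower
  log-sd would not;
* night winds are Weibull with mean 5.7 m/s and shape 2.8, chosen so the
  WOC rule curtails ≈ 31% of in-window bins (the study's observed
  fraction); the bat-call process (flat 0.21 per-bin call probability
  below 8 m/s, ×0.3 above, 30-minute hold) then yields ≈ 39.4% TIMR
  curtailment.  Bat activity is a placeholder Bernoulli process, not a
  biological claim.

Detection in the generator is simulated per carcass per search with
probability p·k^{m−1} while the carcass persists and lies inside the
plot, so the generator shares no code path with the estimator's g
computation; their agreement (within Monte-Carlo error at 10⁵ carcasses)
is an end-to-end check in the test suite.

What the generator does not emulate: within-season arrival pulses (the
study saw an August peak), carcass-level covariates (species size,
visibility), weather-coupled bat activity, off-window turbine operation
(synthetic ops cover the treatment window only, so synthetic percent
energy losses are relative to nighttime energy, unlike the published
whole-period table), and spatial anisotropy of carcass falls.  Passing
recovery tests therefore show the estimator is correct *under the model's
assumptions*, not that those assumptions hold in any particular field
data set.

## Numerical choices

* Optimizers: Nelder–Mead on log-transformed (positivity-constrained)
  parameters, five deterministic moment-based starts (plus a warm start
  inside bootstrap loops, which then skip the multi-start sweep);
  objective tolerance 1e−8 (1e−7 warm).
* Likelihood guards: truncation masses below 1e−9 and non-finite values
  return a large penalty, which prevents an underflow-driven divergence
  of the truncated-normal TWL objective when sd → ∞.
* Density modes are located on a 4097-point grid over [0, 2τ].
* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), infinite when n ≤ k+1; ties broken
  by fewer parameters, then lexicographic family name.
* Seeds: a single integer seed per run; sub-streams are spawned
  deterministically (numpy SeedSequence), so reports are byte-identical
  under a fixed seed and config.

## Known limitations

* AC interval undercoverage at field sample sizes (see above).
* Adjusted fatality estimates for the curtailment treatments inherit a
  downward median bias at small n: upward-skewed AC estimates (and the
  pooled-AC fallback, whose pooled value exceeds the TIMR-specific truth)
  deflate M̂; the study itself notes its TIMR estimate "may be
  artificially low" for the same reason.
* k is unidentifiable from single-search trials; levels (not ratios) of
  adjusted fatalities depend on the supplied value.
* The season-level g uses no temporal covariates; arrival is uniform over
  nights.
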