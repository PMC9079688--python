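# Methods

## Model and assumptions

The pipeline is a comparative risk assessment: disease burden is the part
of observed incidence that a log-linear concentration-response (C-R)
function attributes to NO₂ exposure above a low-concentration threshold.
Its key assumptions are those of any such assessment:

* the C-R function estimated on *ambient* NO₂ transfers to total exposure
  once exposure is rescaled to an equivalent ambient concentration by the
  exposure factor (RR is evaluated at `C_exp / f_exp`, converted with
  ppb = 0.487 × µg/m³);
* source contributions act proportionally: a source's share of
  attributable cases equals its share of exposure concentration
  (`PS_ambient : PS_cooking : PS_SHS`, with the SHS term weighted by the
  population proportion exposed to second-hand smoke);
* scenario effects are evaluated on the same population via the potential
  impact fraction, i.e. baseline incidence and population are held fixed.

The second-hand-smoke concentration is derived as the excess of a smoking
household's indoor-source exposure over its cooking exposure; a negative
excess (possible from noise in upstream exposure modeling) is clamped to
zero with a warning, because a negative source concentration is
physically meaningless.

For the outdoor restriction scenarios, the condition "outdoor air meets
the target" applies to the *outdoor concentration*, while the tables store
outdoor-*source exposure*; the 2019 outdoor level is therefore recovered
as `ambient_mean / f_exp` before comparison with the target, and capped
strata get exposure `target × f_exp`. The SD of a capped stratum is scaled
by the same ratio as the mean (constant coefficient of variation): whether
the original analysis rescaled scenario SDs is unknowable from the outputs
alone, and preserving relative variability is the conservative choice. The
smoking ban is represented as `P_SHS = 0` — a mixture-weight change, not a
concentration edit — which matches how the SHS term enters every formula.

`P_SHS` is stored per province and applied to all strata in the province;
a per-group override is possible by supplying a group-level `p_shs` column
upstream of assembly.

## Two-stage Monte Carlo

* **Inner (variability) stage** — per stratum and household type,
  individual exposure is drawn per source from a lognormal matched to the
  tabulated mean/SD (concentrations are positive and right-skewed; a
  zero-truncated normal is available via `MCConfig.exposure_family`).
  Per-source draws are summed to total exposure; the RR of each draw is
  averaged to the population-level R̄R. Default 2000 draws.
* **Outer (uncertainty) stage** — RR₀ is lognormal with median 1.26 and
  log-scale set so the 2.5th/97.5th quantiles match 1.10–1.37 (positivity
  plus the asymmetric printed interval make lognormal the natural family);
  LC is triangular(0, 2, 5) ppb, keeping the stated mode inside the stated
  range (uniform(0, 5) is available but its mean 2.5 shifts the centre);
  baseline incidence, direct cost and treatment days get national
  multiplicative factors drawn from a normal with mean 1, CV 0.1,
  truncated at 0. A single national factor (rather than independent
  per-group draws) is used because independent draws would cancel in
  national aggregates and understate uncertainty; the factors for
  incidence, cost and days are drawn independently of one another.
  Default 1000 draws.

The LC and RR₀ values of an uncertainty draw are held fixed across that
draw's variability average. Variability draws are *shared* between the
baseline and every scenario within a repeat (common random numbers):
scenario contrasts (PIF) then measure the transformation, not sampling
noise, and the ordering IT1 ≤ IT2 ≤ IT3 ≤ AQG holds draw by draw.

Summary statistics are the mean and the 2.5th–97.5th percentiles over
uncertainty draws, with linear interpolation between order statistics
(`numpy.percentile` default), so intervals are bit-reproducible given a
seed. Strata are processed in city-aligned chunks: peak memory is
proportional to chunk size × variability draws, never strata × draws ×
uncertainty. RR exponentiation is done in log space.

Note one structural consequence of the common-random-numbers design: the
smoking-ban reduction can exceed the SHS-attributed caseload, because the
source attribution is proportional to concentration shares while the
scenario contrast removes the (convex) risk contribution of the smoking
household branch entirely.

## Synthetic study population

The real exposure/population tables are not redistributable, so the
generator emulates their structure: 330 cities in 31 provinces; city-level
outdoor-source exposure means uniform on 8–35 µg/m³; the cooking share of
(cooking + ambient) exposure linear in latitude, averaging 0.25
nationally and higher in the north; a small city-level SHS increment
(0.5–2.5 µg/m³, so tobacco contributes a percent or two of exposure);
within-stratum CV 0.3; heavy-tailed (lognormal, σ = 1) city sizes
normalized to 177 million urban children; incidence declining with age
and higher in boys (12–4 per 1000/year); exposure factors 0.5–0.9 and
SHS-exposure proportions 0.3–0.6 by province; direct costs 900–1600 RMB,
treatment 2–5 days, daily per-capita GDP 150–450 RMB mildly correlated
with city size. Each table comes from an independent child stream of one
seed, so bundles are bit-reproducible.

What the generator does **not** emulate: spatial correlation between
neighbouring cities, correlation between exposure and incidence,
seasonality, within-province heterogeneity of f_exp, or the real
magnitudes of any particular Chinese city. Passing tests therefore
demonstrate the correctness and stability of the *method* on structurally
realistic inputs, not agreement with any city's actual burden.

## Numerical and design choices

* The printed unit relation between ppb and µg/m³ for NO₂ is implemented
  as ppb = 0.487 × µg/m³ (the standard mass-to-mixing-ratio conversion);
  the opposite reading would put typical urban exposures at hundreds of
  ppb and produce absurd risks. The factor is a config field.
* PAF is undefined below R̄R = 1; the C-R function cannot produce such
  values, so they are rejected as corrupt input (an opt-in flag floors
  them instead). Scenario UIs are *not* truncated at zero: with household
  heterogeneity a smoking-ban draw can be marginally negative.
* Degenerate inputs collapse exactly: zero SDs plus point parameters give
  zero-width intervals equal to the closed-form pipeline
  (`deterministic_burden`), which the tests verify to machine precision.
* Costs are aggregated at stratum level so age/sex costs and city GDP bind
  before summation; nominal 2019 RMB, no discounting.
* Chunk size (`MCConfig.chunk_groups`) is part of the configuration: it
  changes the order in which variability draws are consumed, so outputs
  are reproducible for a fixed configuration + seed.

## Problem sizes used by the shipped checks

The repeated-simulation stability check reported by
`scripts/acceptance.py` keeps the full 330-city population and 250
repeats, and uses 100 variability × 400 uncertainty draws per repeat —
sizes chosen so the whole check runs in minutes on one core. The
uncertainty stage keeps the larger count because it dominates the
repeat-to-repeat spread of the national estimate; the variability stage
averages across ~8000 strata and contributes little. The test suite's
stability test uses a 50-city fixture with 100 repeats for the same
reason. The interactive defaults remain 2000 × 1000 × 250.

## Known limitations

* Source proportions are computed from concentration means, so
  within-stratum correlation between sources is ignored (none is supplied
  by the input schema).
* The C-R function is the single log-linear form; no spline or sublinear
  alternatives.
* Scenario combinations (e.g. EC + AQG jointly) are not composed; each
  scenario is evaluated against baseline alone.
* The cost model is cost-of-illness only — no willingness-to-pay
  valuation — and the indirect component prices caregiver time at daily
  per-capita GDP, which understates costs where wages exceed GDP per
  capita.
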