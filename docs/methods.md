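# Methods

## Exposure model

Per-capita dietary MeHg exposure for a country's general population is the
sum over pathways of daily intake (g/person/day) times MeHg concentration
(μg/g): four trophic-level bins each for seafood and freshwater fish, plus a
single rice term. Everything downstream is linear in both tables, which the
engine exploits (see *Numerical choices*).

Assumptions inherited from the modelling tradition this follows:

* Only seafood, freshwater fish and rice matter; other foods carry
  negligible MeHg for general populations.
* Within-bin concentration data are summarised by geometric means, the
  natural location parameter for log-normally distributed residue data.
* Countries without their own concentration data silently (but logged at
  INFO) fall back to global geometric means; a missing *intake* record is a
  hard error, because intake is what defines the population being assessed.
* Farmed and wild fish concentrations are combined as the
  farm-fraction-weighted *geometric* mixture
  `exp(f·ln c_farm + (1−f)·ln c_wild)`. An arithmetic mixture would break
  geometric-mean semantics and the homogeneity property; the geometric form
  keeps scaling exact and is our own choice, since only the farm/wild split
  itself is given.
* When a per-bin consumption inventory is missing, the country's marine
  trophic index assigns all fish intake to the bin containing the MTI. The
  mapping from MTI to a bin distribution is genuinely open; the single-bin
  rule is the most conservative reading, and a triangular 1/4–1/2–1/4 spread
  over adjacent bins is available via `allocate_fish_consumption(...,
  spread=True)` for sensitivity checks.

Units: intakes are canonically g/person/day; annual FAO-style kg/year
figures convert by ×1000/365.25 (`KG_PER_YEAR_TO_G_PER_DAY`). Exposure is
μg/person/day, i.e. the product EDI×BW of a per-body-weight daily dose and
body weight.

## Future concentrations

2010 concentration tables are scaled per country-year by proxy ratios:
freshwater fish by atmospheric deposition `D_year/D_2010` (deposition is the
dominant Hg source to surface freshwaters), rice by soil Hg
`S_year/S_2010` (soil–rice correlation), seafood by one *global*
harvest-weighted plankton MeHg ratio `P_year/P_2010` (plankton uptake is the
biggest concentration step in marine biomagnification, and regional
percentage changes are fairly uniform). Scaling composes exactly:
re-scaling a year-y₁ table by y₂/y₁ ratios equals scaling directly to y₂.

Scenario emission anchors (Mg/yr): 1890 in 2010 for all scenarios; CP rises
slightly to 1960 by 2035 and holds (holding the 2035 level is our reading of
"near-constant", and it reproduces the relative 2050 emission changes of the
other scenarios exactly); NP-Delayed reaches 1020 and MFR 300 in 2050; A1B
and A2 reach 4900 and 3900. Interpolation between anchors is linear in time;
the anchors are sparse and nothing in the source trajectories suggests
curvature between them.

## Health endpoints

* IQ: `ΔIQ = γλβ·intake`, linear and threshold-free; defaults β = 0.6 μg/L
  per μg/day, λ = 0.2 μg/g per μg/L, γ = 0.3 points per μg/g, so the slope is
  0.036 points per μg/day. National loss is per-fetus decrement × births.
* FHA: `ΔCF = Σ_g POP_g·Cf_g·ω·(1−e^{−φλβ·intake})` with φ = 0.066 per μg/g
  and ω = 0.33 the subjective probability of causality. The model is
  saturating: the attributable fraction can never exceed ω. Below
  0.5 μg/day it agrees with its linearisation within 1%.
* Biomarkers: `C_blood = β·intake`, `C_hair = λ·C_blood`, used to validate
  modelled exposure against survey data (Pearson r plus mean ± SD per set;
  at least 3 paired countries required).

Because every formula uses the product EDI×BW (= daily intake), the
body-weight parameter cancels and is retained (default 60 kg) only for
reporting per-kg doses. Gender enters only through populations and baseline
FHA incidence; a single national intake is used for both genders, as no
gendered intake data exist at this scale.

## Valuation

IQ points are valued at $18,832 (2008 USD) each, deaths at a $6.3 million
VSL (2005 USD); both transfer across countries by the PPP per-capita GDP
ratio to the US with unit income elasticity. IQ losses are taken as a lump
value in the birth year (not a discounted lifetime earnings stream — the
per-point value already capitalises lifetime earnings). Currency-year
deflators to 2020 USD are configuration values defaulting to 1.0
(placeholders: no single inflation series is canonical), so default outputs
are in mixed native base years unless deflators are supplied.

Accumulation to the horizon uses the future-value convention: each year's
loss is compounded forward, `Σ_y L_y·(1+r)^{2050−y}`, r = 3% — "realised to
2050". A `present_value_2010` mode is selectable. A constant series
satisfies the geometric closed form exactly, which the tests verify against
direct summation.

## Uncertainty propagation

Four factor groups are sampled jointly per draw (n = 1000 by default), each
draw re-evaluating the full pipeline; the 2.5th/97.5th percentiles (linear,
type-7 interpolation — the most common default, chosen here once and
documented) form the 95% CI. Sampling granularity is at the group level: one
intake multiplier per country per draw, one concentration multiplier per
(category, trophic bin), mirroring the grouped sensitivity bars; finer
per-record sampling would be a straightforward extension but is not
implemented.

Distribution shapes (given ranges, not families, in the sources; all
config-overridable):

| group | form | default |
|---|---|---|
| consumption | log-normal multiplier per country | σ_log = ln 2 / (2·1.96): 95% range spans factor 2 |
| concentration | log-normal multiplier per (category, bin) | σ_log = 0.2·ln(GSD) |
| β, λ | truncated normal (≥0) | relative SD 0.10 |
| γ, φ | truncated normal (≥0) | relative SD 0.45 |
| ω | two-point | {0.165, 0.66} |
| IQ value | two-point | {$8,013, $18,832} |
| VSL | log-uniform | [$1M, $10M] |

The concentration table's geometric SDs describe *population* spread of
individual samples (GSD ≈ 2.5 within a bin); using them raw as uncertainty
of the bin geometric mean would let this group dwarf all others. The 0.2
scale treats them as shrunk to a standard error of the geometric mean, which
makes consumption and concentration contribute comparably — the behaviour
the underlying analysis reports. The pharmacokinetic SDs (10%) reflect the
stated 10–20% contribution; the epidemiological slopes and ω carry the large
spreads (factor ~2 each way) that make dose-response the widest envelope.

Reproducibility: draw *i* of seed *s* uses an independent generator seeded
with `[s, i]`, so results are bit-identical for a fixed (seed, spec, world)
and independent of draw order.

One-factor-at-a-time envelopes re-run the Monte Carlo with a single group
varying; the joint run gives the overall CI. Both modes are exposed because
overall ranges and per-factor bars answer different questions.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs (FAO
food balance sheets, a literature concentration database, UN population
prospects, WHO heart-disease incidence, SSP2 GDP, scenario runs of a 3-D
environmental model) without reproducing any of them:

* **Archetypes** — island-high-seafood (120–350 g/day seafood, small
  populations), asian-rice-freshwater (50–100 g/day seafood, 250–450 g/day
  rice, large populations), inland-low (minimal fish). Jittered parameters
  within archetypes, rather than fully independent sampling, make the
  exposure geography (island > coastal > inland) structurally guaranteed.
  Default mix 25/35/40% reproduces global pathway shares near
  seafood 56% / freshwater fish 34% / rice 10%.
* **Flagship** — one deterministic island country calibrated so its seafood
  pathway evaluates to exactly 33 μg/day at 190 kg/yr consumption (the
  highest observed national combination), anchoring ranking tests.
* **Concentrations** — wild geometric means (0.02, 0.05, 0.10, 0.20) μg/g
  for seafood bins and (0.03, 0.08, 0.15, 0.30) for freshwater fish: exactly
  the ~10× biomagnification span; farmed fish at 0.6× wild; rice at
  0.003 μg/g. Within-bin GSD 2.5 (fish) / 2.0 (rice). ~60% of countries get
  their own records (a jittered global multiple); the rest exercise the
  GLOBAL fallback.
* **Demographics/economics** — populations grow 0.5–1.2%/yr by archetype
  (≈ +40% globally by 2050), crude birth rates 1.4–3% declining slowly,
  FHA incidence ≈ 6–9×10⁻⁴ per person-year (male 1.3×, female 0.7×), GDP
  converging toward a US trajectory growing 1.5%/yr from $49k PPP.
* **Trajectories** — proxies start at exactly 1.0 in 2010 and reach their
  2050 responses along a logistic ramp (smooth and monotone; the source
  trajectories' shape is otherwise unconstrained). Defaults: deposition
  responses 0.52 / 0.72 / 1.00 / 1.59 / 1.87 (MFR / NP-Delayed / CP / A2 /
  A1B) and soil responses 0.97–1.04. The plankton response is deposition
  damped toward unity by a factor of 0.5 — the plankton response is
  qualitatively "similar to deposition" but the realised health responses
  imply damping, and no printed number pins it down, so it is an explicit
  calibration parameter.

What the generator does **not** emulate: within-country heterogeneity and
high-exposure subpopulations (artisanal gold miners, marine-mammal
consumers), species-level consumption, spatially resolved deposition,
correlated shocks between countries, dietary change over time (consumption
patterns are held at 2010 levels, as in the source analysis). Passing tests
therefore demonstrate correctness of the *pipeline mechanics and model
forms* under realistic magnitudes — not predictive validity for any real
country.

## Numerical choices

* The scenario engine never rebuilds concentration tables: exposure is
  linear in concentrations, so year-y exposure factorises into 2010 pathway
  exposures times proxy ratios. Tests verify the vectorised engine against
  an independent straight-line per-record recomputation to 1e-9 relative.
* `1 − e^{−x}` is computed with `expm1` for accuracy at small doses.
* Geometric means are computed in log space.
* Exposure additivity holds to 1e-12 relative; degenerate inputs (zero
  intake, zero births, empty bins) return exact zeros or are flagged absent
  rather than zero-filled (empty concentration bins).
* Ties/edges: a trophic level on a bin boundary belongs to the upper bin
  (half-open bins, level 5.0 to the top bin); percentile rule is type-7.
* Default problem sizes (12-country worlds, 41 years, 1000 draws) keep a
  full test-and-acceptance cycle under a minute on one CPU while leaving
  every mechanism exercised; all sizes are configuration, not constants.

## Known limitations

* No nutrient (n-3) benefit offsets; the net health effect of fish
  consumption can be positive at low MeHg levels.
* No age structure: births and gender-specific FHA incidence are the only
  demographic detail; IQ and FHA endpoints only.
* Valuation ignores cost-of-illness beyond the two endpoints and uses unit
  income elasticity for both value transfers.
* Deflators default to 1.0, so cross-base-year sums mix currency years
  unless configured.
* The plankton damping factor is a free calibration parameter; scenario
  deltas inherit its uncertainty wholesale.
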