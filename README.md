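# mehgrisk

Country-resolved modelling of dietary **methylmercury (MeHg)** exposure, its
health effects, and their economic cost — with Monte Carlo uncertainty
propagation and emission-scenario projections to 2050.

MeHg, the organic form of mercury, bioaccumulates in aquatic food webs and
reaches people almost entirely through food: seafood, freshwater fish and
rice. Prenatal exposure lowers the IQ of newborns; chronic adult exposure is
associated with fatal heart attacks (FHA). This package is aimed at
environmental-health modellers and policy analysts who need to turn national
food-intake tables and food MeHg concentrations into health burdens and
monetary losses, and to compare mercury-emission policy scenarios.

## The model

**Exposure** (μg MeHg/person/day) aggregates intake I (g/day) times
concentration C (μg/g) over pathways, with fish split into four trophic-level
bins i (2–2.5, 2.5–3.5, 3.5–4.5, 4.5–5; concentrations rise ~10× across the
range):

```
E = Σᵢ Iᵢ·Cᵢ (freshwater fish) + Σᵢ Iᵢ·Cᵢ (seafood) + I·C (rice)
```

Per-bin concentrations are geometric means; countries without their own data
fall back to global geometric means; farmed/wild supply is combined as a
farm-fraction-weighted geometric mixture.

**Future exposure** scales the 2010 concentrations with environmental
proxies from emission-scenario runs: freshwater fish follow the country's
atmospheric deposition ratio `D_year/D_2010`, rice the soil-mercury ratio
`S_year/S_2010`, seafood a single global harvest-weighted plankton-MeHg ratio
`P_year/P_2010`. Five scenarios span 2010–2050: CP (current policy,
near-constant emissions), NP-Delayed, MFR (maximum feasible reduction), A1B
and A2.

**Health endpoints.** IQ loss is linear and threshold-free,

```
ΔIQ = γ·λ·β · intake        (β = 0.6 μg/L per μg/day, λ = 0.2 μg/g per μg/L,
                             γ = 0.3 IQ points per μg/g hair)
```

so 33 μg/day — the highest national per-capita seafood exposure — gives
1.2 IQ points per fetus. FHA deaths are log-linear in hair Hg and capped by
the probability of causality ω:

```
ΔCF = Σ_g POP_g · Cf_g · ω · (1 − e^{−φ·λ·β·intake}),   φ = 0.066 per μg/g, ω = 0.33
```

Blood and hair biomarkers (`C_blood = β·intake`, `C_hair = λ·C_blood`) allow
validation against survey data.

**Valuation.** IQ points at $18,832 (2008 USD) each and deaths at a
$6.3 million VSL (2005 USD), both transferred across countries by the ratio
of PPP per-capita GDP to the US value; annual losses 2010–2050 are
compounded forward to 2050 at a 3% discount rate.

**Uncertainty.** The whole calculation is repeated 1000 times with the four
dominant factor groups sampled jointly — food consumption (log-normal,
95% range ≈ factor 2), food MeHg concentrations (log-normal from the table's
geometric SDs), dose-response coefficients, and valuation (two-point IQ
value; log-uniform VSL on $1–10M) — and the 2.5/97.5 percentiles form the
95% CI. One-factor-at-a-time envelopes show each group's contribution.

A seed-deterministic **synthetic-world generator** provides complete,
statistically faithful inputs (three country archetypes: high-seafood
islands, rice-and-freshwater-fish countries, low-fish inland countries), so
everything runs without external data.

## Worked example

```python
import mehgrisk as m

world = m.generate_world(m.SyntheticWorldConfig(seed=1))
frame, summary = m.run_baseline(world)
print(frame.loc[["I00", "A03", "L02"],
                ["exposure_total", "per_fetus_iq", "fha_deaths", "total_usd"]])
```

```
         exposure_total  per_fetus_iq  fha_deaths     total_usd
country
I00              33.382         1.202      28.950  9.599262e+07
A03               7.418         0.267    7457.678  5.573834e+10
L02               0.873         0.031      58.768  3.201799e+07
```

`I00` is the calibrated island flagship: 33 μg/day of seafood MeHg exposure
and the top per-fetus IQ decrement (1.2 points), but few people — so the big
monetary losses sit with the populous country `A03`, whose deaths reflect its
population and baseline heart-attack incidence. Globally this world loses
3.43×10⁶ IQ points/yr, 1.28×10⁴ deaths/yr and $77.4 billion/yr, and modelled
blood Hg correlates with the (synthetic) survey values at r = 0.97.

Scenario comparison and uncertainty:

```python
tables, ssum = m.run_scenarios(world)
ssum["cumulative_discounted_usd"]
# {'A1B': 9.03e+12, 'A2': 8.52e+12, 'CP': 7.44e+12,
#  'NP-Delayed': 6.92e+12, 'MFR': 6.55e+12}

res = m.run_uncertainty(world, m.UncertaintySpec(n_draws=1000, seed=1))
# CP point $7.44e+12, 95% CI [$1.25e+12, $1.74e+13]
```

Cumulative discounted losses order as MFR < NP-Delayed < CP < A2 < A1B, and
the dose-response group dominates the uncertainty envelope.

The same runs are available from the shell:

```
mehgrisk generate-world --seed 1 --out world/
mehgrisk run-baseline --config run.yaml
mehgrisk run-scenarios --config run.yaml
mehgrisk run-uncertainty --config run.yaml
mehgrisk report --out out/
```

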