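"""Synthetic input worlds for the exposure-to-valuation pipeline.

Real applications of the pipeline draw on FAO food-balance sheets, a
literature database of food MeHg concentrations, UN demographic projections,
WHO heart-disease incidence, SSP2 GDP projections and scenario runs of a 3-D
environmental model. This module generates complete stand-in worlds with the
same statistical structure so that every stage can run and be tested at desk
scale:

* three country archetypes -- small island states with very high seafood
  consumption, populous rice-and-freshwater-fish countries, and inland
  low-fish countries -- with jittered parameters, so that the qualitative
  exposure geography (island > coastal > inland) is structurally guaranteed;
* fish MeHg geometric means spanning ~10x across the four trophic-level bins;
* five emission scenarios whose 2050 environmental-proxy responses are
  calibrated to the deposition changes of the underlying scenario runs
  (MFR -48%, NP-Delayed -28%, A1B +87%, A2 +59% relative to the flat CP
  reference; soil responses within -3%..+4%), with a configurable damping
  factor translating deposition change into the global plankton response.

All randomness flows from a single seed; a fixed seed reproduces the world
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as expo
from .exposure import (
    GLOBAL,
    FARM,
    WILD,
    NO_ORIGIN,
    RICE,
    SEAFOOD,
    FRESHWATER_FISH,
    BIN_LABELS,
    KG_PER_YEAR_TO_G_PER_DAY,
    ConcentrationTable,
    FoodIntakeTable,
)
from .dose_response import DemographicTrajectory, DoseResponseParams
from .scaling import EnvironmentalTrajectory
from .valuation import EconomicTrajectory


@dataclass(frozen=True)
class Archetype:
    """Parameter ranges for one country archetype (jittered per country)."""

    name: str
    code_prefix: str
    seafood_g_day: tuple[float, float]
    fw_g_day: tuple[float, float]
    rice_g_day: tuple[float, float]
    seafood_fractions: tuple[float, float, float, float]
    fw_fractions: tuple[float, float, float, float]
    population: tuple[float, float]
    gdp_pc: tuple[float, float]
    birth_rate: float  # births per person per year, 2010
    pop_growth: float  # fractional per year
    fha_incidence: float  # baseline fatal-heart-attack deaths per person-year
    farm_fraction: float


ARCHETYPES: dict[str, Archetype] = {
    "island": Archetype(
        name="island",
        code_prefix="I",
        seafood_g_day=(120.0, 350.0),
        fw_g_day=(1.0, 4.0),
        rice_g_day=(30.0, 90.0),
        seafood_fractions=(0.15, 0.55, 0.25, 0.05),
        fw_fractions=(0.2, 0.6, 0.2, 0.0),
        population=(3e5, 5e6),
        gdp_pc=(1.0e4, 5.5e4),
        birth_rate=0.014,
        pop_growth=0.005,
        fha_incidence=8.0e-4,
        farm_fraction=0.05,
    ),
    "asian": Archetype(
        name="asian",
        code_prefix="A",
        seafood_g_day=(50.0, 100.0),
        fw_g_day=(20.0, 45.0),
        rice_g_day=(250.0, 450.0),
        seafood_fractions=(0.2, 0.6, 0.15, 0.05),
        fw_fractions=(0.2, 0.6, 0.2, 0.0),
        population=(5e7, 5e8),
        gdp_pc=(4.0e3, 3.5e4),
        birth_rate=0.016,
        pop_growth=0.008,
        fha_incidence=9.0e-4,
        farm_fraction=0.3,
    ),
    "inland": Archetype(
        name="inland",
        code_prefix="L",
        seafood_g_day=(0.5, 4.0),
        fw_g_day=(4.0, 12.0),
        rice_g_day=(20.0, 60.0),
        seafood_fractions=(0.2, 0.6, 0.15, 0.05),
        fw_fractions=(0.25, 0.6, 0.15, 0.0),
        population=(5e6, 8e7),
        gdp_pc=(1.0e3, 8.0e3),
        birth_rate=0.03,
        pop_growth=0.012,
        fha_incidence=6.0e-4,
        farm_fraction=0.2,
    ),
}

#: 2050 environmental-proxy responses per scenario relative to the flat CP
#: reference: (deposition ratio, soil ratio).
DEFAULT_SCENARIO_RESPONSES: dict[str, tuple[float, float]] = {
    "CP": (1.00, 1.00),
    "NP-Delayed": (0.72, 0.98),
    "MFR": (0.52, 0.97),
    "A2": (1.59, 1.03),
    "A1B": (1.87, 1.04),
}


@dataclass
class SyntheticWorldConfig:
    """Calibration knobs for world generation. Defaults define the study
    conditions; see the methods note for the rationale of each value."""

    n_countries: int = 12
    seed: int = 0
    years: tuple[int, int] = (2010, 2050)
    archetype_weights: dict[str, float] = field(
        default_factory=lambda: {"island": 0.25, "asian": 0.35, "inland": 0.40}
    )
    #: include one deterministic island country calibrated so that its seafood
    #: pathway exposure is exactly ``flagship_seafood_exposure`` ug/day at a
    #: seafood consumption of ``flagship_seafood_kg_y`` kg/year
    flagship: bool = True
    flagship_seafood_kg_y: float = 190.0
    flagship_seafood_exposure: float = 33.0
    #: wild-caught geometric-mean concentrations (ug/g) for the four trophic
    #: bins; the top/bottom ratio sets the ~10x biomagnification span
    conc_seafood_bins: tuple[float, float, float, float] = (0.02, 0.05, 0.10, 0.20)
    conc_fw_bins: tuple[float, float, float, float] = (0.03, 0.08, 0.15, 0.30)
    conc_rice: float = 0.003
    farm_discount: float = 0.6  # farmed fish GM relative to wild
    gsd_fish: float = 2.5
    gsd_rice: float = 2.0
    #: probability that a country has its own concentration records (others
    #: exercise the GLOBAL fallback)
    country_conc_prob: float = 0.6
    country_conc_jitter: float = 0.15  # sigma of log-normal country factor
    scenario_responses: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_RESPONSES)
    )
    plankton_damping: float = 0.5  # plankton response per unit deposition change
    logistic_rate: float = 0.15
    logistic_mid: float = 2030.0
    include_biomarkers: bool = True
    biomarker_noise_sigma: float = 0.35
    us_gdp_pc_2010: float = 4.9e4
    us_gdp_growth: float = 0.015

    def __post_init__(self):
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights sum to {total}, expected 1")
        unknown = set(self.archetype_weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")
        if any(w < 0 for w in self.archetype_weights.values()):
            raise ValueError("archetype weights must be non-negative")


@dataclass
class World:
    """A complete, mutually consistent set of pipeline inputs."""

    intake: FoodIntakeTable
    concentrations: ConcentrationTable
    demographics: DemographicTrajectory
    economics: EconomicTrajectory
    trajectories: dict[str, EnvironmentalTrajectory]
    farm_fractions: dict[str, float]
    measured_blood: dict[str, float] = field(default_factory=dict)
    config: SyntheticWorldConfig | None = None

    @property
    def countries(self) -> list[str]:
        return self.intake.countries

    def content_hash(self) -> str:
        """Stable digest of all tables (reproducibility check)."""
        h = hashlib.sha256()
        for frame in (
            self.intake.df,
            self.concentrations.df,
            self.demographics.df,
            self.economics.df,
            *(self.trajectories[k].df for k in sorted(self.trajectories)),
        ):
            h.update(frame.round(12).to_csv(index=False).encode())
        h.update(json.dumps(self.farm_fractions, sort_keys=True).encode())
        h.update(
            json.dumps({k: round(v, 12) for k, v in sorted(self.measured_blood.items())}).encode()
        )
        return h.hexdigest()

    def manifest(self) -> dict:
        return {
            "units": {
                "intake": "g per person per day",
                "concentration": "ug MeHg per g food (geometric mean)",
                "population": "persons",
                "fha_incidence": "deaths per person per year",
                "births": "newborns per year",
                "gdp_pc_ppp": "PPP USD per capita",
                "trajectories": "relative to 2010 (unitless)",
            },
            "seed": self.config.seed if self.config else None,
            "config": dataclasses.asdict(self.config) if self.config else None,
            "content_hash": self.content_hash(),
        }

    def to_csv_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.intake.to_csv(path / "intake.csv")
        self.concentrations.to_csv(path / "concentrations.csv")
        self.demographics.to_csv(path / "demographics.csv")
        self.economics.to_csv(path / "economics.csv")
        traj = pd.concat(
            [t.df.assign(scenario=name) for name, t in sorted(self.trajectories.items())]
        )
        traj.to_csv(path / "trajectories.csv", index=False)
        pd.DataFrame(
            {"country": list(self.farm_fractions), "farm_fraction": list(self.farm_fractions.values())}
        ).to_csv(path / "farm_fractions.csv", index=False)
        if self.measured_blood:
            pd.DataFrame(
                {"country": list(self.measured_blood), "blood_ug_L": list(self.measured_blood.values())}
            ).to_csv(path / "measured_blood.csv", index=False)
        (path / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))

    @classmethod
    def from_csv_dir(cls, path) -> "World":
        path = Path(path)
        traj_df = pd.read_csv(path / "trajectories.csv")
        trajectories = {
            str(name): EnvironmentalTrajectory(str(name), g.drop(columns=["scenario"]))
            for name, g in traj_df.groupby("scenario")
        }
        ff = pd.read_csv(path / "farm_fractions.csv")
        measured = {}
        if (path / "measured_blood.csv").exists():
            mb = pd.read_csv(path / "measured_blood.csv")
            measured = dict(zip(mb["country"], mb["blood_ug_L"].astype(float)))
        return cls(
            intake=FoodIntakeTable.from_csv(path / "intake.csv"),
            concentrations=ConcentrationTable.from_csv(path / "concentrations.csv"),
            demographics=DemographicTrajectory.from_csv(path / "demographics.csv"),
            economics=EconomicTrajectory.from_csv(path / "economics.csv"),
            trajectories=trajectories,
            farm_fractions=dict(zip(ff["country"], ff["farm_fraction"].astype(float))),
            measured_blood=measured,
        )


def _logistic_ramp(years: np.ndarray, y0: int, y1: int, rate: float, mid: float) -> np.ndarray:
    """Smooth monotone ramp from exactly 0 at y0 to exactly 1 at y1."""
    f = 1.0 / (1.0 + np.exp(-rate * (years - mid)))
    f0 = 1.0 / (1.0 + math.exp(-rate * (y0 - mid)))
    f1 = 1.0 / (1.0 + math.exp(-rate * (y1 - mid)))
    return (f - f0) / (f1 - f0)


def generate_scenario_trajectories(
    config: SyntheticWorldConfig,
) -> dict[str, EnvironmentalTrajectory]:
    """Yearly D, S, P proxy trajectories per scenario (GLOBAL series).

    Each proxy starts at 1.0 in 2010 and reaches its configured 2050 response
    along a logistic-in-time path. The plankton response is the deposition
    response damped toward unity by ``plankton_damping``.
    """
    if "CP" not in config.scenario_responses:
        raise ValueError("scenario responses must include the CP reference")
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    ramp = _logistic_ramp(years, y0, y1, config.logistic_rate, config.logistic_mid)
    out: dict[str, EnvironmentalTrajectory] = {}
    for name, (d2050, s2050) in config.scenario_responses.items():
        p2050 = 1.0 + config.plankton_damping * (d2050 - 1.0)
        df = pd.DataFrame(
            {
                "country": GLOBAL,
                "year": years,
                "D": 1.0 + (d2050 - 1.0) * ramp,
                "S": 1.0 + (s2050 - 1.0) * ramp,
                "P": 1.0 + (p2050 - 1.0) * ramp,
            }
        )
        out[name] = EnvironmentalTrajectory(name, df)
    return out


def _global_concentration_records(config: SyntheticWorldConfig) -> list[tuple]:
    records = []
    for cat, bins in ((SEAFOOD, config.conc_seafood_bins), (FRESHWATER_FISH, config.conc_fw_bins)):
        for label, c in zip(BIN_LABELS, bins):
            records.append((GLOBAL, cat, label, WILD, c, config.gsd_fish))
            records.append((GLOBAL, cat, label, FARM, c * config.farm_discount, config.gsd_fish))
    records.append((GLOBAL, RICE, None, NO_ORIGIN, config.conc_rice, config.gsd_rice))
    return records


def _country_concentration_records(
    country: str, factor: float, config: SyntheticWorldConfig
) -> list[tuple]:
    recs = []
    for g, cat, label, orig, c, gsd in _global_concentration_records(config):
        recs.append((country, cat, label, orig, c * factor, gsd))
    return recs


def _effective_wild_mix(fractions, bins) -> float:
    return float(sum(f * c for f, c in zip(fractions, bins)))


def generate_world(config: SyntheticWorldConfig | None = None) -> World:
    """Generate a complete synthetic world (seed-deterministic)."""
    config = config or SyntheticWorldConfig()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))

    # --- country roster ----------------------------------------------------
    names = sorted(config.archetype_weights)
    n = config.n_countries
    n_jittered = n - (1 if config.flagship and n >= 1 else 0)
    # largest-remainder apportionment keeps every archetype represented
    quotas = {a: config.archetype_weights[a] * n_jittered for a in names}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    remainder = n_jittered - sum(counts.values())
    for a in sorted(names, key=lambda a: quotas[a] - counts[a], reverse=True)[:remainder]:
        counts[a] += 1

    roster: list[tuple[str, str, bool]] = []  # (country, archetype, flagship?)
    if config.flagship and n >= 1:
        roster.append(("I00", "island", True))
    serial = {a: 1 for a in names}
    for a in names:
        for _ in range(counts[a]):
            roster.append((f"{ARCHETYPES[a].code_prefix}{serial[a]:02d}", a, False))
            serial[a] += 1

    # --- intake, farm fractions, demographics, economics -------------------
    intake_rows: list[tuple] = []
    conc_rows: list[tuple] = list(_global_concentration_records(config))
    farm_fractions: dict[str, float] = {}
    demo_rows: list[dict] = []
    econ_rows: list[dict] = []
    us_gdp = {
        y: config.us_gdp_pc_2010 * (1.0 + config.us_gdp_growth) ** (y - y0) for y in years
    }

    for country, aname, is_flagship in roster:
        a = ARCHETYPES[aname]
        farm_fractions[country] = a.farm_fraction

        if is_flagship:
            seafood = config.flagship_seafood_kg_y * KG_PER_YEAR_TO_G_PER_DAY
            fw = float(np.mean(a.fw_g_day))
            rice = float(np.mean(a.rice_g_day))
            pop = 4.0e5
            gdp = 1.5e4
            # country-specific concentration factor making the seafood pathway
            # evaluate to exactly the configured exposure
            eff_wild = _effective_wild_mix(a.seafood_fractions, config.conc_seafood_bins)
            eff = eff_wild * config.farm_discount**a.farm_fraction
            factor = config.flagship_seafood_exposure / (seafood * eff)
            conc_rows.extend(_country_concentration_records(country, factor, config))
        else:
            seafood = rng.uniform(*a.seafood_g_day)
            fw = rng.uniform(*a.fw_g_day)
            rice = rng.uniform(*a.rice_g_day)
            pop = math.exp(rng.uniform(math.log(a.population[0]), math.log(a.population[1])))
            gdp = math.exp(rng.uniform(math.log(a.gdp_pc[0]), math.log(a.gdp_pc[1])))
            if rng.random() < config.country_conc_prob:
                factor = math.exp(rng.normal(0.0, config.country_conc_jitter))
                conc_rows.extend(_country_concentration_records(country, factor, config))

        for label, f in zip(BIN_LABELS, a.seafood_fractions):
            if f > 0:
                intake_rows.append((country, SEAFOOD, label, seafood * f))
        for label, f in zip(BIN_LABELS, a.fw_fractions):
            if f > 0:
                intake_rows.append((country, FRESHWATER_FISH, label, fw * f))
        intake_rows.append((country, RICE, None, rice))

        birth_rate = a.birth_rate * math.exp(rng.normal(0.0, 0.1))
        fha = a.fha_incidence * math.exp(rng.normal(0.0, 0.2))
        gdp_growth = 0.015 + 0.012 * max(0.0, 1.0 - gdp / us_gdp[y0])
        for y in years:
            pop_y = pop * (1.0 + a.pop_growth) ** (y - y0)
            births_y = pop_y * birth_rate * (1.0 - 0.002) ** (y - y0)
            for gender, share, fha_mult in (("male", 0.502, 1.3), ("female", 0.498, 0.7)):
                demo_rows.append(
                    {
                        "country": country,
                        "year": y,
                        "gender": gender,
                        "population": pop_y * share,
                        "fha_incidence": fha * fha_mult,
                        "births": births_y,
                    }
                )
            econ_rows.append(
                {
                    "country": country,
                    "year": y,
                    "gdp_pc_ppp": gdp * (1.0 + gdp_growth) ** (y - y0),
                    "us_gdp_pc_ppp": us_gdp[y],
                }
            )

    intake = FoodIntakeTable.from_records(intake_rows)
    concentrations = ConcentrationTable.from_records(conc_rows)
    demographics = DemographicTrajectory(pd.DataFrame(demo_rows))
    economics = EconomicTrajectory(pd.DataFrame(econ_rows))
    trajectories = generate_scenario_trajectories(config)

    world = World(
        intake=intake,
        concentrations=concentrations,
        demographics=demographics,
        economics=economics,
        trajectories=trajectories,
        farm_fractions=farm_fractions,
        config=config,
    )

    if config.include_biomarkers:
        from .dose_response import biomarkers  # local import avoids cycle at module load

        params = DoseResponseParams()
        measured = {}
        for country in world.countries:
            res = expo.compute_exposure(
                intake, concentrations, country, farm_fraction=farm_fractions
            )
            blood = biomarkers(res.total, params).blood
            measured[country] = blood * math.exp(rng.normal(0.0, config.biomarker_noise_sigma))
        world.measured_blood = measured

    return world
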