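"""Scenario emission trajectories and future concentration scaling.

Future food MeHg concentrations are obtained by scaling present-day (2010)
values with environmental proxies from the scenario runs: freshwater-fish
concentrations follow the country's atmospheric Hg deposition D, rice follows
the country's soil Hg concentration S, and seafood follows a single global
plankton-MeHg index P weighted by the spatial distribution of fish harvest:

    C_year^fw   = C_2010^fw   * D_year / D_2010   (per country)
    C_year^rice = C_2010^rice * S_year / S_2010   (per country)
    C_year^sea  = C_2010^sea  * P_year / P_2010   (global)

Five emission scenarios span 2010-2050: CP (current policy, near-constant
emissions), NP-Delayed (new-policy cuts delayed to 2050), MFR (maximum
feasible reduction), and the growth scenarios A1B and A2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import (
    GLOBAL,
    RICE,
    SEAFOOD,
    FRESHWATER_FISH,
    ConcentrationTable,
)

log = logging.getLogger(__name__)

SCENARIO_NAMES = ("CP", "NP-Delayed", "MFR", "A1B", "A2")


@dataclass(frozen=True)
class ScenarioDefinition:
    """Named emission scenario with (year, Mg/yr) anchor points."""

    name: str
    emission_anchors: tuple[tuple[int, float], ...]

    def __post_init__(self):
        years = [y for y, _ in self.emission_anchors]
        if years != sorted(years):
            raise ValueError(f"{self.name}: anchors must be sorted by year")
        if 2010 not in years:
            raise ValueError(f"{self.name}: a 2010 anchor is required")
        if any(e <= 0 for _, e in self.emission_anchors):
            raise ValueError(f"{self.name}: emissions must be positive")

    def emission(self, year: float) -> float:
        return interpolate_anchors(self.emission_anchors, year)


#: Global primary anthropogenic Hg emission anchors (Mg/yr), 2010-2050.
#: CP holds emissions near-constant apart from a small rise to 1960 Mg/yr by
#: 2035; NP-Delayed reaches the 1020 Mg/yr new-policy level in 2050; MFR
#: reaches 300 Mg/yr; A1B and A2 grow to 4900 and 3900 Mg/yr.
SCENARIOS: dict[str, ScenarioDefinition] = {
    "CP": ScenarioDefinition("CP", ((2010, 1890.0), (2035, 1960.0), (2050, 1960.0))),
    "NP-Delayed": ScenarioDefinition("NP-Delayed", ((2010, 1890.0), (2050, 1020.0))),
    "MFR": ScenarioDefinition("MFR", ((2010, 1890.0), (2050, 300.0))),
    "A1B": ScenarioDefinition("A1B", ((2010, 1890.0), (2050, 4900.0))),
    "A2": ScenarioDefinition("A2", ((2010, 1890.0), (2050, 3900.0))),
}


def interpolate_anchors(
    anchors: Sequence[tuple[int, float]], year: float
) -> float:
    """Piecewise-linear interpolation between anchor points (no extrapolation)."""
    if len(anchors) < 1:
        raise ValueError("at least one anchor is required")
    years = np.array([y for y, _ in anchors], dtype=float)
    values = np.array([v for _, v in anchors], dtype=float)
    if not (years[0] <= year <= years[-1]):
        raise ValueError(
            f"year {year} outside anchor range [{years[0]:.0f}, {years[-1]:.0f}]"
        )
    return float(np.interp(year, years, values))


@dataclass
class EnvironmentalTrajectory:
    """Per-scenario yearly environmental proxies D, S, P.

    Backed by a DataFrame with columns ``country`` (ISO3 or GLOBAL), ``year``,
    ``D`` (atmospheric Hg deposition), ``S`` (soil Hg concentration) and ``P``
    (harvest-weighted plankton MeHg). Values may be absolute or relative; only
    ratios to the 2010 value are ever used. Country lookups fall back to the
    GLOBAL series.
    """

    scenario: str
    df: pd.DataFrame

    COLUMNS = ("country", "year", "D", "S", "P")

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"trajectory missing columns {sorted(missing)}")
        for var in ("D", "S", "P"):
            if (self.df[var] <= 0).any():
                raise ValueError(
                    f"{self.scenario}: proxy {var} must be strictly positive"
                )
        self._series: dict[str, pd.DataFrame] = {
            c: g.set_index("year")[["D", "S", "P"]].sort_index()
            for c, g in self.df.groupby("country")
        }
        for c, g in self._series.items():
            if 2010 not in g.index:
                raise ValueError(
                    f"{self.scenario}/{c}: year 2010 required for normalization"
                )

    @classmethod
    def from_csv(cls, path, scenario: str | None = None) -> "EnvironmentalTrajectory":
        df = pd.read_csv(path)
        if scenario is None:
            if "scenario" not in df.columns:
                raise ValueError("scenario column or explicit name required")
            names = df["scenario"].unique()
            if len(names) != 1:
                raise ValueError(f"expected one scenario per file, found {list(names)}")
            scenario = str(names[0])
        df = df.drop(columns=[c for c in ("scenario",) if c in df.columns])
        return cls(scenario, df)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "scenario", self.scenario)
        out.to_csv(path, index=False)

    def _frame(self, country: str) -> pd.DataFrame:
        if country in self._series:
            return self._series[country]
        if GLOBAL in self._series:
            return self._series[GLOBAL]
        raise KeyError(
            f"{self.scenario}: no trajectory for {country!r} and no GLOBAL series"
        )

    def value(self, country: str, year: int, var: str) -> float:
        frame = self._frame(country)
        if year not in frame.index:
            raise KeyError(f"{self.scenario}/{country}: year {year} not in trajectory")
        return float(frame.loc[year, var])

    def ratio(self, country: str, year: int, var: str) -> float:
        """Proxy value relative to 2010 (the Eq. scaling ratio)."""
        base = self.value(country, 2010, var)
        if base <= 0:
            raise ValueError(
                f"{self.scenario}/{country}: non-positive 2010 {var} value {base}"
            )
        return self.value(country, year, var) / base

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())


def scale_concentrations(
    base: ConcentrationTable,
    traj: EnvironmentalTrajectory,
    country: str,
    year: int,
) -> ConcentrationTable:
    """Concentration table for ``year`` for one country's consumers.

    Freshwater-fish records are scaled by the country's deposition ratio
    D_year/D_2010, rice by the soil ratio S_year/S_2010, and seafood by the
    global plankton ratio P_year/P_2010. Geometric SDs and all other fields
    are untouched.
    """
    factors = {
        FRESHWATER_FISH: traj.ratio(country, year, "D"),
        RICE: traj.ratio(country, year, "S"),
        SEAFOOD: traj.ratio(GLOBAL, year, "P"),
    }
    return base.scaled(factors)
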