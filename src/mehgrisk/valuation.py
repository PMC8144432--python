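"""Economic valuation of MeHg health endpoints.

IQ decrements are monetised at a US value per IQ point ($18,832 in 2008 USD,
a lifetime-earnings figure) and FHA deaths at a US value of statistical life
($6.3 million in 2005 USD); both are transferred to other countries by the
ratio of PPP-adjusted per-capita GDP to the US value (unit income elasticity).
Annual losses over 2010-2050 are accumulated to the 2050 horizon by forward
compounding at a 3% discount rate (each year's loss is "realized to 2050").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

US = "USA"


@dataclass
class ValuationParams:
    """Monetary values, currency-year deflators and discounting settings.

    ``deflators`` maps a monetary base year to the factor converting it to
    2020 USD. The defaults of 1.0 leave values in their native base years;
    supply CPI-style factors to report in 2020 USD.
    """

    iq_value: float = 18_832.0  # USD per IQ point, 2008 base
    iq_value_low: float = 8_013.0
    vsl: float = 6.3e6  # USD per death, 2005 base
    vsl_range: tuple[float, float] = (1.0e6, 1.0e7)
    discount_rate: float = 0.03
    horizon_year: int = 2050
    deflators: dict[int, float] = field(default_factory=lambda: {2008: 1.0, 2005: 1.0})
    discount_mode: str = "future_value"  # or "present_value_2010"

    def __post_init__(self):
        for name in ("iq_value", "iq_value_low", "vsl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.vsl_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid VSL range {self.vsl_range}")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValueError(f"discount rate must lie in [0, 1), got {self.discount_rate}")
        if self.discount_mode not in ("future_value", "present_value_2010"):
            raise ValueError(f"unknown discount mode {self.discount_mode!r}")

    def deflator(self, base_year: int) -> float:
        return float(self.deflators.get(base_year, 1.0))


@dataclass
class EconomicRecord:
    """PPP per-capita GDP of one country-year plus the US denominator."""

    country: str
    year: int
    gdp_pc_ppp: float
    us_gdp_pc_ppp: float

    def __post_init__(self):
        if self.gdp_pc_ppp <= 0 or self.us_gdp_pc_ppp <= 0:
            raise ValueError("per-capita GDP values must be positive")

    @property
    def gdp_ratio(self) -> float:
        return self.gdp_pc_ppp / self.us_gdp_pc_ppp


@dataclass
class EconomicTrajectory:
    """Country x year PPP per-capita GDP (SSP2-style projection).

    CSV dialect: country, year, gdp_pc_ppp, us_gdp_pc_ppp.
    """

    df: pd.DataFrame

    COLUMNS = ("country", "year", "gdp_pc_ppp", "us_gdp_pc_ppp")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"economics missing columns {sorted(missing)}")
        if (self.df["gdp_pc_ppp"] <= 0).any() or (self.df["us_gdp_pc_ppp"] <= 0).any():
            raise ValueError("per-capita GDP values must be positive")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "EconomicTrajectory":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def at(self, country: str, year: int) -> EconomicRecord:
        sub = self.df[(self.df["country"] == country) & (self.df["year"] == year)]
        if sub.empty:
            raise KeyError(f"no economic record for {country} in {year}")
        row = sub.iloc[0]
        return EconomicRecord(
            country=country,
            year=year,
            gdp_pc_ppp=float(row["gdp_pc_ppp"]),
            us_gdp_pc_ppp=float(row["us_gdp_pc_ppp"]),
        )


@dataclass
class EconomicLossResult:
    country: str
    year: int
    iq_loss_usd: float
    fha_loss_usd: float

    def __post_init__(self):
        if self.iq_loss_usd < 0 or self.fha_loss_usd < 0:
            raise ValueError("losses must be non-negative")

    @property
    def total_usd(self) -> float:
        return self.iq_loss_usd + self.fha_loss_usd


def iq_monetary_loss(
    total_iq: float,
    econ: EconomicRecord,
    params: ValuationParams,
    year: int | None = None,
) -> float:
    """Monetised IQ loss: points x per-point value x deflator x GDP ratio."""
    if total_iq < 0:
        raise ValueError("IQ loss must be non-negative")
    return total_iq * params.iq_value * params.deflator(2008) * econ.gdp_ratio


def fha_monetary_loss(
    deaths: float,
    econ: EconomicRecord,
    params: ValuationParams,
    year: int | None = None,
) -> float:
    """Monetised FHA deaths: deaths x VSL x deflator x GDP ratio."""
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    return deaths * params.vsl * params.deflator(2005) * econ.gdp_ratio


def discount_to_horizon(
    annual_losses: Mapping[int, float] | pd.Series,
    rate: float = 0.03,
    horizon: int = 2050,
    mode: str = "future_value",
) -> float:
    """Accumulate a yearly loss series to the horizon year.

    The default future-value convention compounds each year's loss forward:
    ``sum_y L_y * (1+rate)^(horizon-y)``. The alternative
    ``present_value_2010`` discounts each year back to 2010 instead.
    """
    if isinstance(annual_losses, pd.Series):
        items = list(annual_losses.items())
    else:
        items = list(annual_losses.items())
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    total = 0.0
    for year, loss in items:
        if year > horizon:
            raise ValueError(f"loss year {year} lies beyond the horizon {horizon}")
        if mode == "future_value":
            total += loss * (1.0 + rate) ** (horizon - year)
        elif mode == "present_value_2010":
            total += loss / (1.0 + rate) ** (year - 2010)
        else:
            raise ValueError(f"unknown discount mode {mode!r}")
    return total
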