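"""Dietary methylmercury exposure aggregation.

Per-capita MeHg exposure for a country's general population is the sum of
intake x concentration over three food pathways -- seafood, freshwater fish
(both split into four trophic-level bins), and rice:

    E = sum_i I_i^FW * C_i^FW  +  sum_i I_i^sea * C_i^sea  +  I^rice * C^rice

with E in ug MeHg per person per day, intakes in g/day and concentrations in
ug/g. Fish concentrations biomagnify roughly tenfold from herbivorous
(trophic level 2) to apex (level 5) species, so concentration data are
binned by trophic level and summarised by the geometric mean per bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GLOBAL = "GLOBAL"

#: grams per day equivalent of 1 kg per year (FAO annual convention)
KG_PER_YEAR_TO_G_PER_DAY = 1000.0 / 365.25

SEAFOOD = "seafood"
FRESHWATER_FISH = "freshwater_fish"
RICE = "rice"
CATEGORIES = (SEAFOOD, FRESHWATER_FISH, RICE)
FISH_CATEGORIES = (SEAFOOD, FRESHWATER_FISH)

FARM = "farm"
WILD = "wild"
NO_ORIGIN = "n/a"


class TrophicBin(Enum):
    """Four contiguous trophic-level bins covering [2, 5]."""

    TL_2_25 = ("2-2.5", 2.0, 2.5)
    TL_25_35 = ("2.5-3.5", 2.5, 3.5)
    TL_35_45 = ("3.5-4.5", 3.5, 4.5)
    TL_45_5 = ("4.5-5", 4.5, 5.0)

    def __init__(self, label: str, lower: float, upper: float):
        self.label = label
        self.lower = lower
        self.upper = upper

    @classmethod
    def from_label(cls, label: str) -> "TrophicBin":
        for b in cls:
            if b.label == label:
                return b
        raise KeyError(f"unknown trophic bin label {label!r}")

    @classmethod
    def from_trophic_level(cls, tl: float) -> "TrophicBin":
        if not (2.0 <= tl <= 5.0):
            raise ValueError(f"trophic level {tl} outside the binned range [2, 5]")
        for b in cls:
            # half-open bins; level 5 belongs to the top bin
            if b.lower <= tl < b.upper:
                return b
        return cls.TL_45_5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


BIN_LABELS = tuple(b.label for b in TrophicBin)


def bin_concentrations(
    samples: Iterable[tuple[float, float]],
) -> dict[TrophicBin, float]:
    """Geometric mean MeHg concentration per trophic-level bin.

    Parameters
    ----------
    samples:
        Iterable of ``(trophic_level, concentration_ug_per_g)`` pairs.

    Returns
    -------
    dict mapping each non-empty :class:`TrophicBin` to the geometric mean of
    its samples. Empty bins are absent from the result (not reported as 0).
    """
    logs: dict[TrophicBin, list[float]] = {}
    for i, (tl, conc) in enumerate(samples):
        if conc <= 0:
            raise ValueError(
                f"sample {i} (trophic level {tl}): non-positive concentration {conc}"
            )
        b = TrophicBin.from_trophic_level(tl)  # raises for tl outside [2, 5]
        logs.setdefault(b, []).append(math.log(conc))
    return {b: math.exp(np.mean(v)) for b, v in logs.items()}


def allocate_fish_consumption(
    total_intake: float,
    fractions: Sequence[float] | Mapping[TrophicBin, float] | None = None,
    mti: float | None = None,
    spread: bool = False,
) -> dict[TrophicBin, float]:
    """Split a country's total fish intake (g/day) across trophic bins.

    Either explicit per-bin ``fractions`` (summing to 1) are applied, or, when
    a detailed consumption inventory is missing, the country's marine trophic
    index ``mti`` is used: all intake is assigned to the bin containing the
    MTI, or, with ``spread=True``, a triangular 1/4-1/2-1/4 weighting over the
    adjacent bins.
    """
    if total_intake < 0:
        raise ValueError(f"total intake must be non-negative, got {total_intake}")
    bins = list(TrophicBin)
    if fractions is not None:
        if isinstance(fractions, Mapping):
            fracs = [float(fractions.get(b, 0.0)) for b in bins]
        else:
            fracs = [float(f) for f in fractions]
            if len(fracs) != len(bins):
                raise ValueError(f"expected {len(bins)} fractions, got {len(fracs)}")
        if any(f < 0 for f in fracs):
            raise ValueError("bin fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"bin fractions sum to {sum(fracs)}, expected 1")
        return {b: total_intake * f for b, f in zip(bins, fracs)}
    if mti is None:
        raise ValueError("either bin fractions or a marine trophic index is required")
    home = TrophicBin.from_trophic_level(mti)  # validates mti in [2, 5]
    if not spread:
        return {b: (total_intake if b is home else 0.0) for b in bins}
    idx = bins.index(home)
    weights = dict.fromkeys(bins, 0.0)
    weights[home] = 0.5
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(bins):
            weights[bins[j]] = 0.25
    norm = sum(weights.values())
    return {b: total_intake * w / norm for b, w in weights.items()}


@dataclass
class FoodIntakeTable:
    """Per-country, per-category (and per-trophic-bin for fish) daily intake.

    Backed by a DataFrame with columns ``country`` (ISO3), ``category``
    ({seafood, freshwater_fish, rice}), ``trophic_bin`` (bin label, empty for
    rice) and ``intake`` (g per person per day).
    """

    df: pd.DataFrame

    COLUMNS = ("country", "category", "trophic_bin", "intake")

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"intake table missing columns {sorted(missing)}")
        if (self.df["intake"] < 0).any():
            bad = self.df[self.df["intake"] < 0].iloc[0]
            raise ValueError(
                f"negative intake for {bad['country']}/{bad['category']}: {bad['intake']}"
            )
        if not self.df["category"].isin(CATEGORIES).all():
            bad = sorted(set(self.df["category"]) - set(CATEGORIES))
            raise ValueError(f"unknown food categories {bad}")
        rice = self.df[self.df["category"] == RICE]
        if not (rice["trophic_bin"].fillna("") == "").all():
            raise ValueError("rice intake records must not carry a trophic bin")
        fish = self.df[self.df["category"].isin(FISH_CATEGORIES)]
        bad_bins = set(fish["trophic_bin"]) - set(BIN_LABELS)
        if bad_bins:
            raise ValueError(f"fish intake records carry unknown bins {sorted(bad_bins)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str | None, float]]
    ) -> "FoodIntakeTable":
        rows = [
            {"country": c, "category": cat, "trophic_bin": b or "", "intake": v}
            for c, cat, b, v in records
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "FoodIntakeTable":
        df = pd.read_csv(path, dtype={"trophic_bin": str}, keep_default_na=False)
        df["intake"] = df["intake"].astype(float)
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country"].unique())

    def records(self, country: str) -> list[tuple[str, str | None, float]]:
        sub = self.df[self.df["country"] == country]
        if sub.empty:
            raise KeyError(f"country {country!r} not present in the intake table")
        return [
            (r.category, r.trophic_bin or None, float(r.intake))
            for r in sub.itertuples()
        ]


@dataclass
class ConcentrationTable:
    """MeHg concentration (geometric mean, ug/g) per category x bin x origin.

    Rows are keyed by country or the ``GLOBAL`` fallback used for countries
    without their own measurements. ``gsd`` holds the within-bin geometric
    standard deviation used for uncertainty sampling. Origin is ``farm`` or
    ``wild`` for fish categories and ``n/a`` for rice.
    """

    df: pd.DataFrame

    COLUMNS = ("country", "category", "trophic_bin", "origin", "concentration", "gsd")

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()
        self._index = {
            (r.country, r.category, r.trophic_bin or None, r.origin): (
                float(r.concentration),
                float(r.gsd),
            )
            for r in self.df.itertuples()
        }

    def validate(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"concentration table missing columns {sorted(missing)}")
        if (self.df["concentration"] <= 0).any():
            bad = self.df[self.df["concentration"] <= 0].iloc[0]
            raise ValueError(
                "non-positive concentration for "
                f"{bad['country']}/{bad['category']}/{bad['trophic_bin']}: "
                f"{bad['concentration']}"
            )
        if (self.df["gsd"] < 1).any():
            raise ValueError("geometric standard deviations must be >= 1")
        keys = self.df[["category", "trophic_bin", "origin"]].drop_duplicates()
        glob = self.df[self.df["country"] == GLOBAL]
        gkeys = set(map(tuple, glob[["category", "trophic_bin", "origin"]].values))
        for cat, b, orig in map(tuple, keys.values):
            if (cat, b, orig) not in gkeys:
                raise ValueError(
                    f"no GLOBAL fallback record for ({cat}, {b or 'n/a'}, {orig})"
                )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str | None, str, float, float]],
    ) -> "ConcentrationTable":
        rows = [
            {
                "country": c,
                "category": cat,
                "trophic_bin": b or "",
                "origin": orig,
                "concentration": v,
                "gsd": g,
            }
            for c, cat, b, orig, v, g in records
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        df = pd.read_csv(path, dtype={"trophic_bin": str}, keep_default_na=False)
        df["concentration"] = df["concentration"].astype(float)
        df["gsd"] = df["gsd"].astype(float)
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def lookup(
        self, country: str, category: str, trophic_bin: str | None, origin: str
    ) -> float:
        """Concentration with silent-but-logged GLOBAL fallback."""
        key = (country, category, trophic_bin, origin)
        if key in self._index:
            return self._index[key][0]
        gkey = (GLOBAL, category, trophic_bin, origin)
        if gkey in self._index:
            log.info(
                "no %s concentration for %s/%s/%s; using GLOBAL geometric mean",
                country,
                category,
                trophic_bin or "n/a",
                origin,
            )
            return self._index[gkey][0]
        raise KeyError(
            f"no concentration record for ({category}, {trophic_bin or 'n/a'}, "
            f"{origin}) even after GLOBAL fallback"
        )

    def gsd(self, category: str, trophic_bin: str | None, origin: str = WILD) -> float:
        key = (GLOBAL, category, trophic_bin, origin)
        if key not in self._index:
            raise KeyError(f"no GLOBAL record for ({category}, {trophic_bin}, {origin})")
        return self._index[key][1]

    def effective(
        self,
        country: str,
        category: str,
        trophic_bin: str | None,
        farm_fraction: float = 0.0,
    ) -> float:
        """Concentration seen by consumers, mixing farmed and wild supply.

        Fish categories combine the farm and wild geometric means as the
        farm-fraction-weighted geometric mixture
        ``exp(f*ln(c_farm) + (1-f)*ln(c_wild))``, preserving geometric-mean
        semantics. Rice has a single origin.
        """
        if category == RICE:
            return self.lookup(country, category, None, NO_ORIGIN)
        if not (0.0 <= farm_fraction <= 1.0):
            raise ValueError(f"farm fraction must lie in [0, 1], got {farm_fraction}")
        c_wild = self.lookup(country, category, trophic_bin, WILD)
        if farm_fraction == 0.0:
            return c_wild
        c_farm = self.lookup(country, category, trophic_bin, FARM)
        return math.exp(
            farm_fraction * math.log(c_farm)
            + (1.0 - farm_fraction) * math.log(c_wild)
        )

    def scaled(self, factors: Mapping[str, float]) -> "ConcentrationTable":
        """New table with each category's concentrations multiplied."""
        for cat, f in factors.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} in scaling factors")
            if f <= 0:
                raise ValueError(f"scaling factor for {cat} must be positive, got {f}")
        df = self.df.copy()
        mult = df["category"].map(lambda c: factors.get(c, 1.0))
        df["concentration"] = df["concentration"] * mult
        return ConcentrationTable(df)


@dataclass
class ExposureResult:
    """Per-capita dietary MeHg exposure for one country-year."""

    country: str
    year: int
    total: float  # ug/day per capita
    by_pathway: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.by_pathway.values()):
            raise ValueError("pathway exposures must be non-negative")
        s = sum(self.by_pathway.values())
        if not math.isclose(self.total, s, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"total exposure {self.total} does not match pathway sum {s}"
            )


def _resolve_farm_fraction(
    farm_fraction: float | Mapping[str, float], country: str
) -> float:
    if isinstance(farm_fraction, Mapping):
        return float(farm_fraction.get(country, 0.0))
    return float(farm_fraction)


def exposure_contributions(
    intake: FoodIntakeTable,
    conc: ConcentrationTable,
    country: str,
    farm_fraction: float | Mapping[str, float] = 0.0,
) -> list[tuple[str, str | None, float]]:
    """Per-record intake x concentration products (ug/day).

    Returns one ``(category, trophic_bin, contribution)`` triple per intake
    record; the exposure total is their sum. This is the single place where
    intake and concentration tables are joined.
    """
    f = _resolve_farm_fraction(farm_fraction, country)
    out = []
    for category, bin_label, g_per_day in intake.records(country):
        c = conc.effective(country, category, bin_label, farm_fraction=f)
        out.append((category, bin_label, g_per_day * c))
    return out


def compute_exposure(
    intake: FoodIntakeTable,
    conc: ConcentrationTable,
    country: str,
    year: int = 2010,
    farm_fraction: float | Mapping[str, float] = 0.0,
) -> ExposureResult:
    """Total and per-pathway dietary MeHg exposure for one country."""
    contribs = exposure_contributions(intake, conc, country, farm_fraction)
    by_pathway = {cat: 0.0 for cat in CATEGORIES}
    for category, _bin, value in contribs:
        by_pathway[category] += value
    return ExposureResult(
        country=country,
        year=year,
        total=sum(by_pathway.values()),
        by_pathway=by_pathway,
    )
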