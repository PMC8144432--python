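"""Dose-response models linking dietary MeHg intake to health endpoints.

Two endpoints are modelled for the general population:

* prenatal IQ decrement, linear and threshold-free in maternal intake:
  ``dIQ = gamma * lambda * beta * intake`` (points per fetus), where the
  one-compartment pharmacokinetic coefficients beta (intake -> blood Hg,
  0.6 ug/L per ug/day) and lambda (blood -> hair, 0.2 ug/g per ug/L) chain
  into the epidemiological slope gamma (0.3 IQ points per ug/g hair);

* fatal heart attacks (FHA) in adults, log-linear in hair Hg:
  ``dCF = sum_g POP_g * Cf_g * omega * (1 - exp(-phi*lambda*beta*intake))``
  with phi = 0.066 per ug/g hair and omega = 0.33 the subjective probability
  that the epidemiological association is causal.

Intake is carried as ug MeHg per person per day, i.e. the product
EDI x BW of the per-body-weight daily dose and female adult body weight;
because only this product enters any formula, results are independent of the
body-weight value itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DoseResponseParams:
    """Pharmacokinetic and epidemiological coefficients.

    beta : ug/L blood per ug/day intake (one-compartment steady state)
    lambda_ : ug/g hair per ug/L blood
    gamma : IQ points per ug/g maternal hair Hg
    phi : FHA hazard slope per ug/g hair Hg
    omega : probability of causality for the FHA association, in [0, 1]
    bw : adult female body weight (kg); reporting convenience only, the
        models operate on the intake product EDI x BW and never on bw alone
    """

    beta: float = 0.6
    lambda_: float = 0.2
    gamma: float = 0.3
    phi: float = 0.066
    omega: float = 0.33
    bw: float = 60.0

    def __post_init__(self):
        for name in ("beta", "lambda_", "gamma", "phi", "omega", "bw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")

    @property
    def iq_slope(self) -> float:
        """IQ points lost per ug/day of intake (gamma*lambda*beta)."""
        return self.gamma * self.lambda_ * self.beta

    @property
    def fha_exponent_slope(self) -> float:
        """Exponent per ug/day of intake in the FHA model (phi*lambda*beta)."""
        return self.phi * self.lambda_ * self.beta


DEFAULT_PARAMS = DoseResponseParams()


@dataclass
class DemographicRecord:
    """Population structure of one country-year."""

    country: str
    year: int
    pop_by_gender: dict[str, float]
    fha_incidence_by_gender: dict[str, float]  # deaths per person per year
    births: float

    def __post_init__(self):
        for g in ("male", "female"):
            if g not in self.pop_by_gender or g not in self.fha_incidence_by_gender:
                raise ValueError(f"gender {g!r} missing from demographic record")
        if any(v < 0 for v in self.pop_by_gender.values()):
            raise ValueError("populations must be non-negative")
        if any(v < 0 for v in self.fha_incidence_by_gender.values()):
            raise ValueError("FHA incidence must be non-negative")
        if self.births < 0:
            raise ValueError("births must be non-negative")

    @property
    def baseline_fha_deaths(self) -> float:
        """sum_g POP_g * Cf_g, the baseline FHA deaths per year."""
        return sum(
            self.pop_by_gender[g] * self.fha_incidence_by_gender[g]
            for g in self.pop_by_gender
        )


@dataclass
class DemographicTrajectory:
    """Country x year x gender population, FHA incidence and births.

    CSV dialect: country, year, gender, population, fha_incidence, births
    (births repeated on each gender row of the same country-year).
    """

    df: pd.DataFrame

    COLUMNS = ("country", "year", "gender", "population", "fha_incidence", "births")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"demographics missing columns {sorted(missing)}")
        for col in ("population", "fha_incidence", "births"):
            if (self.df[col] < 0).any():
                raise ValueError(f"demographics column {col} must be non-negative")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "DemographicTrajectory":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def at(self, country: str, year: int) -> DemographicRecord:
        sub = self.df[(self.df["country"] == country) & (self.df["year"] == year)]
        if sub.empty:
            raise KeyError(f"no demographics for {country} in {year}")
        births = float(sub["births"].iloc[0])
        return DemographicRecord(
            country=country,
            year=year,
            pop_by_gender={r.gender: float(r.population) for r in sub.itertuples()},
            fha_incidence_by_gender={
                r.gender: float(r.fha_incidence) for r in sub.itertuples()
            },
            births=births,
        )


@dataclass
class BiomarkerEstimate:
    """Steady-state blood (ug/L) and hair (ug/g) Hg implied by intake."""

    blood: float
    hair: float

    def __post_init__(self):
        if self.blood < 0 or self.hair < 0:
            raise ValueError("biomarker concentrations must be non-negative")


@dataclass
class HealthEndpointResult:
    country: str
    year: int
    per_fetus_iq: float
    total_iq: float
    fha_deaths: float

    def __post_init__(self):
        if min(self.per_fetus_iq, self.total_iq, self.fha_deaths) < 0:
            raise ValueError("health endpoints must be non-negative")


def _check_intake(intake: float) -> None:
    if intake < 0:
        raise ValueError(f"intake must be non-negative, got {intake} ug/day")


def per_fetus_iq(
    intake: float, params: DoseResponseParams = DEFAULT_PARAMS
) -> float:
    """IQ points lost per fetus at a maternal intake of ``intake`` ug/day."""
    _check_intake(intake)
    return params.iq_slope * intake


def total_iq_loss(per_fetus: float, demo: DemographicRecord | float) -> float:
    """National IQ loss per year: per-fetus decrement x newborns."""
    if per_fetus < 0:
        raise ValueError("per-fetus IQ decrement must be non-negative")
    births = demo.births if isinstance(demo, DemographicRecord) else float(demo)
    if births < 0:
        raise ValueError("births must be non-negative")
    return per_fetus * births


def fha_deaths(
    intake: float,
    demo: DemographicRecord,
    params: DoseResponseParams = DEFAULT_PARAMS,
) -> float:
    """MeHg-attributable fatal heart attack deaths per year.

    Saturating in intake: the attributable fraction approaches the
    probability-of-causality cap omega as intake grows, so deaths are always
    strictly below omega times the baseline FHA deaths for finite intake.
    """
    _check_intake(intake)
    rel = -math.expm1(-params.fha_exponent_slope * intake)  # 1 - exp(-k*intake)
    return demo.baseline_fha_deaths * params.omega * rel


def biomarkers(
    intake: float, params: DoseResponseParams = DEFAULT_PARAMS
) -> BiomarkerEstimate:
    """Blood and hair Hg implied by a steady dietary intake (ug/day)."""
    _check_intake(intake)
    blood = params.beta * intake
    return BiomarkerEstimate(blood=blood, hair=params.lambda_ * blood)


@dataclass
class BiomarkerEvaluation:
    """Agreement between modelled and measured biomarker levels."""

    pearson_r: float
    n: int
    predicted_mean: float
    predicted_sd: float
    measured_mean: float
    measured_sd: float


def evaluate_biomarkers(
    predicted, measured
) -> BiomarkerEvaluation:
    """Pearson correlation and per-set summaries for paired country values."""
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("predicted and measured vectors must be paired")
    if pred.size < 3:
        raise ValueError(f"at least 3 paired countries required, got {pred.size}")
    r = float(stats.pearsonr(pred, meas).statistic)
    return BiomarkerEvaluation(
        pearson_r=r,
        n=int(pred.size),
        predicted_mean=float(pred.mean()),
        predicted_sd=float(pred.std(ddof=1)),
        measured_mean=float(meas.mean()),
        measured_sd=float(meas.std(ddof=1)),
    )
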