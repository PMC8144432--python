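"""High-level runs tying the pipeline stages into headline reports.

Three entry points mirror the study design: ``run_baseline`` produces the
present-day per-country exposure/health/loss table and rankings,
``run_scenarios`` produces yearly global trajectories per emission scenario
with cumulative discounted losses at the horizon, and ``run_uncertainty``
propagates the four factor-group uncertainties by Monte Carlo. Each writes
CSV tables plus a JSON summary when an output directory is given, and all
outputs regenerate bit-identically from the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .dose_response import (
    DoseResponseParams,
    biomarkers,
    evaluate_biomarkers,
    fha_deaths,
    per_fetus_iq,
    total_iq_loss,
)
from .exposure import compute_exposure
from .pipeline import PipelineEngine
from .synthetic import SyntheticWorldConfig, World, generate_world
from .uncertainty import MonteCarloResult, UncertaintySpec, factor_sensitivity, run_monte_carlo
from .valuation import ValuationParams, fha_monetary_loss, iq_monetary_loss

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    world_dir: str | None = None  # load tables from CSV instead of generating
    scenarios: tuple[str, ...] = ("CP", "NP-Delayed", "MFR", "A1B", "A2")
    years: tuple[int, int] = (2010, 2050)
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    valuation: ValuationParams = field(default_factory=ValuationParams)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    uncertainty_scenario: str = "CP"
    output_dir: str = "out"
    seed: int | None = None  # overrides world and uncertainty seeds
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is not None:
            self.world = dataclasses.replace(self.world, seed=int(self.seed))
            self.uncertainty = dataclasses.replace(self.uncertainty, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "world" in raw:
            w = dict(raw["world"])
            for key in ("years", "archetype_weights", "scenario_responses"):
                if key in w and isinstance(w[key], list):
                    w[key] = tuple(w[key])
            if "scenario_responses" in w and isinstance(w["scenario_responses"], dict):
                w["scenario_responses"] = {
                    k: tuple(v) for k, v in w["scenario_responses"].items()
                }
            kwargs["world"] = SyntheticWorldConfig(**w)
        if "dose_response" in raw:
            kwargs["dose_response"] = DoseResponseParams(**raw["dose_response"])
        if "valuation" in raw:
            v = dict(raw["valuation"])
            if "vsl_range" in v:
                v["vsl_range"] = tuple(v["vsl_range"])
            if "deflators" in v:
                v["deflators"] = {int(k): float(x) for k, x in v["deflators"].items()}
            kwargs["valuation"] = ValuationParams(**v)
        if "uncertainty" in raw:
            u = dict(raw["uncertainty"])
            for key in ("omega_values", "iq_point_values", "vsl_bounds"):
                if key in u:
                    u[key] = tuple(u[key])
            kwargs["uncertainty"] = UncertaintySpec(**u)
        for key in ("world_dir", "uncertainty_scenario", "output_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(raw["scenarios"])
        if "years" in raw:
            kwargs["years"] = tuple(raw["years"])
        return cls(**kwargs)


def build_world(config: RunConfig) -> World:
    if config.world_dir is not None:
        return World.from_csv_dir(config.world_dir)
    return generate_world(config.world)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def run_baseline(
    world: World,
    dr_params: DoseResponseParams | None = None,
    val_params: ValuationParams | None = None,
    year: int = 2010,
    out_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Present-day per-country health impacts and a ranked summary."""
    dr = dr_params or DoseResponseParams()
    val = val_params or ValuationParams()
    rows = []
    for country in world.countries:
        exp = compute_exposure(
            world.intake, world.concentrations, country, year, world.farm_fractions
        )
        demo = world.demographics.at(country, year)
        econ = world.economics.at(country, year)
        pf = per_fetus_iq(exp.total, dr)
        tiq = total_iq_loss(pf, demo)
        deaths = fha_deaths(exp.total, demo, dr)
        bio = biomarkers(exp.total, dr)
        rows.append(
            {
                "country": country,
                "year": year,
                "exposure_total": exp.total,
                "exposure_seafood": exp.by_pathway["seafood"],
                "exposure_freshwater_fish": exp.by_pathway["freshwater_fish"],
                "exposure_rice": exp.by_pathway["rice"],
                "per_fetus_iq": pf,
                "total_iq": tiq,
                "fha_deaths": deaths,
                "blood_ug_L": bio.blood,
                "hair_ug_g": bio.hair,
                "iq_loss_usd": iq_monetary_loss(tiq, econ, val),
                "fha_loss_usd": fha_monetary_loss(deaths, econ, val),
            }
        )
    frame = pd.DataFrame(rows).set_index("country")
    frame["total_usd"] = frame["iq_loss_usd"] + frame["fha_loss_usd"]

    summary: dict[str, Any] = {
        "year": year,
        "global": {
            "total_iq_points": float(frame["total_iq"].sum()),
            "fha_deaths": float(frame["fha_deaths"].sum()),
            "iq_loss_usd": float(frame["iq_loss_usd"].sum()),
            "fha_loss_usd": float(frame["fha_loss_usd"].sum()),
            "total_usd": float(frame["total_usd"].sum()),
        },
        "rankings": {
            "per_fetus_iq": frame["per_fetus_iq"].sort_values(ascending=False).head(10).to_dict(),
            "total_usd": frame["total_usd"].sort_values(ascending=False).head(10).to_dict(),
        },
    }
    if world.measured_blood and len(world.measured_blood) >= 3:
        countries = [c for c in frame.index if c in world.measured_blood]
        ev = evaluate_biomarkers(
            frame.loc[countries, "blood_ug_L"].to_numpy(),
            [world.measured_blood[c] for c in countries],
        )
        summary["biomarker_evaluation"] = dataclasses.asdict(ev)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "baseline.csv")
        _write_json(out / "baseline_summary.json", summary)
    return frame, summary


def run_scenarios(
    world: World,
    scenarios: Sequence[str] | None = None,
    dr_params: DoseResponseParams | None = None,
    val_params: ValuationParams | None = None,
    years: tuple[int, int] = (2010, 2050),
    out_dir=None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Yearly global health-effect trajectories per emission scenario."""
    scenarios = list(scenarios or sorted(world.trajectories))
    missing = [s for s in scenarios if s not in world.trajectories]
    if missing:
        raise KeyError(f"no trajectories for scenarios {missing}")
    engine = PipelineEngine(world, dr_params, val_params, years=years)
    tables: dict[str, pd.DataFrame] = {}
    cumulative: dict[str, float] = {}
    for s in scenarios:
        tables[s] = engine.yearly_global(s)
        cumulative[s] = engine.cumulative_discounted_loss(s)
    summary = {
        "years": list(years),
        "cumulative_discounted_usd": cumulative,
        "ordering_2050_total_usd": sorted(
            scenarios, key=lambda s: float(tables[s]["total_usd"].iloc[-1])
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, t in tables.items():
            t.to_csv(out / f"scenario_{s}.csv")
        _write_json(out / "scenarios_summary.json", summary)
    return tables, summary


def run_uncertainty(
    world: World,
    spec: UncertaintySpec | None = None,
    dr_params: DoseResponseParams | None = None,
    val_params: ValuationParams | None = None,
    scenario: str = "CP",
    with_sensitivity: bool = True,
    out_dir=None,
    dump_draws: bool = False,
) -> MonteCarloResult:
    """Monte Carlo 95% CI (and per-factor envelopes) for one scenario."""
    spec = spec or UncertaintySpec()
    result = run_monte_carlo(
        world, spec, scenario=scenario, dr_params=dr_params, val_params=val_params
    )
    if with_sensitivity:
        result.sensitivity = factor_sensitivity(
            world, spec, scenario=scenario, dr_params=dr_params, val_params=val_params
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = result.summary()
        payload["scenario"] = scenario
        _write_json(out / "uncertainty_summary.json", payload)
        if dump_draws:
            pd.DataFrame({"draw": np.arange(result.draws.size), "value": result.draws}).to_csv(
                out / "uncertainty_draws.csv", index=False
            )
    return result


def write_report(out_dir) -> Path:
    """Assemble available JSON summaries into a single markdown report."""
    out = Path(out_dir)
    lines = ["# MeHg exposure and health-risk report", ""]
    for name, title in (
        ("baseline_summary.json", "Present-day baseline"),
        ("scenarios_summary.json", "Emission scenarios"),
        ("uncertainty_summary.json", "Uncertainty"),
    ):
        p = out / name
        if not p.exists():
            continue
        data = json.loads(p.read_text())
        lines += [f"## {title}", "", "```json", json.dumps(data, indent=2, sort_keys=True), "```", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
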