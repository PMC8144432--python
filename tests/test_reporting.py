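"""End-to-end runs, report regeneration and the command-line interface."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import mehgrisk as m
from mehgrisk.cli import main


def straight_line_totals(world, dr, val, year=2010):
    """Independent plain-loop recomputation of global baseline totals."""
    iq_pts = deaths = iq_usd = fha_usd = 0.0
    for c in world.countries:
        E = 0.0
        sub = world.intake.df[world.intake.df["country"] == c]
        for r in sub.itertuples():
            b = r.trophic_bin or None
            E += r.intake * world.concentrations.effective(
                c, r.category, b, 0.0 if r.category == "rice" else world.farm_fractions[c]
            )
        demo = world.demographics.at(c, year)
        econ = world.economics.at(c, year)
        pf = dr.gamma * dr.lambda_ * dr.beta * E
        tiq = pf * demo.births
        dth = demo.baseline_fha_deaths * dr.omega * (
            1 - math.exp(-dr.phi * dr.lambda_ * dr.beta * E)
        )
        iq_pts += tiq
        deaths += dth
        iq_usd += tiq * val.iq_value * val.deflator(2008) * econ.gdp_ratio
        fha_usd += dth * val.vsl * val.deflator(2005) * econ.gdp_ratio
    return iq_pts, deaths, iq_usd + fha_usd


class TestRunBaseline:
    def test_flagship_tops_per_fetus_iq_ranking(self, default_world):
        frame, summary = m.run_baseline(default_world)
        assert frame["per_fetus_iq"].idxmax() == "I00"
        top = next(iter(summary["rankings"]["per_fetus_iq"]))
        assert top == "I00"

    def test_zero_concentration_world_zero_impacts(self, default_world):
        tiny = m.ConcentrationTable(
            default_world.concentrations.df.assign(concentration=1e-300)
        )
        world = m.World(
            intake=default_world.intake,
            concentrations=tiny,
            demographics=default_world.demographics,
            economics=default_world.economics,
            trajectories=default_world.trajectories,
            farm_fractions=default_world.farm_fractions,
        )
        frame, summary = m.run_baseline(world)
        assert summary["global"]["total_usd"] == pytest.approx(0.0, abs=1e-250)
        assert summary["global"]["fha_deaths"] == pytest.approx(0.0, abs=1e-250)

    def test_global_totals_equal_sum_over_countries(self, default_world):
        frame, summary = m.run_baseline(default_world)
        assert summary["global"]["total_usd"] == pytest.approx(frame["total_usd"].sum())
        assert summary["global"]["fha_deaths"] == pytest.approx(frame["fha_deaths"].sum())

    def test_biomarker_evaluation_block_present(self, default_world):
        _, summary = m.run_baseline(default_world)
        ev = summary["biomarker_evaluation"]
        assert ev["n"] == len(default_world.countries)
        assert -1.0 <= ev["pearson_r"] <= 1.0


class TestRunScenarios:
    def test_cp_deaths_rise_with_population_while_exposure_flat(self, default_world):
        tables, _ = m.run_scenarios(default_world, ["CP"])
        cp = tables["CP"]
        assert cp["fha_deaths"].iloc[-1] > cp["fha_deaths"].iloc[0]
        engine = m.PipelineEngine(default_world)
        E = engine.exposures("CP")
        assert np.allclose(E[0], E[-1])  # per-capita exposure constant under CP

    def test_identical_scenarios_identical_trajectories(self, default_world):
        world = m.World(
            intake=default_world.intake,
            concentrations=default_world.concentrations,
            demographics=default_world.demographics,
            economics=default_world.economics,
            trajectories={
                "CP": default_world.trajectories["CP"],
                "CP2": m.EnvironmentalTrajectory("CP2", default_world.trajectories["CP"].df),
            },
            farm_fractions=default_world.farm_fractions,
        )
        tables, summary = m.run_scenarios(world, ["CP", "CP2"])
        pd.testing.assert_frame_equal(tables["CP"], tables["CP2"])
        assert summary["cumulative_discounted_usd"]["CP"] == pytest.approx(
            summary["cumulative_discounted_usd"]["CP2"]
        )

    def test_2050_cumulative_loss_ordering(self, default_world):
        _, summary = m.run_scenarios(default_world)
        c = summary["cumulative_discounted_usd"]
        assert c["MFR"] < c["NP-Delayed"] < c["CP"] < c["A2"] < c["A1B"]

    def test_missing_scenario_rejected(self, default_world):
        with pytest.raises(KeyError, match="nope"):
            m.run_scenarios(default_world, ["nope"])


class TestEndToEndOracle:
    def test_engine_matches_straight_line_recomputation(self):
        """Global totals from the vectorised engine equal an independent
        plain-loop recomputation on 10 random 5-country worlds."""
        dr, val = m.DoseResponseParams(), m.ValuationParams()
        for seed in range(10):
            world = m.generate_world(
                m.SyntheticWorldConfig(n_countries=5, seed=100 + seed)
            )
            frame, summary = m.run_baseline(world, dr, val)
            iq_pts, deaths, total_usd = straight_line_totals(world, dr, val)
            assert summary["global"]["total_iq_points"] == pytest.approx(iq_pts, rel=1e-9)
            assert summary["global"]["fha_deaths"] == pytest.approx(deaths, rel=1e-9)
            assert summary["global"]["total_usd"] == pytest.approx(total_usd, rel=1e-9)
            engine = m.PipelineEngine(world, dr, val)
            cp2010 = engine.yearly_global("CP").loc[2010]
            assert cp2010["total_usd"] == pytest.approx(total_usd, rel=1e-9)
            assert cp2010["iq_points"] == pytest.approx(iq_pts, rel=1e-9)


class TestRunUncertainty:
    def test_single_draw_degenerate_point_report(self, default_world, tmp_path):
        spec = m.UncertaintySpec(n_draws=1).degenerate()
        res = m.run_uncertainty(
            default_world, spec, with_sensitivity=False, out_dir=tmp_path
        )
        assert res.ci_low == res.ci_high == pytest.approx(res.point_estimate)
        payload = json.loads((tmp_path / "uncertainty_summary.json").read_text())
        assert payload["n_draws"] == 1

    def test_seeded_reports_regenerate_bit_identically(self, default_world, tmp_path):
        spec = m.UncertaintySpec(n_draws=25, seed=7)
        for d in ("a", "b"):
            m.run_uncertainty(
                default_world, spec, with_sensitivity=True, out_dir=tmp_path / d
            )
        assert (tmp_path / "a/uncertainty_summary.json").read_bytes() == (
            tmp_path / "b/uncertainty_summary.json"
        ).read_bytes()


class TestCLI:
    def test_generate_then_run_baseline_from_files(self, tmp_path):
        runner = CliRunner()
        wdir = str(tmp_path / "world")
        res = runner.invoke(main, ["generate-world", "--seed", "3", "--out", wdir])
        assert res.exit_code == 0, res.output
        cfg = tmp_path / "run.yaml"
        cfg.write_text(f"world_dir: {wdir}\noutput_dir: {tmp_path / 'out'}\n")
        res = runner.invoke(main, ["run-baseline", "--config", str(cfg)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "baseline.csv").exists()
        summary = json.loads((tmp_path / "out" / "baseline_summary.json").read_text())
        assert summary["global"]["total_usd"] > 0

    def test_scenarios_uncertainty_and_report(self, tmp_path):
        runner = CliRunner()
        out = str(tmp_path / "out")
        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "world: {n_countries: 6}\nuncertainty: {n_draws: 15}\n"
            f"seed: 5\noutput_dir: {out}\n"
        )
        for cmd in ("run-scenarios", "run-uncertainty"):
            res = runner.invoke(main, [cmd, "--config", str(cfg)])
            assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["report", "--out", out])
        assert res.exit_code == 0, res.output
        text = (tmp_path / "out" / "report.md").read_text()
        assert "Emission scenarios" in text and "Uncertainty" in text

    def test_validation_failure_exit_code(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("world: {archetype_weights: {island: 0.5, asian: 0.1}}\n")
        res = runner.invoke(main, ["run-baseline", "--config", str(cfg)])
        assert res.exit_code == 1

    def test_config_seed_reproducibility(self, tmp_path):
        runner = CliRunner()
        hashes = []
        for d in ("w1", "w2"):
            out = str(tmp_path / d)
            res = runner.invoke(main, ["generate-world", "--seed", "11", "--out", out])
            assert res.exit_code == 0, res.output
            hashes.append(
                json.loads((tmp_path / d / "manifest.json").read_text())["content_hash"]
            )
        assert hashes[0] == hashes[1]
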