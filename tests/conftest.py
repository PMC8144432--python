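import numpy as np
import pytest

import mehgrisk as m


@pytest.fixture(scope="session")
def default_world():
    """One shared default synthetic world (seed 1)."""
    return m.generate_world(m.SyntheticWorldConfig(seed=1))


@pytest.fixture()
def simple_tables():
    """Hand-checkable one-country tables: seafood 10 g/d @ 0.1 ug/g,
    freshwater fish 5 g/d @ 0.2 ug/g, rice 200 g/d @ 0.005 ug/g."""
    intake = m.FoodIntakeTable.from_records(
        [
            ("AAA", "seafood", "2.5-3.5", 10.0),
            ("AAA", "freshwater_fish", "2.5-3.5", 5.0),
            ("AAA", "rice", None, 200.0),
        ]
    )
    conc = m.ConcentrationTable.from_records(
        [
            ("GLOBAL", "seafood", "2.5-3.5", "wild", 0.1, 2.0),
            ("GLOBAL", "seafood", "2.5-3.5", "farm", 0.05, 2.0),
            ("GLOBAL", "freshwater_fish", "2.5-3.5", "wild", 0.2, 2.0),
            ("GLOBAL", "freshwater_fish", "2.5-3.5", "farm", 0.1, 2.0),
            ("GLOBAL", "rice", None, "n/a", 0.005, 2.0),
        ]
    )
    return intake, conc


def random_small_world(rng: np.random.Generator) -> tuple:
    """A tiny random (intake, concentration, farm fraction) world for oracle
    comparisons. Returns (intake, conc, farm_fractions, raw_records)."""
    countries = [f"C{i:02d}" for i in range(rng.integers(2, 5))]
    bins = ["2-2.5", "2.5-3.5", "3.5-4.5", "4.5-5"]
    intake_rows, conc_rows = [], []
    for cat in ("seafood", "freshwater_fish"):
        for b in bins:
            conc_rows.append(("GLOBAL", cat, b, "wild", rng.uniform(0.01, 0.5), 2.5))
            conc_rows.append(("GLOBAL", cat, b, "farm", rng.uniform(0.01, 0.5), 2.5))
    conc_rows.append(("GLOBAL", "rice", None, "n/a", rng.uniform(0.001, 0.01), 2.0))
    farm_fractions = {}
    for c in countries:
        for cat in ("seafood", "freshwater_fish"):
            for b in bins:
                if rng.random() < 0.7:
                    intake_rows.append((c, cat, b, rng.uniform(0.0, 50.0)))
        intake_rows.append((c, "rice", None, rng.uniform(0.0, 400.0)))
        farm_fractions[c] = float(rng.uniform(0.0, 1.0))
        if rng.random() < 0.5:  # country-specific concentration records
            f = rng.uniform(0.5, 2.0)
            for g, cat, b, o, v, gsd in list(conc_rows):
                if g == "GLOBAL":
                    conc_rows.append((c, cat, b, o, v * f, gsd))
    intake = m.FoodIntakeTable.from_records(intake_rows)
    conc = m.ConcentrationTable.from_records(conc_rows)
    return intake, conc, farm_fractions
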