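import logging

import numpy as np
import pandas as pd
import pytest

from mifspatial.cell_io import CellTable, PanelConfig
from mifspatial.phenotyping import assign_phenotypes, call_positivity
from mifspatial.regions import classify_compartments, segment_glut_regions
from mifspatial.synthetic import SimulationConfig, simulate_sample

# the explicit-positivity-column warning is expected on generator output
logging.getLogger("mifspatial.phenotyping").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    return PanelConfig()


@pytest.fixture(scope="session")
def sim_sample(panel):
    """One default simulated sample, fully processed through regions."""
    meta, table, truth = simulate_sample(SimulationConfig(seed=42), "SIM0")
    table = assign_phenotypes(call_positivity(table, panel))
    table, grid = classify_compartments(table, panel)
    table, grid = segment_glut_regions(table, grid, panel)
    return meta, table, grid, truth


def make_table(rows: list[dict], markers=("SOX10", "CD3", "CD31", "GLUT1")) -> CellTable:
    """Hand-built cell table; missing intensities default to 0."""
    df = pd.DataFrame(rows)
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    for col in ("x", "y"):
        if col not in df.columns:
            df[col] = pd.Series(dtype=float)
        df[col] = df[col].astype(float)
    for m in markers:
        col = f"{m}_intensity"
        if col not in df.columns:
            df[col] = 0.0
        df[col] = df[col].astype(float).fillna(0.0)
    return CellTable(df, tuple(markers))


@pytest.fixture
def small_panel() -> PanelConfig:
    markers = ("SOX10", "CD3", "CD31", "GLUT1")
    return PanelConfig(markers=markers, thresholds={m: 3.0 for m in markers})
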