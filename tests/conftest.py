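"""Shared fixtures: toy colonies, the study registry, simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from philopatry.geo import build_distance_matrix, load_colony_map, resolve_aliases
from philopatry.report import AnalysisConfig, prepare_inputs
from philopatry.studymap import study_colony
from philopatry.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_colony():
    """Five beaches on a 3-4-5 friendly grid, all three regions present."""
    coords = pd.DataFrame(
        {
            "code": ["A", "B", "C", "D", "E"],
            "easting_m": [0.0, 3.0, 100.0, 200.0, 300.0],
            "northing_m": [0.0, 4.0, 0.0, 0.0, 0.0],
            "region": ["Northern", "Northern", "Central", "Southern", "Southern"],
        }
    )
    return resolve_aliases(load_colony_map(coords))


@pytest.fixture(scope="session")
def toy_matrix(toy_colony):
    return build_distance_matrix(toy_colony)


@pytest.fixture(scope="session")
def study_map():
    return study_colony()


@pytest.fixture(scope="session")
def study_matrix(study_map):
    return build_distance_matrix(study_map)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset plus its qualified pairs."""
    colony, matrix, records, truth = simulate_dataset(SimConfig(seed=3))
    inputs = prepare_inputs(AnalysisConfig(), colony=colony, records=records)
    return {
        "colony": colony,
        "matrix": matrix,
        "records": records,
        "truth": truth,
        "inputs": inputs,
    }
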