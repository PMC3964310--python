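import warnings

import pandas as pd
import pytest

from apms.countmatrix import (
    CountMatrix,
    Run,
    identity_normalized,
    zero_bait_self_counts,
)
from apms.pipeline import run_pipeline
from apms.saint import apply_thresholds, score_bait
from apms.simulate import SimConfig, simulate_counts


def small_matrix() -> CountMatrix:
    """2 controls + 2 bait runs, 3 preys, hand-set counts."""
    runs = [
        Run("CONTROL_r1", None, 1),
        Run("CONTROL_r2", None, 2),
        Run("BAITX_r1", "BAITX", 1),
        Run("BAITX_r2", "BAITX", 2),
    ]
    counts = pd.DataFrame(
        {
            "CONTROL_r1": [860, 40, 0],
            "CONTROL_r2": [1060, 40, 0],
            "BAITX_r1": [1960, 40, 0],
            "BAITX_r2": [1960, 40, 0],
        },
        index=["PREYA", "PREYB", "PREYC"],
    )
    preys = pd.DataFrame(
        {
            "accession": ["ACC_A", "ACC_B", "ACC_C"],
            "length": [100, 200, 300],
        },
        index=["PREYA", "PREYB", "PREYC"],
    )
    return CountMatrix(counts=counts, preys=preys, runs=runs)


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    return small_matrix()


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_data(sim_cfg):
    """Default synthetic count matrix and its truth table."""
    return simulate_counts(sim_cfg)


@pytest.fixture(scope="session")
def scored_default(sim_data):
    """SAINT results per bait on the default synthetic matrix."""
    matrix, truth = sim_data
    norm = identity_normalized(zero_bait_self_counts(matrix))
    out = {}
    for bait in matrix.baits:
        results = score_bait(norm, bait)
        apply_thresholds(results)
        out[bait] = results
    return out


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full default pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline({"seed": 1}, outdir=outdir)
    return outdir
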