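import warnings

import numpy as np
import pandas as pd
import pytest

from fatestrat.containers import ExpressionMatrix, SurvivalTable
from fatestrat.synth import (
    SimulationConfig,
    simulate_cell_lines,
    simulate_cohort,
    simulate_spatial,
    simulate_trajectory,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def spatial_default():
    cfg = SimulationConfig(seed=1, n_genes=200, n_spots=300)
    return cfg, *simulate_spatial(cfg)


@pytest.fixture(scope="session")
def trajectory_default():
    cfg = SimulationConfig(seed=2, n_genes=120, n_spots=400)
    return cfg, *simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def cohort_default():
    cfg = SimulationConfig(seed=1, n_genes=34, n_samples=400)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cell_line_default():
    cfg = SimulationConfig(seed=1, n_genes=34, n_samples=400)
    return cfg, *simulate_cell_lines(cfg)


@pytest.fixture()
def tiny_survival():
    """Six samples, tie-free times, two events censored."""
    data = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
        },
        index=[f"p{i}" for i in range(6)],
    )
    return SurvivalTable(data)


def expression_from_array(arr, genes=None, samples=None, layer="normalised"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=samples), layer=layer
    )
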