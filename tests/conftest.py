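import numpy as np
import pandas as pd
import pytest

from txcascade.differential import run_de_timecourse
from txcascade.io import ExpressionMatrix, SampleSheet
from txcascade.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Low-noise 1200-gene study with the full planted cascade (seed 7)."""
    config = SimConfig(n_genes=1200, n_tfs=20, noise_sd=0.1, seed=7)
    expr, kb, truth = simulate_study(config)
    return config, expr, kb, truth


@pytest.fixture(scope="session")
def small_de(small_study):
    _, expr, _, _ = small_study
    return run_de_timecourse(expr, "both", "control")


@pytest.fixture()
def tiny_expression():
    """3 genes x 4 samples (2 conditions x 1 time x 2 replicates)."""
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ["c1", "c2", "t1", "t2"],
        "condition": ["control", "control", "drug", "drug"],
        "time_h": [2.0, 2.0, 2.0, 2.0],
        "replicate": [1, 2, 1, 2],
    }))
    values = pd.DataFrame(
        np.array([[1.0, 1.2, 3.0, 3.2],
                  [5.0, 5.1, 5.0, 5.2],
                  [2.0, 2.2, 0.5, 0.4]]),
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=["c1", "c2", "t1", "t2"],
    )
    return ExpressionMatrix(values, sheet)
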