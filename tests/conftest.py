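import numpy as np
import pandas as pd
import pytest

from starchnet.datamodel import ExpressionMatrix, default_diurnal_grid


@pytest.fixture
def diurnal_grid():
    """The study sampling grid: 1,2,4,8,12 h in darkness then light."""
    return default_diurnal_grid(10)


@pytest.fixture
def small_matrix(diurnal_grid):
    """5 genes x 10 arrays with reproducible noise."""
    times, phases = diurnal_grid
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        values=rng.standard_normal((5, 10)),
        array_time_h=times,
        array_phase=phases,
    )


@pytest.fixture
def annotation_table():
    return pd.DataFrame(
        {
            "gene_id": ["S1", "S2", "TF1", "TF2", "CLK1"],
            "role": ["target", "target", "regulator", "regulator", "clock"],
            "family": ["", "", "F0", "F0", "clock"],
        }
    )
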