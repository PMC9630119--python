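import numpy as np
import pandas as pd
import pytest

from wmglia import simulate
from wmglia.qc import SMARTSEQ_METRICS, QCThresholds


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_counts():
    """Default synthetic matrix (fold-8 markers, young vs aged WM)."""
    design = simulate.default_design(seed=3)
    return simulate.generate_counts(design)


def passing_qc_row() -> dict:
    """One cell with every metric at its interval midpoint."""
    return {
        m: (lo + hi) / 2 for m, (lo, hi) in QCThresholds().bounds().items()
    }


def random_qc_table(rng: np.random.Generator, n_cells: int) -> pd.DataFrame:
    """QC metrics drawn from ranges straddling the default bounds."""
    bounds = QCThresholds().bounds()
    data = {}
    for metric in SMARTSEQ_METRICS:
        lo, hi = bounds[metric]
        span = hi - lo
        data[metric] = rng.uniform(
            max(0.0, lo - 0.3 * span), hi + 0.3 * span, size=n_cells
        )
    table = pd.DataFrame(data, index=[f"c{i}" for i in range(n_cells)])
    table.index.name = "cell_id"
    return table
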