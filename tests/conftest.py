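import numpy as np
import pandas as pd
import pytest

from immunecoex import (
    CountMatrix,
    SimulationConfig,
    filter_low_expressed,
    normalize_log_cpm,
    simulate_counts,
    tmm_factors,
)


def make_count_matrix(counts: np.ndarray, genes=None, samples=None,
                      cell_types=None) -> CountMatrix:
    """Assemble a CountMatrix from a plain array with generated ids."""
    counts = np.asarray(counts)
    g, s = counts.shape
    genes = genes or [f"g{i}" for i in range(g)]
    samples = samples or [f"s{j}" for j in range(s)]
    if cell_types is None:
        cell_types = ["A"] * (s // 2) + ["B"] * (s - s // 2)
    meta = pd.DataFrame(
        {"cell_type": cell_types, "individual": [f"i{j}" for j in range(s)]},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), metadata=meta
    )


@pytest.fixture(scope="session")
def sim_study():
    """One default-condition simulated study, normalized, shared across tests."""
    cm, truth = simulate_counts(SimulationConfig(seed=11))
    filt = filter_low_expressed(cm)
    expr = normalize_log_cpm(filt, tmm_factors(filt))
    return cm, truth, expr


@pytest.fixture
def rng():
    return np.random.default_rng(42)
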