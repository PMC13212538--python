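import numpy as np
import pandas as pd
import pytest

from metstab import MetDataset, SyntheticConfig, simulate_met, toy_matrix


@pytest.fixture(scope="session")
def toy():
    """Fixed 3x3 means matrix with hand-computed decomposition."""
    return toy_matrix()


@pytest.fixture(scope="session")
def default_sim():
    """Balanced 30 x 4 x 3 single-trait dataset at the reference variances."""
    cfg = SyntheticConfig(
        var_genotype=100.0, var_ge=50.0, var_residual=25.0, seed=1
    )
    return simulate_met(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Small 8 x 4 x 2 dataset for fast structural checks."""
    cfg = SyntheticConfig(
        n_genotypes=8, n_environments=4, n_replicates=2, ge_rank=2, seed=7
    )
    return simulate_met(cfg)


def balanced_frame(g=4, e=3, r=2, traits=("BR", "GY"), seed=0, fn=None):
    """Wide-format balanced trial table; cell values from ``fn(i,j,k,t)`` or random."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(g):
        for j in range(e):
            for k in range(r):
                row = {"GEN": f"G{i+1}", "ENV": f"E{j+1}", "REP": f"R{k+1}"}
                for t, name in enumerate(traits):
                    row[name] = (
                        fn(i, j, k, t) if fn is not None
                        else float(rng.normal(100, 10))
                    )
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def wide_frame():
    return balanced_frame


@pytest.fixture()
def met_from_frame():
    def _make(df, traits):
        return MetDataset.from_wide(df, list(traits))
    return _make
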