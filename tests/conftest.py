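import numpy as np
import pandas as pd
import pytest

import cwpsoil as cw


@pytest.fixture(scope="session")
def desk_data():
    """One desk-scale synthetic survey shared across tests (fixed seed)."""
    return cw.simulate_dataset("desk", seed=11)


@pytest.fixture(scope="session")
def toy_sites():
    """6 sites, 3 CWP species, for hand-checkable core/overlap cases."""
    return pd.DataFrame(
        {
            "cwp_species": ["maize", "maize", "rice", "rice", "wheat", "wheat"],
            "latitude": [0.0] * 6,
            "longitude": [0.0] * 6,
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="site_id"),
    )


@pytest.fixture
def grouped_regression():
    """Balanced 10-group design with known fixed effects for LMM tests."""
    rng = np.random.default_rng(42)
    n = 125
    sizes = [12, 13, 12, 13, 12, 13, 12, 13, 12, 13]
    groups = pd.Series(np.repeat([f"cwp{i}" for i in range(10)], sizes))
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["pH", "MAT", "sand"])
    u = rng.normal(0, 0.5, 10)
    y = pd.Series(
        0.5 * X["pH"].to_numpy()
        - 0.3 * X["MAT"].to_numpy()
        + u[pd.factorize(groups)[0]]
        + rng.normal(0, 0.5, n)
    )
    return y, X, groups
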