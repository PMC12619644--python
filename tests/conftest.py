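import numpy as np
import pandas as pd
import pytest

from kdca import DesignInputs, MvnSimConfig, simulate_mvn_pathway


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def design_from_sim(data, categorical=True):
    """Wrap a simulated MVN pathway into DesignInputs."""
    X = pd.DataFrame({f"x{l}": data.X[:, l] for l in range(data.X.shape[1])})
    return DesignInputs(
        Y=data.Y,
        X=X,
        C=pd.DataFrame({"c": data.C}),
        categorical=tuple(X.columns) if categorical else (),
    )


def make_design(rng, n=60, r=4, binary_x=True, categorical=True):
    """Small design with Y independent of X (a generic null input)."""
    x = rng.integers(0, 2, n).astype(float) if binary_x else rng.uniform(0, 2, n)
    c = rng.uniform(0, 2, n)
    Y = rng.standard_normal((n, r))
    return DesignInputs(
        Y=Y,
        X=pd.DataFrame({"x": x}),
        C=pd.DataFrame({"c": c}),
        categorical=("x",) if (binary_x and categorical) else (),
    )


@pytest.fixture
def null_mvn_design(rng):
    data = simulate_mvn_pathway(
        MvnSimConfig(tau_range=(0.0, 0.0), delta_max=0.1), rng
    )
    return design_from_sim(data)
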