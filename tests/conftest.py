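import numpy as np
import pytest

from mblr.compositional import LogRatioTable
from mblr.model_core import DesignMatrix, ModelSpec
from mblr.phylo import model_covariance
from mblr.simulator import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_truth():
    """Small simulated dataset shared by fast tests (n=40, S=5)."""
    return simulate_dataset(SimulationConfig(n=40, s=5, p=2, a=(1.0, 0.5, 0.0), seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_problem(rng, n=12, s1=3, p=2):
    """A consistent (y, design, cov, spec) tuple with identity covariance."""
    y = LogRatioTable(
        rng.normal(size=(n, s1)),
        [f"sample{i}" for i in range(n)],
        [f"taxon{j}" for j in range(s1)],
        "ref",
    )
    design = DesignMatrix.with_intercept(rng.normal(size=(n, p - 1)), [f"x{j}" for j in range(p - 1)])
    cov = model_covariance(None, [f"taxon{j}" for j in range(s1)] + ["ref"], "ref")
    return y, design, cov, ModelSpec()
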