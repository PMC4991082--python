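import numpy as np
import pandas as pd
import pytest

from dielnet.preprocess import ExpressionMatrix
from dielnet.simulate import SimConfig, generate_expression


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples (2 timepoints x 2 replicates), raw scale."""
    values = pd.DataFrame(
        [[100.0, 110.0, 200.0, 190.0], [50.0, 55.0, 45.0, 60.0], [500.0, 480.0, 510.0, 505.0]],
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
        columns=["ZT00_r1", "ZT00_r2", "ZT12_r1", "ZT12_r2"],
    )
    return ExpressionMatrix(
        values, zt=np.array([0.0, 0.0, 12.0, 12.0]), replicate=np.array([1, 2, 1, 2])
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset with ground truth (seed 0)."""
    return generate_expression(SimConfig(seed=0))


def mini_config(**kw) -> SimConfig:
    """A small, fast simulation configuration for structural tests."""
    base = dict(
        n_genes=300,
        frac_rhythmic=0.2,
        n_modules=3,
        frac_below_background=0.05,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)
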