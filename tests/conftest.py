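import numpy as np
import pandas as pd
import pytest

from healthmrp.frame import PostStratFrame
from healthmrp.model import PosteriorDraws
from healthmrp.schema import (
    Covariate,
    CovariateSchema,
    IMD_VARIABLE,
    default_schema,
    enumerate_cells,
)


@pytest.fixture(scope="session")
def schema11():
    return default_schema()


@pytest.fixture
def toy_schema():
    """Two binary covariates and one 3-level covariate (no deprivation)."""
    return CovariateSchema(
        (
            Covariate("a", ("a0", "a1"), "a0"),
            Covariate("b", ("b0", "b1"), "b0"),
            Covariate("c", ("c0", "c1", "c2"), "c0"),
        )
    )


@pytest.fixture
def model_schema():
    """Smallest schema the model accepts: one binary covariate + IMD quintile."""
    return CovariateSchema(
        (
            Covariate("t", ("0", "1"), "0"),
            Covariate(IMD_VARIABLE, ("1", "2", "3", "4", "5"), "1"),
        )
    )


def make_draws(schema, n_draws, rng=None, zero=False):
    """PosteriorDraws with random (or all-zero) natural-scale parameters."""
    rng = rng or np.random.default_rng(0)
    cols = ["intercept"]
    cols += [f"{v}[{l}]" for v, l in schema.non_reference_pairs(exclude=(IMD_VARIABLE,))]
    cols += ["imd_mu", "imd_sigma"] + [f"imd[{q}]" for q in range(1, 6)]
    if zero:
        data = np.zeros((n_draws, len(cols)))
        data[:, cols.index("imd_sigma")] = 1e-6
    else:
        data = rng.normal(0, 0.8, size=(n_draws, len(cols)))
        data[:, cols.index("imd_sigma")] = np.abs(data[:, cols.index("imd_sigma")])
    return PosteriorDraws(
        schema=schema,
        outcome="literacy",
        params=pd.DataFrame(data, columns=cols),
        chains=1,
    )


def random_frame(schema, rng):
    """A random valid post-stratification frame over the schema's cells."""
    index = enumerate_cells(schema)
    w = rng.random(index.n_cells)
    w = w / w.sum()
    return PostStratFrame(index, w)


@pytest.fixture
def make_random_frame():
    return random_frame


@pytest.fixture
def make_posterior_draws():
    return make_draws
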