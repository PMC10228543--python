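import numpy as np
import pytest

from tailspin import model, simulate


@pytest.fixture(scope="session")
def params():
    return model.default_params()


@pytest.fixture(scope="session")
def wt_truth(params):
    return model.generate_truth("WT", 0, params, seed=1)


@pytest.fixture(scope="session")
def wt_table(params):
    return simulate.simulate_construct_tables("WT", 0, params, seed=1)


@pytest.fixture(scope="session")
def tables_0mm(params):
    """Peak tables for all six constructs at 0 mM KCl, one seed."""
    return {
        c: simulate.simulate_construct_tables(c, 0, params, seed=1)
        for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q", "R2/8/17/26Q")
    }


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
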