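import numpy as np
import pandas as pd
import pytest

from hybridscan import synthetic_population as sp


@pytest.fixture(scope="session")
def small_ref():
    """Two 300-kb scaffolds; shared across tests that only read it."""
    return sp.generate_reference(2, 300_000, gc=0.40, seed=1)


@pytest.fixture(scope="session")
def tiny_ref():
    return sp.generate_reference(2, 50_000, gc=0.40, seed=2)


def make_calls(rows):
    """Build a call table from (scaffold, pos, ref, alt, gt, depth, alt_depth, qual)."""
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold",
            "pos",
            "ref",
            "alt",
            "genotype_class",
            "depth",
            "alt_depth",
            "qual",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
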