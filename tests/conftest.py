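import pandas as pd
import pytest

from mycotree import design as dz
from mycotree import traits as tz
from mycotree.datasets import demo_trait_table


@pytest.fixture(scope="session")
def trait_table():
    return demo_trait_table(seed=0)


@pytest.fixture(scope="session")
def pools(trait_table):
    return tz.select_pools(trait_table, pool_size=5)


@pytest.fixture(scope="session")
def default_design(pools):
    return dz.assemble_design(pools, seed=1)


@pytest.fixture(scope="session")
def placed_design(default_design):
    return dz.randomize_layout(default_design, seed=2)


@pytest.fixture(scope="session")
def layouts(placed_design):
    return dz.layouts_for_design(placed_design, seed=3)


def make_trait_frame(rows):
    return pd.DataFrame(rows)
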