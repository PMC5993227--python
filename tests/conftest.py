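import numpy as np
import pytest

from hdallom.plot_data import Tree
from hdallom.synthetic import GeneratorConfig, generate_dataset


def make_tree(tree_id="t1", diameter=20.0, height=15.0, **kw):
    return Tree(tree_id=tree_id, diameter=diameter, height=height, **kw)


@pytest.fixture(scope="session")
def small_dataset():
    """Four modest synthetic plots with their truth manifest."""
    config = GeneratorConfig(n_plots=4, trees_per_plot=(200, 260), master_seed=42)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_plots(small_dataset):
    return small_dataset[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
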