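import numpy as np
import pytest
from hypothesis import settings

# deterministic property-test examples, no on-disk example database
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from clonadapt import fixture_tree, normalize_height, paint_regime, parse_tree
from clonadapt.dataset import ExpressionDataset
from clonadapt.synthetic import FIXTURE_REGIMES


@pytest.fixture(scope="session")
def tree23():
    return fixture_tree()


@pytest.fixture(scope="session")
def painting_har(tree23):
    return paint_regime(tree23, set(FIXTURE_REGIMES["HA-R"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_tree(rng, n_tips, min_len=0.1, max_len=1.0):
    """Random bifurcating tree with uniform branch lengths, unit height."""
    counter = [0]

    def build(names):
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        l1 = rng.uniform(min_len, max_len)
        l2 = rng.uniform(min_len, max_len)
        return f"({build(left)}:{l1:.6f},{build(right)}:{l2:.6f})"

    names = [f"t{i}" for i in range(n_tips)]
    rng.shuffle(names)
    return normalize_height(parse_tree(build(names) + ";"))


def cells_dataset(tree, replicates, values=None, genes=("g0",), rng=None):
    """Dataset with ``replicates`` cells per tip; values default to iid N(0,1)."""
    cells, mapping = [], {}
    for name in tree.tip_names:
        for j in range(replicates):
            c = f"{name}_c{j}"
            cells.append(c)
            mapping[c] = name
    if values is None:
        rng = rng or np.random.default_rng(0)
        values = rng.normal(size=(len(genes), len(cells)))
    return ExpressionDataset(genes=list(genes), cells=cells, values=values,
                             cell_to_subline=mapping)
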