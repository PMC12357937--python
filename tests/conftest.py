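import numpy as np
import pytest
from hypothesis import settings

from intronevo.simulate import paper_fixture

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture():
    """Packaged lineage matrices and the two backbone topologies."""
    return paper_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rooted_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """A random rooted binary topology over leaves L1..Ln."""
    nodes = [f"L{i + 1}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
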