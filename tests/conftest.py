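import numpy as np
import pytest

from phyloconverge import SyntheticScenario, make_synthetic_study, simulate_tree


@pytest.fixture(scope="session")
def study17():
    """One deterministic 17-species synthetic study shared across tests."""
    return make_synthetic_study(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def tree17(study17):
    return study17[1]


@pytest.fixture(scope="session")
def table17(study17):
    return study17[0]


@pytest.fixture(scope="session")
def tree64():
    return simulate_tree(64, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def balanced_newick(depth: int, edge: float = 1.0, _prefix: str = "t") -> str:
    """Newick for a fully balanced binary tree with 2**depth tips."""

    def rec(d, path):
        if d == 0:
            return f"{_prefix}{path}:{edge}"
        return f"({rec(d - 1, path + '0')},{rec(d - 1, path + '1')}):{edge}"

    return f"({rec(depth - 1, '0')},{rec(depth - 1, '1')});"


def star_newick(n: int, edge: float = 1.0) -> str:
    tips = ",".join(f"s{i}:{edge}" for i in range(n))
    return f"({tips});"
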