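import random

import pytest

from gemqc.fixtures import ToyModelSpec, make_toy_model
from gemqc.model import GprAnd, GprLeaf, GprOr


def random_gpr_tree(rng: random.Random, max_leaves: int = 12):
    """Random GPR tree with 1..max_leaves distinct gene leaves."""
    n_leaves = rng.randint(1, max_leaves)
    nodes = [GprLeaf(f"g{i}") for i in range(n_leaves)]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        k = rng.randint(2, min(3, len(nodes)))
        children = [nodes.pop() for _ in range(k)]
        op = GprAnd if rng.random() < 0.5 else GprOr
        nodes.append(op(children))
    return nodes[0]


@pytest.fixture
def chain_model():
    """Plain 3-step chain: hand-solvable, optimum == uptake cap (10)."""
    return make_toy_model(ToyModelSpec(chain_length=3, seed=0))


@pytest.fixture
def rich_model():
    """Everything enabled: isozymes, dead ends, auxotrophy, energy branch."""
    return make_toy_model(ToyModelSpec(
        chain_length=3, n_isozyme_pairs=2, n_dead_ends=2,
        include_auxotroph_branch=True, include_energy_branch=True, seed=42))


SPEC_MATRIX = [
    ToyModelSpec(chain_length=1, seed=0),
    ToyModelSpec(chain_length=4, seed=1),
    ToyModelSpec(chain_length=2, n_isozyme_pairs=1, seed=2),
    ToyModelSpec(chain_length=2, n_dead_ends=3, seed=3),
    ToyModelSpec(chain_length=2, include_auxotroph_branch=True, seed=4),
    ToyModelSpec(chain_length=2, include_energy_branch=True, seed=5),
    ToyModelSpec(chain_length=3, n_isozyme_pairs=2, n_dead_ends=2,
                 include_auxotroph_branch=True, include_energy_branch=True,
                 seed=6, uptake_cap=8.0),
]
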