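import numpy as np
import pytest

from rbmaf import redblue
from rbmaf.oracle import enumerate_all_tree_pairs, exact_maf
from rbmaf.synth import _random_nested, worked_examples
from rbmaf.treeio import RootedBinaryTree, TreePair, augment_with_rho

SWEEP_SEED = 20240917  # fixed: the test-time random instance set is part of the suite


@pytest.fixture(scope="session")
def fixtures():
    return worked_examples()


@pytest.fixture(scope="session")
def worked_pair(fixtures):
    return fixtures["worked_example"]


@pytest.fixture(scope="session")
def worked_coloring(worked_pair):
    """The coloring of the worked example: R={R1,R2}, B={B1,B2}."""
    u = redblue.lowest_root_of_infeasibility(worked_pair, [worked_pair.labels])
    return redblue.make_coloring(worked_pair, u)


def random_pair(n, rng, prefix="t"):
    labels = [f"{prefix}{j + 1}" for j in range(n)]
    return TreePair(
        RootedBinaryTree(_random_nested(labels, rng)),
        RootedBinaryTree(_random_nested(labels, rng)),
    )


def _solve(pair):
    aug = augment_with_rho(pair)
    result = redblue.run(aug)
    opt = exact_maf(aug).opt_cuts
    return {"pair": pair, "aug": aug, "result": result, "opt": opt}


@pytest.fixture(scope="session")
def sweep4():
    """All 225 ordered pairs on 4 leaves, rho-augmented, solved both ways."""
    return [_solve(pair) for pair in enumerate_all_tree_pairs(4)]


@pytest.fixture(scope="session")
def random_sweep():
    """500 seeded uniform random pairs on 6-10 leaves, rho-augmented."""
    rng = np.random.default_rng(SWEEP_SEED)
    out = []
    for _ in range(500):
        n = int(rng.integers(6, 11))
        out.append(_solve(random_pair(n, rng)))
    return out
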