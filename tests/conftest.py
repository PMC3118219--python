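import numpy as np
import pytest
from skbio import TreeNode

from phagecompare.synth import SyntheticConfig, generate_community


def random_binary_tree(rng: np.random.Generator, n_tips: int,
                       min_len: float = 0.5, max_len: float = 2.0) -> TreeNode:
    """Random rooted binary tree with positive branch lengths, tips t1..tn."""
    nodes = [TreeNode(name=f"t{i + 1}", length=float(rng.uniform(min_len, max_len)))
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(
            TreeNode(children=[a, b], length=float(rng.uniform(min_len, max_len)))
        )
    root = TreeNode(children=nodes)
    root.length = None
    return root


@pytest.fixture(scope="session")
def default_community():
    """A community generated under the default study conditions."""
    return generate_community(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_clusters(default_community):
    from phagecompare.clustering import greedy_cluster

    return greedy_cluster(default_community.proteins)
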