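import numpy as np
import pytest

import microtriage as mt


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study (seed 1), shared read-only."""
    return mt.simulate_study(mt.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_triage(default_study):
    table, metadata, annotations, _, _ = default_study
    return mt.triage_features(table, metadata, annotations)


@pytest.fixture
def tiny_table():
    return mt.FeatureTable(
        np.array([[5, 0, 2], [1, 3, 0], [0, 7, 4]]),
        ["f1", "f2", "f3"],
        ["s1", "s2", "s3"],
    )


def random_tree_and_presence(rng, max_leaves=12):
    """A random small tree plus two random non-degenerate presence sets."""
    n = int(rng.integers(3, max_leaves + 1))
    tree = mt.simulate_tree(n, int(rng.integers(2**31)))
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    while True:
        a = {t for t in taxa if rng.random() < 0.5}
        b = {t for t in taxa if rng.random() < 0.5}
        if a | b:
            return tree, a, b


def brute_force_unifrac(tree, a, b):
    """Independent per-branch oracle: enumerate every branch of the
    midpoint-rooted tree and test descendant-leaf intersection with each
    sample directly."""
    work = tree.clone(depth=1)
    work.reroot_at_midpoint(update_bipartitions=True)
    unique = shared = 0.0
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = {nd.taxon.label for nd in node.preorder_iter() if nd.taxon is not None}
        in_a = bool(leaves & a)
        in_b = bool(leaves & b)
        length = float(node.edge.length or 0.0)
        if in_a or in_b:
            shared += length
            if in_a != in_b:
                unique += length
    return unique / shared if shared > 0 else 0.0
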