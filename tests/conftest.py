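import numpy as np
import pytest
import skbio

import assemblytrace as at


@pytest.fixture(scope="session")
def small_tree():
    return skbio.TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture()
def small_table():
    return at.CommunityTable(
        np.array([[5, 3, 0], [0, 3, 7]]), ["s1", "s2"], ["A", "B", "C"]
    )


@pytest.fixture(scope="session")
def metacommunity():
    return at.make_metacommunity(120, seed=11)


@pytest.fixture(scope="session")
def chronosequence():
    """One full synthetic study, shared across tests (read-only)."""
    return at.generate_chronosequence(at.ScenarioConfig(seed=0))


def random_instance(rng, n_tips, n_samples):
    """Random small table + random tree for oracle comparisons."""
    taxa = [f"T{i}" for i in range(n_tips)]
    tree = at.simulate_tree(taxa, seed=int(rng.integers(2**31)))
    counts = rng.integers(0, 20, size=(n_samples, n_tips))
    # ensure no empty sample and every taxon observed somewhere
    counts[:, 0] += 1
    counts[0, :] += 1
    return at.CommunityTable(counts, [f"s{i}" for i in range(n_samples)], taxa), tree
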