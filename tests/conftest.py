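import numpy as np
import pytest

import amplicord as ac


@pytest.fixture(scope="session")
def db20():
    """The bundled reference scale: 20 taxa, 4 confusable V3-V4 pairs."""
    return ac.build_reference_db(n_taxa=20, n_confusable_groups=4, group_size=2, seed=1)


@pytest.fixture(scope="session")
def records20(db20):
    return ac.db_records(db20)


@pytest.fixture(scope="session")
def lineages20(db20):
    return ac.db_lineages(db20)


@pytest.fixture(scope="session")
def index20(records20):
    return ac.ReferenceIndex(records20)


@pytest.fixture(scope="session")
def even4_profile(db20):
    return ac.sample_community(db20, "even", n_taxa=4, seed=3, sample_name="mock")


def random_tree(rng, n_leaves):
    """Random binary topology with uniform branch lengths, as a TreeNode."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    parts = [f"{n}:{rng.uniform(0.05, 1.0):.6f}" for n in nodes]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.6f}")
    newick = f"({parts[0]},{parts[1]});" if len(parts) == 2 else f"({parts[0]});"
    return ac.parse_newick(newick)


def random_profile(rng, leaves, max_support=None):
    """Dirichlet profile over a random subset of leaves."""
    support_size = rng.integers(1, (max_support or len(leaves)) + 1)
    chosen = rng.choice(leaves, size=support_size, replace=False)
    weights = rng.dirichlet(np.ones(support_size))
    return {leaf: float(w) for leaf, w in zip(chosen, weights)}
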