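import itertools

import numpy as np
import pytest

from moltloss.fixtures import (
    load_major_taxon_tree,
    load_nematode_presence,
    load_nematode_tree,
)
from moltloss.io import State
from moltloss.tree import TaxonTree


@pytest.fixture(scope="session")
def nematode_tree() -> TaxonTree:
    return load_nematode_tree()


@pytest.fixture(scope="session")
def nematode_presence():
    return load_nematode_presence()


@pytest.fixture(scope="session")
def major_taxon_tree() -> TaxonTree:
    return load_major_taxon_tree()


def brute_force_min_losses(tree: TaxonTree, states) -> int:
    """Exhaustive minimum loss count over all single-gain edge-labelings.

    Independent of the Dollo implementation: enumerates every origin node
    whose subtree contains all PRESENT leaves and every subset of loss
    edges of increasing size, accepting the first subset consistent with
    the observed states (MISSING is compatible with anything).
    """
    present = {l for l, s in states.items() if s is State.PRESENT}
    absent = {l for l, s in states.items() if s is State.ABSENT}
    assert present, "needs at least one present leaf"
    origins = [
        n
        for n in tree.preorder()
        if present <= set(tree.subtree_leaf_labels(n))
    ]
    best = None
    for origin in origins:
        under = [n for n in tree.preorder() if tree.is_ancestor(origin, n, strict=True)]
        origin_leaves = set(tree.subtree_leaf_labels(origin))
        max_k = len(absent) if best is None else min(len(absent), best - 1)
        for k in range(0, max_k + 1):
            found = False
            for combo in itertools.combinations(under, k):
                lost = set()
                for edge in combo:
                    lost.update(tree.subtree_leaf_labels(edge))
                ok = True
                for leaf in present:
                    if leaf not in origin_leaves or leaf in lost:
                        ok = False
                        break
                if ok:
                    for leaf in absent:
                        if leaf in origin_leaves and leaf not in lost:
                            ok = False
                            break
                if ok:
                    found = True
                    break
            if found:
                best = k if best is None else min(best, k)
                break
    assert best is not None
    return best


def random_states(tree: TaxonTree, rng: np.random.Generator, p_missing=0.15):
    """Random leaf-state vector with at least one PRESENT leaf."""
    leaves = tree.leaf_labels
    while True:
        states = {}
        for leaf in leaves:
            u = rng.random()
            if u < p_missing:
                states[leaf] = State.MISSING
            elif u < 0.5 + p_missing / 2:
                states[leaf] = State.ABSENT
            else:
                states[leaf] = State.PRESENT
        if any(s is State.PRESENT for s in states.values()):
            return states
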