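import itertools

import numpy as np
import pytest

from morphokey import fixtures as fx
from morphokey.ancestral import RootedTree, TreeNode


@pytest.fixture(scope="session")
def table1():
    return fx.load_table1()


@pytest.fixture(scope="session")
def printed_key():
    return fx.load_key()


@pytest.fixture(scope="session")
def panels():
    zrc, mcz, holo = fx.load_specimen_panels()
    return {"zrc": zrc, "mcz": mcz, "holotype": holo}


@pytest.fixture(scope="session")
def morphocode():
    return fx.load_morphocode()


# ---------------------------------------------------------------------------
# Independent oracles and random-tree helpers shared by test modules
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree, tip_states):
    """Exhaustive minimum over all internal single-state assignments.

    Returns (min steps, {internal node postorder number -> MPR state set}).
    Polymorphic tips contribute edge cost 0 iff the parent's state is in
    their set (equivalent to minimising over tip resolutions).
    """
    nodes = tree.postorder()
    numbers = {id(n): i for i, n in enumerate(nodes)}
    internals = [n for n in nodes if not n.is_leaf]
    states = sorted({s for v in tip_states.values()
                     for s in (v if isinstance(v, (set, frozenset)) else [v])})
    parents = tree.parents()
    idx = {id(n): i for i, n in enumerate(internals)}
    best, best_sets = None, None
    for assign in itertools.product(states, repeat=len(internals)):
        cost = 0
        for n in internals:
            p = parents[id(n)]
            if p is not None and assign[idx[id(n)]] != assign[idx[id(p)]]:
                cost += 1
        for leaf in tree.leaves():
            p = parents[id(leaf)]
            ts = tip_states[leaf.label]
            ts = ts if isinstance(ts, (set, frozenset)) else {ts}
            if assign[idx[id(p)]] not in ts:
                cost += 1
        if best is None or cost < best:
            best = cost
            best_sets = {numbers[id(n)]: set() for n in internals}
        if cost == best:
            for n in internals:
                best_sets[numbers[id(n)]].add(assign[idx[id(n)]])
    return best, best_sets


def random_tree(rng, n_tips, polytomy_prob=0.3):
    """Random rooted shape by sequential joining; occasional polytomies."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) >= 3 and rng.random() < polytomy_prob) else 2
        picks = [nodes.pop(int(rng.integers(0, len(nodes)))) for _ in range(k)]
        nodes.append(TreeNode(children=picks))
    return RootedTree(nodes[0])


def random_tip_states(rng, tree, n_states, polymorphic_prob=0.2):
    tips = {}
    for lbl in tree.tip_labels:
        if rng.random() < polymorphic_prob and n_states >= 2:
            size = int(rng.integers(2, n_states + 1))
            tips[lbl] = set(map(str, rng.choice(n_states, size=size, replace=False)))
        else:
            tips[lbl] = str(rng.integers(0, n_states))
    return tips
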