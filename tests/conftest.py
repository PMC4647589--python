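import itertools
import math

import numpy as np
import pytest

import pherotrace as pt
from pherotrace.mk import transition_matrix
from pherotrace.simulate import simulate_yule_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def quartet():
    """Balanced 4-tip tree with unit branch lengths."""
    return pt.set_unit_branch_lengths(
        pt.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    )


@pytest.fixture(scope="session")
def study_tree():
    return pt.set_unit_branch_lengths(pt.datasets.load_study_tree())


@pytest.fixture(scope="session")
def study_clades():
    return pt.datasets.load_study_clades()


def random_unit_tree(n_tips, rng):
    return pt.set_unit_branch_lengths(simulate_yule_tree(n_tips, rng=rng))


def enumeration_log_likelihood(tree, tip_states, q, prior=(0.5, 0.5), clamp=None):
    """Independent oracle: sum over all ancestral state assignments of the
    product of root prior and per-edge transition probabilities.  ``clamp``
    optionally fixes one internal node's state, which is the defining
    computation behind marginal (proportional-likelihood) reconstruction."""
    nodes = list(tree.nodes)
    internal = [n for n in nodes if not n.is_tip]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = {n.id: s for n, s in zip(internal, assign)}
        if clamp is not None and st[clamp[0]] != clamp[1]:
            continue
        ok = True
        for n in tree.tips():
            s = tip_states[n.label]
            if s in (0, 1, "0", "1"):
                st[n.id] = int(s)
            else:
                st[n.id] = None  # missing: sum over both below
        # expand missing tips by summation
        missing = [n.id for n in tree.tips() if st[n.id] is None]
        for miss_assign in itertools.product([0, 1], repeat=len(missing)):
            for nid, s in zip(missing, miss_assign):
                st[nid] = s
            p = prior[st[tree.root.id]]
            for n in nodes:
                if n.is_root:
                    continue
                P = transition_matrix(q, n.length)
                p *= P[st[n.parent.id], st[n.id]]
            total += p
        for nid in missing:
            st[nid] = None
    return math.log(total) if total > 0 else float("-inf")


def enumeration_marginal_present(tree, tip_states, q, node_id, prior=(0.5, 0.5)):
    """Clamp-and-renormalize by brute force at one node."""
    l1 = math.exp(enumeration_log_likelihood(tree, tip_states, q,
                                             prior, clamp=(node_id, 1)))
    l0 = math.exp(enumeration_log_likelihood(tree, tip_states, q,
                                             prior, clamp=(node_id, 0)))
    return l1 / (l0 + l1)
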