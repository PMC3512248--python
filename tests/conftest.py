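"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: the Mk1
likelihood/marginal oracles enumerate ancestral state assignments with the
closed-form transition probability written out locally, and the topology
oracle enumerates every unrooted leaf-labelled binary tree by stepwise leaf
insertion.
"""

from __future__ import annotations

import itertools
import math
import random

import pytest

from lgtrates.trees import DatedTree, Node, Tree


# ---------------------------------------------------------------------------
# random tree generation (for property tests)
# ---------------------------------------------------------------------------

def random_binary_tree(labels, rng, min_length=0.05, max_length=2.0) -> DatedTree:
    """Random rooted binary topology over ``labels`` with random lengths."""
    nodes = [Node(label=l, length=rng.uniform(min_length, max_length)) for l in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = Node(length=rng.uniform(min_length, max_length))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return DatedTree(root)


# ---------------------------------------------------------------------------
# Mk1 enumeration oracles
# ---------------------------------------------------------------------------

def _p_mk1(q: float, t: float, i: int, j: int) -> float:
    stay = 0.5 * (1.0 + math.exp(-2.0 * q * t))
    return stay if i == j else 1.0 - stay


def brute_force_likelihood(tree: Tree, tips: dict[str, int], q: float,
                           root_prior: float = 0.5) -> float:
    """Sum over all ancestral state assignments of prior x transition products."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for states in itertools.product((0, 1), repeat=len(internals)):
        assignment = {id(n): s for n, s in zip(internals, states)}
        for leaf in tree.leaves():
            assignment[id(leaf)] = tips[leaf.label]
        prob = root_prior if assignment[id(tree.root)] == 1 else 1.0 - root_prior
        for node in tree.postorder():
            if node.parent is None:
                continue
            prob *= _p_mk1(q, node.length, assignment[id(node.parent)], assignment[id(node)])
        total += prob
    return total


def brute_force_marginals(tree: Tree, tips: dict[str, int], q: float,
                          root_prior: float = 0.5) -> dict[frozenset, float]:
    """P(state 1 at node | tips) by conditioning the enumeration."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    per_node = {id(n): [0.0, 0.0] for n in tree.postorder()}
    for states in itertools.product((0, 1), repeat=len(internals)):
        assignment = {id(n): s for n, s in zip(internals, states)}
        for leaf in tree.leaves():
            assignment[id(leaf)] = tips[leaf.label]
        prob = root_prior if assignment[id(tree.root)] == 1 else 1.0 - root_prior
        for node in tree.postorder():
            if node.parent is None:
                continue
            prob *= _p_mk1(q, node.length, assignment[id(node.parent)], assignment[id(node)])
        for node in tree.postorder():
            per_node[id(node)][assignment[id(node)]] += prob
    out = {}
    for node in tree.postorder():
        p0, p1 = per_node[id(node)]
        out[tree.leafset(node)] = p1 / (p0 + p1)
    return out


# ---------------------------------------------------------------------------
# unrooted-topology enumeration oracle
# ---------------------------------------------------------------------------

def _subtree_leafsets(structure, acc):
    """Collect the leafset of every subtree of a nested-tuple structure."""
    if isinstance(structure, tuple):
        left = _subtree_leafsets(structure[0], acc)
        right = _subtree_leafsets(structure[1], acc)
        leaves = left | right
        acc.append(leaves)
        return leaves
    return frozenset([structure])


def enumerate_unrooted_split_sets(labels) -> list[frozenset]:
    """All unrooted binary trees over ``labels``, each as its set of
    canonical nontrivial splits (side not containing the smallest label)."""
    labels = sorted(labels)
    if len(labels) < 4:
        return [frozenset()]
    anchor, rest = labels[0], labels[1:]
    # tree = structure hanging off the anchor leaf; insert leaves one by one
    structures = [(rest[0], rest[1])]
    for new in rest[2:]:
        grown = []
        for s in structures:
            grown.extend(_insert_everywhere(s, new))
        structures = grown
    leafset = frozenset(labels)
    out = []
    for s in structures:
        acc: list[frozenset] = []
        _subtree_leafsets(s, acc)
        splits = set()
        for side in acc:
            other = leafset - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(side if anchor not in side else other)
        out.append(frozenset(splits))
    return out


def _insert_everywhere(structure, leaf):
    """All structures from inserting ``leaf`` on any edge (incl. root edge)."""
    results = [(structure, leaf)]
    if isinstance(structure, tuple):
        left, right = structure
        for new_left in _insert_everywhere(left, leaf):
            results.append((new_left, right))
        for new_right in _insert_everywhere(right, leaf):
            results.append((left, new_right))
    return results


def oracle_split_displayable(split, ref_splits, labels) -> bool:
    """True iff some unrooted binary tree on ``labels`` displays all of
    ``ref_splits`` plus ``split`` (exhaustive search)."""
    for tree_splits in enumerate_unrooted_split_sets(labels):
        if split in tree_splits and ref_splits <= tree_splits:
            return True
    return False


@pytest.fixture
def rng():
    return random.Random(13579)
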