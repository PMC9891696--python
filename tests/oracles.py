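"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a formulation structurally different
from the library implementation (explicit edit-operation recursion instead
of the Gotoh table; exhaustive internal-state enumeration instead of
pruning), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


def brute_force_alignment_score(a: str, b: str, scheme) -> int:
    """Optimal global alignment score by recursion over explicit edit ops.

    Affine gaps: the first residue of a gap run costs gap_open, each further
    one gap_extend.  Exhaustive over all global alignments of a and b.
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> int:
        # state: 0 = last op was a match column, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0
        result = -(10 ** 9)
        if i < len(a) and j < len(b):
            result = max(result, scheme.score(a[i], b[j]) + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = ge if state == 1 else go
            result = max(result, cost + best(i + 1, j, 1))
        if j < len(b):
            cost = ge if state == 2 else go
            result = max(result, cost + best(i, j + 1, 2))
        return result

    score = best(0, 0, 0)
    best.cache_clear()
    return score


def enumerate_rooted_topologies(labels: tuple[str, ...]):
    """All rooted binary leaf-labeled topologies as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    n = len(rest)
    for mask in range(2 ** n):
        left = (first,) + tuple(x for k, x in enumerate(rest) if mask >> k & 1)
        right = tuple(x for k, x in enumerate(rest) if not (mask >> k & 1))
        if not right:
            continue
        for lt in enumerate_rooted_topologies(left):
            for rt in enumerate_rooted_topologies(right):
                yield (lt, rt)


def topology_to_newick(shape, lengths) -> str:
    """Attach branch lengths (an iterator of floats) to a nested-tuple shape."""

    def fmt(node) -> str:
        if isinstance(node, str):
            return f"{node}:{next(lengths)}"
        left, right = node
        return f"({fmt(left)},{fmt(right)}):{next(lengths)}"

    if isinstance(shape, str):
        raise ValueError("need at least 2 leaves")
    left, right = shape
    return f"({fmt(left)},{fmt(right)});"


def brute_force_site_likelihoods(tree, msa, model) -> np.ndarray:
    """Per-site likelihoods by summing over every internal-state assignment."""
    rows = dict(zip(msa.ids, msa.rows))
    internals = [n for n in tree.postorder() if not n.is_leaf]
    k = model.n_states
    pmats = {id(n): model.transition_matrix(n.length)
             for n in tree.postorder() if n.parent is not None}
    n_sites = len(msa.rows[0])
    likes = np.zeros(n_sites)
    for s in range(n_sites):
        total = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            states = {id(n): st for n, st in zip(internals, assign)}
            p = model.frequencies[states[id(tree.root)]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                if node.is_leaf:
                    idx = model.state_index(rows[node.name][s])
                    if idx is not None:  # gap: sum_j P[i, j] = 1
                        p *= pmats[id(node)][states[id(node.parent)], idx]
                else:
                    p *= pmats[id(node)][states[id(node.parent)], states[id(node)]]
            total += p
        likes[s] = total
    return likes


def brute_force_log_likelihood(tree, msa, model) -> float:
    return float(np.sum(np.log(brute_force_site_likelihoods(tree, msa, model))))


def brute_force_marginal_posterior(tree, msa, model, node_name: str) -> np.ndarray:
    """(n_sites, k) posterior at one internal node by state enumeration."""
    rows = dict(zip(msa.ids, msa.rows))
    internals = [n for n in tree.postorder() if not n.is_leaf]
    target = next(n for n in internals if n.name == node_name)
    k = model.n_states
    pmats = {id(n): model.transition_matrix(n.length)
             for n in tree.postorder() if n.parent is not None}
    n_sites = len(msa.rows[0])
    post = np.zeros((n_sites, k))
    for s in range(n_sites):
        for assign in itertools.product(range(k), repeat=len(internals)):
            states = {id(n): st for n, st in zip(internals, assign)}
            p = model.frequencies[states[id(tree.root)]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                if node.is_leaf:
                    idx = model.state_index(rows[node.name][s])
                    if idx is not None:
                        p *= pmats[id(node)][states[id(node.parent)], idx]
                else:
                    p *= pmats[id(node)][states[id(node.parent)], states[id(node)]]
            post[s, states[id(target)]] += p
        post[s] /= post[s].sum()
    return post


def split_set(tree) -> frozenset:
    """Unrooted leaf bipartitions (as frozensets of the smaller side names)."""
    all_leaves = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        below = frozenset(l.name for l in node.postorder() if l.is_leaf)
        other = all_leaves - below
        if len(below) > 1 and len(other) > 1:
            splits.add(min(below, other, key=sorted))
    return frozenset(splits)
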