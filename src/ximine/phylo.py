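"""Phylogenetics: trees, Newick I/O, distances, neighbor joining, likelihood.

The tree is a plain rooted data structure (parent links, branch lengths);
"unrooted" trees are represented with a trifurcating top node, the usual
convention.  Tree search is deliberately distance-based: neighbor joining on
p- or Poisson-corrected distances is exact on additive inputs and fully
deterministic, and :func:`tree_likelihood` (Felsenstein pruning under a
reversible amino-acid substitution model) is available to score fixed
topologies.  All tie-breaks are lexicographic on leaf labels so repeated runs
are byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np

if TYPE_CHECKING:  # avoids an import cycle with align
    from .align import MultipleAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class NewickError(ValueError):
    """Malformed Newick text; message carries the character offset."""


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class TreeNode:
    """One node: ``length`` is the branch to the parent (root: 0)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def __repr__(self) -> str:
        kind = "leaf" if self.is_leaf else f"internal/{len(self.children)}"
        return f"TreeNode({self.name!r}, {self.length}, {kind})"


class PhyloTree:
    """A phylogeny with branch lengths and unique leaf labels."""

    def __init__(self, root: TreeNode, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = [n.name for n in self.root.postorder() if n.is_leaf]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate leaf labels: {dupes}")
        if any(lbl is None for lbl in labels):
            raise NewickError("unlabeled leaf")

    # -- queries ------------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> TreeNode:
        for node in self.root.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def __repr__(self) -> str:
        state = "rooted" if self.rooted else "unrooted"
        return f"PhyloTree({len(self.leaves())} leaves, {state})"


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("():,;\t\n ")


def read_newick(text: str, rooted: bool = True) -> PhyloTree:
    """Parse one Newick statement; errors report the character offset.

    A missing branch length on a non-root edge is taken as 1.0 (with a
    warning) so topology-only trees remain usable.
    """
    s = text.strip()
    pos = 0

    def fail(msg: str) -> NewickError:
        return NewickError(f"{msg} (offset {pos})")

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def parse_length(node: TreeNode, is_root: bool) -> None:
        nonlocal pos
        if peek() == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise fail(f"bad branch length {s[start:pos]!r}")
        elif not is_root:
            warnings.warn("branch length absent; using 1.0", stacklevel=4)
            node.length = 1.0

    def parse_subtree(is_root: bool = False) -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if peek() == "(":
            pos += 1
            node.add_child(parse_subtree())
            while peek() == ",":
                pos += 1
                node.add_child(parse_subtree())
            if peek() != ")":
                raise fail("unbalanced parentheses: expected ')'")
            pos += 1
            label = parse_label()
            node.name = label or None
        else:
            label = parse_label()
            if not label:
                raise fail("expected a leaf label")
            node.name = label
        parse_length(node, is_root)
        return node

    if not s:
        raise fail("empty Newick text")
    root = parse_subtree(is_root=True)
    if peek() != ";":
        raise fail("missing ';' terminator")
    pos += 1
    if pos != len(s):
        raise fail("trailing characters after ';'")
    return PhyloTree(root, rooted=rooted)


def _min_leaf_label(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    return min(_min_leaf_label(c) for c in node.children)


def write_newick(tree: PhyloTree, include_internal_names: bool = True) -> str:
    """Canonical Newick: children sorted by smallest descendant leaf label."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            parts = sorted(node.children, key=_min_leaf_label)
            body = "(" + ",".join(fmt(c, False) for c in parts) + ")"
            if include_internal_names and node.name:
                body += node.name
        if not is_root:
            body += ":" + format(node.length, ".10g")
        return body

    return fmt(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

_POISSON_P_CAP = 0.95


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a model tag."""

    ids: list[str]
    matrix: np.ndarray
    model: str = "p_distance"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("distance matrix must be finite")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.matrix[i, j])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(format(x, ".10g") for x in self.matrix[i])
                fh.write(f"{name}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str, model: str = "p_distance") -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(header, np.array(rows), model)


def distance_matrix(msa: "MultipleAlignment", model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances from an MSA.

    ``p_distance`` is the mismatch fraction over columns where both rows are
    ungapped; ``poisson`` applies d = -ln(1 - p) with p capped at 0.95.  'X'
    never counts as a match.  A pair with no comparable column is an error.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = list(msa.ids)
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    gap = ord("-")
    unknown = ord("X")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (rows[i] != gap) & (rows[j] != gap)
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            match = both & (rows[i] == rows[j]) & (rows[i] != unknown)
            p = 1.0 - match.sum() / compared
            if model == "poisson":
                p = min(p, _POISSON_P_CAP)
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D, model)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou–Nei)
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix (unrooted).

    Exact on additive matrices; negative branch-length estimates are clamped
    to zero; agglomeration ties are broken lexicographically by the smallest
    descendant leaf label so the result is deterministic.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name) for name in dm.ids]
    keys = [_key for _key in dm.ids]  # smallest descendant label per active node
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    if n == 2:
        root = TreeNode()
        half = D[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.add_child(node)
        return PhyloTree(root, rooted=False)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and
                                          (best is None or pair_key < best[2])):
                    best_q = q
                    best = (i, j, pair_key)
        i, j, _ = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the merged node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    i, j, k = active
    a = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    b = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    c = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    root = TreeNode()
    for idx, ln in zip((i, j, k), (a, b, c)):
        nodes[idx].length = max(ln, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Tree utilities: patristic distance, midpoint rooting
# ---------------------------------------------------------------------------

def patristic_distance(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    na, nb = tree.find(leaf_a), tree.find(leaf_b)
    if not na.is_leaf or not nb.is_leaf:
        raise KeyError("patristic distance is defined between leaves")
    if na is nb:
        return 0.0
    anc_a: dict[int, float] = {}
    node, dist = na, 0.0
    while node is not None:
        anc_a[id(node)] = dist
        dist += node.length
        node = node.parent
    node, dist = nb, 0.0
    while node is not None:
        if id(node) in anc_a:
            return dist + anc_a[id(node)]
        dist += node.length
        node = node.parent
    raise RuntimeError("leaves are not connected")  # pragma: no cover


def _path_between(na: TreeNode, nb: TreeNode) -> list[TreeNode]:
    up_a = []
    node = na
    while node is not None:
        up_a.append(node)
        node = node.parent
    seen = {id(n): i for i, n in enumerate(up_a)}
    up_b = []
    node = nb
    while id(node) not in seen:
        up_b.append(node)
        node = node.parent
    lca_index = seen[id(node)]
    return up_a[: lca_index + 1] + list(reversed(up_b))


def _splice_degree_two(node: TreeNode) -> None:
    """Remove an unnamed pass-through node, merging its two edge lengths."""
    if node.name is not None or len(node.children) != 1 or node.parent is None:
        return
    child = node.children[0]
    child.length += node.length
    parent = node.parent
    parent.children[parent.children.index(node)] = child
    child.parent = parent


def _reroot(tree: PhyloTree, child: TreeNode, dist_from_parent: float) -> PhyloTree:
    """Root the tree on the edge above ``child``, ``dist_from_parent`` below
    its parent.  ``tree`` is mutated; callers pass a copy."""
    parent = child.parent
    if parent is None:
        raise ValueError("cannot reroot above the root")
    eps = 1e-12
    if dist_from_parent <= eps and not parent.is_leaf:
        return _reroot_at_node(tree, parent)
    if child.length - dist_from_parent <= eps and not child.is_leaf:
        return _reroot_at_node(tree, child)

    chain: list[tuple[TreeNode, float]] = [(parent, dist_from_parent)]
    node = parent
    while node.parent is not None:
        chain.append((node.parent, node.length))
        node = node.parent
    path = [n for n, _ in chain]
    for upper, lower in zip(path[1:], path[:-1]):
        upper.children.remove(lower)
    parent.children.remove(child)

    new_root = TreeNode()
    child.length -= dist_from_parent
    new_root.add_child(child)
    prev = new_root
    for node, ln in chain:
        node.length = ln
        prev.add_child(node)
        prev = node
    old_root = path[-1]
    _splice_degree_two(old_root)
    return PhyloTree(new_root, rooted=True)


def _reroot_at_node(tree: PhyloTree, node: TreeNode) -> PhyloTree:
    if node.parent is None:
        return PhyloTree(node, rooted=True)
    chain: list[tuple[TreeNode, float]] = []
    cur = node
    while cur.parent is not None:
        chain.append((cur.parent, cur.length))
        cur = cur.parent
    path = [node] + [n for n, _ in chain]
    for upper, lower in zip(path[1:], path[:-1]):
        upper.children.remove(lower)
    prev = node
    for n, ln in chain:
        n.length = ln
        prev.add_child(n)
        prev = n
    node.length = 0.0
    node.parent = None
    old_root = path[-1]
    _splice_degree_two(old_root)
    return PhyloTree(node, rooted=True)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Path lengths between leaves are preserved; if the midpoint falls exactly
    on an internal node that node becomes the root (making the operation
    idempotent on symmetric trees).
    """
    work = tree.copy()
    names = sorted(work.leaf_names())
    if len(names) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    best_pair, best_d = None, -1.0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = patristic_distance(work, a, b)
            if d > best_d + 1e-15:
                best_d, best_pair = d, (a, b)
    a, b = best_pair
    half = best_d / 2.0
    path = _path_between(work.find(a), work.find(b))
    # walk from a toward b accumulating edge lengths
    acc = 0.0
    eps = 1e-12
    for prev, nxt in zip(path[:-1], path[1:]):
        # the edge between prev and nxt is stored on whichever is the child
        if nxt.parent is prev:
            edge_child, edge_len = nxt, nxt.length
        else:
            edge_child, edge_len = prev, prev.length
        if acc + edge_len >= half - eps:
            within = half - acc  # distance into this edge, measured from prev
            if edge_child is nxt:  # walking downward: prev is the parent side
                return _reroot(work, edge_child, within)
            # walking upward: prev is the child side, so flip the offset
            return _reroot(work, edge_child, edge_len - within)
        acc += edge_len
    raise RuntimeError("midpoint not found on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Substitution model and pruning likelihood
# ---------------------------------------------------------------------------

class SubstitutionModel:
    """Reversible amino-acid substitution model.

    Built from symmetric exchangeabilities and equilibrium frequencies; the
    rate matrix is normalized to one expected substitution per unit branch
    length, and P(t) = exp(Qt) is computed through an eigendecomposition of
    the symmetrized rate matrix (stable for reversible models).
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 alphabet: str = AMINO_ACIDS) -> None:
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        k = len(alphabet)
        if S.shape != (k, k):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0) or np.any(pi < 0):
            raise ValueError("exchangeabilities and frequencies must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        self.alphabet = alphabet
        self.frequencies = pi / pi.sum()
        Q = S * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.frequencies, np.diag(Q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        self.rate_matrix = Q / mu
        sqrt_pi = np.sqrt(self.frequencies)
        B = (sqrt_pi[:, None] * self.rate_matrix) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U.T * sqrt_pi[None, :]
        self._right = U / sqrt_pi[:, None]
        self._index = {ch: i for i, ch in enumerate(alphabet)}

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def state_index(self, residue: str) -> int | None:
        """Model-state index, or None for gap/ambiguous (treated as missing)."""
        return self._index.get(residue)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        return np.maximum(P, 0.0)

    @classmethod
    def poisson(cls, alphabet: str = AMINO_ACIDS) -> "SubstitutionModel":
        k = len(alphabet)
        S = np.ones((k, k)) - np.eye(k)
        return cls(S, np.full(k, 1.0 / k), alphabet)

    @classmethod
    def from_file(cls, path: str, alphabet: str = AMINO_ACIDS) -> "SubstitutionModel":
        """Load ``frequencies`` line then a k×k exchangeability table."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([float(x) for x in line.split()])
        k = len(alphabet)
        if len(rows) != k + 1 or len(rows[0]) != k:
            raise ValueError("model file must hold a frequency line plus a square table")
        return cls(np.array(rows[1:]), np.array(rows[0]), alphabet)


def _node_partials(tree: PhyloTree, msa: "MultipleAlignment",
                   model: SubstitutionModel) -> tuple[dict[int, np.ndarray],
                                                      dict[int, np.ndarray],
                                                      dict[int, np.ndarray]]:
    """Downward (inside) partial likelihoods for every node.

    Returns (partials, log_scales, transition matrices) keyed by id(node);
    partials have shape (n_states, n_sites).  Gaps and residues outside the
    model alphabet give a vector of ones (missing data).
    """
    row_by_id = dict(zip(msa.ids, msa.rows))
    n_sites = len(msa.rows[0])
    k = model.n_states
    partials: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}
    pmats: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in row_by_id:
                raise KeyError(f"leaf {node.name!r} missing from the alignment")
            L = np.zeros((k, n_sites))
            for s, ch in enumerate(row_by_id[node.name]):
                idx = model.state_index(ch)
                if idx is None:
                    L[:, s] = 1.0
                else:
                    L[idx, s] = 1.0
            partials[id(node)] = L
            scales[id(node)] = np.zeros(n_sites)
        else:
            L = np.ones((k, n_sites))
            sc = np.zeros(n_sites)
            for child in node.children:
                P = model.transition_matrix(child.length)
                pmats[id(child)] = P
                L = L * (P @ partials[id(child)])
                sc = sc + scales[id(child)]
            m = L.max(axis=0)
            m[m == 0] = 1.0
            L = L / m
            partials[id(node)] = L
            scales[id(node)] = sc + np.log(m)
    return partials, scales, pmats


def tree_likelihood(tree: PhyloTree, msa: "MultipleAlignment",
                    model: SubstitutionModel) -> float:
    """Log-likelihood of the alignment on the tree by Felsenstein pruning.

    Gaps are missing data; sites are independent; the returned value is the
    sum of per-site log-likelihoods.
    """
    partials, scales, _ = _node_partials(tree, msa, model)
    root = tree.root
    site_like = model.frequencies @ partials[id(root)]
    if np.any(site_like <= 0):
        raise ValueError("zero likelihood at some site")
    return float(np.sum(np.log(site_like) + scales[id(root)]))


# ---------------------------------------------------------------------------
# Phylogeny-aware candidate selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateSelection:
    """Leaves picked for follow-up: near verified enzymes, plus a
    max-min-diverse spread across the tree."""

    near_picks: list[tuple[str, float]] = field(default_factory=list)
    spread_picks: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [x for x, _ in self.near_picks] + [x for x, _ in self.spread_picks]


def select_candidates(tree: PhyloTree, verified_ids: Iterable[str],
                      n_near: int, n_spread: int) -> CandidateSelection:
    """Pick candidates from a tree anchored by verified (known-active) leaves.

    ``near_picks``: the ``n_near`` unverified leaves closest (patristic) to
    any verified leaf.  ``spread_picks``: greedy max-min diversification —
    repeatedly add the unverified, unpicked leaf whose minimum distance to
    everything already selected (verified + picks) is largest.  Ties break on
    the leaf label.
    """
    verified = sorted(set(verified_ids))
    if not verified:
        raise ValueError("verified set must be non-empty")
    names = sorted(tree.leaf_names())
    missing = [v for v in verified if v not in names]
    if missing:
        raise KeyError(f"verified ids not in tree: {missing}")
    unverified = [x for x in names if x not in set(verified)]
    if n_near + n_spread > len(unverified):
        raise ValueError("asked for more picks than unverified leaves")

    dist: dict[tuple[str, str], float] = {}

    def d(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in dist:
            dist[key] = patristic_distance(tree, x, y)
        return dist[key]

    near_scored = sorted(((min(d(u, v) for v in verified), u) for u in unverified),
                         key=lambda t: (t[0], t[1]))
    near = [(u, s) for s, u in near_scored[:n_near]]

    selected = list(verified) + [u for u, _ in near]
    pool = [u for u in unverified if u not in {x for x, _ in near}]
    spread: list[tuple[str, float]] = []
    for _ in range(n_spread):
        best_u, best_score = None, -1.0
        for u in pool:
            score = min(d(u, s) for s in selected)
            if score > best_score + 1e-15 or (abs(score - best_score) <= 1e-15
                                              and best_u is not None and u < best_u):
                best_u, best_score = u, score
        spread.append((best_u, best_score))
        selected.append(best_u)
        pool.remove(best_u)
    return CandidateSelection(near, spread)
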