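"""Marginal ancestral sequence reconstruction on a rooted tree.

For each requested internal node and alignment site, the posterior over
residues is proportional to the product of the inside (downward) partial
likelihood at the node and the outside contribution from the rest of the
tree, both computed by pruning.  The reported sequence takes the maximum a
posteriori residue per site (ties broken by alphabet order).  A site is only
resurrected where enough of the node's descendant leaves actually carry a
residue: columns gapped in more than half of the descendants are emitted as
gaps, mirroring the "surviving sites" convention of resurrection studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .phylo import PhyloTree, SubstitutionModel, TreeNode, _node_partials
from .seqio import ProteinRecord

if TYPE_CHECKING:
    from .align import MultipleAlignment

DEFAULT_GAP_MAJORITY = 0.5


@dataclass
class NodeReconstruction:
    node_id: str
    posteriors: np.ndarray  # (n_sites, n_states); rows sum to 1
    map_sequence: str  # gaps at sites failing the surviving-site rule
    mean_map_posterior: float


@dataclass
class AncestralReconstruction:
    alphabet: str
    nodes: dict[str, NodeReconstruction]

    def __getitem__(self, node_id: str) -> NodeReconstruction:
        return self.nodes[node_id]

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.nodes.values():
                fh.write(f">{rec.node_id} mean_map_posterior="
                         f"{rec.mean_map_posterior:.4f}\n{rec.map_sequence}\n")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("node\tsite\tresidue\tprobability\n")
            for rec in self.nodes.values():
                for s in range(rec.posteriors.shape[0]):
                    for k, ch in enumerate(self.alphabet):
                        fh.write(f"{rec.node_id}\t{s + 1}\t{ch}\t"
                                 f"{rec.posteriors[s, k]:.6g}\n")


def _label_internal_nodes(tree: PhyloTree) -> None:
    """Give anonymous internal nodes stable names N1, N2, ... (preorder)."""
    counter = 0
    taken = {n.name for n in tree.postorder() if n.name}
    for node in tree.root.preorder():
        if not node.is_leaf and node.name is None:
            counter += 1
            while f"N{counter}" in taken:
                counter += 1
            node.name = f"N{counter}"


def marginal_asr(tree: PhyloTree, msa: "MultipleAlignment",
                 model: SubstitutionModel,
                 node_ids: Iterable[str] | None = None,
                 gap_majority: float = DEFAULT_GAP_MAJORITY) -> AncestralReconstruction:
    """Marginal reconstruction at internal nodes of a rooted tree.

    ``node_ids`` defaults to every internal node (anonymous nodes are first
    labeled N1, N2, ... in preorder).  Gaps in the alignment are missing
    data; posteriors are exact under the model via inside-outside pruning.
    """
    if not tree.rooted:
        raise ValueError("ancestral reconstruction needs a rooted tree")
    work = tree.copy()
    _label_internal_nodes(work)
    internal_names = {n.name for n in work.postorder() if not n.is_leaf}
    if node_ids is None:
        requested = [n.name for n in work.root.preorder() if not n.is_leaf]
    else:
        requested = list(node_ids)
        for name in requested:
            if name not in internal_names:
                if name in set(work.leaf_names()):
                    raise ValueError(f"{name!r} is a leaf; reconstruct internal nodes only")
                raise KeyError(f"no internal node named {name!r}")

    partials, scales, pmats = _node_partials(work, msa, model)
    k = model.n_states
    n_sites = partials[id(work.root)].shape[1]
    pi = model.frequencies

    # outside vectors: contribution of everything except the node's subtree
    outside: dict[int, np.ndarray] = {id(work.root): np.tile(pi[:, None], (1, n_sites))}
    for node in work.root.preorder():
        if node.is_leaf:
            continue
        down = {id(c): pmats[id(c)] @ partials[id(c)] for c in node.children}
        for child in node.children:
            if child.is_leaf:
                continue
            sib = outside[id(node)].copy()
            for other in node.children:
                if other is not child:
                    sib = sib * down[id(other)]
            out = pmats[id(child)].T @ sib
            m = out.max(axis=0)
            m[m == 0] = 1.0
            outside[id(child)] = out / m

    row_by_id = dict(zip(msa.ids, msa.rows))
    nodes: dict[str, NodeReconstruction] = {}
    by_name = {n.name: n for n in work.postorder() if not n.is_leaf}
    alphabet = model.alphabet
    for name in requested:
        node = by_name[name]
        joint = partials[id(node)] * outside[id(node)]
        totals = joint.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError(f"zero posterior mass at node {name!r}")
        post = (joint / totals).T  # (n_sites, k)
        map_idx = post.argmax(axis=1)  # ties -> lowest index = alphabet order
        descendants = [l.name for l in node.postorder() if l.is_leaf]
        gap_frac = np.zeros(n_sites)
        for leaf in descendants:
            row = row_by_id[leaf]
            gap_frac += np.array([ch == "-" for ch in row], dtype=float)
        gap_frac /= len(descendants)
        chars = []
        kept_posts = []
        for s in range(n_sites):
            if gap_frac[s] > gap_majority:
                chars.append("-")
            else:
                chars.append(alphabet[map_idx[s]])
                kept_posts.append(post[s, map_idx[s]])
        mean_post = float(np.mean(kept_posts)) if kept_posts else 0.0
        nodes[name] = NodeReconstruction(name, post, "".join(chars), mean_post)
    return AncestralReconstruction(alphabet, nodes)


def asr_accuracy(reconstructed: str, truth: str) -> float:
    """Percent identical positions, ignoring columns gapped in both."""
    if len(reconstructed) != len(truth):
        raise ValueError("sequences must have equal length")
    compared = matched = 0
    for x, y in zip(reconstructed, truth):
        if x == "-" and y == "-":
            continue
        compared += 1
        if x == y:
            matched += 1
    if compared == 0:
        raise ValueError("no comparable positions")
    return 100.0 * matched / compared
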