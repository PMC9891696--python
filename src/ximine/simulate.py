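"""Synthetic protein-family generator with full ground truth.

Evolves a family along a birth-process (Yule) or user-fixed tree under a
reversible substitution model, holding catalytic sites frozen, then injects
the terminal anomalies the mining pipeline must detect: N-terminal
truncations, N-terminal extensions and an internal inserted motif (default
"NTSIPFD").  Everything is returned alongside the truth — the tree, every
ancestral sequence, and a per-leaf event log whose replay reproduces the
emitted sequences exactly — so mining, diagnosis and ancestral
reconstruction can all be scored without any external data.

Substitution is site-independent and indel-free during descent; indels enter
only as at-most-one post-hoc event per leaf.  That keeps likelihood and
reconstruction checks exact while still producing every anomaly class the
pipeline repairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .asr import _label_internal_nodes
from .mining import ConservedSiteSpec, ReferenceProfile, default_conserved_sites
from .phylo import PhyloTree, SubstitutionModel, TreeNode, read_newick, write_newick
from .seqio import ProteinRecord, SequenceSet, write_fasta

DEFAULT_INSERT_MOTIF = "NTSIPFD"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated family.

    ``branch_scale`` is the expected number of substitutions per site per
    branch: fixed trees have their branch lengths multiplied by it, Yule
    trees are rescaled so the mean branch length equals it.  Anomaly size
    ranges bracket the defects observed in real inactive family members
    (truncations of 22 and 37 residues, an extension of 11).
    """

    n_leaves: int = 20
    tree_mode: str = "yule"  # yule | fixed
    birth_rate: float = 1.0
    fixed_tree: str | None = None  # Newick text, used when tree_mode == "fixed"
    sequence_length: int = 390
    branch_scale: float = 0.05
    freeze_conserved: bool = True
    conserved_sites: ConservedSiteSpec = field(default_factory=default_conserved_sites)
    p_n_truncate: float = 0.0
    p_n_extend: float = 0.0
    p_internal_insert: float = 0.0
    truncate_range: tuple[int, int] = (15, 40)
    extend_range: tuple[int, int] = (8, 15)
    insert_motif: str = DEFAULT_INSERT_MOTIF
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.tree_mode not in ("yule", "fixed"):
            raise ValueError(f"unknown tree_mode {self.tree_mode!r}")
        if self.tree_mode == "fixed" and not self.fixed_tree:
            raise ValueError("tree_mode 'fixed' needs fixed_tree Newick text")
        if self.tree_mode == "yule" and self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be positive")
        if self.branch_scale < 0:
            raise ValueError("branch_scale must be nonnegative")
        probs = (self.p_n_truncate, self.p_n_extend, self.p_internal_insert)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("event probabilities must sum to at most 1")
        for lo, hi in (self.truncate_range, self.extend_range):
            if not (0 < lo <= hi):
                raise ValueError("event size ranges must be positive and ordered")
        if self.freeze_conserved and len(self.conserved_sites):
            top = max(self.conserved_sites.positions)
            if self.sequence_length < top:
                raise ValueError(
                    f"sequence_length {self.sequence_length} shorter than the "
                    f"largest conserved position {top}")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["conserved_sites"] = [
            {"position": s.position, "residue": s.residue, "role": s.role}
            for s in self.conserved_sites]
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafEvent:
    leaf_id: str
    kind: str  # n_truncate | n_extend | internal_insert
    size: int
    position: int  # 1-based start of the inserted motif (insertions only)
    fragment: str  # extension residues / inserted motif


@dataclass
class GroundTruth:
    tree: PhyloTree  # internal nodes labeled N1, N2, ... (N1 = root)
    ancestors: dict[str, str]  # internal node name -> residues
    pre_event_leaves: dict[str, str]  # leaf id -> residues before events
    events: list[LeafEvent]
    config: SimulationConfig

    def event_for(self, leaf_id: str) -> LeafEvent | None:
        for ev in self.events:
            if ev.leaf_id == leaf_id:
                return ev
        return None

    def root_record(self, record_id: str = "ROOT") -> ProteinRecord:
        return ProteinRecord(record_id, self.ancestors["N1"], "simulated root")

    def reference_profile(self) -> ReferenceProfile:
        """The true root as a conserved-site reference profile."""
        return ReferenceProfile(self.root_record(), self.config.conserved_sites)

    def write(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "true_tree.nwk"), "w") as fh:
            fh.write(write_newick(self.tree) + "\n")
        ancestors = SequenceSet(
            ProteinRecord(name, seq, "simulated ancestor")
            for name, seq in sorted(self.ancestors.items()))
        write_fasta(ancestors, os.path.join(out_dir, "ancestors.fasta"))
        with open(os.path.join(out_dir, "events.tsv"), "w") as fh:
            fh.write("leaf_id\tkind\tsize\tposition\tfragment\n")
            for ev in self.events:
                fh.write(f"{ev.leaf_id}\t{ev.kind}\t{ev.size}\t{ev.position}\t"
                         f"{ev.fragment}\n")
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            fh.write(self.config.to_json() + "\n")


# ---------------------------------------------------------------------------
# Tree sampling
# ---------------------------------------------------------------------------

def yule_tree(n_leaves: int, birth_rate: float, rng: np.random.Generator) -> PhyloTree:
    """Pure-birth tree: exponential waiting times, uniform lineage splits."""
    root = TreeNode()
    active = [root]
    pending = {id(root): 0.0}
    while len(active) < n_leaves:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            pending[id(node)] += dt
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.length = pending.pop(id(node))
        for _ in range(2):
            child = TreeNode()
            node.add_child(child)
            active.append(child)
            pending[id(child)] = 0.0
    dt = rng.exponential(1.0 / (birth_rate * n_leaves))
    for node in active:
        node.length = pending.pop(id(node)) + dt
    root.length = 0.0
    leaves = [n for n in root.postorder() if n.is_leaf]
    width = len(str(len(leaves)))
    for i, leaf in enumerate(leaves, start=1):
        leaf.name = f"L{i:0{width}d}"
    return PhyloTree(root, rooted=True)


def _scaled_tree(config: SimulationConfig, rng: np.random.Generator) -> PhyloTree:
    if config.tree_mode == "fixed":
        tree = read_newick(config.fixed_tree)
        tree.rooted = True
        for node in tree.postorder():
            if node.parent is not None:
                node.length *= config.branch_scale
    else:
        tree = yule_tree(config.n_leaves, config.birth_rate, rng)
        lengths = [n.length for n in tree.postorder() if n.parent is not None]
        mean = sum(lengths) / len(lengths)
        if mean > 0:
            factor = config.branch_scale / mean
            for node in tree.postorder():
                if node.parent is not None:
                    node.length *= factor
    _label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _sample_root(config: SimulationConfig, model: SubstitutionModel,
                 rng: np.random.Generator) -> np.ndarray:
    states = rng.choice(model.n_states, size=config.sequence_length,
                        p=model.frequencies)
    if config.freeze_conserved:
        index = {ch: i for i, ch in enumerate(model.alphabet)}
        for site in config.conserved_sites:
            states[site.position - 1] = index[site.residue]
    return states


def _evolve_branch(parent_states: np.ndarray, P: np.ndarray,
                   frozen: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    child = parent_states.copy()
    k = P.shape[0]
    for state in range(k):
        mask = (parent_states == state) & ~frozen
        count = int(mask.sum())
        if count:
            child[mask] = rng.choice(k, size=count, p=P[state])
    return child


def simulate_family(config: SimulationConfig,
                    model: SubstitutionModel | None = None) -> tuple[SequenceSet, GroundTruth]:
    """Evolve a family along a tree and inject at most one anomaly per leaf.

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical sequences, tree and event log.
    """
    config.validate()
    if model is None:
        model = SubstitutionModel.poisson()
    rng = np.random.default_rng(config.seed)
    tree = _scaled_tree(config, rng)

    frozen = np.zeros(config.sequence_length, dtype=bool)
    if config.freeze_conserved:
        for site in config.conserved_sites:
            frozen[site.position - 1] = True

    states: dict[int, np.ndarray] = {id(tree.root): _sample_root(config, model, rng)}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        P = model.transition_matrix(node.length)
        states[id(node)] = _evolve_branch(states[id(node.parent)], P, frozen, rng)

    alphabet = model.alphabet

    def decode(arr: np.ndarray) -> str:
        return "".join(alphabet[i] for i in arr)

    ancestors = {n.name: decode(states[id(n)])
                 for n in tree.postorder() if not n.is_leaf}
    leaves = [n for n in tree.root.postorder() if n.is_leaf]
    pre_event = {n.name: decode(states[id(n)]) for n in leaves}

    events: list[LeafEvent] = []
    extant: list[ProteinRecord] = []
    p_t, p_e, p_i = config.p_n_truncate, config.p_n_extend, config.p_internal_insert
    for leaf in leaves:
        seq = pre_event[leaf.name]
        u = rng.random()
        event: LeafEvent | None = None
        if u < p_t:
            lo, hi = config.truncate_range
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(seq) - 1)
            event = LeafEvent(leaf.name, "n_truncate", size, 0, "")
        elif u < p_t + p_e:
            lo, hi = config.extend_range
            size = int(rng.integers(lo, hi + 1))
            fragment = decode(rng.choice(model.n_states, size=size, p=model.frequencies))
            event = LeafEvent(leaf.name, "n_extend", size, 0, fragment)
        elif u < p_t + p_e + p_i:
            motif = config.insert_motif
            position = int(rng.integers(2, len(seq) + 1))  # internal start, 1-based
            event = LeafEvent(leaf.name, "internal_insert", len(motif), position, motif)
        if event is not None:
            events.append(event)
            seq = replay_events(seq, [event])
        extant.append(ProteinRecord(leaf.name, seq, "simulated extant"))

    truth = GroundTruth(tree, ancestors, pre_event, events, config)
    return SequenceSet(extant), truth


def replay_events(pre_event_seq: str, events: Iterable[LeafEvent]) -> str:
    """Re-apply logged anomaly events; must reproduce the emitted sequence."""
    seq = pre_event_seq
    for ev in events:
        if ev.kind == "n_truncate":
            if ev.size >= len(seq):
                raise ValueError(f"{ev.leaf_id}: truncation {ev.size} >= length {len(seq)}")
            seq = seq[ev.size:]
        elif ev.kind == "n_extend":
            if len(ev.fragment) != ev.size:
                raise ValueError(f"{ev.leaf_id}: fragment length != size")
            seq = ev.fragment + seq
        elif ev.kind == "internal_insert":
            start = ev.position - 1
            if not (0 < start <= len(seq)):
                raise ValueError(f"{ev.leaf_id}: insert position {ev.position} not internal")
            seq = seq[:start] + ev.fragment + seq[start:]
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return seq
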