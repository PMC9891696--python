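import math

import numpy as np
import pytest

from ximine import (MultipleAlignment, PhyloTree, SubstitutionModel,
                    distance_matrix, midpoint_root, nj_tree,
                    patristic_distance, read_newick, select_candidates,
                    tree_likelihood, write_newick)
from ximine.phylo import DistanceMatrix, _reroot_at_node
from ximine.simulate import yule_tree
from oracles import (brute_force_log_likelihood, split_set,
                     enumerate_rooted_topologies, topology_to_newick)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_p_distance_hand_count():
    msa = MultipleAlignment(["a", "b"], ["AAAA", "AATT"])
    dm = distance_matrix(msa, "p_distance")
    assert dm[("a", "b")] == pytest.approx(0.5)
    poisson = distance_matrix(msa, "poisson")
    assert poisson[("a", "b")] == pytest.approx(-math.log(0.5), abs=1e-4)


def test_identical_rows_zero_distance():
    msa = MultipleAlignment(["a", "b"], ["MKW-", "MKW-"])
    assert distance_matrix(msa)[("a", "b")] == 0.0


def test_no_comparable_columns_errors():
    msa = MultipleAlignment(["a", "b"], ["MK--", "--WH"])
    with pytest.raises(ValueError, match="'a' and 'b'"):
        distance_matrix(msa)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    names = sorted(tree.leaf_names())
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = patristic_distance(tree, names[i], names[j])
    return DistanceMatrix(names, D)


def test_two_taxa_single_edge():
    dm = DistanceMatrix(["A", "B"], np.array([[0, 1.4], [1.4, 0]]))
    tree = nj_tree(dm)
    assert patristic_distance(tree, "A", "B") == pytest.approx(1.4)


def test_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = nj_tree(DistanceMatrix(["A", "B", "C"], D))
    lengths = {l.name: l.length for l in tree.leaves()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_four_taxon_additive_recovery():
    source = read_newick("((A:1,B:2):1,(C:3,D:1):0);", rooted=False)
    tree = nj_tree(_additive_matrix(source))
    assert split_set(tree) == split_set(source)
    for a, b in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
        assert patristic_distance(tree, a, b) == pytest.approx(
            patristic_distance(source, a, b), abs=1e-9)


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(23)
    for trial in range(30):
        n = int(rng.integers(5, 11))
        true = yule_tree(n, 1.0, rng)
        for node in true.postorder():  # strictly positive branch lengths
            if node.parent is not None:
                node.length = float(rng.uniform(0.1, 2.0))
        dm = _additive_matrix(true)
        est = nj_tree(dm)
        assert split_set(est) == split_set(true), f"trial {trial}"
        names = dm.ids
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert patristic_distance(est, a, b) == pytest.approx(
                    dm[(a, b)], abs=1e-9)


def test_nj_against_dendropy():
    """Cross-check topology against dendropy's independent NJ."""
    import dendropy

    rng = np.random.default_rng(31)
    true = yule_tree(7, 1.0, rng)
    for node in true.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.2, 1.5))
    dm = _additive_matrix(true)
    mine = nj_tree(dm)

    import io

    csv_rows = ["," + ",".join(dm.ids)]
    for i, name in enumerate(dm.ids):
        csv_rows.append(name + "," + ",".join(str(x) for x in dm.matrix[i]))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=io.StringIO("\n".join(csv_rows)))
    dtree = pdm.nj_tree()
    dnewick = dtree.as_string(schema="newick").strip()
    theirs = read_newick(dnewick.split("]")[-1].strip(), rooted=False)
    assert split_set(mine) == split_set(theirs)


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))


# ---------------------------------------------------------------------------
# midpoint rooting and patristic distances
# ---------------------------------------------------------------------------

def test_midpoint_two_leaves():
    tree = read_newick("(A:0.5,B:1.5);", rooted=False)
    rooted = midpoint_root(tree)
    assert rooted.rooted
    depths = {l.name: _depth(l) for l in rooted.leaves()}
    assert depths["A"] == pytest.approx(1.0)
    assert depths["B"] == pytest.approx(1.0)


def _depth(node):
    d = 0.0
    while node.parent is not None:
        d += node.length
        node = node.parent
    return d


def test_midpoint_caterpillar():
    # diameter path A..D has length 1+0.5+0.5+3 = 5; midpoint 2.5 from A
    tree = read_newick("(((A:1,B:0.2):0.5,C:0.3):0.5,D:3);", rooted=False)
    rooted = midpoint_root(tree)
    depths = {l.name: _depth(l) for l in rooted.leaves()}
    assert depths["A"] == pytest.approx(2.5)
    assert depths["D"] == pytest.approx(2.5)
    # total path lengths preserved
    for a, b in [("A", "B"), ("A", "D"), ("B", "C"), ("C", "D")]:
        assert patristic_distance(rooted, a, b) == pytest.approx(
            patristic_distance(tree, a, b))


def test_midpoint_idempotent_on_symmetric_tree():
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
    once = midpoint_root(tree)
    twice = midpoint_root(once)
    assert write_newick(once) == write_newick(twice)


def test_patristic_examples():
    tree = read_newick("(A:1,B:2);")
    assert patristic_distance(tree, "A", "B") == pytest.approx(3.0)
    assert patristic_distance(tree, "A", "A") == 0.0
    with pytest.raises(KeyError):
        patristic_distance(tree, "A", "Z")


def test_patristic_matches_dendropy():
    import io

    import dendropy

    rng = np.random.default_rng(13)
    tree = yule_tree(8, 1.0, rng)
    text = write_newick(tree)
    dtree = dendropy.Tree.get(data=text, schema="newick")
    pdm = dtree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dtree.taxon_namespace}
    names = tree.leaf_names()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert patristic_distance(tree, a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def test_single_leaf_closed_form():
    model = SubstitutionModel.poisson("AB")
    tree = PhyloTree(read_newick("(A:0,B:0);").root)
    msa = MultipleAlignment(["A", "B"], ["A", "A"])
    assert tree_likelihood(tree, msa, model) == pytest.approx(math.log(0.5))


def test_zero_branches_unanimous():
    model = SubstitutionModel.poisson("ABCD")
    tree = read_newick("((A:0,B:0):0,C:0);")
    msa = MultipleAlignment(["A", "B", "C"], ["CC", "CC", "CC"])
    assert tree_likelihood(tree, msa, model) == pytest.approx(2 * math.log(0.25))


def test_pruning_matches_enumeration_on_small_trees():
    rng = np.random.default_rng(17)
    for n_leaves, alphabet in [(3, "AB"), (4, "ABC"), (5, "AB")]:
        model = SubstitutionModel.poisson(alphabet)
        labels = tuple(f"T{i}" for i in range(n_leaves))
        shapes = list(enumerate_rooted_topologies(labels))
        for shape in shapes[:12]:
            lengths = iter(float(x) for x in rng.uniform(0.05, 1.2, size=20))
            tree = read_newick(topology_to_newick(shape, lengths))
            rows = ["".join(alphabet[i] for i in rng.integers(0, len(alphabet), 3))
                    for _ in labels]
            msa = MultipleAlignment(list(labels), rows)
            assert tree_likelihood(tree, msa, model) == pytest.approx(
                brute_force_log_likelihood(tree, msa, model), abs=1e-10)


def test_pulley_principle_root_invariance():
    """Sliding the root along a branch leaves the likelihood unchanged."""
    model = SubstitutionModel.poisson("ABCD")
    msa = MultipleAlignment(["A", "B", "C", "D"],
                            ["ABBA", "ABCA", "DBBA", "ABBD"])
    t1 = read_newick("(((A:0.3,B:0.4):0.2,C:0.5):0.15,D:0.25);")
    t2 = read_newick("(((A:0.3,B:0.4):0.2,C:0.5):0.05,D:0.35);")
    t3 = read_newick("(((A:0.3,B:0.4):0.2,C:0.5):0.4,D:0.0);")
    ll = [tree_likelihood(t, msa, model) for t in (t1, t2, t3)]
    assert ll[0] == pytest.approx(ll[1], abs=1e-8)
    assert ll[0] == pytest.approx(ll[2], abs=1e-8)
    # rerooting at an internal node is also neutral
    work = t1.copy()
    target = [n for n in work.postorder() if not n.is_leaf and n.parent is not None][0]
    ll_rerooted = tree_likelihood(_reroot_at_node(work, target), msa, model)
    assert ll_rerooted == pytest.approx(ll[0], abs=1e-8)


def test_model_file_round_trip(tmp_path):
    model = SubstitutionModel.poisson("ABC")
    path = tmp_path / "model.txt"
    with open(path, "w") as fh:
        fh.write(" ".join(str(x) for x in model.frequencies) + "\n")
        k = model.n_states
        S = np.ones((k, k)) - np.eye(k)
        for row in S:
            fh.write(" ".join(str(x) for x in row) + "\n")
    loaded = SubstitutionModel.from_file(path, "ABC")
    np.testing.assert_allclose(loaded.rate_matrix, model.rate_matrix)


def test_transition_matrix_rows_sum_to_one():
    model = SubstitutionModel.poisson()
    for t in (0.0, 0.05, 1.0, 10.0):
        P = model.transition_matrix(t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(model.transition_matrix(0.0), np.eye(20), atol=1e-12)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

@pytest.fixture
def anchored_tree():
    return read_newick("((A:0.5,B:0.5):1,(C:3,D:2):1);")


def test_near_pick_forced(anchored_tree):
    sel = select_candidates(anchored_tree, ["A"], n_near=1, n_spread=0)
    assert [x for x, _ in sel.near_picks] == ["B"]


def test_spread_pick_max_min(anchored_tree):
    sel = select_candidates(anchored_tree, ["A"], n_near=1, n_spread=1)
    assert [x for x, _ in sel.spread_picks] == ["C"]  # farthest from {A, B}


def test_selection_exhaustion(anchored_tree):
    sel = select_candidates(anchored_tree, ["A"], n_near=3, n_spread=0)
    assert sorted(x for x, _ in sel.near_picks) == ["B", "C", "D"]
    assert sel.spread_picks == []


def test_selection_disjointness(anchored_tree):
    sel = select_candidates(anchored_tree, ["A"], n_near=1, n_spread=2)
    ids = sel.ids
    assert len(set(ids)) == len(ids)
    assert "A" not in ids


def test_selection_empty_verified_errors(anchored_tree):
    with pytest.raises(ValueError, match="verified"):
        select_candidates(anchored_tree, [], 1, 0)
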