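import numpy as np
import pytest
from hypothesis import given, strategies as st

from ximine import (MultipleAlignment, ProteinRecord, SequenceSet,
                    center_star_msa, global_align, map_reference_positions,
                    percent_identity, simple_scheme)
from conftest import RESIDUES, random_protein
from oracles import brute_force_alignment_score

short_seq = st.text(alphabet=RESIDUES, min_size=1, max_size=8)


def test_identity_alignment(blosum):
    a = global_align("ACDE", "ACDE", blosum)
    assert a.row_a == a.row_b == "ACDE"
    assert a.identity_pct == 100.0
    assert a.score == sum(blosum.score(ch, ch) for ch in "ACDE")


def test_known_gap_placement(simple):
    a = global_align("ACDE", "ACE", simple)
    assert a.score == brute_force_alignment_score("ACDE", "ACE", simple)
    assert a.row_b.replace("-", "") == "ACE"
    assert len(a.row_a) == 4


def test_empty_partner():
    a = global_align("MK", "")
    assert a.row_b == "--"
    assert a.row_a == "MK"


@pytest.mark.parametrize("scheme_name", ["linear", "affine"])
def test_score_matches_exhaustive_enumeration(scheme_name, simple, blosum):
    scheme = simple if scheme_name == "linear" else blosum
    rng = np.random.default_rng(42)
    for _ in range(150):
        a = random_protein(rng, int(rng.integers(1, 7)))
        b = random_protein(rng, int(rng.integers(1, 7)))
        got = global_align(a, b, scheme).score
        assert got == brute_force_alignment_score(a, b, scheme), (a, b)


def test_score_matches_biopython_global_aligner(blosum):
    """Independent cross-check against Biopython's affine global aligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = np.zeros((21, 21))
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            matrix[i, j] = blosum.score(x, y)
    from Bio.Align import substitution_matrices
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=alphabet, dims=2, data=matrix)
    aligner.open_gap_score = blosum.gap_open
    aligner.extend_gap_score = blosum.gap_extend
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = random_protein(rng, int(rng.integers(5, 60)))
        b = random_protein(rng, int(rng.integers(5, 60)))
        assert global_align(a, b, blosum).score == int(aligner.score(a, b))


def test_percent_identity_hand_counts(simple):
    a = global_align("AAAA", "AATT", simple)
    assert percent_identity(a, "shorter_sequence") == 50.0
    assert percent_identity(a, "alignment_columns") == 50.0
    disjoint = global_align("AAAA", "TTTT", simple)
    assert percent_identity(disjoint) == 0.0


@given(short_seq, short_seq)
def test_percent_identity_symmetric_and_100_iff_identical(a, b):
    scheme = simple_scheme()
    ab = percent_identity(global_align(a, b, scheme))
    ba = percent_identity(global_align(b, a, scheme))
    assert ab == pytest.approx(ba)
    if a == b and "X" not in a:
        assert ab == 100.0
    if ab == 100.0 and len(a) == len(b):
        assert a == b or "X" in a + b


def test_x_scores_zero_and_never_identical(blosum):
    assert blosum.score("X", "W") == 0
    assert blosum.score("X", "X") == 0
    a = global_align("AXA", "AXA", blosum)
    assert a.identity_pct == pytest.approx(100 * 2 / 3)


def test_coordinate_map_identity(simple):
    a = global_align("ACDE", "ACDE", simple)
    cmap = map_reference_positions(a)
    assert all(cmap[i] == i for i in range(1, 5))


def test_coordinate_map_hand_traced():
    from ximine.align import PairwiseAlignment

    aln = PairwiseAlignment("AC-DE", "ACXDE", 0)
    cmap = map_reference_positions(aln)
    assert cmap[3] == 4  # reference D sits over candidate position 4
    gap = PairwiseAlignment("ACD", "A-D", 0)
    assert map_reference_positions(gap)[2] is None


@given(short_seq, short_seq)
def test_coordinate_map_strictly_increasing_and_invertible(a, b):
    scheme = simple_scheme()
    fwd = map_reference_positions(global_align(a, b, scheme))
    defined = [(r, c) for r, c in sorted(fwd.positions.items()) if c is not None]
    for (r1, c1), (r2, c2) in zip(defined, defined[1:]):
        assert r1 < r2 and c1 < c2
    # composing with the reverse map is the identity where defined
    rev = map_reference_positions(global_align(b, a, scheme))
    for r, c in defined:
        if rev.get(c) is not None:
            assert rev[c] == r


def test_center_star_identical_sequences(simple):
    seqs = SequenceSet([ProteinRecord("a", "MKHW"), ProteinRecord("b", "MKHW"),
                        ProteinRecord("c", "MKHW")])
    msa = center_star_msa(seqs, "a", simple)
    assert all("-" not in row for row in msa.rows)


def test_center_star_single_deletion(blosum):
    base = "MKHWCDEFGH"
    seqs = SequenceSet([ProteinRecord("c", base),
                        ProteinRecord("d", base[:4] + base[5:]),
                        ProteinRecord("e", base)])
    msa = center_star_msa(seqs, "c", blosum)
    assert msa.row("d").count("-") == 1
    assert msa.n_columns >= len(base)
    for rid, original in [("c", base), ("d", base[:4] + base[5:]), ("e", base)]:
        assert msa.row(rid).replace("-", "") == original


def test_center_star_degapping_recovers_inputs(blosum):
    rng = np.random.default_rng(11)
    base = random_protein(rng, 40)
    records = [ProteinRecord("center", base)]
    for i in range(4):
        seq = list(base)
        cut = int(rng.integers(5, 35))
        if i % 2 == 0:
            del seq[cut:cut + int(rng.integers(1, 4))]
        else:
            seq[cut:cut] = list(random_protein(rng, int(rng.integers(1, 4))))
        records.append(ProteinRecord(f"s{i}", "".join(seq)))
    msa = center_star_msa(SequenceSet(records), "center", blosum)
    assert msa.n_columns >= 40
    for rec in records:
        assert msa.row(rec.id).replace("-", "") == rec.residues
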