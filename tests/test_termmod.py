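import numpy as np
import pytest

from ximine import (MultipleAlignment, PlanError, ProteinRecord, apply_plan,
                    consensus_mismatches, diagnose_termini, propose_plan)
from ximine.termmod import Edit, ModificationPlan
from ximine.simulate import SimulationConfig, simulate_family
from conftest import random_protein


@pytest.fixture(scope="module")
def reference():
    _, truth = simulate_family(SimulationConfig(n_leaves=4, seed=9, branch_scale=0.0))
    return truth.root_record("REF")


def test_identity_is_complete(reference, blosum):
    d = diagnose_termini(reference, reference, blosum)
    assert (d.n_deficit, d.n_overhang, d.c_deficit, d.c_overhang) == (0, 0, 0, 0)
    assert d.classification == "complete"


def test_n_truncation_measured_exactly(reference, blosum):
    candidate = ProteinRecord("anaxi_like", reference.residues[22:])
    d = diagnose_termini(candidate, reference, blosum)
    assert d.n_deficit == 22 and d.classification == "N_truncated"


def test_n_extension_measured_exactly(reference, blosum):
    rng = np.random.default_rng(2)
    candidate = ProteinRecord("neoxi_like", random_protein(rng, 11) + reference.residues)
    d = diagnose_termini(candidate, reference, blosum)
    assert d.n_overhang == 11 and d.classification == "N_extended"


def test_c_terminal_anomalies(reference, blosum):
    truncated = ProteinRecord("ct", reference.residues[:-15])
    d = diagnose_termini(truncated, reference, blosum)
    assert d.c_deficit == 15 and d.classification == "C_truncated"
    rng = np.random.default_rng(3)
    extended = ProteinRecord("ce", reference.residues + random_protein(rng, 9))
    d2 = diagnose_termini(extended, reference, blosum)
    assert d2.c_overhang == 9 and d2.classification == "C_extended"


def test_small_overhang_is_noise(reference, blosum):
    candidate = ProteinRecord("near", reference.residues[3:])
    d = diagnose_termini(candidate, reference, blosum)
    assert d.classification == "complete"  # below the 5-residue threshold


def test_propose_graft_for_truncation(reference, blosum):
    candidate = ProteinRecord("cand", reference.residues[22:])
    d = diagnose_termini(candidate, reference, blosum)
    plan = propose_plan(d, donor=reference)
    assert [e.kind for e in plan.edits] == ["graft_N"]
    assert plan.edits[0].fragment == reference.residues[:22]
    repaired = apply_plan(candidate, plan)
    assert repaired.residues == reference.residues
    assert repaired.id.endswith("-mod")
    assert diagnose_termini(repaired, reference, blosum).classification == "complete"


def test_propose_trim_for_extension(reference, blosum):
    rng = np.random.default_rng(4)
    candidate = ProteinRecord("cand", random_protein(rng, 11) + reference.residues)
    d = diagnose_termini(candidate, reference, blosum)
    plan = propose_plan(d)
    assert [e.kind for e in plan.edits] == ["trim_N"]
    assert apply_plan(candidate, plan).residues == reference.residues


def test_point_mutations_on_complete_sequence(reference, blosum):
    d = diagnose_termini(reference, reference, blosum)
    observed_60 = reference.residues[59]
    observed_325 = reference.residues[324]
    plan = propose_plan(d, consensus_mismatches=[(60, observed_60, "Q"),
                                                 (325, observed_325, "S")])
    assert [e.kind for e in plan.edits] == ["point_mutation", "point_mutation"]
    out = apply_plan(reference, plan)
    assert out.residues[59] == "Q" and out.residues[324] == "S"
    untouched = [i for i in range(len(reference)) if i not in (59, 324)]
    assert all(out.residues[i] == reference.residues[i] for i in untouched)


def test_internal_motif_deletion(reference):
    seq = reference.residues
    with_motif = ProteinRecord("rhixi_like", seq[:100] + "NTSIPFD" + seq[100:])
    plan = ModificationPlan("rhixi_like",
                            [Edit("delete_internal", fragment="NTSIPFD", position=101)])
    out = apply_plan(with_motif, plan)
    assert out.residues == seq
    assert len(out) == len(with_motif) - 7


def test_failfast_validation(reference):
    with pytest.raises(PlanError, match="motif mismatch"):
        apply_plan(reference, ModificationPlan(
            "x", [Edit("delete_internal", fragment="NTSIPFD", position=5)]))
    with pytest.raises(PlanError, match="expected"):
        wrong = "Q" if reference.residues[59] != "Q" else "S"
        apply_plan(reference, ModificationPlan(
            "x", [Edit("point_mutation", position=60, from_residue=wrong,
                       to_residue="A")]))
    with pytest.raises(PlanError, match="trim_N"):
        apply_plan(ProteinRecord("s", "MKW"), ModificationPlan(
            "s", [Edit("trim_N", count=10)]))
    short_donor = ProteinRecord("d", "MK")
    diag = diagnose_termini(ProteinRecord("c", reference.residues[22:]), reference)
    with pytest.raises(PlanError, match="shorter"):
        propose_plan(diag, donor=short_donor)


def test_trim_then_graft_is_identity(reference):
    for k in (1, 5, 17):
        head = reference.residues[:k]
        plan = ModificationPlan("r", [Edit("trim_N", count=k),
                                      Edit("graft_N", fragment=head)])
        assert apply_plan(reference, plan).residues == reference.residues


@pytest.mark.parametrize("kind", ["truncate", "extend"])
def test_repair_round_trip_all_sizes(kind, reference, blosum):
    rng = np.random.default_rng(8)
    for k in range(1, 41):
        if kind == "truncate":
            candidate = ProteinRecord("c", reference.residues[k:])
        else:
            candidate = ProteinRecord("c", random_protein(rng, k) + reference.residues)
        # threshold 1: repair every measured defect, however small
        d = diagnose_termini(candidate, reference, blosum, anomaly_threshold=1)
        plan = propose_plan(d, donor=reference)
        repaired = apply_plan(candidate, plan)
        final = diagnose_termini(repaired, reference, blosum)
        assert final.classification == "complete", (kind, k)
        assert len(repaired) == len(reference), (kind, k)


def test_plan_json_round_trip(reference):
    plan = ModificationPlan("t", [Edit("graft_N", fragment="MKW", donor_id="d"),
                                  Edit("point_mutation", position=3,
                                       from_residue="W", to_residue="A")])
    assert ModificationPlan.from_json(plan.to_json()) == plan


def _toy_msa(rows):
    return MultipleAlignment([f"r{i}" for i in range(len(rows))], rows)


def test_consensus_identical_candidate_clean(blosum):
    msa = _toy_msa(["MKWHD", "MKWHD", "MKWHD", "MKWHD"])
    cand = ProteinRecord("c", "MKWHD")
    assert consensus_mismatches(cand, msa, 0.8, blosum) == []


def test_consensus_flags_engineered_column(blosum):
    msa = _toy_msa(["MKWHDEFGHKLW", "MKWHDEFGHKLW", "MKWHDEFGHKLW", "MKWHDEFGHKLW"])
    cand = ProteinRecord("c", "MKWADEFGHKLW")  # H -> A at position 4
    hits = consensus_mismatches(cand, msa, 1.0, blosum)
    assert hits == [(4, "A", "H")]


def test_consensus_respects_conservation_threshold(blosum):
    # column 4 is split 2/2: below 0.9 conservation, so never reported
    msa = _toy_msa(["MKWHDEFGHKLW", "MKWHDEFGHKLW", "MKWADEFGHKLW", "MKWADEFGHKLW"])
    cand = ProteinRecord("c", "MKWCDEFGHKLW")
    assert consensus_mismatches(cand, msa, 0.9, blosum) == []


def test_round_trip_repairs_on_simulated_anomalies(blosum):
    cfg = SimulationConfig(n_leaves=12, seed=21, branch_scale=0.03,
                           p_n_truncate=0.4, p_n_extend=0.3, sequence_length=380)
    seqs, truth = simulate_family(cfg)
    reference = truth.root_record("REF")
    hits = total = 0
    for event in truth.events:
        total += 1
        d = diagnose_termini(seqs[event.leaf_id], reference, blosum)
        measured = d.n_deficit if event.kind == "n_truncate" else d.n_overhang
        if measured == event.size:
            hits += 1
    assert total > 0
    assert hits == total  # exact size recovery at this divergence
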