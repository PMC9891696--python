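"""Terminal-fragment diagnosis and sequence repair.

Inactive family members often differ from active ones by terminal defects:
a missing N-terminal fragment (e.g. 22 or 37 residues), a surplus N-terminal
extension (e.g. 11 residues), an internal inserted motif (e.g. "NTSIPFD"),
or scattered residues discordant with the active-sequence consensus.  This
module measures those defects against a reference by global alignment
(:func:`diagnose_termini`), turns a diagnosis into an explicit edit script
(:func:`propose_plan`) and applies the script with fail-fast residue
validation (:func:`apply_plan`) — silent coordinate drift being the classic
failure mode of manual sequence surgery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import (MultipleAlignment, ScoringScheme, blosum62_scheme,
                    global_align, map_reference_positions)
from .seqio import ProteinRecord

#: Terminal gap runs shorter than this are indel noise, not defects.
DEFAULT_ANOMALY_THRESHOLD = 5


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminalDiagnosis:
    candidate_id: str
    reference_id: str
    n_deficit: int    # reference residues before the candidate begins
    n_overhang: int   # candidate residues before the reference begins
    c_deficit: int
    c_overhang: int
    classification: str  # complete | N_truncated | N_extended | C_truncated | C_extended | mixed

    def to_tsv_row(self) -> str:
        return (f"{self.candidate_id}\t{self.reference_id}\t{self.n_deficit}\t"
                f"{self.n_overhang}\t{self.c_deficit}\t{self.c_overhang}\t"
                f"{self.classification}")


def _leading_run(row: str) -> int:
    count = 0
    for ch in row:
        if ch != "-":
            break
        count += 1
    return count


def _classify(n_deficit: int, n_overhang: int, c_deficit: int, c_overhang: int,
              threshold: int) -> str:
    n_label = None
    if n_deficit >= threshold:
        n_label = "N_truncated"
    elif n_overhang >= threshold:
        n_label = "N_extended"
    c_label = None
    if c_deficit >= threshold:
        c_label = "C_truncated"
    elif c_overhang >= threshold:
        c_label = "C_extended"
    if n_label and c_label:
        return "mixed"
    return n_label or c_label or "complete"


def diagnose_termini(candidate: ProteinRecord, reference: ProteinRecord,
                     scheme: ScoringScheme | None = None,
                     anomaly_threshold: int = DEFAULT_ANOMALY_THRESHOLD) -> TerminalDiagnosis:
    """Measure terminal deficits/overhangs of a candidate against a reference.

    Counts come from the maximal leading and trailing gap runs of the global
    alignment; a terminus is anomalous when its count reaches
    ``anomaly_threshold`` (default 5; the family's observed true defects are
    11, 22 and 37 residues).
    """
    if scheme is None:
        scheme = blosum62_scheme()
    aln = global_align(reference.residues, candidate.residues, scheme)
    ref_row, cand_row = aln.row_a, aln.row_b
    n_deficit = _leading_run(cand_row)       # candidate gapped -> missing start
    n_overhang = _leading_run(ref_row)       # reference gapped -> extra start
    c_deficit = _leading_run(cand_row[::-1])
    c_overhang = _leading_run(ref_row[::-1])
    return TerminalDiagnosis(
        candidate.id, reference.id, n_deficit, n_overhang, c_deficit, c_overhang,
        _classify(n_deficit, n_overhang, c_deficit, c_overhang, anomaly_threshold))


def diagnoses_to_tsv(diagnoses: Iterable[TerminalDiagnosis], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\treference_id\tn_deficit\tn_overhang\t"
                 "c_deficit\tc_overhang\tclassification\n")
        for d in diagnoses:
            fh.write(d.to_tsv_row() + "\n")


# ---------------------------------------------------------------------------
# Edit script
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """One repair step; ``kind`` decides which fields are meaningful."""

    kind: str  # graft_N | graft_C | trim_N | trim_C | delete_internal | point_mutation
    fragment: str = ""       # graft/delete motif residues
    donor_id: str = ""       # provenance of grafted fragments
    count: int = 0           # trim length
    position: int = 0        # 1-based; delete_internal start / mutation site
    from_residue: str = ""
    to_residue: str = ""


@dataclass
class ModificationPlan:
    target_id: str
    edits: list[Edit] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {"target_id": self.target_id,
                   "edits": [{k: v for k, v in e.__dict__.items()} for e in self.edits]}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModificationPlan":
        payload = json.loads(text)
        return cls(payload["target_id"], [Edit(**e) for e in payload["edits"]])


class PlanError(ValueError):
    """An edit does not validate against the current sequence state."""


def propose_plan(diagnosis: TerminalDiagnosis, donor: ProteinRecord | None = None,
                 consensus_mismatches: Sequence[tuple[int, str, str]] = ()) -> ModificationPlan:
    """Build the repair script implied by a diagnosis.

    N/C truncations graft the donor's terminal ``deficit`` residues (the
    donor is assumed to share the reference coordinate frame); extensions
    trim the overhang.  Consensus mismatches (position, observed, consensus)
    append point mutations whose positions refer to the post-graft sequence.
    """
    edits: list[Edit] = []
    if diagnosis.classification in ("N_truncated", "mixed") and diagnosis.n_deficit > 0:
        if donor is None:
            raise PlanError("N-terminal graft needs a donor sequence")
        if len(donor) < diagnosis.n_deficit:
            raise PlanError(f"donor {donor.id!r} shorter than the {diagnosis.n_deficit}-residue fragment")
        edits.append(Edit("graft_N", fragment=donor.residues[:diagnosis.n_deficit],
                          donor_id=donor.id))
    if diagnosis.classification in ("N_extended", "mixed") and diagnosis.n_overhang > 0:
        edits.append(Edit("trim_N", count=diagnosis.n_overhang))
    if diagnosis.classification in ("C_truncated", "mixed") and diagnosis.c_deficit > 0:
        if donor is None:
            raise PlanError("C-terminal graft needs a donor sequence")
        if len(donor) < diagnosis.c_deficit:
            raise PlanError(f"donor {donor.id!r} shorter than the {diagnosis.c_deficit}-residue fragment")
        edits.append(Edit("graft_C", fragment=donor.residues[-diagnosis.c_deficit:],
                          donor_id=donor.id))
    if diagnosis.classification in ("C_extended", "mixed") and diagnosis.c_overhang > 0:
        edits.append(Edit("trim_C", count=diagnosis.c_overhang))
    for position, observed, consensus in consensus_mismatches:
        edits.append(Edit("point_mutation", position=position,
                          from_residue=observed, to_residue=consensus))
    return ModificationPlan(diagnosis.candidate_id, edits)


def apply_plan(seq: ProteinRecord, plan: ModificationPlan) -> ProteinRecord:
    """Apply an edit script, validating every edit against the current state.

    Grafts prepend/append; trims drop terminal residues; internal deletions
    require the motif to match at the stated start; point mutations require
    the observed residue.  The output id gets a ``-mod`` suffix.
    """
    residues = seq.residues
    for edit in plan.edits:
        if edit.kind == "graft_N":
            residues = edit.fragment + residues
        elif edit.kind == "graft_C":
            residues = residues + edit.fragment
        elif edit.kind == "trim_N":
            if edit.count > len(residues):
                raise PlanError(f"trim_N({edit.count}) longer than sequence")
            residues = residues[edit.count:]
        elif edit.kind == "trim_C":
            if edit.count > len(residues):
                raise PlanError(f"trim_C({edit.count}) longer than sequence")
            residues = residues[: len(residues) - edit.count]
        elif edit.kind == "delete_internal":
            start = edit.position - 1
            observed = residues[start:start + len(edit.fragment)]
            if observed != edit.fragment:
                raise PlanError(f"motif mismatch at {edit.position}: "
                                f"expected {edit.fragment!r}, found {observed!r}")
            residues = residues[:start] + residues[start + len(edit.fragment):]
        elif edit.kind == "point_mutation":
            idx = edit.position - 1
            if idx < 0 or idx >= len(residues):
                raise PlanError(f"mutation position {edit.position} out of range")
            if residues[idx] != edit.from_residue:
                raise PlanError(f"expected {edit.from_residue} at {edit.position}, "
                                f"found {residues[idx]}")
            residues = residues[:idx] + edit.to_residue + residues[idx + 1:]
        else:
            raise PlanError(f"unknown edit kind {edit.kind!r}")
        if not residues:
            raise PlanError("edit script emptied the sequence")
    return ProteinRecord(seq.id + "-mod", residues, seq.description)


# ---------------------------------------------------------------------------
# Consensus comparison against active sequences
# ---------------------------------------------------------------------------

def consensus_mismatches(candidate: ProteinRecord, active_msa: MultipleAlignment,
                         min_conservation: float = 0.8,
                         scheme: ScoringScheme | None = None,
                         center_id: str | None = None) -> list[tuple[int, str, str]]:
    """Candidate positions discordant with the active-sequence consensus.

    A column counts when at least ``min_conservation`` of the active rows
    share one residue and the candidate differs there.  The candidate is
    placed into MSA coordinates by aligning it to the (de-gapped) center row
    (default: the first row).  Returns (candidate position 1-based, candidate
    residue, consensus residue) tuples.
    """
    if len(active_msa.ids) < 2:
        raise ValueError("active MSA needs at least 2 rows")
    if not (0.5 < min_conservation <= 1.0):
        raise ValueError("min_conservation must lie in (0.5, 1]")
    if scheme is None:
        scheme = blosum62_scheme()
    center = center_id or active_msa.ids[0]
    center_row = active_msa.row(center)
    center_seq = center_row.replace("-", "")
    aln = global_align(center_seq, candidate.residues, scheme)
    cmap = map_reference_positions(aln)  # center position -> candidate position

    # center position per MSA column
    col_to_center: list[int | None] = []
    cpos = 0
    for ch in center_row:
        if ch == "-":
            col_to_center.append(None)
        else:
            cpos += 1
            col_to_center.append(cpos)

    n_rows = len(active_msa.rows)
    results: list[tuple[int, str, str]] = []
    for col in range(active_msa.n_columns):
        column = [row[col] for row in active_msa.rows]
        residues = [ch for ch in column if ch != "-"]
        if not residues:
            continue
        top = max(set(residues), key=lambda ch: (residues.count(ch), ch))
        if residues.count(top) / n_rows < min_conservation:
            continue
        center_pos = col_to_center[col]
        if center_pos is None:
            continue
        cand_pos = cmap.get(center_pos)
        if cand_pos is None:
            continue
        observed = candidate.residues[cand_pos - 1]
        if observed != top:
            results.append((cand_pos, observed, top))
    return results
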