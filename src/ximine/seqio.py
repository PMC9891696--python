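"""Sequence and tree I/O: FASTA records and Newick trees.

Defines the core :class:`ProteinRecord` / :class:`SequenceSet` containers used
by every mining stage, and lossless round-trip readers/writers for the two
plain-text formats the pipeline exchanges (multi-record FASTA, single-tree
Newick).  Residues are upper-cased on input and restricted to the 20 canonical
amino acids plus ``X`` (unknown); ids are case-sensitive and must be unique
within a collection.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)


class FastaError(ValueError):
    """Malformed FASTA input (duplicate id, illegal residue, empty body)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be non-empty")
        residues = self.residues.upper()
        if not residues:
            raise FastaError(f"record {self.id!r}: empty sequence body")
        for pos, ch in enumerate(residues, start=1):
            if ch not in _ALPHABET_SET:
                raise FastaError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: list[ProteinRecord] = []
        self._by_id: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._by_id:
            raise FastaError(f"duplicate record id {record.id!r}")
        self._records.append(record)
        self._by_id[record.id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __getitem__(self, id_or_index: str | int) -> ProteinRecord:
        if isinstance(id_or_index, int):
            return self._records[id_or_index]
        return self._by_id[id_or_index]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def subset(self, keep: Iterable[str]) -> "SequenceSet":
        """Records whose id is in ``keep``, preserving this set's order."""
        wanted = set(keep)
        return SequenceSet(r for r in self._records if r.id in wanted)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"SequenceSet({len(self)} records)"


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Parse a (possibly line-wrapped) FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes the id; the remainder
    is the description.  Duplicate ids, illegal residues and empty record
    bodies raise :class:`FastaError`.
    """
    seqs = SequenceSet()
    with open(path) as fh:
        for title, body in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FastaError("FASTA header with empty id")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            seqs.add(ProteinRecord(rec_id, body.replace(" ", ""), description))
    return seqs


def write_fasta(seqs: SequenceSet | Iterable[ProteinRecord], path: str | os.PathLike,
                wrap_width: int = 60) -> None:
    """Write records as FASTA; sequence lines wrapped at ``wrap_width``."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    with open(path, "w") as fh:
        for rec in seqs:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(rec.residues), wrap_width):
                fh.write(rec.residues[start:start + wrap_width] + "\n")


# Tree exchange lives with the tree structure; re-exported here so that all
# file-format entry points are importable from one place.
from .phylo import PhyloTree, read_newick, write_newick  # noqa: E402,F401
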