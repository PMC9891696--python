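"""Sequence-screening stages of the mining pipeline.

Four operations reduce a raw protein collection to credible family members:
a length window (370–470 residues for the xylose-isomerase family), a
length-based type call (type II above 400 residues), greedy identity-threshold
dereplication at 73% (CD-HIT-style: longest-first, join the first
representative matched at or above the threshold with the shorter-sequence
identity denominator), and a conserved-catalytic-site filter that maps each
candidate into the reference coordinate frame by global alignment and demands
the catalytic residues in place.

The default conserved-site profile is the 15-residue set in PirXI
(*Piromyces* sp. E2 xylose isomerase) coordinates: ten metal-ion-binding
residues (H102, D105, E233, K235, E269, H272, D297, D308, D310, D340) and
five substrate-pocket residues (W50, F61, W140, F146, W189).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .align import (PairwiseAlignment, ScoringScheme, blosum62_scheme,
                    global_align, map_reference_positions, percent_identity)
from .seqio import ProteinRecord, SequenceSet


# ---------------------------------------------------------------------------
# Length screening and type classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthWindow:
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


#: The family-wide screening window and the per-type windows.
FAMILY_WINDOW = LengthWindow(370, 470)
TYPE_I_WINDOW = LengthWindow(380, 390)
TYPE_II_WINDOW = LengthWindow(440, 460)

#: Length above which a sequence is called type II (strictly more than).
TYPE_BOUNDARY = 400


def filter_by_length(seqs: SequenceSet, window: LengthWindow = FAMILY_WINDOW) -> SequenceSet:
    """Keep records whose length lies inside the window (inclusive)."""
    return SequenceSet(r for r in seqs if len(r) in window)


def classify_type(seq: ProteinRecord | str) -> str:
    """``type_II`` for sequences of more than 400 residues, else ``type_I``."""
    length = len(seq.residues) if isinstance(seq, ProteinRecord) else len(seq)
    return "type_II" if length > TYPE_BOUNDARY else "type_I"


# ---------------------------------------------------------------------------
# Conserved-site profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservedSite:
    position: int  # 1-based reference coordinate
    residue: str
    role: str  # metal_binding | pocket


@dataclass(frozen=True)
class ConservedSiteSpec:
    sites: tuple[ConservedSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("site positions must be unique and sorted")
        for s in self.sites:
            if s.role not in ("metal_binding", "pocket"):
                raise ValueError(f"unknown site role {s.role!r}")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("position\tresidue\trole\n")
            for s in self.sites:
                fh.write(f"{s.position}\t{s.residue}\t{s.role}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ConservedSiteSpec":
        sites = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError("site spec TSV must start with a position/residue/role header")
            for line in fh:
                if not line.strip():
                    continue
                pos, res, role = line.rstrip("\n").split("\t")
                sites.append(ConservedSite(int(pos), res, role))
        return cls(tuple(sites))


def default_conserved_sites() -> ConservedSiteSpec:
    """The 15 catalytic/pocket residues of PirXI, in PirXI coordinates."""
    metal = [(102, "H"), (105, "D"), (233, "E"), (235, "K"), (269, "E"),
             (272, "H"), (297, "D"), (308, "D"), (310, "D"), (340, "D")]
    pocket = [(50, "W"), (61, "F"), (140, "W"), (146, "F"), (189, "W")]
    sites = ([ConservedSite(p, r, "metal_binding") for p, r in metal]
             + [ConservedSite(p, r, "pocket") for p, r in pocket])
    sites.sort(key=lambda s: s.position)
    return ConservedSiteSpec(tuple(sites))


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference sequence plus its conserved-site map; the coordinate frame
    every candidate is judged in."""

    reference: ProteinRecord
    sites: ConservedSiteSpec

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.position > len(self.reference):
                raise ValueError(f"site {s.position} beyond reference length")
            observed = self.reference.residues[s.position - 1]
            if observed != s.residue:
                raise ValueError(
                    f"reference residue {observed} at {s.position} does not match "
                    f"site spec {s.residue}")


# ---------------------------------------------------------------------------
# Greedy dereplication clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    identities: dict[str, float] = field(default_factory=dict)


DEFAULT_IDENTITY_THRESHOLD = 73.0


def dereplicate(seqs: SequenceSet,
                identity_threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD,
                scheme: ScoringScheme | None = None) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are taken longest-first (ties by id); each joins the first
    existing cluster whose representative it matches at identity >= threshold
    (inclusive; shorter-sequence denominator), else founds a new cluster.
    Identical residues merge unconditionally (identity 100).  Representatives
    end up pairwise below the threshold.
    """
    if not (0 < identity_threshold_pct <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    if scheme is None:
        scheme = blosum62_scheme()
    order = sorted(seqs, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    for rec in order:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if rec.residues == rep.residues:
                ident = 100.0
            else:
                aln = global_align(rep.residues, rec.residues, scheme)
                ident = percent_identity(aln, "shorter_sequence")
            if ident >= identity_threshold_pct:
                cluster.member_ids.append(rec.id)
                cluster.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], {rec.id: 100.0}))
            reps.append(rec)
    return clusters


def clusters_to_tsv(clusters: list[Cluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity_pct\n")
        for cl in clusters:
            for member in cl.member_ids:
                ident = cl.identities.get(member, float("nan"))
                fh.write(f"{cl.representative_id}\t{member}\t{ident:.2f}\n")


# ---------------------------------------------------------------------------
# Conserved-site retention filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteOutcome:
    site: ConservedSite
    status: str  # matched | mismatched | unaligned
    observed: str | None = None  # candidate residue for mismatched


@dataclass(frozen=True)
class SiteReport:
    candidate_id: str
    outcomes: tuple[SiteOutcome, ...]
    allowed_misses: int

    @property
    def n_matched(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "matched")

    @property
    def n_missed(self) -> int:
        return len(self.outcomes) - self.n_matched

    @property
    def passed(self) -> bool:
        return self.n_missed <= self.allowed_misses


def check_conserved_sites(candidate: ProteinRecord, profile: ReferenceProfile,
                          scheme: ScoringScheme | None = None,
                          allowed_misses: int = 0) -> SiteReport:
    """Judge a candidate's catalytic sites in the reference frame.

    The candidate is globally aligned to the profile reference; each site is
    read through the resulting coordinate map, so N-terminal truncations or
    extensions that leave the site columns aligned do not move the sites.
    """
    if scheme is None:
        scheme = blosum62_scheme()
    aln = global_align(profile.reference.residues, candidate.residues, scheme)
    cmap = map_reference_positions(aln)
    outcomes = []
    for site in profile.sites:
        cand_pos = cmap.get(site.position)
        if cand_pos is None:
            outcomes.append(SiteOutcome(site, "unaligned"))
        else:
            observed = candidate.residues[cand_pos - 1]
            if observed == site.residue:
                outcomes.append(SiteOutcome(site, "matched", observed))
            else:
                outcomes.append(SiteOutcome(site, "mismatched", observed))
    return SiteReport(candidate.id, tuple(outcomes), allowed_misses)


def site_reports_to_tsv(reports: Iterable[SiteReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tposition\texpected\trole\tstatus\tobserved\tpassed\n")
        for rep in reports:
            for o in rep.outcomes:
                observed = o.observed if o.observed is not None else "-"
                fh.write(f"{rep.candidate_id}\t{o.site.position}\t{o.site.residue}\t"
                         f"{o.site.role}\t{o.status}\t{observed}\t{rep.passed}\n")
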