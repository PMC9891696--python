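"""End-to-end mining workflow.

Chains the stages in the order the screening procedure runs: length window
-> identity dereplication -> conserved-site retention -> center-star MSA on
the reference -> corrected distances -> neighbor joining -> midpoint rooting
-> candidate selection -> terminal diagnosis, with optional ancestral
reconstruction at chosen internal nodes.  Verified (known-active) sequences
and the reference bypass the filters, anchoring the tree the way previously
validated enzymes anchor the published phylogeny.

Every stage writes its artifact into the run directory and appends a
manifest entry (stage, input count, output count, parameters, wall time);
re-running with the same inputs and seed reproduces every artifact
byte-for-byte (the manifest's wall-time fields aside).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Iterable

from . import align, asr as asr_mod, mining, phylo, termmod
from .seqio import ProteinRecord, SequenceSet, write_fasta

logger = logging.getLogger("ximine.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    length_window: mining.LengthWindow = field(default_factory=lambda: mining.FAMILY_WINDOW)
    identity_threshold_pct: float = mining.DEFAULT_IDENTITY_THRESHOLD
    allowed_misses: int = 0
    distance_model: str = "poisson"
    n_near: int = 2
    n_spread: int = 3
    asr_nodes: tuple[str, ...] = ()  # internal node names; "root" = the tree's root
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.identity_threshold_pct <= 100):
            raise ValueError("identity threshold must lie in (0, 100]")
        if self.allowed_misses < 0:
            raise ValueError("allowed_misses must be nonnegative")
        if self.distance_model not in ("p_distance", "poisson"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.n_near < 0 or self.n_spread < 0:
            raise ValueError("selection counts must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "length_window": [self.length_window.min_len, self.length_window.max_len],
            "identity_threshold_pct": self.identity_threshold_pct,
            "allowed_misses": self.allowed_misses,
            "distance_model": self.distance_model,
            "n_near": self.n_near,
            "n_spread": self.n_spread,
            "asr_nodes": list(self.asr_nodes),
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    out_dir: str
    manifest: list[dict]
    clusters: list[mining.Cluster]
    site_reports: list[mining.SiteReport]
    msa: align.MultipleAlignment
    tree: phylo.PhyloTree
    selection: phylo.CandidateSelection
    diagnoses: list[termmod.TerminalDiagnosis]
    reconstruction: asr_mod.AncestralReconstruction | None


def run_mining_pipeline(seqs: SequenceSet, reference_profile: mining.ReferenceProfile,
                        verified_ids: Iterable[str], config: PipelineConfig,
                        out_dir: str) -> PipelineResult:
    """Run the whole mining workflow; artifacts land in ``out_dir``.

    ``verified_ids`` are retained unconditionally (a warning is logged if a
    filter would have dropped them); when empty, the reference alone anchors
    candidate selection.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    scheme = align.blosum62_scheme()
    reference = reference_profile.reference
    verified = sorted(set(verified_ids))
    unknown = [v for v in verified if v not in seqs]
    if unknown:
        raise PipelineError(f"stage setup: verified ids not in input: {unknown}")
    manifest: list[dict] = []

    def record_stage(name: str, n_in: int, n_out: int, params: dict, t0: float) -> None:
        entry = {"stage": name, "n_in": n_in, "n_out": n_out,
                 "params": params, "seed": config.seed,
                 "wall_time_s": round(time.perf_counter() - t0, 6)}
        manifest.append(entry)
        logger.info("stage=%s in=%d out=%d params=%s", name, n_in, n_out, params)

    def run_stage(name: str, func):
        t0 = time.perf_counter()
        try:
            return func(t0)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    # 1. length filter ------------------------------------------------------
    def stage_length(t0):
        kept = mining.filter_by_length(seqs, config.length_window)
        dropped_verified = [v for v in verified if v not in kept]
        if dropped_verified:
            logger.warning("verified ids outside the length window, retained: %s",
                           dropped_verified)
            kept = SequenceSet(list(kept) + [seqs[v] for v in dropped_verified])
        write_fasta(kept, os.path.join(out_dir, "01_length_filtered.fasta"))
        record_stage("length_filter", len(seqs), len(kept),
                     {"window": [config.length_window.min_len,
                                 config.length_window.max_len]}, t0)
        return kept

    kept = run_stage("length_filter", stage_length)

    # 2. dereplication ------------------------------------------------------
    def stage_derep(t0):
        clusters = mining.dereplicate(kept, config.identity_threshold_pct, scheme)
        mining.clusters_to_tsv(clusters, os.path.join(out_dir, "02_clusters.tsv"))
        rep_ids = [c.representative_id for c in clusters]
        extra = [v for v in verified if v not in rep_ids]
        reps = SequenceSet([kept[r] for r in rep_ids] + [seqs[v] for v in extra])
        if extra:
            logger.warning("verified ids absorbed into clusters, retained: %s", extra)
        write_fasta(reps, os.path.join(out_dir, "02_representatives.fasta"))
        record_stage("dereplication", len(kept), len(reps),
                     {"identity_threshold_pct": config.identity_threshold_pct}, t0)
        return clusters, reps

    clusters, reps = run_stage("dereplication", stage_derep)

    # 3. conserved-site filter ---------------------------------------------
    def stage_sites(t0):
        reports = [mining.check_conserved_sites(rec, reference_profile, scheme,
                                                config.allowed_misses)
                   for rec in reps]
        mining.site_reports_to_tsv(reports, os.path.join(out_dir, "03_site_reports.tsv"))
        passing = {rep.candidate_id for rep in reports if rep.passed}
        dropped_verified = [v for v in verified if v in reps and v not in passing]
        if dropped_verified:
            logger.warning("verified ids failing the site filter, retained: %s",
                           dropped_verified)
            passing |= set(dropped_verified)
        survivors = reps.subset(passing)
        write_fasta(survivors, os.path.join(out_dir, "03_site_filtered.fasta"))
        record_stage("conserved_sites", len(reps), len(survivors),
                     {"allowed_misses": config.allowed_misses,
                      "n_sites": len(reference_profile.sites)}, t0)
        return reports, survivors

    site_reports, survivors = run_stage("conserved_sites", stage_sites)

    # 4. multiple alignment on the reference -------------------------------
    def stage_msa(t0):
        pool = [r for r in survivors if r.id != reference.id]
        msa_set = SequenceSet([reference] + pool)
        if len(msa_set) < 2:
            raise ValueError("fewer than 2 sequences survive to the alignment stage")
        msa = align.center_star_msa(msa_set, reference.id, scheme)
        msa.to_fasta(os.path.join(out_dir, "04_msa.fasta"))
        record_stage("center_star_msa", len(msa_set), len(msa.ids),
                     {"center": reference.id}, t0)
        return msa

    msa = run_stage("center_star_msa", stage_msa)

    # 5-7. distances, NJ, midpoint root ------------------------------------
    def stage_tree(t0):
        dm = phylo.distance_matrix(msa, config.distance_model)
        dm.to_tsv(os.path.join(out_dir, "05_distances.tsv"))
        unrooted = phylo.nj_tree(dm)
        with open(os.path.join(out_dir, "06_nj_tree.nwk"), "w") as fh:
            fh.write(phylo.write_newick(unrooted) + "\n")
        rooted = phylo.midpoint_root(unrooted)
        asr_mod._label_internal_nodes(rooted)
        with open(os.path.join(out_dir, "07_rooted_tree.nwk"), "w") as fh:
            fh.write(phylo.write_newick(rooted) + "\n")
        record_stage("tree", len(dm.ids), len(rooted.leaves()),
                     {"distance_model": config.distance_model}, t0)
        return rooted

    tree = run_stage("tree", stage_tree)

    # 8. candidate selection ------------------------------------------------
    def stage_select(t0):
        anchors = verified if verified else [reference.id]
        anchors = [a for a in anchors if a in set(tree.leaf_names())]
        available = len(tree.leaves()) - len(anchors)
        n_near = min(config.n_near, available)
        n_spread = min(config.n_spread, available - n_near)
        if available == 0 or (n_near == 0 and n_spread == 0):
            selection = phylo.CandidateSelection()
        else:
            selection = phylo.select_candidates(tree, anchors, n_near, n_spread)
        with open(os.path.join(out_dir, "08_selection.tsv"), "w") as fh:
            fh.write("pick_kind\tleaf_id\tscore\n")
            for leaf, score in selection.near_picks:
                fh.write(f"near\t{leaf}\t{score:.6g}\n")
            for leaf, score in selection.spread_picks:
                fh.write(f"spread\t{leaf}\t{score:.6g}\n")
        record_stage("select_candidates", available, len(selection.ids),
                     {"n_near": n_near, "n_spread": n_spread,
                      "anchors": anchors}, t0)
        return selection

    selection = run_stage("select_candidates", stage_select)

    # 9. terminal diagnosis of the selected candidates ----------------------
    def stage_diagnose(t0):
        diagnoses = [termmod.diagnose_termini(survivors[c], reference, scheme)
                     for c in selection.ids if c in survivors]
        termmod.diagnoses_to_tsv(diagnoses, os.path.join(out_dir, "09_diagnoses.tsv"))
        n_anomalous = sum(1 for d in diagnoses if d.classification != "complete")
        record_stage("diagnose_termini", len(diagnoses), n_anomalous, {}, t0)
        return diagnoses

    diagnoses = run_stage("diagnose_termini", stage_diagnose)

    # 10. optional ancestral reconstruction ---------------------------------
    reconstruction = None
    if config.asr_nodes:
        def stage_asr(t0):
            nodes = [tree.root.name if n == "root" else n for n in config.asr_nodes]
            model = phylo.SubstitutionModel.poisson()
            recon = asr_mod.marginal_asr(tree, msa, model, nodes)
            recon.to_fasta(os.path.join(out_dir, "10_ancestors.fasta"))
            recon.to_tsv(os.path.join(out_dir, "10_posteriors.tsv"))
            record_stage("marginal_asr", len(nodes), len(recon.nodes), {"nodes": nodes}, t0)
            return recon

        reconstruction = run_stage("marginal_asr", stage_asr)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"config": config.to_dict(), "stages": manifest}, fh, indent=2)
        fh.write("\n")
    return PipelineResult(out_dir, manifest, clusters, site_reports, msa, tree,
                          selection, diagnoses, reconstruction)
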