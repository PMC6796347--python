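"""End-to-end orchestration of the NRS discovery pipeline.

Stage order mirrors the discovery workflow: per-assembly extraction,
redundancy clustering, contamination screen, presence matrix with
non-private/major-allele flags, novelty stratification, flank anchoring,
insertion/alternate classification, gene intersection, repeat profiling and
transcription support.  A rerun with the same configuration and inputs is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as nio
from .align import AlignParams, KmerIndex
from .annotate import (
    ReadMapParams,
    RepeatProfile,
    TandemParams,
    repeat_profile,
    tr_association,
    transcription_support,
)
from .classify import NRSCall, classify_call, intersect_genes
from .errors import DegenerateInputError
from .extract import NRSRecord, SIMPLE_REPEAT_CLASSES, extract_assembly_nrs
from .place import AnchorParams, Placement, anchor, extract_flanks, find_n_runs, gap_overlap
from .simulate import Cohort
from .unify import (
    PresenceMatrix,
    build_presence_matrix,
    cluster_redundant,
    novelty_stratify,
    pca_occurrence,
    representatives,
    screen_contamination,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold of the workflow, defaulting to the published rules."""

    min_identity: float = 90.0        # low-identity harvest / subtract-back
    min_seed_len: int = 100           # minimum harvested piece before merging
    merge_gap: int = 200              # adjacent-region merge distance
    min_nrs_len: int = 400            # minimum NRS length
    cluster_identity: float = 0.95    # redundancy clustering -c
    cluster_coverage: float = 0.8     # redundancy clustering -aS (of shorter)
    contamination_identity: float = 90.0
    contamination_coverage: float = 90.0
    presence_identity: float = 95.0
    presence_coverage: float = 80.0
    novelty_identity: float = 80.0
    novelty_coverage: float = 50.0
    flank_len: int = 1000
    min_flank: int = 200
    insertion_slop: int = 20
    alt_max_identity: float = 90.0
    alt_min_ref_span: int = 400
    flank_profile: int = 5000
    rna_min_reads: int = 10
    rna_min_samples: int = 2
    est_min_identity: float = 95.0
    est_max_evalue: float = 1e-5
    align: AlignParams = field(default_factory=AlignParams)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    tandem: TandemParams = field(default_factory=TandemParams)
    reads: ReadMapParams = field(default_factory=ReadMapParams)
    seed: int = 0


@dataclass
class PipelineResult:
    per_assembly_nrs: dict[str, list[NRSRecord]]
    clusters: list
    call_set: list[NRSRecord]          # non-redundant, decontaminated
    removed_contaminants: list[NRSRecord]
    presence: PresenceMatrix
    novelty_no_alignment: list[str]
    placements: dict[str, Placement]
    calls: dict[str, NRSCall]
    gene_hits: list[dict]
    profiles: dict[str, RepeatProfile]
    tr_regression: tuple[float, float, float] | None
    transcription: dict
    pca_coords: pd.DataFrame | None
    summary: dict


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory cohort; optionally write all reports."""
    cfg = config or PipelineConfig()
    params = cfg.align
    reference = cohort.reference.genome
    ref_index = KmerIndex(reference, k=params.k, max_occ=params.max_occ)
    summary: dict = {}

    # 1. per-assembly extraction
    per_assembly: dict[str, list[NRSRecord]] = {}
    for name in cohort.assembly_names:
        records = extract_assembly_nrs(
            cohort.assemblies[name], ref_index, cohort.assembly_tracks[name],
            assembly_name=name, params=params, min_identity=cfg.min_identity,
            min_seed_len=cfg.min_seed_len, merge_gap=cfg.merge_gap,
            min_nrs_len=cfg.min_nrs_len,
        )
        per_assembly[name] = records
        logger.info("extract/%s: %d NRS, %d bp", name, len(records),
                    sum(len(r) for r in records))
    all_records = [r for recs in per_assembly.values() for r in recs]
    summary["nrs_candidates"] = len(all_records)
    summary["nrs_candidate_bp"] = sum(len(r) for r in all_records)

    # 2. redundancy clustering -> unified call set
    if all_records:
        clusters = cluster_redundant(
            all_records, cfg.cluster_identity, cfg.cluster_coverage, params
        )
        unified = representatives(clusters, all_records)
    else:
        clusters, unified = [], []
    summary["clusters"] = len(clusters)

    # 3. contamination screen
    call_set, removed = screen_contamination(
        unified, cohort.decoy_db, cfg.contamination_identity,
        cfg.contamination_coverage, params,
    )
    summary["call_set"] = len(call_set)
    summary["call_set_bp"] = sum(len(r) for r in call_set)
    summary["contaminants_removed"] = len(removed)

    # 4. presence matrix over humans + outgroups
    genomes = {name: cohort.assemblies[name] for name in cohort.assembly_names}
    genomes.update({name: cohort.outgroups[name] for name in cohort.outgroup_names})
    presence = (
        build_presence_matrix(
            call_set, genomes, human_names=cohort.assembly_names,
            min_identity=cfg.presence_identity, min_cov=cfg.presence_coverage,
            params=params,
        )
        if call_set
        else PresenceMatrix(pd.DataFrame(), [])
    )
    if call_set:
        summary["non_private"] = int(presence.non_private.sum())
        summary["major_allele"] = int(presence.major_allele.sum())

    # 5. novelty stratification
    no_aln, residual = (
        novelty_stratify(call_set, ref_index, cfg.novelty_identity,
                         cfg.novelty_coverage, params)
        if call_set
        else ([], [])
    )
    summary["novel_no_alignment"] = len(no_aln)

    # 6. placement; breakends are voted across redundancy-cluster members
    # (the same variant seen in other carriers) so that a private background
    # substitution next to a junction cannot shift the consensus breakpoint
    ref_gaps = find_n_runs(reference, cfg.anchor.min_gap_run)
    by_id = {r.nrs_id: r for recs in per_assembly.values() for r in recs}
    members_of = {c.representative: c.members for c in clusters}
    placements: dict[str, Placement] = {}

    def _place(rec: NRSRecord) -> Placement:
        flanks = extract_flanks(
            rec, cohort.assemblies[rec.source_assembly], cfg.flank_len, cfg.min_flank
        )
        return anchor(rec, flanks, ref_index, ref_gaps, cfg.anchor, params)

    for rec in call_set:
        pl = _place(rec)
        siblings = [m for m in members_of.get(rec.nrs_id, []) if m != rec.nrs_id][:4]
        if pl.status == "precise" and siblings:
            lefts, rights = [pl.left_breakend], [pl.right_breakend]
            for sib_id in siblings:
                sib = by_id.get(sib_id)
                if sib is None:
                    continue
                sp = _place(sib)
                if (
                    sp.status == "precise"
                    and sp.chrom == pl.chrom
                    and abs(sp.left_breakend - pl.left_breakend) <= 50
                    and abs(sp.right_breakend - pl.right_breakend) <= 50
                ):
                    lefts.append(sp.left_breakend)
                    rights.append(sp.right_breakend)
            for attr, votes in (("left_breakend", lefts), ("right_breakend", rights)):
                value, n = Counter(votes).most_common(1)[0]
                if n >= 2:  # ties resolve to the representative (listed first)
                    setattr(pl, attr, value)
            if pl.right_breakend < pl.left_breakend:
                pl.right_breakend = pl.left_breakend
        placements[rec.nrs_id] = pl
    pls = list(placements.values())
    gap_overlap(pls, reference, cfg.anchor)
    for status in ("precise", "unlocalized", "unplaced"):
        summary[f"placed_{status}"] = sum(1 for p in pls if p.status == status)
    summary["in_gap"] = sum(1 for p in pls if p.in_gap)

    # 7. classification + gene intersection
    seq_by_id = {r.nrs_id: r.sequence for r in call_set}
    calls: dict[str, NRSCall] = {}
    for rec in call_set:
        pl = placements[rec.nrs_id]
        if pl.status == "precise":
            calls[rec.nrs_id] = classify_call(
                pl, rec.sequence, reference, cfg.insertion_slop,
                cfg.alt_min_ref_span, cfg.alt_max_identity, params,
            )
    gene_hits = intersect_genes(list(calls.values()), cohort.reference.genes)
    for cls in ("insertion", "alternate", "ambiguous"):
        summary[f"calls_{cls}"] = sum(1 for c in calls.values() if c.call == cls)
    summary["genic_hits"] = len(gene_hits)

    # 8. repeat profiles + TR association
    te_index = KmerIndex(cohort.reference.te_library, k=params.k, max_occ=params.max_occ)
    profiles: dict[str, RepeatProfile] = {}
    for nrs_id, call in calls.items():
        profiles[nrs_id] = repeat_profile(
            call, placements[nrs_id], seq_by_id[nrs_id], reference,
            cohort.reference.repeat_track, te_index, cfg.flank_profile,
            params, cfg.tandem,
        )
    try:
        tr_reg = tr_association(list(profiles.values()))
    except DegenerateInputError:
        tr_reg = None
    if tr_reg:
        summary["tr_association_r2"] = round(tr_reg[2], 4)

    # 9. transcription support
    transcription = transcription_support(
        call_set, cohort.read_samples, cohort.est_db, reference,
        cfg.rna_min_reads, cfg.rna_min_samples, cfg.est_min_identity,
        cfg.est_max_evalue, params, cfg.reads,
    )
    summary["rna_supported"] = sum(1 for t in transcription.values() if t.rna_supported)
    summary["est_supported"] = sum(1 for t in transcription.values() if t.est_supported)
    summary["transcribed"] = sum(1 for t in transcription.values() if t.transcribed)

    # 10. occurrence PCA (descriptive; degenerate matrices are skipped)
    try:
        pca_coords, _ev = pca_occurrence(presence) if call_set else (None, None)
    except DegenerateInputError:
        pca_coords = None

    result = PipelineResult(
        per_assembly_nrs=per_assembly, clusters=clusters, call_set=call_set,
        removed_contaminants=removed, presence=presence,
        novelty_no_alignment=[r.nrs_id for r in no_aln], placements=placements,
        calls=calls, gene_hits=gene_hits, profiles=profiles,
        tr_regression=tr_reg, transcription=transcription,
        pca_coords=pca_coords, summary=summary,
    )
    if outdir is not None:
        write_outputs(result, cohort, Path(outdir))
    return result


def write_outputs(result: PipelineResult, cohort: Cohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    nio.write_nrs_fasta(outdir / "call_set.fasta", result.call_set)
    pd.DataFrame(
        [
            {"member": m, "representative": c.representative}
            for c in result.clusters
            for m in c.members
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    if len(result.presence.table):
        result.presence.to_frame().to_csv(outdir / "presence_matrix.tsv", sep="\t")
    nio.write_placements_bed(outdir / "placements.bed", list(result.placements.values()))
    nio.calls_to_frame(list(result.calls.values())).to_csv(
        outdir / "calls.tsv", sep="\t", index=False
    )
    seqs = {r.nrs_id: r.sequence for r in result.call_set}
    nio.write_calls_vcf(
        outdir / "calls.vcf", list(result.calls.values()), seqs, cohort.reference.genome
    )
    pd.DataFrame(
        [
            {
                "nrs_id": p.nrs_id,
                "te_fraction_internal": p.te_fraction_internal,
                "tr_fraction_internal": p.tr_fraction_internal,
                "te_fraction_flank": p.te_fraction_flank,
                "tr_fraction_flank": p.tr_fraction_flank,
                "ref_tr_fraction": p.ref_tr_fraction,
            }
            for p in result.profiles.values()
        ]
    ).to_csv(outdir / "repeat_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "nrs_id": t.nrs_id,
                "rna_supported": t.rna_supported,
                "supporting_samples": t.supporting_samples,
                "est_supported": t.est_supported,
                "transcribed": t.transcribed,
                **{f"count_{s}": c for s, c in sorted(t.read_counts.items())},
                **{f"cpm_{s}": round(c, 3) for s, c in sorted(t.cpm.items())},
            }
            for t in result.transcription.values()
        ]
    ).to_csv(outdir / "transcription.tsv", sep="\t", index=False)
    if result.pca_coords is not None:
        result.pca_coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    gh = pd.DataFrame(result.gene_hits)
    gh.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
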