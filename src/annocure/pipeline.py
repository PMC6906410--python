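"""End-to-end orchestration: screens -> classification -> curation ->
orthology, phylostratigraphy and completeness, with a run manifest.

The manifest records every count with its denominator so each reported
percentage can be recomputed, and a config snapshot sufficient to re-run
the pipeline deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass

from . import classify as acl
from . import curation as cur
from . import homology as hom
from . import screens as scr
from .classify import percentage
from .completeness import assembly_stats, completeness_report
from .io import GeneModel, Hit, TranscriptEvidence, reduce_transcriptome
from .phylo import (assign_phylostrata, compare_catalogs, detect_inparalogs,
                    mcl_orthology)
from .simulate import ScenarioBundle


@dataclass
class PipelineConfig:
    evalue_threshold: float = 1e-5
    weak_band_upper: float = 1e-3
    phylo_evalue: float = 1e-3
    dedupe_rule: str = "shared_transcript"
    min_cds_overlap: int = 30
    min_residual_aa: int = 20
    min_peptide_len: int = 60
    inflation: float = 1.5
    complete_cov: float = 0.7
    frag_cov: float = 0.1


@dataclass
class PipelineResult:
    manifest: dict
    loci: list[scr.Locus]
    classifications: dict[str, acl.LocusClassification]
    corrections: list[cur.CorrectionRecord]
    curated_annotation: dict[str, GeneModel]
    change_log: list[dict]
    brh_before: set[tuple[str, str]]
    brh_after: set[tuple[str, str]]
    catalog_report: dict
    phylostrata: dict[str, str]
    completeness_before: dict
    completeness_after: dict


def report_percentages(count_table: dict[str, tuple[int, int]]) -> dict[str, int | None]:
    """Integer-rounded (half-up) percentages for (numerator, denominator)
    pairs; zero denominators yield None rather than an error."""
    return {name: percentage(num, den) for name, (num, den) in count_table.items()}


def _filtered(hits: list[Hit], threshold: float) -> list[Hit]:
    return [h for h in hits if h.e_value < threshold]


def _best_evalue(hits: list[Hit]) -> dict[str, float]:
    best: dict[str, float] = {}
    for h in hits:
        best[h.query_id] = min(best.get(h.query_id, math.inf), h.e_value)
    return best


def _with_query_coverage(hits: list[Hit], lengths: dict[str, int]) -> list[Hit]:
    out = []
    for h in hits:
        if h.query_id in lengths:
            cov = min(1.0, (abs(h.qend - h.qstart) + 1) / lengths[h.query_id])
            out.append(dataclasses.replace(h, query_coverage=cov))
        else:
            out.append(h)
    return out


def _brh(fwd: list[Hit], rev: list[Hit],
         direction: tuple[str, str]) -> set[tuple[str, str]]:
    return hom.reciprocal_best_hits(
        hom.best_hits(fwd, direction),
        hom.best_hits(rev, direction[::-1]))


def run_pipeline(bundle: ScenarioBundle,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Audit and curate the bundle's draft annotation against its evidence.

    Stages: transcriptome redundancy reduction; screen 1 (missing homologs)
    and screen 2 (hidden orthologs / BRH loss); locus deduplication and
    classification; correction proposal and application; BRH + MCL orthology
    catalogs before/after; phylostratigraphy; completeness proxy.
    """
    cfg = config or PipelineConfig()
    thr = cfg.evalue_threshold
    tables = bundle.hit_tables

    reps = reduce_transcriptome(bundle.transcripts, cfg.min_peptide_len)
    reps_by_id = {t.transcript_id: t for t in reps}
    rep_ids = set(reps_by_id)

    def trans_only(hits: list[Hit]) -> list[Hit]:
        return [h for h in hits if h.subject_id in rep_ids]

    ra = _filtered(tables["ref_vs_annotation"], thr)
    ar = _filtered(tables["annotation_vs_ref"], thr)
    rt = trans_only(_filtered(tables["ref_vs_transcriptome"], thr))
    tr = [h for h in _filtered(tables["transcriptome_vs_ref"], thr)
          if h.query_id in rep_ids]

    # screen 1: homolog in transcriptome but not annotation
    partition = scr.screen_missing_homologs(ra, rt)
    screen1 = partition["transcriptome_only"]
    e_anno = _best_evalue(_filtered(tables["ref_vs_annotation"], cfg.weak_band_upper))
    e_trans = _best_evalue(trans_only(
        _filtered(tables["ref_vs_transcriptome"], cfg.weak_band_upper)))
    weak = {g: scr.flag_weak_similarity(e_anno.get(g, math.inf),
                                        e_trans.get(g, math.inf),
                                        thr, cfg.weak_band_upper)
            for g in screen1}

    # screen 2: BRH ortholog in transcriptome but not annotation
    brh_anno = _brh(ra, ar, ("ref", "anno"))
    brh_trans = _brh(rt, tr, ("ref", "trans"))
    screen2 = scr.screen_hidden_orthologs(brh_trans, brh_anno, screen1)

    results = (scr.make_screen_results(screen1, scr.MISSING_HOMOLOG, rt,
                                       reps_by_id, weak)
               + scr.make_screen_results(screen2, scr.HIDDEN_ORTHOLOG, rt,
                                         reps_by_id))
    loci = scr.dedupe_loci(results, cfg.dedupe_rule)

    tva = _filtered(tables.get("transcriptome_vs_annotation", []), thr)
    classifications, counts = acl.classify_batch(
        loci, bundle.corrupted_annotation, reps_by_id, tva, cfg.min_cds_overlap)

    conservation = _best_evalue(tr)
    corrections = _propose_corrections(
        loci, classifications, bundle.corrupted_annotation, reps,
        bundle.annotation_proteins, conservation, cfg)
    curated, change_log = cur.apply_corrections(bundle.corrupted_annotation,
                                                corrections)

    # orthology catalogs on the curated annotation: hits against surviving
    # old models plus transcript hits renamed to their final gene ids
    replaced_old = {rec.old_gene_id for rec in corrections
                    if rec.old_gene_id is not None}
    surviving = set(curated) - replaced_old  # untouched old models
    tid_to_final: dict[str, str] = {}
    for rec in corrections:
        assignee = rec.inherited_id_assignee
        for m in rec.new_models:
            tid_to_final[m.gene_id] = (rec.old_gene_id
                                       if rec.old_gene_id is not None
                                       and m.gene_id == assignee else m.gene_id)
    ra_after = [h for h in ra if h.subject_id in surviving]
    ar_after = [h for h in ar if h.query_id in surviving]
    for h in trans_only(_filtered(tables["ref_vs_transcriptome"], thr)):
        fid = tid_to_final.get(h.subject_id)
        if fid is not None:
            ra_after.append(dataclasses.replace(h, subject_id=fid))
    for h in tr:
        fid = tid_to_final.get(h.query_id)
        if fid is not None:
            ar_after.append(dataclasses.replace(h, query_id=fid))
    brh_after = _brh(ra_after, ar_after, ("ref", "anno"))

    within = _filtered(tables.get("ref_vs_ref", []), thr)
    cross_best = {q: bh.bitscore
                  for q, bh in hom.best_hits(ra_after, ("ref", "anno")).mapping.items()}
    inparalogs = detect_inparalogs(within, cross_best)
    species_of = {r: "reference" for r in bundle.ref_proteome}
    species_of.update({g: "target" for g in curated})
    edges = [(h.query_id, h.subject_id, h.bitscore)
             for h in ra_after if h.subject_id in species_of]
    edges += [(a, b, h.bitscore) for h in within
              for a, b in [(h.query_id, h.subject_id)] if a != b]
    clusters = mcl_orthology(edges, species_of, ("reference", "target"),
                             inflation=cfg.inflation)
    catalog_report = compare_catalogs(brh_after, clusters,
                                      ("reference", "target"), inparalogs)

    strata_tables = {name.removeprefix("ref_vs_outgroup_"):
                     _filtered(hits, cfg.phylo_evalue)
                     for name, hits in tables.items()
                     if name.startswith("ref_vs_outgroup_")}
    phylostrata = assign_phylostrata(sorted(bundle.ref_proteome), bundle.ladder,
                                     strata_tables)

    marker_ids = sorted(bundle.truth.ortholog_map)
    ref_lengths = {r: len(s) for r, s in bundle.ref_proteome.items()}
    comp_before = completeness_report(
        marker_ids, _with_query_coverage(ra, ref_lengths),
        cfg.complete_cov, cfg.frag_cov)
    comp_after = completeness_report(
        marker_ids, _with_query_coverage(ra_after, ref_lengths),
        cfg.complete_cov, cfg.frag_cov)
    stats = assembly_stats(bundle.genome)

    n_loci = len(loci)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "scenario_config": dataclasses.asdict(bundle.config),
        "screen1": {k: len(v) for k, v in partition.items()},
        "n_screen1_candidates": len(screen1),
        "n_screen2_candidates": len(screen2),
        "n_loci": n_loci,
        "category_counts": counts,
        "category_percentages": report_percentages(
            {label: (k, n_loci) for label, k in counts.items()}),
        "n_corrections": len(corrections),
        "n_replaced": sum(1 for c in corrections if c.old_gene_id),
        "n_new_models": sum(len(c.new_models) for c in corrections),
        "n_residual_segments": sum(len(c.residual_segments) for c in corrections),
        "gene_count_before": len(bundle.corrupted_annotation),
        "gene_count_after": len(curated),
        "n_brh_before": len(brh_anno),
        "n_brh_after": len(brh_after),
        "catalog_report": catalog_report,
        "phylostratum_counts": {
            lab: sum(1 for s in phylostrata.values() if s == lab)
            for lab in bundle.ladder.labels},
        "completeness_before": comp_before.as_dict(),
        "completeness_after": comp_after.as_dict(),
        "assembly_stats": dataclasses.asdict(stats),
    }
    return PipelineResult(manifest, loci, classifications, corrections,
                          curated, change_log, brh_anno, brh_after,
                          catalog_report, phylostrata,
                          comp_before.as_dict(), comp_after.as_dict())


def _propose_corrections(loci, classifications, annotation,
                         representatives: list[TranscriptEvidence],
                         annotation_proteins: dict[str, str],
                         conservation: dict[str, float],
                         cfg: PipelineConfig) -> list[cur.CorrectionRecord]:
    records_by_old: dict[str, list[cur.CorrectionRecord]] = {}
    additions: list[cur.CorrectionRecord] = []
    for locus in loci:
        cls = classifications[locus.locus_id]
        if cls.label in ("weak_similarity", "inconclusive"):
            continue
        t_id = locus.transcript_ids[0]
        t = next(t for t in representatives if t.transcript_id == t_id)
        if cls.label == "missing_gene":
            additions.append(cur.CorrectionRecord(
                f"add:{t.transcript_id}", None,
                [cur.model_from_transcript(t)],
                provenance=[t.evidence_class], category=cls.label))
            continue
        old_id = _replacement_target(cls, annotation, t)
        if old_id is None:
            continue
        old = annotation[old_id]
        candidates = [c for c in representatives
                      if c.scaffold == old.scaffold and c.strand == old.strand
                      and c.span[0] < old.span[1] and c.span[1] > old.span[0]]
        rec = cur.propose_replacement(old, candidates,
                                      annotation_proteins.get(old_id),
                                      cfg.min_residual_aa)
        rec.category = cls.label
        rec.inherited_id_assignee = cur.assign_inherited_id(
            old, rec.new_models, conservation)
        records_by_old.setdefault(old_id, []).append(rec)

    corrections: list[cur.CorrectionRecord] = []
    used: set[str] = set()
    for old_id in sorted(records_by_old):
        rec = cur.resolve_redundant_curations(records_by_old[old_id])
        corrections.append(rec)
        used.update(m.gene_id for m in rec.new_models)
    for rec in additions:
        if any(m.gene_id in used for m in rec.new_models):
            continue
        used.update(m.gene_id for m in rec.new_models)
        corrections.append(rec)
    return corrections


def _replacement_target(cls: acl.LocusClassification,
                        annotation: dict[str, GeneModel],
                        t: TranscriptEvidence) -> str | None:
    best_id, best_nt = None, -1
    for gid in cls.overlapped_genes:
        g = annotation.get(gid)
        if g is None:
            continue
        nt = cur._overlap_nt([*g.cds_exons,
                              *[(s, e) for s, e, _ in g.utr_exons]], t.exons)
        if nt > best_nt or (nt == best_nt and (best_id is None or gid < best_id)):
            best_id, best_nt = gid, nt
    return best_id


def write_manifest(result: PipelineResult, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Ground-truth evaluation (synthetic scenarios only)
# ---------------------------------------------------------------------------

def evaluate_recovery(bundle: ScenarioBundle, result: PipelineResult) -> dict:
    """Score screens/classifications/curation against the injected truth.

    An injected error locus counts as recovered when a candidate locus
    supported by the affected gene's transcript was classified with the
    matching label (fusions: at least one of the two parent transcripts,
    since the fused model necessarily retains a BRH with one parent).
    """
    truth = bundle.truth
    label_by_tid = {}
    for locus in result.loci:
        cls = result.classifications[locus.locus_id]
        for tid in locus.transcript_ids:
            label_by_tid[tid] = cls.label

    expected: list[tuple[set[str], str]] = []
    for g, c in truth.error_class.items():
        if c == "deleted":
            expected.append(({f"t_{g}"}, "missing_gene"))
        elif c.startswith("utr_hidden_in:"):
            expected.append(({f"t_{g}"}, "utr"))
        elif c == "frame_corrupted":
            expected.append(({f"t_{g}"}, "misannotation"))
    for fid, (a, b) in truth.fused_models.items():
        expected.append(({f"t_{a}", f"t_{b}"}, "gene_fusion"))

    recovered = misclassified = 0
    for tids, label in expected:
        found = [label_by_tid[t] for t in tids if t in label_by_tid]
        if label in found:
            recovered += 1
        elif found:
            misclassified += 1
    expected_tids = {t for tids, _ in expected for t in tids}
    false_loci = [t for t in label_by_tid if t not in expected_tids]
    n_exp = len(expected)
    return {
        "n_expected_loci": n_exp,
        "n_recovered": recovered,
        "n_misclassified": misclassified,
        "n_false_positive_loci": len(false_loci),
        "sensitivity": recovered / n_exp if n_exp else 1.0,
        "precision": (recovered / (recovered + misclassified + len(false_loci))
                      if (recovered + misclassified + len(false_loci)) else 1.0),
        "gene_count_after": len(result.curated_annotation),
        "truth_gene_count": len(bundle.truth_annotation),
    }
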