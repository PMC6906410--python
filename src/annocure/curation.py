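"""Turn locus classifications into gene-model corrections and apply them.

A correction either adds new gene models at a previously unannotated locus
or replaces one old model by one or more transcript-derived models.  The
guiding objective is to lose as little annotated coding sequence as
possible: replacement picks the set of mutually compatible evidence
transcripts that covers the most of the old model's CDS, and any uncovered
stretch above a minimum length is emitted as a residual protein segment
under a pseudo-identifier, for later re-alignment.  When one old model is
replaced by several new ones, exactly one new model inherits the old
identifier so the annotation database can track gene history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import GeneModel, Interval, TranscriptEvidence

DEFAULT_PROVENANCE_WEIGHTS = {"isoseq": 3.0, "rnaseq_assembly": 2.0,
                              "legacy_prediction": 1.0}


@dataclass
class CorrectionRecord:
    record_id: str
    old_gene_id: str | None
    new_models: list[GeneModel]
    inherited_id_assignee: str | None = None
    residual_segments: list[tuple[str, str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    category: str = ""


def _intersect(ivs_a: list[Interval], ivs_b: list[Interval]) -> list[Interval]:
    out = []
    for s1, e1 in ivs_a:
        for s2, e2 in ivs_b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return sorted(out)


def _subtract(ivs: list[Interval], minus: list[Interval]) -> list[Interval]:
    out = []
    minus = sorted(minus)
    for s, e in sorted(ivs):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _overlap_nt(ivs_a: list[Interval], ivs_b: list[Interval]) -> int:
    return sum(e - s for s, e in _intersect(ivs_a, ivs_b))


def model_from_transcript(t: TranscriptEvidence) -> GeneModel:
    """Promote an evidence transcript to a gene model (exons become CDS)."""
    return GeneModel(t.transcript_id, t.scaffold, t.strand,
                     list(t.exons), source="transcript_evidence")


def _cds_offsets(model: GeneModel) -> list[tuple[Interval, int]]:
    """(genomic interval, CDS-coordinate offset of its first base) pairs,
    in translation order (strand-aware)."""
    exons = model.cds_exons if model.strand == "+" else model.cds_exons[::-1]
    out, off = [], 0
    for s, e in exons:
        out.append(((s, e), off))
        off += e - s
    return out


def _genomic_to_aa_ranges(model: GeneModel, uncovered: list[Interval]) -> list[tuple[int, int]]:
    """Map uncovered genomic CDS intervals to amino-acid ranges of the old
    protein, merging stretches that are contiguous in CDS coordinates."""
    nt_ranges = []
    for (gs, ge), off in _cds_offsets(model):
        for us, ue in uncovered:
            s, e = max(gs, us), min(ge, ue)
            if s >= e:
                continue
            if model.strand == "+":
                nt_ranges.append((off + s - gs, off + e - gs))
            else:
                nt_ranges.append((off + ge - e, off + ge - s))
    nt_ranges.sort()
    merged: list[list[int]] = []
    for s, e in nt_ranges:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s // 3, -(-e // 3)) for s, e in merged]


def propose_replacement(old: GeneModel, candidates: list[TranscriptEvidence],
                        old_protein: str | None = None,
                        min_residual_aa: int = 20) -> CorrectionRecord:
    """Select mutually compatible candidate transcripts maximizing coverage
    of the old model's CDS (greedy by coverage; ties by longer CDS, then
    lexicographic id) and emit uncovered stretches >= ``min_residual_aa`` as
    residual segments with pseudo-identifiers.

    Zero-coverage candidates overlapping the old model's span (e.g. genes
    hidden in its UTR) are kept as additional new models when they do not
    conflict with the selected set.
    """
    span = old.span
    overlapping = [t for t in candidates
                   if t.scaffold == old.scaffold and t.strand == old.strand
                   and t.span[0] < span[1] and t.span[1] > span[0]]
    if not overlapping:
        raise ValueError(f"no candidate transcript overlaps {old.gene_id}")
    scored = sorted(
        overlapping,
        key=lambda t: (-_overlap_nt(old.cds_exons, t.exons),
                       -sum(e - s for s, e in t.exons), t.transcript_id))
    chosen: list[TranscriptEvidence] = []
    for t in scored:
        if all(_overlap_nt(t.exons, c.exons) == 0 for c in chosen):
            chosen.append(t)
    chosen.sort(key=lambda t: t.span)
    covered = [iv for t in chosen for iv in _intersect(old.cds_exons, t.exons)]
    uncovered = _subtract(old.cds_exons, covered)
    residuals = []
    for i, (aa_s, aa_e) in enumerate(_genomic_to_aa_ranges(old, uncovered), start=1):
        if aa_e - aa_s < min_residual_aa:
            continue
        seq = old_protein[aa_s:aa_e] if old_protein else ""
        residuals.append((f"{old.gene_id}_res{i}", seq))
    return CorrectionRecord(
        record_id=f"replace:{old.gene_id}",
        old_gene_id=old.gene_id,
        new_models=[model_from_transcript(t) for t in chosen],
        residual_segments=residuals,
        provenance=sorted({t.evidence_class for t in chosen}))


def assign_inherited_id(old: GeneModel, new_models: list[GeneModel],
                        conservation_scores: dict[str, float] | None = None) -> str:
    """Pick the new model inheriting the old identifier: the most conserved
    one (lowest e-value against the reference) when scores are available,
    otherwise the one with the longest CDS; ties broken by id."""
    if not new_models:
        raise ValueError("no new models to assign the inherited id to")
    if conservation_scores and any(m.gene_id in conservation_scores for m in new_models):
        best = min(new_models,
                   key=lambda m: (conservation_scores.get(m.gene_id, float("inf")),
                                  -m.cds_length, m.gene_id))
    else:
        best = min(new_models, key=lambda m: (-m.cds_length, m.gene_id))
    return best.gene_id


def _experience(rec: CorrectionRecord,
                weights: dict[str, float]) -> float:
    return max((weights.get(p, 0.0) for p in rec.provenance), default=0.0)


def resolve_redundant_curations(records: list[CorrectionRecord],
                                provenance_weights: dict[str, float] | None = None
                                ) -> CorrectionRecord:
    """Pick one of several curations of the same locus, preferring (in
    order) more new models, higher provenance weight (the stand-in for
    curator experience), transcriptional evidence over legacy predictions,
    and finally deterministic record id order."""
    if not records:
        raise ValueError("no curation records to resolve")
    olds = {r.old_gene_id for r in records}
    if len(olds) > 1:
        raise ValueError(f"records target different genes: {sorted(map(str, olds))}")
    w = provenance_weights or DEFAULT_PROVENANCE_WEIGHTS

    def transcriptional(rec: CorrectionRecord) -> int:
        return int(any(p in ("rnaseq_assembly", "isoseq") for p in rec.provenance))

    return min(records, key=lambda r: (-len(r.new_models), -_experience(r, w),
                                       -transcriptional(r), r.record_id))


def apply_corrections(annotation: dict[str, GeneModel],
                      corrections: list[CorrectionRecord]
                      ) -> tuple[dict[str, GeneModel], list[dict]]:
    """Apply corrections, producing the updated annotation and a change log.

    Old models are removed, new models inserted; the designated assignee of
    each replacement is renamed to the old identifier.  The resulting gene
    count is old count - replaced + added."""
    new_annotation = dict(annotation)
    change_log: list[dict] = []
    deleted: set[str] = set()
    for rec in sorted(corrections, key=lambda r: r.record_id):
        if rec.old_gene_id is not None:
            if rec.old_gene_id not in annotation:
                raise KeyError(f"correction {rec.record_id} targets missing gene "
                               f"{rec.old_gene_id}")
            if rec.old_gene_id in deleted:
                raise ValueError(f"gene {rec.old_gene_id} deleted by two corrections")
            deleted.add(rec.old_gene_id)
            del new_annotation[rec.old_gene_id]
        assignee = rec.inherited_id_assignee
        if rec.old_gene_id is not None and assignee is None and rec.new_models:
            assignee = assign_inherited_id(annotation[rec.old_gene_id], rec.new_models)
        inserted_ids = []
        for m in rec.new_models:
            new_id = rec.old_gene_id if (assignee is not None
                                         and m.gene_id == assignee) else m.gene_id
            if new_id in new_annotation:
                raise ValueError(f"duplicate gene id {new_id} while applying "
                                 f"{rec.record_id}")
            new_annotation[new_id] = replace(m, gene_id=new_id)
            inserted_ids.append(new_id)
        change_log.append({
            "old_id": rec.old_gene_id or "",
            "new_ids": ",".join(inserted_ids),
            "assignee": rec.old_gene_id if assignee is not None else "",
            "category": rec.category,
            "n_residuals": len(rec.residual_segments),
        })
    return new_annotation, change_log


def cds_coverage_nt(reference: dict[str, GeneModel],
                    annotation: dict[str, GeneModel]) -> int:
    """Total reference-CDS nucleotides covered by same-strand annotation CDS."""
    by_key: dict[tuple[str, str], list[Interval]] = {}
    for g in annotation.values():
        by_key.setdefault((g.scaffold, g.strand), []).extend(g.cds_exons)
    total = 0
    for g in reference.values():
        total += _overlap_nt(g.cds_exons, by_key.get((g.scaffold, g.strand), []))
    return total
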