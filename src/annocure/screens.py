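"""Genome-wide screens for missing homologs and hidden orthologs.

Screen 1 partitions reference genes by where their homology evidence lives:
in the draft annotation, in the transcriptome assembly, or both.  Genes with
transcriptome-only evidence are candidate missing genes.  Screen 2 looks for
reference genes whose one-to-one orthology (best-reciprocal hit) is
detectable against the transcriptome but not against the annotation —
typically genes buried inside artificially fused models.  Candidates are
then collapsed to non-redundant genomic loci for curation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import Hit, Interval, TranscriptEvidence

MISSING_HOMOLOG = "missing_homolog"
HIDDEN_ORTHOLOG = "hidden_ortholog"


@dataclass
class ScreenResult:
    """One flagged reference gene with its supporting transcript locus."""

    screen: str
    reference_gene_id: str
    matched_transcript_id: str
    matched_evidence: str
    scaffold: str
    strand: str
    interval: Interval
    weak_similarity: bool = False


@dataclass
class Locus:
    """A non-redundant genomic locus aggregating one or more candidates."""

    locus_id: str
    scaffold: str
    strand: str
    interval: Interval
    transcript_ids: list[str]
    members: list[ScreenResult] = field(default_factory=list)

    @property
    def weak_similarity(self) -> bool:
        return all(m.weak_similarity for m in self.members) and bool(self.members)


def screen_missing_homologs(ref_vs_annotation: list[Hit],
                            ref_vs_transcriptome: list[Hit]) -> dict[str, set[str]]:
    """Partition reference genes by the location of their homology evidence.

    Both hit lists must be filtered at the same e-value threshold.  Returns
    disjoint sets ``both``, ``annotation_only`` and ``transcriptome_only``
    covering every reference gene with at least one hit in either search;
    ``transcriptome_only`` genes are the missing-gene candidates.
    """
    in_anno = {h.query_id for h in ref_vs_annotation}
    in_trans = {h.query_id for h in ref_vs_transcriptome}
    return {
        "both": in_anno & in_trans,
        "annotation_only": in_anno - in_trans,
        "transcriptome_only": in_trans - in_anno,
    }


def screen_hidden_orthologs(brh_ref_transcriptome: set[tuple[str, str]],
                            brh_ref_annotation: set[tuple[str, str]],
                            screen1_candidates: set[str]) -> set[str]:
    """Reference genes with a BRH ortholog in the transcriptome but not in
    the annotation, excluding genes already flagged by the first screen."""
    with_trans = {a for a, _ in brh_ref_transcriptome}
    with_anno = {a for a, _ in brh_ref_annotation}
    return with_trans - with_anno - set(screen1_candidates)


def flag_weak_similarity(evalue_annotation: float, evalue_transcriptome: float,
                         threshold: float = 1e-5, band_upper: float = 1e-3) -> bool:
    """True when one search is just below the e-value threshold and the other
    just above it (within ``[threshold, band_upper)``) — borderline cases for
    which no correction should be proposed.  Absent hits are coded +inf."""
    a, t = evalue_annotation, evalue_transcriptome

    def below(e: float) -> bool:
        return e < threshold

    def in_band(e: float) -> bool:
        return threshold <= e < band_upper and not math.isinf(e)

    return (below(a) and in_band(t)) or (below(t) and in_band(a))


def _merge_interval(a: Interval, b: Interval) -> Interval:
    return (min(a[0], b[0]), max(a[1], b[1]))


def dedupe_loci(candidates: list[ScreenResult],
                rule: str = "shared_transcript") -> list[Locus]:
    """Collapse candidates to non-redundant loci.

    rule="shared_transcript": candidates matching the same transcript share a
    locus.  rule="overlap": candidates whose transcript alignments overlap by
    at least 1 bp on the same scaffold and strand are merged transitively
    (connected components of the overlap graph).  The result is independent
    of input order.
    """
    if rule not in ("shared_transcript", "overlap"):
        raise ValueError(f"unknown dedupe rule {rule!r}")
    cands = sorted(candidates,
                   key=lambda c: (c.scaffold, c.strand, c.interval, c.reference_gene_id))
    groups: list[list[ScreenResult]] = []
    if rule == "shared_transcript":
        by_tid: dict[str, list[ScreenResult]] = {}
        for c in cands:
            by_tid.setdefault(c.matched_transcript_id, []).append(c)
        groups = [by_tid[t] for t in sorted(by_tid)]
    else:
        # sweep-line union of overlapping same-scaffold/strand intervals
        open_group: list[ScreenResult] | None = None
        span: Interval | None = None
        key = None
        for c in cands:
            ckey = (c.scaffold, c.strand)
            if (open_group is not None and ckey == key
                    and c.interval[0] < span[1]):
                open_group.append(c)
                span = _merge_interval(span, c.interval)
            else:
                if open_group:
                    groups.append(open_group)
                open_group, span, key = [c], c.interval, ckey
        if open_group:
            groups.append(open_group)
    loci = []
    for i, members in enumerate(groups):
        span = members[0].interval
        for m in members[1:]:
            span = _merge_interval(span, m.interval)
        tids = sorted({m.matched_transcript_id for m in members})
        loci.append(Locus(f"locus_{i:05d}", members[0].scaffold, members[0].strand,
                          span, tids, members))
    return loci


def make_screen_results(candidate_genes: set[str], screen: str,
                        hits_ref_vs_transcriptome: list[Hit],
                        transcripts: dict[str, TranscriptEvidence],
                        weak_flags: dict[str, bool] | None = None) -> list[ScreenResult]:
    """Attach the best-matching transcript and its genomic locus to each
    candidate reference gene, producing curation-ready records."""
    weak_flags = weak_flags or {}
    best: dict[str, Hit] = {}
    for h in sorted(hits_ref_vs_transcriptome,
                    key=lambda h: (h.query_id, -h.bitscore, h.e_value, h.subject_id)):
        best.setdefault(h.query_id, h)
    out = []
    for g in sorted(candidate_genes):
        h = best.get(g)
        if h is None or h.subject_id not in transcripts:
            continue
        t = transcripts[h.subject_id]
        out.append(ScreenResult(
            screen, g, t.transcript_id,
            f"bits={h.bitscore:g},e={h.e_value:g}",
            t.scaffold, t.strand, t.span, bool(weak_flags.get(g, False))))
    return out
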