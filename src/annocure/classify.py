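"""Automated application of the curators' per-locus decision rules.

Each candidate locus — the genomic alignment of an evidence transcript — is
compared with the draft annotation and classified with a fixed-order
decision tree:

0. borderline homology evidence                        -> weak_similarity
1. no same-strand exon overlap with any gene model     -> missing_gene
2. overlap confined to UTR-class exons                 -> utr
3. CDS-exon overlap and the transcript's ORF has a
   filtered BLAST hit to the overlapped gene's protein -> gene_fusion
4. CDS-exon overlap without such a hit                 -> misannotation
5. anything else                                       -> inconclusive

Antisense-only overlap counts as no overlap.  A "minimal" CDS overlap
(default < 30 nt) without a hit also falls into misannotation, mirroring
curator practice for models clipped by a few codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from intervaltree import IntervalTree

from .io import GeneModel, Hit, TranscriptEvidence
from .screens import Locus

LABELS = ("utr", "missing_gene", "gene_fusion", "misannotation",
          "weak_similarity", "inconclusive")


@dataclass
class LocusClassification:
    locus_id: str
    label: str
    overlapped_genes: list[str] = field(default_factory=list)
    overlapped_exon_classes: list[str] = field(default_factory=list)
    cds_overlap_nt: int = 0
    has_hit_to_overlapped: bool = False
    note: str = ""


class _AnnotationIndex:
    """Interval lookup of CDS/UTR exons per (scaffold, strand)."""

    def __init__(self, annotation: dict[str, GeneModel]):
        self.scaffolds = {g.scaffold for g in annotation.values()}
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for g in annotation.values():
            tree = self.trees.setdefault((g.scaffold, g.strand), IntervalTree())
            for s, e in g.cds_exons:
                tree.addi(s, e, (g.gene_id, "cds"))
            for s, e, _kind in g.utr_exons:
                tree.addi(s, e, (g.gene_id, "utr"))

    def overlaps(self, scaffold: str, strand: str, exons) -> list[tuple[str, str, int]]:
        """(gene_id, exon_class, overlap_nt) for every overlapped exon."""
        tree = self.trees.get((scaffold, strand))
        if tree is None:
            return []
        found = []
        for s, e in exons:
            for iv in tree.overlap(s, e):
                found.append((iv.data[0], iv.data[1],
                              min(e, iv.end) - max(s, iv.begin)))
        return found


def classify_locus(transcript: TranscriptEvidence,
                   annotation: dict[str, GeneModel],
                   hits_transcript_vs_annotation: list[Hit],
                   weak_flag: bool = False,
                   min_cds_overlap: int = 30,
                   index: _AnnotationIndex | None = None) -> LocusClassification:
    """Classify one candidate locus with the fixed-order decision tree."""
    index = index or _AnnotationIndex(annotation)
    if annotation and transcript.scaffold not in index.scaffolds:
        raise ValueError(
            f"transcript {transcript.transcript_id} on unknown scaffold "
            f"{transcript.scaffold!r}")
    cls = LocusClassification(transcript.transcript_id, "inconclusive")
    if weak_flag:
        cls.label = "weak_similarity"
        return cls

    overlaps = index.overlaps(transcript.scaffold, transcript.strand, transcript.exons)
    if not overlaps:
        antis = index.overlaps(transcript.scaffold,
                               "-" if transcript.strand == "+" else "+",
                               transcript.exons)
        cls.label = "missing_gene"
        if antis:
            cls.note = "antisense-only overlap treated as no overlap"
        return cls

    cls.overlapped_genes = sorted({g for g, _c, _n in overlaps})
    cls.overlapped_exon_classes = sorted({c for _g, c, _n in overlaps})
    cds_nt: dict[str, int] = {}
    for g, c, n in overlaps:
        if c == "cds":
            cds_nt[g] = cds_nt.get(g, 0) + n
    cls.cds_overlap_nt = sum(cds_nt.values())

    if not cds_nt:
        cls.label = "utr"
        return cls

    hit_subjects = {h.subject_id for h in hits_transcript_vs_annotation
                    if h.query_id == transcript.transcript_id}
    cls.has_hit_to_overlapped = any(g in hit_subjects for g in cds_nt)
    if cls.has_hit_to_overlapped and cls.cds_overlap_nt >= min_cds_overlap:
        cls.label = "gene_fusion"
    else:
        cls.label = "misannotation"
    return cls


def classify_batch(loci: list[Locus], annotation: dict[str, GeneModel],
                   transcripts: dict[str, TranscriptEvidence],
                   hits_transcript_vs_annotation: list[Hit],
                   min_cds_overlap: int = 30
                   ) -> tuple[dict[str, LocusClassification], dict[str, int]]:
    """Classify every locus (via its first supporting transcript) and tally
    per-category counts.  Returns (classifications by locus id, counts)."""
    index = _AnnotationIndex(annotation)
    results: dict[str, LocusClassification] = {}
    counts = dict.fromkeys(LABELS, 0)
    for locus in loci:
        t = transcripts[locus.transcript_ids[0]]
        cls = classify_locus(t, annotation, hits_transcript_vs_annotation,
                             weak_flag=locus.weak_similarity,
                             min_cds_overlap=min_cds_overlap, index=index)
        cls.locus_id = locus.locus_id
        results[locus.locus_id] = cls
        counts[cls.label] += 1
    return results, counts


def percentage(numerator: int, denominator: int) -> int | None:
    """Integer percentage with half-up rounding; None for a zero denominator."""
    if denominator == 0:
        return None
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def category_percentages(counts: dict[str, int]) -> dict[str, int | None]:
    total = sum(counts.values())
    return {label: percentage(n, total) for label, n in counts.items()}
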