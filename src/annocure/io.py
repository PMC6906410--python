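"""Readers and writers for GFF3, FASTA and BLAST tabular files.

All genomic intervals are 0-based half-open internally; GFF3's 1-based
inclusive coordinates are converted at the I/O boundary, i.e. a GFF3 feature
``start..end`` becomes ``[start-1, end)``.  BLAST hit tables use the standard
12-column outfmt-6 layout.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: annotation provenance classes, ranked for curation preferences
SOURCES = ("prediction", "transcript_evidence", "legacy_annotation")
EVIDENCE_CLASSES = ("rnaseq_assembly", "isoseq", "legacy_prediction")


class ParseError(ValueError):
    """Raised for malformed annotation or hit-table input."""


def _check_intervals(ivs: list[Interval], what: str) -> list[Interval]:
    ivs = sorted(ivs)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{what} intervals overlap: [{s1},{e1}) and [{s2},{e2})")
    for s, e in ivs:
        if e <= s or s < 0:
            raise ValueError(f"invalid {what} interval [{s},{e})")
    return ivs


@dataclass
class GeneModel:
    """An annotated protein-coding gene: CDS exons plus optional UTR exons.

    ``utr_exons`` entries are ``(start, end, kind)`` with kind "five_prime"
    or "three_prime".  Intervals are 0-based half-open, sorted, disjoint.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_exons: list[Interval]
    utr_exons: list[tuple[int, int, str]] = field(default_factory=list)
    source: str = "prediction"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        self.cds_exons = _check_intervals(list(self.cds_exons), "CDS")
        utr = sorted((s, e, k) for s, e, k in self.utr_exons)
        _check_intervals([(s, e) for s, e, k in utr], "UTR")
        self.utr_exons = utr
        if self.cds_length == 0:
            raise ValueError(f"gene {self.gene_id} has no CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.cds_exons] + [s for s, _, _ in self.utr_exons]
        ends = [e for _, e in self.cds_exons] + [e for _, e, _ in self.utr_exons]
        return (min(starts), max(ends))

    @property
    def exons(self) -> list[Interval]:
        """All exonic intervals (CDS and UTR), sorted."""
        return sorted(self.cds_exons + [(s, e) for s, e, _ in self.utr_exons])


@dataclass
class TranscriptEvidence:
    """A genome-aligned transcript with the protein of its longest ORF."""

    transcript_id: str
    scaffold: str
    strand: str
    exons: list[Interval]
    orf_protein: str
    evidence_class: str = "rnaseq_assembly"
    gene_id: str = ""  # locus grouping key for redundancy reduction

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        self.exons = _check_intervals(list(self.exons), "exon")
        if len(self.orf_protein) < 1:
            raise ValueError(f"transcript {self.transcript_id} has empty ORF")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class Hit:
    """One pairwise protein similarity record (outfmt-6 row)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bitscore: float
    query_coverage: float = math.nan
    subject_coverage: float = math.nan
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if self.bitscore <= 0:
            raise ValueError("bitscore must be > 0")
        for cov in (self.query_coverage, self.subject_coverage):
            if not math.isnan(cov) and not 0.0 <= cov <= 1.0:
                raise ValueError("coverage must lie in [0,1]")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_SOURCE_TAG = {"prediction": "prediction",
               "transcript_evidence": "transcript_evidence",
               "legacy_annotation": "legacy_annotation"}


def _subtract(ivs: list[Interval], minus: list[Interval]) -> list[Interval]:
    """Set difference of sorted disjoint interval lists."""
    out: list[Interval] = []
    for s, e in ivs:
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


def _utr_kind(iv: Interval, cds: list[Interval], strand: str) -> str:
    upstream = iv[1] <= cds[0][0]
    if strand == "+":
        return "five_prime" if upstream else "three_prime"
    return "three_prime" if upstream else "five_prime"


def read_annotation(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse a GFF3 annotation into GeneModels keyed by gene id.

    Multiple mRNA isoforms of a gene are collapsed to the one with the
    longest total CDS (ties: lexicographically smallest transcript id).
    UTR exons come from five_prime_UTR/three_prime_UTR features when
    present, otherwise they are inferred as exon-minus-CDS regions.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ParseError(f"gene {gene.id} has no mRNA (line {gene.start})")
        best = None
        for m in mrnas:
            cds_len = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
            key = (-cds_len, m.id)
            if best is None or key < best[0]:
                best = (key, m)
        mrna = best[1]
        gene_span = (gene.start - 1, gene.end)
        cds, utr = [], []
        exons = []
        for c in db.children(mrna, featuretype="CDS"):
            iv = (c.start - 1, c.end)
            if iv[0] < gene_span[0] or iv[1] > gene_span[1]:
                raise ParseError(
                    f"CDS {iv} outside gene span of {gene.id} (line {c.start})")
            cds.append(iv)
        for e in db.children(mrna, featuretype="exon"):
            exons.append((e.start - 1, e.end))
        for kind, ftype in (("five_prime", "five_prime_UTR"),
                            ("three_prime", "three_prime_UTR")):
            for u in db.children(mrna, featuretype=ftype):
                utr.append((u.start - 1, u.end, kind))
        cds = sorted(cds)
        if not utr and exons:
            for iv in _subtract(sorted(exons), cds):
                utr.append((*iv, _utr_kind(iv, cds, gene.strand)))
        source = gene.source if gene.source in SOURCES else "prediction"
        gid = gene.attributes.get("ID", [gene.id])[0]
        models[gid] = GeneModel(gid, gene.seqid, gene.strand, cds, utr, source)
    return models


def write_annotation(models: dict[str, GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels as GFF3 (one mRNA per gene), deterministically ordered."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        ordered = sorted(models.values(), key=lambda g: (g.scaffold, g.span[0], g.gene_id))
        for g in ordered:
            s, e = g.span
            src = _SOURCE_TAG[g.source]
            tid = f"{g.gene_id}.1"
            fh.write(f"{g.scaffold}\t{src}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.scaffold}\t{src}\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={tid};Parent={g.gene_id}\n")
            for xs, xe in g.exons:
                fh.write(f"{g.scaffold}\t{src}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                         f"Parent={tid}\n")
            for cs, ce in g.cds_exons:
                fh.write(f"{g.scaffold}\t{src}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                         f"Parent={tid}\n")
            for us, ue, kind in g.utr_exons:
                fh.write(f"{g.scaffold}\t{src}\t{kind}_UTR\t{us + 1}\t{ue}\t.\t{g.strand}\t.\t"
                         f"Parent={tid}\n")


def write_transcripts(transcripts: list[TranscriptEvidence],
                      gff_path: str | os.PathLike,
                      fasta_path: str | os.PathLike | None = None) -> None:
    """Write transcript alignments as GFF3 and their ORF proteins as FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: (t.scaffold, t.span[0], t.transcript_id)):
            s, e = t.span
            attrs = f"ID={t.transcript_id};evidence_class={t.evidence_class}"
            if t.gene_id:
                attrs += f";gene_id={t.gene_id}"
            fh.write(f"{t.scaffold}\ttranscript_evidence\tmRNA\t{s + 1}\t{e}\t.\t"
                     f"{t.strand}\t.\t{attrs}\n")
            for xs, xe in t.exons:
                fh.write(f"{t.scaffold}\ttranscript_evidence\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{t.strand}\t.\tParent={t.transcript_id}\n")
    if fasta_path is not None:
        write_fasta({t.transcript_id: t.orf_protein for t in transcripts}, fasta_path)


def read_transcripts(gff_path: str | os.PathLike,
                     fasta_path: str | os.PathLike) -> list[TranscriptEvidence]:
    db = gffutils.create_db(str(gff_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    proteins = read_fasta(fasta_path)
    out = []
    for m in db.features_of_type("mRNA"):
        tid = m.attributes.get("ID", [m.id])[0]
        exons = sorted((e.start - 1, e.end) for e in db.children(m, featuretype="exon"))
        out.append(TranscriptEvidence(
            tid, m.seqid, m.strand, exons, proteins[tid],
            evidence_class=m.attributes.get("evidence_class", ["rnaseq_assembly"])[0],
            gene_id=m.attributes.get("gene_id", [""])[0]))
    return sorted(out, key=lambda t: t.transcript_id)


def reduce_transcriptome(transcripts: list[TranscriptEvidence],
                         min_peptide_len: int = 60,
                         drop_single_exon: bool = True) -> list[TranscriptEvidence]:
    """Reduce isoform redundancy to one representative transcript per locus.

    Per locus the isoform with the longest ORF is kept (ties broken by
    lexicographically smallest transcript id); representatives whose peptide
    is shorter than ``min_peptide_len`` amino acids, or that consist of a
    single exon, are discarded.
    """
    by_locus: dict[str, list[TranscriptEvidence]] = {}
    for t in transcripts:
        by_locus.setdefault(t.gene_id or t.transcript_id, []).append(t)
    out = []
    for locus in sorted(by_locus):
        rep = min(by_locus[locus], key=lambda t: (-len(t.orf_protein), t.transcript_id))
        if len(rep.orf_protein) < min_peptide_len:
            continue
        if drop_single_exon and len(rep.exons) < 2:
            continue
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def hits_to_frame(hits: list[Hit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
          h.mismatch, h.gapopen, h.qstart, h.qend, h.sstart, h.send,
          h.e_value, h.bitscore) for h in hits],
        columns=OUTFMT6_COLUMNS)


def write_hits(hits: list[Hit], path: str | os.PathLike) -> None:
    df = hits_to_frame(sorted(hits, key=lambda h: (h.query_id, h.subject_id, h.e_value)))
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_hits(path: str | os.PathLike, max_evalue: float = 1e-5,
              query_lengths: dict[str, int] | None = None,
              subject_lengths: dict[str, int] | None = None) -> list[Hit]:
    """Read a 12-column BLAST tabular file, keeping e-values strictly below
    ``max_evalue``.  If sequence-length maps are supplied, query/subject
    coverages are computed as aligned-span / sequence-length."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")
    df.columns = OUTFMT6_COLUMNS
    if df[OUTFMT6_COLUMNS[2:]].isna().any().any():
        bad = int(df[df[OUTFMT6_COLUMNS[2:]].isna().any(axis=1)].index[0]) + 1
        raise ParseError(f"{path}: malformed row at line {bad}")
    out = []
    for row in df.itertuples(index=False):
        if not row.evalue < max_evalue:
            continue
        qcov = scov = math.nan
        if query_lengths is not None and row.qseqid in query_lengths:
            qcov = min(1.0, (abs(row.qend - row.qstart) + 1) / query_lengths[row.qseqid])
        if subject_lengths is not None and row.sseqid in subject_lengths:
            scov = min(1.0, (abs(row.send - row.sstart) + 1) / subject_lengths[row.sseqid])
        out.append(Hit(row.qseqid, row.sseqid, float(row.pident), int(row.length),
                       float(row.evalue), float(row.bitscore), qcov, scov,
                       int(row.mismatch), int(row.gapopen), int(row.qstart),
                       int(row.qend), int(row.sstart), int(row.send)))
    return out
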