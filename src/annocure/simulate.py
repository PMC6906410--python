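"""Synthetic annotation-audit scenarios with known ground truth.

The generator builds a compact toy genome (intergenic spacing uniform in
[200, 2000) nt, as in gene-dense nematode genomes), a truth annotation, and
a corrupted draft annotation containing a configured number of injected
errors of the classes an annotation audit must detect:

* artificial fusions — two adjacent same-strand genes merged into one model,
* deleted genes — models missing entirely,
* UTR-hidden genes — a gene's exons re-annotated as a neighbour's UTR,
* frame corruptions — the annotated reading frame shifted by one base so the
  translated protein loses detectable homology while coordinates overlap.

One correct evidence transcript exists per truth gene, and a homologous
reference proteome (one gene per truth gene, plus optional lineage-specific
inparalog duplicates) with a known ortholog map.  Protein sequences are
random 20-letter strings; homology is encoded directly in the emitted
BLAST-style hit tables rather than recomputed by an aligner, with e-values
below 1e-6 for every true pair and bitscores decreasing with a per-gene
simulated divergence.  With probability ``hit_noise`` a hit is dropped or
its e-value inflated into [1e-5, 1e-3) — the borderline band that produces
"weak similarity" cases downstream.  Identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import io as aio
from .io import GeneModel, Hit, TranscriptEvidence
from .phylo import OutgroupLadder

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


class InfeasibleConfig(ValueError):
    """Raised when a scenario config cannot be realised (names the constraint)."""


@dataclass
class ScenarioConfig:
    n_genes: int = 200
    n_scaffolds: int = 4
    mean_cds_len: int = 300  # amino acids
    fusion_count: int = 30
    missing_count: int = 20
    utr_hidden_count: int = 15
    misannotation_count: int = 10
    inparalog_count: int = 0
    hit_noise: float = 0.0
    seed: int = 0
    n_strata: int = 8

    def __post_init__(self) -> None:
        counts = (self.fusion_count, self.missing_count, self.utr_hidden_count,
                  self.misannotation_count, self.inparalog_count)
        if any(c < 0 for c in counts) or self.n_genes <= 0 or self.n_scaffolds <= 0:
            raise InfeasibleConfig("all counts must be non-negative and sizes positive")
        if not 0.0 <= self.hit_noise <= 1.0:
            raise InfeasibleConfig("hit_noise must lie in [0,1]")
        n_errored = (self.fusion_count + self.missing_count
                     + self.utr_hidden_count + self.misannotation_count)
        if n_errored > self.n_genes:
            raise InfeasibleConfig(
                f"error counts sum to {n_errored} > n_genes={self.n_genes}")
        if not 1 <= self.n_strata <= len(ROMAN):
            raise InfeasibleConfig(f"n_strata must be in [1,{len(ROMAN)}]")


@dataclass
class TruthSet:
    """Ground truth of one scenario: per-gene injected error class
    (none | fused_into:<id> | deleted | utr_hidden_in:<id> | frame_corrupted),
    the reference-to-truth ortholog map, per-reference-gene phylostratum,
    and the injected inparalog groups."""

    error_class: dict[str, str]
    ortholog_map: dict[str, str]  # reference gene -> truth gene
    phylostratum: dict[str, str]  # reference gene -> stratum label
    fused_models: dict[str, tuple[str, str]] = field(default_factory=dict)
    utr_hosts: dict[str, str] = field(default_factory=dict)  # victim -> host
    inparalog_groups: list[set[str]] = field(default_factory=list)

    def genes_with(self, prefix: str) -> set[str]:
        return {g for g, c in self.error_class.items() if c.startswith(prefix)}

    def to_tsv(self, path: str | os.PathLike) -> None:
        truth_to_ref = {v: k for k, v in self.ortholog_map.items()}
        with open(path, "w") as fh:
            fh.write("gene_id\terror_class\tref_gene\tphylostratum\n")
            for g in sorted(self.error_class):
                ref = truth_to_ref.get(g, "")
                fh.write(f"{g}\t{self.error_class[g]}\t{ref}\t"
                         f"{self.phylostratum.get(ref, '')}\n")


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    genome: dict[str, str]
    truth_annotation: dict[str, GeneModel]
    corrupted_annotation: dict[str, GeneModel]
    truth_proteins: dict[str, str]
    annotation_proteins: dict[str, str]
    transcripts: list[TranscriptEvidence]
    ref_proteome: dict[str, str]
    ladder: OutgroupLadder
    hit_tables: dict[str, list[Hit]]
    truth: TruthSet

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "hits"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "outgroups"), exist_ok=True)
        aio.write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        aio.write_annotation(self.truth_annotation, os.path.join(outdir, "truth.gff3"))
        aio.write_annotation(self.corrupted_annotation,
                             os.path.join(outdir, "annotation.gff3"))
        aio.write_transcripts(self.transcripts,
                              os.path.join(outdir, "transcripts.gff3"),
                              os.path.join(outdir, "transcripts.fa"))
        aio.write_fasta(self.ref_proteome, os.path.join(outdir, "ref_proteome.fa"))
        aio.write_fasta(self.annotation_proteins,
                        os.path.join(outdir, "annotation_proteins.fa"))
        for label, prots in self.ladder.proteomes.items():
            if prots:
                aio.write_fasta(prots, os.path.join(outdir, "outgroups", f"{label}.fa"))
        for name, hits in self.hit_tables.items():
            aio.write_hits(hits, os.path.join(outdir, "hits", f"{name}.tsv"))
        self.truth.to_tsv(os.path.join(outdir, "truthset.tsv"))
        with open(os.path.join(outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(vars(self.config), fh, sort_keys=True)


def load_bundle(indir: str | os.PathLike) -> ScenarioBundle:
    """Re-read a scenario bundle previously written by ``ScenarioBundle.write``."""
    import glob
    import math

    indir = str(indir)
    with open(os.path.join(indir, "config.yaml")) as fh:
        config = ScenarioConfig(**yaml.safe_load(fh))
    genome = aio.read_fasta(os.path.join(indir, "genome.fa"))
    truth_annotation = aio.read_annotation(os.path.join(indir, "truth.gff3"))
    corrupted = aio.read_annotation(os.path.join(indir, "annotation.gff3"))
    transcripts = aio.read_transcripts(os.path.join(indir, "transcripts.gff3"),
                                       os.path.join(indir, "transcripts.fa"))
    ref_proteome = aio.read_fasta(os.path.join(indir, "ref_proteome.fa"))
    annotation_proteins = aio.read_fasta(os.path.join(indir, "annotation_proteins.fa"))
    truth_proteins = {t.gene_id or t.transcript_id.removeprefix("t_"): t.orf_protein
                      for t in transcripts}
    labels = list(ROMAN[:config.n_strata])
    proteomes: dict[str, dict[str, str]] = {}
    for lab in labels:
        path = os.path.join(indir, "outgroups", f"{lab}.fa")
        proteomes[lab] = aio.read_fasta(path) if os.path.exists(path) else {}
    ladder = OutgroupLadder(labels, proteomes)
    hit_tables = {}
    for path in sorted(glob.glob(os.path.join(indir, "hits", "*.tsv"))):
        name = os.path.splitext(os.path.basename(path))[0]
        hit_tables[name] = aio.read_hits(path, max_evalue=math.inf)

    error_class: dict[str, str] = {}
    ortholog_map: dict[str, str] = {}
    strata: dict[str, str] = {}
    with open(os.path.join(indir, "truthset.tsv")) as fh:
        next(fh)
        for line in fh:
            gene, cls, ref, stratum = line.rstrip("\n").split("\t")
            error_class[gene] = cls
            if ref:
                ortholog_map[ref] = gene
                if stratum:
                    strata[ref] = stratum
    fused_models: dict[str, tuple[str, str]] = {}
    by_fid: dict[str, list[str]] = {}
    for g, cls in error_class.items():
        if cls.startswith("fused_into:"):
            by_fid.setdefault(cls.split(":", 1)[1], []).append(g)
    for fid, members in by_fid.items():
        members.sort(key=lambda g: truth_annotation[g].span[0])
        fused_models[fid] = (members[0], members[1])
    utr_hosts = {g: cls.split(":", 1)[1] for g, cls in error_class.items()
                 if cls.startswith("utr_hidden_in:")}
    inparalog_groups = [{r.removesuffix("_dup"), r}
                        for r in sorted(ref_proteome) if r.endswith("_dup")]
    truth = TruthSet(error_class, ortholog_map, strata, fused_models,
                     utr_hosts, inparalog_groups)
    return ScenarioBundle(config, genome, truth_annotation, corrupted,
                          truth_proteins, annotation_proteins, transcripts,
                          ref_proteome, ladder, hit_tables, truth)


# ---------------------------------------------------------------------------
# Injection primitives
# ---------------------------------------------------------------------------

def inject_fusion(a: GeneModel, b: GeneModel) -> GeneModel:
    """Merge two adjacent same-scaffold, same-strand, non-overlapping gene
    models into one artificial fusion carrying a's identifier; the fused CDS
    is the union of both CDS exon sets."""
    if a.scaffold != b.scaffold or a.strand != b.strand:
        raise ValueError(f"cannot fuse {a.gene_id} and {b.gene_id}: "
                         "different scaffold or strand")
    if a.span[0] > b.span[0]:
        a, b = b, a
    if a.span[1] > b.span[0]:
        raise ValueError(f"cannot fuse overlapping models {a.gene_id}, {b.gene_id}")
    return GeneModel(a.gene_id, a.scaffold, a.strand,
                     sorted(a.cds_exons + b.cds_exons), source="prediction")


def inject_utr_hidden(host: GeneModel, victim: GeneModel) -> GeneModel:
    """Extend the host model so the victim's CDS exons become UTR exons of
    the host (the victim disappears from the corrupted annotation)."""
    if host.scaffold != victim.scaffold:
        raise ValueError("victim must be adjacent to host on the same scaffold")
    upstream = victim.span[1] <= host.span[0]
    if host.strand == "+":
        kind = "five_prime" if upstream else "three_prime"
    else:
        kind = "three_prime" if upstream else "five_prime"
    utr = list(host.utr_exons) + [(s, e, kind) for s, e in victim.cds_exons]
    return GeneModel(host.gene_id, host.scaffold, host.strand,
                     list(host.cds_exons), utr, host.source)


def _frame_shift(g: GeneModel) -> GeneModel:
    """Shift the annotated CDS start by one base (strand-aware)."""
    cds = [list(iv) for iv in g.cds_exons]
    if g.strand == "+":
        cds[0][0] += 1
    else:
        cds[-1][1] -= 1
    return GeneModel(g.gene_id, g.scaffold, g.strand,
                     [tuple(iv) for iv in cds], list(g.utr_exons), g.source)


# ---------------------------------------------------------------------------
# Hit-table emission
# ---------------------------------------------------------------------------

def _pair_hits(query_id: str, subject_id: str, alen: int, divergence: float,
               bits_scale: float = 1.0, qstart: int = 1, sstart: int = 1
               ) -> tuple[Hit, Hit]:
    """Forward and reverse hit records for one homologous pair."""
    pident = round(100.0 * (1.0 - divergence), 1)
    bits = round(max(35.0, 2.0 * alen * (1.0 - divergence) * bits_scale), 1)
    evalue = 10.0 ** (-min(180.0, bits / 2.0))
    mism = int(round(alen * divergence))
    fwd = Hit(query_id, subject_id, pident, alen, evalue, bits,
              mismatch=mism, qstart=qstart, qend=qstart + alen - 1,
              sstart=sstart, send=sstart + alen - 1)
    rev = Hit(subject_id, query_id, pident, alen, evalue, bits,
              mismatch=mism, qstart=sstart, qend=sstart + alen - 1,
              sstart=qstart, send=qstart + alen - 1)
    return fwd, rev


def _self_hit(seq_id: str, length: int) -> Hit:
    return Hit(seq_id, seq_id, 100.0, length, 1e-180, round(2.0 * length, 1),
               qstart=1, qend=length, sstart=1, send=length)


def _perturb(hits: list[Hit], hit_noise: float, rng: np.random.Generator) -> list[Hit]:
    """Drop a hit or inflate its e-value into [1e-5, 1e-3) with probability
    ``hit_noise`` per record (deterministic under a fixed generator state)."""
    if hit_noise == 0.0:
        return list(hits)
    out = []
    for h in hits:
        if rng.random() < hit_noise:
            if rng.random() < 0.5:
                continue  # dropped
            new_e = float(10.0 ** rng.uniform(-5.0, -3.0))
            new_e = min(max(new_e, 1e-5), 9.99e-4)
            out.append(replace(h, e_value=new_e))
        else:
            out.append(h)
    return out


def emit_hit_tables(ortholog_map: dict[str, str],
                    query_proteome: dict[str, str],
                    subject_proteome: dict[str, str],
                    hit_noise: float = 0.0, seed: int = 0,
                    divergence: dict[str, float] | None = None
                    ) -> dict[str, list[Hit]]:
    """Emit bidirectional hit tables plus self-searches for an ortholog map.

    Several queries may map to the same subject (a fused protein); each such
    query aligns to its own stretch of the subject.  True pairs get e-values
    below 1e-6 and bitscores decreasing with divergence; noise drops or
    inflates individual records.
    """
    for q, s in ortholog_map.items():
        if q not in query_proteome:
            raise KeyError(f"ortholog map query {q!r} not in query proteome")
        if s not in subject_proteome:
            raise KeyError(f"ortholog map subject {s!r} not in subject proteome")
    rng = np.random.default_rng(seed)
    divergence = divergence or {}
    offsets: dict[str, int] = {}
    fwd, rev = [], []
    for q in sorted(ortholog_map):
        s = ortholog_map[q]
        alen = min(len(query_proteome[q]),
                   len(subject_proteome[s]) - offsets.get(s, 0))
        d = divergence.get(q, float(rng.uniform(0.05, 0.3)))
        f, r = _pair_hits(q, s, max(alen, 1), d, sstart=offsets.get(s, 0) + 1)
        offsets[s] = offsets.get(s, 0) + alen
        fwd.append(f)
        rev.append(r)
    noise_rng = np.random.default_rng(seed + 1)
    return {
        "forward": _perturb(fwd, hit_noise, noise_rng),
        "reverse": _perturb(rev, hit_noise, noise_rng),
        "query_self": [_self_hit(q, len(seq)) for q, seq in sorted(query_proteome.items())],
        "subject_self": [_self_hit(s, len(seq)) for s, seq in sorted(subject_proteome.items())],
    }


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, len(AA_ALPHABET), length)])


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA_ALPHABET[int(rng.integers(0, len(AA_ALPHABET)))]
    return "".join(out)


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Build a complete, internally consistent scenario bundle.

    The corrupted annotation equals the truth annotation with exactly the
    configured error events injected; transcript evidence carries one
    correct transcript per truth gene; hit tables reflect the true ortholog
    map minus noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # --- gene layout -------------------------------------------------------
    per_scaffold = -(-n // config.n_scaffolds)
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    scaffold_len: dict[str, int] = {}
    gid = 0
    for sc in range(config.n_scaffolds):
        scaffold = f"scaffold_{sc + 1}"
        pos = int(rng.integers(200, 2000))
        for _ in range(per_scaffold):
            if gid >= n:
                break
            gene_id = f"g{gid:04d}"
            aa_len = max(70, int(rng.normal(config.mean_cds_len,
                                            0.3 * config.mean_cds_len)))
            cds_nt = 3 * aa_len
            n_exons = int(rng.integers(2, 5))
            # cut points on a 30 nt grid keep every CDS exon >= 30 nt
            grid = np.arange(30, cds_nt - 29, 30)
            cuts = sorted(rng.choice(grid, size=n_exons - 1, replace=False))
            pieces = np.diff([0, *cuts, cds_nt])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cur = pos
            for piece in pieces:
                exons.append((cur, cur + int(piece)))
                cur += int(piece) + int(rng.integers(50, 301))
            pos = exons[-1][1] + int(rng.integers(200, 2000))
            genes.append(GeneModel(gene_id, scaffold, strand, exons))
            proteins[gene_id] = _random_protein(rng, aa_len)
            gid += 1
        scaffold_len[scaffold] = pos + 500
    index_of = {g.gene_id: i for i, g in enumerate(genes)}

    # --- role assignment ---------------------------------------------------
    assigned: set[str] = set()
    error_class = {g.gene_id: "none" for g in genes}

    adjacent_pairs = [(a, b) for a, b in zip(genes, genes[1:])
                      if a.scaffold == b.scaffold and a.strand == b.strand]
    rng.shuffle(adjacent_pairs)
    fusion_pairs: list[tuple[GeneModel, GeneModel]] = []
    for a, b in adjacent_pairs:
        if len(fusion_pairs) == config.fusion_count:
            break
        if a.gene_id in assigned or b.gene_id in assigned:
            continue
        fusion_pairs.append((a, b))
        assigned.update((a.gene_id, b.gene_id))
    if len(fusion_pairs) < config.fusion_count:
        raise InfeasibleConfig(
            f"fusion_count={config.fusion_count} exceeds available adjacent "
            f"same-strand gene pairs ({len(fusion_pairs)} assignable)")

    utr_events: list[tuple[GeneModel, GeneModel]] = []  # (host, victim)
    order = list(range(len(genes)))
    rng.shuffle(order)
    for i in order:
        if len(utr_events) == config.utr_hidden_count:
            break
        victim = genes[i]
        if victim.gene_id in assigned:
            continue
        for j in (i - 1, i + 1):
            if not 0 <= j < len(genes):
                continue
            host = genes[j]
            if (host.gene_id in assigned or host.scaffold != victim.scaffold
                    or host.strand != victim.strand):
                continue
            utr_events.append((host, victim))
            assigned.update((host.gene_id, victim.gene_id))
            break
    if len(utr_events) < config.utr_hidden_count:
        raise InfeasibleConfig(
            f"utr_hidden_count={config.utr_hidden_count} exceeds available "
            f"victim/host adjacencies ({len(utr_events)} assignable)")

    free = [g for g in genes if g.gene_id not in assigned]
    rng.shuffle(free)
    if len(free) < config.missing_count + config.misannotation_count:
        raise InfeasibleConfig(
            "missing_count + misannotation_count exceeds genes left after "
            "fusion and UTR assignment")
    deleted = free[:config.missing_count]
    frame_corrupted = free[config.missing_count:
                           config.missing_count + config.misannotation_count]

    # --- corrupted annotation ---------------------------------------------
    truth_annotation = {g.gene_id: g for g in genes}
    corrupted: dict[str, GeneModel] = {g.gene_id: replace(g) for g in genes}
    annotation_proteins = dict(proteins)
    fused_models: dict[str, tuple[str, str]] = {}
    for a, b in fusion_pairs:
        fused = inject_fusion(a, b)
        first, second = (a, b) if a.span[0] < b.span[0] else (b, a)
        del corrupted[b.gene_id]
        del annotation_proteins[b.gene_id]
        corrupted[fused.gene_id] = fused
        annotation_proteins[fused.gene_id] = (proteins[first.gene_id]
                                              + proteins[second.gene_id])
        fused_models[fused.gene_id] = (first.gene_id, second.gene_id)
        error_class[a.gene_id] = f"fused_into:{fused.gene_id}"
        error_class[b.gene_id] = f"fused_into:{fused.gene_id}"
    utr_hosts: dict[str, str] = {}
    for host, victim in utr_events:
        corrupted[host.gene_id] = inject_utr_hidden(corrupted[host.gene_id], victim)
        del corrupted[victim.gene_id]
        del annotation_proteins[victim.gene_id]
        error_class[victim.gene_id] = f"utr_hidden_in:{host.gene_id}"
        utr_hosts[victim.gene_id] = host.gene_id
    for g in deleted:
        del corrupted[g.gene_id]
        del annotation_proteins[g.gene_id]
        error_class[g.gene_id] = "deleted"
    junk_lengths = {}
    for g in frame_corrupted:
        corrupted[g.gene_id] = _frame_shift(corrupted[g.gene_id])
        junk_len = corrupted[g.gene_id].cds_length // 3
        annotation_proteins[g.gene_id] = _random_protein(rng, junk_len)
        junk_lengths[g.gene_id] = junk_len
        error_class[g.gene_id] = "frame_corrupted"

    # --- transcript evidence ----------------------------------------------
    transcripts = []
    for g in genes:
        evidence = "isoseq" if rng.random() < 0.3 else "rnaseq_assembly"
        transcripts.append(TranscriptEvidence(
            f"t_{g.gene_id}", g.scaffold, g.strand, list(g.cds_exons),
            proteins[g.gene_id], evidence_class=evidence, gene_id=g.gene_id))

    # --- reference proteome and ortholog map -------------------------------
    divergence = {g.gene_id: float(rng.uniform(0.05, 0.3)) for g in genes}
    ref_proteome = {f"ce_{g.gene_id}": _mutate(rng, proteins[g.gene_id],
                                               divergence[g.gene_id])
                    for g in genes}
    ortholog_map = {f"ce_{g.gene_id}": g.gene_id for g in genes}
    inparalog_groups: list[set[str]] = []
    dup_parents = [g.gene_id for g in genes if error_class[g.gene_id] == "none"]
    rng.shuffle(dup_parents)
    if config.inparalog_count > len(dup_parents):
        raise InfeasibleConfig("inparalog_count exceeds unmodified genes available")
    dup_parents = sorted(dup_parents[:config.inparalog_count])
    for g in dup_parents:
        dup = f"ce_{g}_dup"
        ref_proteome[dup] = _mutate(rng, ref_proteome[f"ce_{g}"], 0.02)
        inparalog_groups.append({f"ce_{g}", dup})

    # --- phylostrata --------------------------------------------------------
    labels = list(ROMAN[:config.n_strata])
    strata = {r: labels[int(rng.integers(0, len(labels)))] for r in sorted(ortholog_map)}
    rank = {lab: i for i, lab in enumerate(labels)}
    ladder_prots: dict[str, dict[str, str]] = {lab: {} for lab in labels}
    outgroup_tables: dict[str, list[Hit]] = {lab: [] for lab in labels[1:]}
    for r in sorted(ortholog_map):
        for lab in labels[1:]:
            if rank[lab] <= rank[strata[r]]:
                og_id = f"og{lab}_{r}"
                ladder_prots[lab][og_id] = _mutate(rng, ref_proteome[r], 0.3)
                f, _ = _pair_hits(r, og_id, len(ref_proteome[r]), 0.45)
                outgroup_tables[lab].append(f)
    ladder = OutgroupLadder(labels, ladder_prots)

    # --- hit tables ---------------------------------------------------------
    def ortho_hits(target_of: dict[str, tuple[str, int]], scale: float = 1.0
                   ) -> tuple[list[Hit], list[Hit]]:
        fwd, rev = [], []
        for ref in sorted(target_of):
            subject, soff = target_of[ref]
            g = ortholog_map.get(ref, ref.removeprefix("ce_").removesuffix("_dup"))
            f, r = _pair_hits(ref, subject, len(proteins[g]),
                              divergence[g], bits_scale=scale, sstart=soff + 1)
            fwd.append(f)
            rev.append(r)
        return fwd, rev

    # reference vs corrupted annotation
    anno_target: dict[str, tuple[str, int]] = {}
    for g in genes:
        cls = error_class[g.gene_id]
        if cls in ("deleted", "frame_corrupted") or cls.startswith("utr_hidden_in:"):
            continue
        if cls.startswith("fused_into:"):
            fid = cls.split(":", 1)[1]
            first, _second = fused_models[fid]
            off = 0 if g.gene_id == first else len(proteins[first])
            anno_target[f"ce_{g.gene_id}"] = (fid, off)
        else:
            anno_target[f"ce_{g.gene_id}"] = (g.gene_id, 0)
    ra_fwd, ra_rev = ortho_hits(anno_target)
    dup_anno = {f"ce_{g}_dup": anno_target[f"ce_{g}"] for g in dup_parents
                if f"ce_{g}" in anno_target}
    da_fwd, da_rev = ortho_hits(dup_anno, scale=0.9)

    # reference vs transcriptome (every gene has its correct transcript)
    trans_target = {f"ce_{g.gene_id}": (f"t_{g.gene_id}", 0) for g in genes}
    rt_fwd, rt_rev = ortho_hits(trans_target)
    dup_trans = {f"ce_{g}_dup": (f"t_{g}", 0) for g in dup_parents}
    dt_fwd, dt_rev = ortho_hits(dup_trans, scale=0.9)

    # transcriptome vs corrupted annotation (near-identical protein content)
    ta = []
    for g in genes:
        cls = error_class[g.gene_id]
        if cls in ("deleted", "frame_corrupted") or cls.startswith("utr_hidden_in:"):
            continue
        if cls.startswith("fused_into:"):
            fid = cls.split(":", 1)[1]
            first, _second = fused_models[fid]
            off = 0 if g.gene_id == first else len(proteins[first])
            f, _ = _pair_hits(f"t_{g.gene_id}", fid, len(proteins[g.gene_id]),
                              0.0, sstart=off + 1)
        else:
            f, _ = _pair_hits(f"t_{g.gene_id}", g.gene_id,
                              len(proteins[g.gene_id]), 0.0)
        ta.append(f)

    # within-reference-species searches: identity self-hits plus inparalogs
    ref_self = [_self_hit(r, len(seq)) for r, seq in sorted(ref_proteome.items())]
    for g in dup_parents:
        f, r = _pair_hits(f"ce_{g}", f"ce_{g}_dup", len(ref_proteome[f"ce_{g}"]), 0.02)
        ref_self.extend([f, r])

    noise_rng = np.random.default_rng(config.seed + 1)
    hit_tables = {
        "ref_vs_annotation": _perturb(sorted(ra_fwd + da_fwd,
                                             key=lambda h: (h.query_id, h.subject_id)),
                                      config.hit_noise, noise_rng),
        "annotation_vs_ref": _perturb(sorted(ra_rev + da_rev,
                                             key=lambda h: (h.query_id, h.subject_id)),
                                      config.hit_noise, noise_rng),
        "ref_vs_transcriptome": _perturb(sorted(rt_fwd + dt_fwd,
                                                key=lambda h: (h.query_id, h.subject_id)),
                                         config.hit_noise, noise_rng),
        "transcriptome_vs_ref": _perturb(sorted(rt_rev + dt_rev,
                                                key=lambda h: (h.query_id, h.subject_id)),
                                         config.hit_noise, noise_rng),
        "transcriptome_vs_annotation": sorted(ta, key=lambda h: (h.query_id, h.subject_id)),
        "ref_vs_ref": ref_self,
    }
    for lab, hits in outgroup_tables.items():
        hit_tables[f"ref_vs_outgroup_{lab}"] = hits

    genome = {sc: _random_genome(rng, ln) for sc, ln in sorted(scaffold_len.items())}
    truth = TruthSet(error_class, ortholog_map, strata,
                     fused_models, utr_hosts, inparalog_groups)
    return ScenarioBundle(config, genome, truth_annotation, corrupted,
                          proteins, annotation_proteins, transcripts,
                          ref_proteome, ladder, hit_tables, truth)
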