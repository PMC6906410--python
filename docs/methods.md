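# Methods

## Problem setting and model

`annocure` audits a draft genome annotation *A* (gene models with CDS and
UTR exons, GFF3) against two evidence sources: a set *T* of genome-aligned
transcripts, each with the protein of its longest ORF, and a curated
reference proteome *R* from a related species (one protein per gene, longest
isoform). All pairwise protein similarity is consumed as BLAST-style
tabular hit records (outfmt 6); the pipeline itself never runs an aligner.
Internally all genomic coordinates are 0-based half-open; GFF3's 1-based
inclusive convention is converted at the I/O boundary, which keeps interval
arithmetic uniform.

The audit rests on two observations. First, a gene that is missing from *A*
(or hidden in a neighbour's UTR, or annotated in the wrong frame) still
leaves homology evidence in *T*: its reference ortholog has a hit among the
transcriptome ORFs but none among the annotated proteins. Second, an
artificial fusion of two genes into one model leaves total homology intact
but destroys one-to-one orthology — a fused model can be the reciprocal best
hit of only one of its constituents — so the second screen compares BRH
maps of *R*↔*T* and *R*↔*A* rather than raw hits.

## Thresholds and decision rules

- **Homology threshold.** e-value < 10⁻⁵ (strict inequality everywhere).
- **Weak-similarity band.** A candidate is exempted from correction when
  one of the two searches is below threshold and the other lies in
  [10⁻⁵, `band_upper`), default `band_upper` = 10⁻³. The band's upper edge
  is a judgment call ("slightly above threshold" has no canonical value);
  10⁻³ matches the looser threshold used for phylostratigraphy, and the
  parameter is exposed.
- **Locus deduplication.** Candidates sharing a supporting transcript share
  a locus (default); an alternative rule merges transcript alignments that
  overlap ≥ 1 bp on the same scaffold and strand (transitively). Both are
  order-independent.
- **Classification order.** weak_similarity → missing_gene (no same-strand
  exon overlap; antisense-only overlap counts as none, with a note) → utr
  (UTR-exon overlap only) → gene_fusion (CDS overlap ≥ `min_cds_overlap`,
  default 30 nt, plus an ORF-vs-overlapped-protein hit) → misannotation
  (CDS overlap without such a hit, or overlap below the minimum) →
  inconclusive. Weak similarity is checked first because those loci get no
  correction by design; the remaining rules are mutually exclusive given
  fixed overlap facts.

## Curation

Replacement selects candidate transcripts greedily by the number of old-CDS
nucleotides they cover (ties: longer CDS, then lexicographic id), keeping
only mutually CDS-disjoint transcripts. Greedy rather than exact set cover:
genuine evidence transcripts rarely conflict, and determinism matters more
than optimality at the margins. Zero-coverage transcripts that overlap the
old model's span (genes hidden in its UTR) are retained as additional new
models. Uncovered CDS stretches are mapped strand-aware from genomic to
protein coordinates, merged when contiguous in CDS space, and emitted as
residual segments when ≥ `min_residual_aa` (default 20 aa — shorter
stretches are treated as alignment noise); they carry pseudo identifiers
and are exported as FASTA for external re-alignment, which is deliberately
out of scope.

Identifier inheritance: the most conserved new model (lowest e-value
against the reference) inherits the old identifier, falling back to the
longest CDS when no scores are available; ties break by id. When several
curations target the same old model, one is chosen by (1) more new models,
(2) higher provenance weight (Iso-seq 3 > RNA-seq assembly 2 > legacy
prediction 1 — the numeric stand-in for curator experience), (3) any
transcriptional evidence over pure prediction, (4) record id.
`apply_corrections` validates that no gene is deleted twice and that no
identifier is inserted twice; it is the identity on an empty correction
set and order-independent for non-conflicting corrections.

## Orthology, gene age, completeness

**BRH.** Best hit per query = maximal bitscore, ties by smaller e-value,
then lexicographic subject id (deterministic; the tie policy is ours, as no
canonical rule exists). Self-hits are excluded from cross-species maps but
kept for inparalog detection.

**MCL.** Markov clustering on the symmetrized, bitscore-weighted similarity
graph: self-loops (max incident weight) are added, columns normalized, then
expansion (matrix squaring) alternates with inflation (entrywise power
1.5 + renormalization) until the matrix changes by < 10⁻⁶, max 100
iterations; clusters are the connected attractor systems of the limit
matrix. Column stochasticity is preserved exactly at every step by
construction and asserted in tests. Inflation is exposed as a sensitivity
parameter: one-to-one counts from default-parameter Markov clustering are
known to run conservative relative to BRH.

**Inparalogs.** Two same-species genes form an inparalog pair when their
mutual bitscore exceeds both genes' best cross-species bitscores
(InParanoid's core rule, adopted here as the explicit operationalization of
"lineage-specific duplicate"); groups are connected components of
qualifying pairs.

**Phylostratigraphy.** Outgroup proteomes are pooled per stratum along a
ladder phylogeny (stratum I = species-specific, higher = older). A gene is
assigned to the most distant stratum whose pooled set contains a hit at
e < 10⁻³; no hit at all → stratum I. Assignment is monotone: extra hits in
more distant sets can only age a gene.

**Completeness proxy.** A marker (reference gene) is complete when some
protein covers ≥ `complete_cov` of it (default 0.7): exactly one such
protein → complete single-copy, several → duplicated; best coverage in
[0.1, 0.7) → fragmented; less → missing. The cutoffs are plain coverage
heuristics standing in for HMM-score logic, chosen to reproduce the
four-category semantics at desk scale; they are configurable and reported
to one decimal. N50 is the length of the sequence at which the
descending-order prefix sum first reaches half the total.

**Percentages.** All reported integer percentages use half-up rounding
(`Decimal` quantization), and every manifest percentage is stored next to
its numerator and denominator so it can be recomputed.

## Synthetic scenarios

The generator emulates a compact nematode-like genome: genes with 2–4 CDS
exons (each ≥ 30 nt; CDS length normal around 300 aa, floor 70 aa), introns
of 50–300 nt, intergenic spacing uniform in [200, 2000) nt — spacing at
which fusion and UTR-overlap errors are geometrically plausible — on a few
scaffolds, strands random. Error injection: fusions merge adjacent
same-strand gene pairs (CDS union, one identifier); deletions remove
models; UTR-hiding re-annotates a victim's CDS exons as a same-strand
neighbour's UTR; frame corruption shifts the CDS start by 1 nt and replaces
the model's protein with a random string, destroying homology while
coordinates still overlap. One correct transcript per truth gene serves as
evidence (30 % labelled Iso-seq, the rest RNA-seq assembly).

Proteins are random 20-letter strings and homology is encoded directly in
the emitted hit tables: a true pair's bitscore is 2·L·(1−d) for alignment
length L and a per-gene divergence d ~ U(0.05, 0.3), with e-value
10^(−bits/2) capped at 10⁻¹⁸⁰ — monotone per query and always < 10⁻⁶, so
zero-noise BRH maps equal the true ortholog map. Fused proteins are parent
concatenations and hit both parents' reference genes at offset coordinates.
With probability `hit_noise` a record is dropped or its e-value inflated
into [10⁻⁵, 10⁻³), which generates weak-similarity cases. Optional
reference-side inparalog duplicates score 0.9× against targets and higher
within-species. A local Smith–Waterman toy scorer (match/mismatch/linear
gap, e-value proxy K·m·n·2^(−score), K = 0.1) exists for aligner-free
smoke runs; it makes no Karlin–Altschul claims.

What the generator does **not** emulate: real codon structure or splice
signals, read-level noise, partial transcript coverage, paralogous
cross-hits between unrelated loci, and assembly errors. Passing the
recovery suites therefore demonstrates the correctness of the screens,
rules and bookkeeping under clean evidence — not screen performance on
real, noisy transcriptomes.

## Problem sizes and determinism

The standard study scenario is 200 genes on 4 scaffolds with 30 fusions,
20 deletions, 15 UTR-hidden genes, 10 frame corruptions and zero hit noise;
oracle-based suites (O(n²) BRH, union–find locus merging) run on 60–100
gene scenarios. A full pipeline run at this scale takes well under a
second. Every random choice flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical scenario
bundles and identical manifests.

## Known limitations

- Exactly one of a fused model's two parents retains a BRH with the fused
  model, so the hidden-ortholog screen flags fusions through one parent;
  recovery is therefore evaluated per error locus, not per parent gene.
- The curation stage re-annotates CDS only; UTRs of new models and isoform
  structure are out of scope.
- Residual protein segments are exported, not re-mapped to the genome.
- The completeness proxy is coverage-based and not comparable in absolute
  terms to HMM-based marker benchmarks.
- The classifier accepts a single evidence class per locus; it does not
  require corroboration from a second transcript technology.
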