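"""Single-copy-completeness proxy and basic assembly statistics.

The completeness report mimics the four-category semantics of universal
single-copy marker benchmarking (complete single-copy / duplicated /
fragmented / missing) using plain coverage cutoffs on marker-vs-proteome
hits instead of HMM scores: a marker covered to at least ``complete_cov``
by exactly one protein is complete single-copy, by several proteins
duplicated; best coverage in ``[frag_cov, complete_cov)`` is fragmented,
anything less is missing.  Percentages are reported to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import Hit


@dataclass
class CompletenessReport:
    complete_single: float
    duplicated: float
    fragmented: float
    missing: float
    marker_count: int

    @property
    def combined_complete(self) -> float:
        return round(self.complete_single + self.duplicated, 1)

    def as_dict(self) -> dict:
        return {
            "complete_single": self.complete_single,
            "duplicated": self.duplicated,
            "fragmented": self.fragmented,
            "missing": self.missing,
            "combined_complete": self.combined_complete,
            "marker_count": self.marker_count,
        }


def completeness_report(marker_ids: Iterable[str],
                        hits_markers_vs_proteins: list[Hit],
                        complete_cov: float = 0.7,
                        frag_cov: float = 0.1) -> CompletenessReport:
    """Classify each marker by how completely the proteome covers it.

    ``hits_markers_vs_proteins`` must carry query (= marker) coverages, e.g.
    computed by ``read_hits`` with a marker-length map.
    """
    markers = sorted(set(marker_ids))
    if not markers:
        raise ValueError("empty marker set")
    by_marker: dict[str, list[Hit]] = {m: [] for m in markers}
    for h in hits_markers_vs_proteins:
        if h.query_id in by_marker:
            by_marker[h.query_id].append(h)
    n_single = n_dup = n_frag = n_miss = 0
    for m in markers:
        hits = by_marker[m]
        complete_subjects = {h.subject_id for h in hits
                             if h.query_coverage >= complete_cov}
        if len(complete_subjects) == 1:
            n_single += 1
        elif len(complete_subjects) > 1:
            n_dup += 1
        else:
            best = max((h.query_coverage for h in hits), default=0.0)
            if frag_cov <= best < complete_cov:
                n_frag += 1
            else:
                n_miss += 1
    n = len(markers)
    pct = lambda k: round(100.0 * k / n, 1)  # noqa: E731
    return CompletenessReport(pct(n_single), pct(n_dup), pct(n_frag),
                              pct(n_miss), n)


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int


def assembly_stats(sequences: Iterable[str] | dict[str, str]) -> AssemblyStats:
    """Sequence count, total length, and N50 (shortest length in the set of
    longest sequences jointly covering at least half the total)."""
    if isinstance(sequences, dict):
        lengths = [len(s) for s in sequences.values()]
    else:
        lengths = [len(s) for s in sequences]
    if not lengths:
        raise ValueError("assembly_stats requires at least one sequence")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return AssemblyStats(len(lengths), total, length)
    raise AssertionError("unreachable")
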