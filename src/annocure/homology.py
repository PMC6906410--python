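"""Best-hit and best-reciprocal-hit orthology over filtered BLAST hit sets.

A best-reciprocal hit (BRH) pair across two protein sets is the standard
proxy for one-to-one orthology: each protein is the other's highest-scoring
homology hit.  Ties on bitscore are broken by smaller e-value, then by
lexicographic subject id, so the maps are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .io import Hit


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    bitscore: float
    e_value: float


@dataclass
class BestHitMap:
    """Per-query best subject for one search direction (e.g. ref -> anno)."""

    direction: tuple[str, str]
    mapping: dict[str, BestHit]

    def __getitem__(self, query_id: str) -> BestHit:
        return self.mapping[query_id]

    def __contains__(self, query_id: str) -> bool:
        return query_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def best_hits(hits: list[Hit], direction: tuple[str, str] = ("A", "B"),
              exclude_self: bool = True) -> BestHitMap:
    """Reduce a (pre-filtered) hit list to the best subject per query.

    Best = maximal bitscore; ties broken by smaller e-value, then by
    lexicographically smallest subject id.  Self-hits (query == subject) are
    excluded by default, as they are meaningless in cross-species maps.
    """
    mapping: dict[str, BestHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.e_value, h.subject_id)):
        if exclude_self and h.query_id == h.subject_id:
            continue
        if h.query_id not in mapping:
            mapping[h.query_id] = BestHit(h.subject_id, h.bitscore, h.e_value)
    return BestHitMap(direction, mapping)


def reciprocal_best_hits(map_ab: BestHitMap, map_ba: BestHitMap) -> set[tuple[str, str]]:
    """Extract BRH pairs (a, b): b is a's best hit and a is b's best hit.

    The two maps must be inverse directions of the same search pair.
    """
    if map_ab.direction == map_ba.direction:
        raise ValueError(f"both maps have direction {map_ab.direction}; need inverse directions")
    if map_ab.direction != map_ba.direction[::-1]:
        raise ValueError(
            f"directions {map_ab.direction} and {map_ba.direction} are not inverse")
    pairs = set()
    for a, bh in map_ab.mapping.items():
        back = map_ba.mapping.get(bh.subject_id)
        if back is not None and back.subject_id == a:
            pairs.add((a, bh.subject_id))
    return pairs


_EVALUE_K = 0.1  # fixed prefactor of the toy e-value model K*m*n*2^-score


def toy_similarity(seq_a: str, seq_b: str, match: float = 1.0,
                   mismatch: float = -1.0, gap: float = -1.0) -> tuple[float, float]:
    """Smith-Waterman local alignment score with linear gap penalty, plus a
    toy e-value proxy ``K*m*n*2^-score`` (K fixed at 0.1).

    This is a deliberately simple BLAST stand-in for end-to-end smoke runs;
    no Karlin-Altschul statistics are estimated.  The score is symmetric in
    its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    score = float(aligner.score(seq_a, seq_b))
    e_proxy = _EVALUE_K * len(seq_a) * len(seq_b) * 2.0 ** (-score)
    return score, e_proxy
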