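"""Phylostratigraphy, Markov-clustering orthology, and catalog comparison.

Gene age is estimated phylostratigraphically: outgroup proteomes are pooled
along a ladder-like phylogeny (stratum I = species-specific, higher strata
= progressively more distant outgroups) and each query gene is assigned to
the most distant stratum in which a homolog is detectable.

Ortholog groups are alternatively defined by Markov clustering (MCL) of the
bitscore-weighted similarity graph: the column-stochastic transition matrix
is alternately expanded (squared) and inflated (entrywise power followed by
renormalization) until convergence; clusters are the connected attractor
systems of the limit matrix.  An InParanoid-style rule detects lineage
specific inparalogs: two genes of the same species whose mutual bitscore
exceeds either one's best cross-species bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np

from .classify import percentage
from .io import Hit


@dataclass
class OutgroupLadder:
    """Ordered phylostratum labels, innermost first, with pooled proteomes."""

    labels: list[str]
    proteomes: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate phylostratum labels in ladder")


def assign_phylostrata(query_gene_ids: Iterable[str], ladder: OutgroupLadder,
                       hits_per_set: dict[str, list[Hit]]) -> dict[str, str]:
    """Assign each query gene to the most distant stratum whose pooled
    outgroup set contains a homology hit (tables pre-filtered, conventionally
    at e < 1e-3); genes without any hit fall into the innermost stratum."""
    unknown = set(hits_per_set) - set(ladder.labels)
    if unknown:
        raise ValueError(f"hit tables for unknown strata: {sorted(unknown)}")
    rank = {label: i for i, label in enumerate(ladder.labels)}
    assignment = {g: ladder.labels[0] for g in query_gene_ids}
    for label, hits in hits_per_set.items():
        for h in hits:
            if h.query_id in assignment and rank[label] > rank[assignment[h.query_id]]:
                assignment[h.query_id] = label
    return assignment


@dataclass
class OrthoCluster:
    cluster_id: str
    members: dict[str, list[str]]  # species -> gene ids
    relation_class: str

    @property
    def genes(self) -> list[str]:
        return sorted(g for ids in self.members.values() for g in ids)


def _relation_class(members: dict[str, list[str]],
                    species_pair: tuple[str, str]) -> str:
    n_a = len(members.get(species_pair[0], []))
    n_b = len(members.get(species_pair[1], []))
    if n_a == 0 or n_b == 0:
        return "species_specific"
    if n_a == 1 and n_b == 1:
        return "one_to_one"
    if n_a == 1:
        return "one_to_many"
    if n_b == 1:
        return "many_to_one"
    return "many_to_many"


def mcl(matrix: np.ndarray, inflation: float = 1.5, tol: float = 1e-6,
        max_iter: int = 100,
        on_iteration: Callable[[np.ndarray], None] | None = None) -> np.ndarray:
    """Run Markov clustering on a non-negative symmetric weight matrix and
    return the limit matrix.  Self-loops (weight = max incident edge, or 1
    for isolated nodes) are added before column normalization, the usual
    guard against parity effects of pure expansion."""
    if not np.all(np.isfinite(matrix)) or np.any(matrix < 0):
        raise ValueError("MCL requires finite non-negative weights")
    m = matrix.astype(float).copy()
    if m.size == 0:
        return m
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated /= inflated.sum(axis=0, keepdims=True)
        if on_iteration is not None:
            on_iteration(inflated)
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            break
        m = inflated
    return m


def mcl_orthology(edges: Iterable[tuple[str, str, float]],
                  species_of: dict[str, str],
                  species_pair: tuple[str, str] | None = None,
                  inflation: float = 1.5, tol: float = 1e-6,
                  max_iter: int = 100,
                  on_iteration: Callable[[np.ndarray], None] | None = None
                  ) -> list[OrthoCluster]:
    """Cluster a bitscore-weighted similarity graph into ortholog groups.

    Nodes are genes; ``species_of`` maps each gene to its species.  The
    relation class of each cluster is derived from per-species member counts
    for ``species_pair`` (default: the first two species names in sorted
    order)."""
    nodes = sorted(species_of)
    index = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, weight in edges:
        if a == b:
            continue
        if not np.isfinite(weight):
            raise ValueError(f"non-finite weight on edge ({a}, {b})")
        i, j = index[a], index[b]
        w[i, j] = max(w[i, j], float(weight))
        w[j, i] = w[i, j]
    limit = mcl(w, inflation=inflation, tol=tol, max_iter=max_iter,
                on_iteration=on_iteration)
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i, j in zip(*np.nonzero(limit > tol)):
        if i != j:
            g.add_edge(int(i), int(j))
    if species_pair is None:
        uniq = sorted(set(species_of.values()))
        species_pair = (uniq[0], uniq[1] if len(uniq) > 1 else uniq[0])
    clusters = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(nodes[i] for i in c))
    for k, comp in enumerate(comps):
        members: dict[str, list[str]] = {}
        for i in sorted(comp):
            members.setdefault(species_of[nodes[i]], []).append(nodes[i])
        clusters.append(OrthoCluster(f"cluster_{k:05d}", members,
                                     _relation_class(members, species_pair)))
    return clusters


def detect_inparalogs(within_species_hits: list[Hit],
                      cross_best_bitscore: dict[str, float]) -> list[set[str]]:
    """Group same-species genes whose mutual bitscore exceeds both genes'
    best cross-species bitscores (lineage-specific duplicates postdating the
    speciation).  Genes without any cross-species hit score 0.  Groups are
    connected components of the qualifying-pair graph."""
    pair_score: dict[tuple[str, str], float] = {}
    for h in within_species_hits:
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        pair_score[key] = max(pair_score.get(key, 0.0), h.bitscore)
    g = nx.Graph()
    for (a, b), s in pair_score.items():
        if (s > cross_best_bitscore.get(a, 0.0)
                and s > cross_best_bitscore.get(b, 0.0)):
            g.add_edge(a, b)
    return sorted(nx.connected_components(g), key=min)


def compare_catalogs(brh_pairs: set[tuple[str, str]],
                     clusters: list[OrthoCluster],
                     species_pair: tuple[str, str],
                     inparalog_groups: list[set[str]] | None = None) -> dict:
    """Compare the BRH catalog with the cluster-derived one-to-one catalog.

    Reports the fraction of cluster one-to-one pairs also found by BRH, the
    fraction with the identical partner, and how many BRH genes without a
    cluster one-to-one assignment are explicable by inparalog expansion."""
    inparalog_groups = inparalog_groups or []
    brh_partner = dict(brh_pairs)
    cluster_pairs = []
    for c in clusters:
        if c.relation_class == "one_to_one":
            a = c.members[species_pair[0]][0]
            b = c.members[species_pair[1]][0]
            cluster_pairs.append((a, b))
    in_brh = [p for p in cluster_pairs if p[0] in brh_partner]
    same_partner = [p for p in in_brh if brh_partner[p[0]] == p[1]]
    o2o_a_genes = {a for a, _ in cluster_pairs}
    unexplained = sorted({a for a in brh_partner if a not in o2o_a_genes})
    in_group = {g for grp in inparalog_groups for g in grp}
    explained = [a for a in unexplained
                 if a in in_group or brh_partner[a] in in_group]
    return {
        "n_brh": len(brh_pairs),
        "n_clusters": len(clusters),
        "n_cluster_one_to_one": len(cluster_pairs),
        "pct_one_to_one_in_brh": percentage(len(in_brh), len(cluster_pairs)),
        "pct_identical_partner": percentage(len(same_partner), len(in_brh)),
        "n_brh_without_cluster_one_to_one": len(unexplained),
        "n_explained_by_inparalogs": len(explained),
        "pct_explained_by_inparalogs": percentage(len(explained), len(unexplained)),
    }
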