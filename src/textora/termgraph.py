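"""Graph-based post-processing of enriched terms.

Two stages act on an enrichment table:

* **Sub-term filtering** removes strictly redundant terms.  Terms whose
  entity sets are in a subset relation (the smaller fully contained in the
  larger) are connected; edges survive only between string sub-terms
  ("olfactory" vs "olfactory receptor"); a term is then dropped unless it
  is the highest-ranked among itself and its neighbors.

* **Term grouping** clusters the surviving, conceptually related terms.
  Edge weight is the product of the cosine similarity of two terms'
  tf-idf vectors restricted to the query genes and over all genes; weak
  edges (w < 0.15) are cut and greedy modularity maximization finds the
  communities, each labelled by its three top-ranked terms joined by " | ".

Ranking everywhere is effect size desc, FDR asc, total info desc, then
lexicographic — a strict total order, so results are independent of input
row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TYPE_CHECKING

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ParameterError
from .vectorize import TermMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .enrich import EnrichmentRow

__all__ = [
    "TermGroup",
    "rank_key",
    "is_subterm",
    "filter_subterms",
    "group_weight",
    "group_terms",
]


@dataclass
class TermGroup:
    """A community of related enriched terms."""

    label: str
    members: list[str]


def rank_key(row: "EnrichmentRow") -> tuple:
    """Total-order ranking key: effect desc, fdr asc, total info desc, term asc."""
    return (-row.effect_size, row.fdr, -row.total_info, row.term)


def _term_strings(term: str, synonyms: Mapping[str, Sequence[str]] | None) -> list[str]:
    """Strings a term stands for: its members if a synonym label, else itself."""
    if synonyms and term in synonyms:
        return list(synonyms[term])
    return [term.lstrip("~")]


def _contiguous_subseq(a: Sequence[str], b: Sequence[str]) -> bool:
    if len(a) > len(b):
        return False
    return any(tuple(b[i : i + len(a)]) == tuple(a) for i in range(len(b) - len(a) + 1))


def is_subterm(
    t1: str, t2: str, synonyms: Mapping[str, Sequence[str]] | None = None
) -> bool:
    """True if either term's token sequence is a contiguous subsequence of the
    other's (synonym labels compared via their member strings)."""
    for s1 in _term_strings(t1, synonyms):
        for s2 in _term_strings(t2, synonyms):
            a, b = s1.split(), s2.split()
            if _contiguous_subseq(a, b) or _contiguous_subseq(b, a):
                return True
    return False


def filter_subterms(
    rows: Sequence["EnrichmentRow"],
    gene_sets: Mapping[str, set],
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> list["EnrichmentRow"]:
    """Drop enriched terms that are redundant with a sub/super-term neighbor.

    Edges connect terms whose gene sets are in a subset relation AND that are
    string sub-terms of one another; each term survives only if it is the
    highest-ranked among itself and its neighbors (single pass over the
    original graph).
    """
    if not rows:
        return []
    key = {r.term: rank_key(r) for r in rows}
    terms = sorted(key, key=key.get)
    neighbors: dict[str, list[str]] = {t: [] for t in terms}
    for i, t1 in enumerate(terms):
        s1 = gene_sets[t1]
        for t2 in terms[i + 1 :]:
            s2 = gene_sets[t2]
            if (s1 <= s2 or s2 <= s1) and is_subterm(t1, t2, synonyms):
                neighbors[t1].append(t2)
                neighbors[t2].append(t1)
    keep = {
        t
        for t in terms
        if all(key[t] <= key[u] for u in neighbors[t])
    }
    return [r for r in rows if r.term in keep]


def _cosine_columns(X: sp.spmatrix, j1: int, j2: int) -> float:
    v1 = np.asarray(X[:, j1].todense()).ravel()
    v2 = np.asarray(X[:, j2].todense()).ravel()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("cosine similarity undefined for a zero vector")
    return float(v1 @ v2 / (n1 * n2))


def group_weight(
    t1: str, t2: str, matrix: TermMatrix, query_entities: Sequence[str]
) -> float:
    """Edge weight between two terms: cossim over query genes × cossim over
    all genes.  tf-idf is non-negative, so the product lies in [0, 1]."""
    j1, j2 = matrix.term_index(t1), matrix.term_index(t2)
    q_idx = [matrix.entity_index(e) for e in query_entities]
    wq = _cosine_columns(matrix.values[q_idx], j1, j2)
    wg = _cosine_columns(matrix.values, j1, j2)
    return max(0.0, wq * wg)


def _pairwise_weights(
    terms: Sequence[str], matrix: TermMatrix, query_entities: Sequence[str]
) -> np.ndarray:
    cols = [matrix.term_index(t) for t in terms]
    Xq = np.asarray(matrix.values[[matrix.entity_index(e) for e in query_entities]][:, cols].todense())
    Xg = np.asarray(matrix.values[:, cols].todense())

    def cos(X: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        Xn = X / norms
        return Xn.T @ Xn

    W = cos(Xq) * cos(Xg)
    return np.clip(W, 0.0, 1.0)


def group_terms(
    rows: Sequence["EnrichmentRow"],
    matrix: TermMatrix,
    query_entities: Sequence[str],
    weight_threshold: float = 0.15,
) -> tuple[list[TermGroup], dict[str, str]]:
    """Group retained terms into communities of related concepts.

    Edges weaker than ``weight_threshold`` are removed; greedy modularity
    maximization (edge-weighted) finds communities; isolated terms form
    singleton groups.  Returns the groups plus a term → group-label map.
    """
    if not rows:
        return [], {}
    key = {r.term: rank_key(r) for r in rows}
    terms = sorted(key, key=key.get)
    G = nx.Graph()
    G.add_nodes_from(terms)
    if len(terms) > 1:
        W = _pairwise_weights(terms, matrix, query_entities)
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                if W[i, j] >= weight_threshold:
                    G.add_edge(terms[i], terms[j], weight=float(W[i, j]))

    communities: list[list[str]] = []
    for comp in nx.connected_components(G):
        comp = sorted(comp, key=key.get)
        if len(comp) == 1:
            communities.append(comp)
            continue
        sub = G.subgraph(comp)
        # node insertion order is rank order, which fixes tie-breaking
        for c in nx.community.greedy_modularity_communities(sub, weight="weight"):
            communities.append(sorted(c, key=key.get))

    groups: list[TermGroup] = []
    label_of: dict[str, str] = {}
    for members in sorted(communities, key=lambda ms: key[ms[0]]):
        label = " | ".join(members[:3])
        groups.append(TermGroup(label=label, members=list(members)))
        for t in members:
            label_of[t] = label
    return groups, label_of
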