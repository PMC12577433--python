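"""Synonym-set learning by density clustering of token embeddings.

Vocabularies extracted from biomedical prose are full of interchangeable
surface forms — plural/singular pairs ("oncogene"/"oncogenes"), an
abbreviation and its expansion ("UPR"/"unfolded protein response").  We
collapse these by embedding every token, clustering over pairwise cosine
distance with HDBSCAN (min_cluster_size=2, min_samples=2), and treating
every cluster as a synonym set labelled ``~`` + its most document-frequent
member.  Members become drop-in replacements for the label throughout the
corpus.

The embedder is a pluggable contract.  The shipped default is a
deterministic character-n-gram hashing embedder, suitable for offline
builds and tests; an adapter for a pretrained transformer encoder can be
substituted without touching the clustering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import HDBSCAN
from sklearn.metrics import homogeneity_completeness_v_measure
from sklearn.preprocessing import normalize

from .corpus import TokenizedSentence
from .errors import ContractError, ParameterError

__all__ = [
    "TokenEmbedder",
    "HashingNgramEmbedder",
    "TokenEmbeddingTable",
    "SynonymSet",
    "embed_tokens",
    "cluster_synonyms",
    "apply_synonyms",
    "clustering_agreement",
    "synonym_map",
]


class TokenEmbedder(Protocol):
    """Contract: map token strings to fixed-length finite vectors,
    deterministically for a fixed configuration."""

    dim: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray:  # (n_tokens, dim)
        ...


class HashingNgramEmbedder:
    """Deterministic character-n-gram hashing embedder.

    Each token is padded (``^token$``), decomposed into character n-grams,
    and each n-gram is hashed into one of ``dim`` signed buckets (the signs
    keep unrelated tokens near-orthogonal in expectation).  Vectors are L2
    normalized.  Spelling variants share most n-grams and land close in
    cosine space, which is exactly the signal the synonym clustering needs.
    """

    def __init__(self, dim: int = 256, ngram: int = 3):
        if dim < 8 or ngram < 2:
            raise ParameterError("dim must be >= 8 and ngram >= 2")
        self.dim = dim
        self.ngram = ngram

    def _vector(self, token: str) -> np.ndarray:
        v = np.zeros(self.dim)
        s = f"^{token.lower()}$"
        n = self.ngram
        grams = [s[i : i + n] for i in range(max(1, len(s) - n + 1))]
        for g in grams:
            h = int.from_bytes(
                hashlib.blake2b(g.encode("utf-8"), digest_size=8).digest(), "big"
            )
            sign = 1.0 if (h >> 62) & 1 else -1.0
            v[h % self.dim] += sign
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not len(tokens):
            return np.zeros((0, self.dim))
        return np.stack([self._vector(t) for t in tokens])


@dataclass
class TokenEmbeddingTable:
    """One fixed-length vector per vocabulary token."""

    tokens: list[str]
    vectors: np.ndarray  # (n_tokens, dim)
    dim: int

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.tokens), self.dim):
            raise ContractError(
                f"embedding shape {self.vectors.shape} does not match "
                f"({len(self.tokens)}, {self.dim})"
            )
        if len(self.tokens) and not np.all(np.isfinite(self.vectors)):
            raise ContractError("embedding contains non-finite values")


@dataclass
class SynonymSet:
    """A cluster of interchangeable tokens.

    The label is ``~`` + the member with the highest document frequency
    (ties broken lexicographically); every token belongs to at most one set.
    """

    label: str
    members: list[str]
    member_df: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label.startswith("~"):
            raise ParameterError("SynonymSet label must start with '~'")
        if len(self.members) < 2:
            raise ParameterError("SynonymSet needs at least 2 members")


def label_for(members: Sequence[str], df: Mapping[str, int]) -> str:
    """Naming rule: '~' + most document-frequent member, ties lexicographic."""
    best = sorted(members, key=lambda t: (-df.get(t, 0), t))[0]
    return "~" + best


def embed_tokens(tokens: Sequence[str], embedder: TokenEmbedder) -> TokenEmbeddingTable:
    """Embed a vocabulary with the given embedder, preserving order."""
    vectors = embedder.embed(list(tokens))
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or (len(tokens) and vectors.shape[1] != embedder.dim):
        raise ContractError(
            f"embedder returned shape {vectors.shape}, expected (*, {embedder.dim})"
        )
    return TokenEmbeddingTable(tokens=list(tokens), vectors=vectors, dim=embedder.dim)


def cluster_synonyms(
    table: TokenEmbeddingTable,
    df: Mapping[str, int],
    *,
    min_cluster_size: int = 2,
    min_samples: int = 2,
    max_distance: float | None = 0.3,
) -> list[SynonymSet]:
    """Density-cluster token embeddings over cosine distance into synonym sets.

    Noise points stay unclustered (they remain ordinary standalone terms).
    Embeddings are L2-normalized first — cosine distance is scale-invariant,
    so clustering must be too.  Raw density clusters are then refined:
    synonyms are near-duplicates in embedding space, so each cluster is
    split into connected components of its ``distance <= max_distance``
    graph and undersized components revert to noise — without this, density
    clustering chains through the near-orthogonal bulk of the vocabulary
    and merges unrelated tokens.  Pass ``max_distance=None`` to disable.
    """
    if len(table.tokens) < 2:
        raise ParameterError("need at least 2 tokens to cluster")
    V = normalize(table.vectors.astype(np.float64))
    dist = 1.0 - V @ V.T
    np.clip(dist, 0.0, 2.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        metric="precomputed",
        copy=True,
    ).fit_predict(dist)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            clusters.setdefault(int(lab), []).append(i)
    member_groups: list[list[str]] = []
    for idx in clusters.values():
        if max_distance is None:
            member_groups.append([table.tokens[i] for i in idx])
            continue
        sub = dist[np.ix_(idx, idx)] <= max_distance
        n_comp, comp = connected_components(csr_matrix(sub), directed=False)
        for c in range(n_comp):
            group = [table.tokens[idx[i]] for i in np.flatnonzero(comp == c)]
            if len(group) >= min_cluster_size:
                member_groups.append(group)
    sets = []
    for members in member_groups:
        members = sorted(members)
        sets.append(
            SynonymSet(
                label=label_for(members, df),
                members=members,
                member_df={m: int(df.get(m, 0)) for m in members},
            )
        )
    sets.sort(key=lambda s: s.label)
    # guard against pathological duplicate labels across clusters
    seen: dict[str, int] = {}
    for s in sets:
        if s.label in seen:
            seen[s.label] += 1
            s.label = f"{s.label}#{seen[s.label]}"
        else:
            seen[s.label] = 0
    return sets


def synonym_map(sets: Sequence[SynonymSet]) -> dict[str, str]:
    """member → label mapping; raises if sets overlap."""
    mapping: dict[str, str] = {}
    for s in sets:
        for m in s.members:
            if m in mapping:
                raise ParameterError(f"token {m!r} belongs to more than one SynonymSet")
            mapping[m] = s.label
    return mapping


def apply_synonyms(
    sentences: Sequence[TokenizedSentence], sets: Sequence[SynonymSet]
) -> list[TokenizedSentence]:
    """Replace every member occurrence (word or phrase term) by its set label.

    Token counts are conserved: replacement is one-for-one in place.
    """
    mapping = synonym_map(sets)
    out: list[TokenizedSentence] = []
    for ts in sentences:
        out.append(
            TokenizedSentence(
                entity=ts.entity,
                source=ts.source,
                sentence_index=ts.sentence_index,
                text=ts.text,
                tokens=[mapping.get(t, t) for t in ts.tokens],
                token_spans=list(ts.token_spans),
                phrases=[(mapping.get(p, p), i, j) for p, i, j in ts.phrases],
            )
        )
    return out


def clustering_agreement(
    predicted: Mapping[str, object], reference: Mapping[str, object]
) -> tuple[float, float, float]:
    """Entropy-based agreement between two token partitions.

    Both partitions are restricted to their common token universe first.
    Returns (homogeneity, completeness, v_measure), each in [0, 1].
    """
    common = sorted(set(predicted) & set(reference))
    if not common:
        raise ParameterError("partitions share no tokens")
    ref_ids = {c: i for i, c in enumerate(dict.fromkeys(reference[t] for t in common))}
    pred_ids = {c: i for i, c in enumerate(dict.fromkeys(predicted[t] for t in common))}
    h, c, v = homogeneity_completeness_v_measure(
        [ref_ids[reference[t]] for t in common],
        [pred_ids[predicted[t]] for t in common],
    )
    return float(h), float(c), float(v)
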