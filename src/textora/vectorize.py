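"""tf-idf embedding of entity descriptions and derived artifacts.

Each entity's descriptions (all sources concatenated) form one document.
The entity-by-term matrix weights raw term counts by smoothed inverse
document frequency, idf = ln((1+N)/(1+df)) + 1, followed by L2 row
normalization — a tf-idf value is interpretable as mutual information
between term and entity, and its per-term sums drive the effect sizes
reported downstream.  Binarizing the matrix yields a de novo gene-set
database: term → set of entities whose description mentions it.

Also here: the custom stopword rules (embedding-similarity to common words,
all-stopword phrases, majority-stopword synonym sets, high gene fraction)
and the truncated-SVD latent semantic embedding used for gene-gene
similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.preprocessing import normalize

from .corpus import TokenizedSentence
from .errors import FitError, LookupError_, ParameterError
from .synonyms import SynonymSet, TokenEmbedder

__all__ = [
    "TermMatrix",
    "StopwordList",
    "LsaEmbedding",
    "CHROMOSOME_LOCATION",
    "count_terms",
    "fit_tfidf",
    "binarize",
    "derive_stopwords",
    "lsa",
    "gene_similarity",
]

#: cytogenetic band names like "19q13" or "Xp21.3" look like high-frequency
#: junk but are biologically meaningful; they are never stopworded.
CHROMOSOME_LOCATION = re.compile(r"^([0-9]{1,2}|[XY])[pq][0-9]+(\.[0-9]+)?$")


@dataclass
class TermMatrix:
    """Sparse entity-by-term tf-idf matrix with its fit parameters."""

    entities: list[str]
    terms: list[str]
    values: sp.csr_matrix
    df: np.ndarray  # document frequency per retained term
    params: dict

    def __post_init__(self) -> None:
        self._entity_pos = {e: i for i, e in enumerate(self.entities)}
        self._term_pos = {t: j for j, t in enumerate(self.terms)}

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    def entity_index(self, entity: str) -> int:
        try:
            return self._entity_pos[entity]
        except KeyError:
            raise LookupError_(f"unknown entity {entity!r}") from None

    def term_index(self, term: str) -> int:
        try:
            return self._term_pos[term]
        except KeyError:
            raise LookupError_(f"unknown term {term!r}") from None

    def has_entity(self, entity: str) -> bool:
        return entity in self._entity_pos

    def has_term(self, term: str) -> bool:
        return term in self._term_pos


@dataclass
class StopwordList:
    """Terms excluded from enrichment, with the rule that flagged each."""

    terms: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class LsaEmbedding:
    """Unit-norm rows of a rank-k SVD of the tf-idf matrix."""

    entities: list[str]
    vectors: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self._pos = {e: i for i, e in enumerate(self.entities)}

    def row(self, entity: str) -> np.ndarray:
        try:
            return self.vectors[self._pos[entity]]
        except KeyError:
            raise LookupError_(f"unknown entity {entity!r}") from None


def count_terms(
    corpus: Sequence[TokenizedSentence],
) -> tuple[list[str], list[str], sp.csr_matrix]:
    """Aggregate a tokenized corpus into an entity-by-term count matrix.

    All sentences of an entity (across sources) are pooled into one document.
    Entity order follows first appearance; term order is lexicographic.
    """
    entities: list[str] = []
    e_pos: dict[str, int] = {}
    counts: list[dict[str, int]] = []
    for ts in corpus:
        if ts.entity not in e_pos:
            e_pos[ts.entity] = len(entities)
            entities.append(ts.entity)
            counts.append({})
        c = counts[e_pos[ts.entity]]
        for term, n in ts.term_counts().items():
            c[term] = c.get(term, 0) + n
    terms = sorted({t for c in counts for t in c})
    t_pos = {t: j for j, t in enumerate(terms)}
    rows, cols, data = [], [], []
    for i, c in enumerate(counts):
        for t, n in c.items():
            rows.append(i)
            cols.append(t_pos[t])
            data.append(n)
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(entities), len(terms)), dtype=np.float64
    )
    return entities, terms, X


def fit_tfidf(
    corpus: Sequence[TokenizedSentence],
    max_df: float = 0.6,
    min_df: int = 3,
    *,
    binary: bool = False,
    idf: str = "smooth",
    norm: str | None = "l2",
    sublinear_tf: bool = False,
) -> TermMatrix:
    """Fit the entity-by-term tf-idf matrix.

    Terms outside the document-frequency bounds (df < min_df or
    df/N > max_df) are dropped before weighting.  ``idf`` is "smooth"
    (ln((1+N)/(1+df)) + 1) or "plain" (ln(N/df) + 1); ``norm`` is "l2" or
    None.  Both are recorded in params.
    """
    entities, terms, X = count_terms(corpus)
    n = len(entities)
    if n < min_df:
        raise FitError(f"need at least min_df={min_df} entities, got {n}")
    df_all = np.asarray((X > 0).sum(axis=0)).ravel().astype(int)
    keep = (df_all >= min_df) & (df_all <= max_df * n)
    if not keep.any():
        raise FitError("vocabulary is empty after document-frequency filtering")
    terms = [t for t, k in zip(terms, keep) if k]
    X = X[:, keep]
    df = df_all[keep]
    if binary:
        X = (X > 0).astype(np.float64)
    transformer = TfidfTransformer(
        norm=norm,
        use_idf=True,
        smooth_idf=(idf == "smooth"),
        sublinear_tf=sublinear_tf,
    )
    values = sp.csr_matrix(transformer.fit_transform(X))
    values.sort_indices()
    params = {
        "max_df": max_df,
        "min_df": min_df,
        "binary": binary,
        "idf": idf,
        "norm": norm,
        "sublinear_tf": sublinear_tf,
    }
    return TermMatrix(entities=entities, terms=terms, values=values, df=df, params=params)


def binarize(matrix: TermMatrix) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """The de novo gene-set database: term → entities and entity → terms."""
    csc = matrix.values.tocsc()
    term_to_entities: dict[str, set[str]] = {}
    for j, term in enumerate(matrix.terms):
        rows = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
        ents = {matrix.entities[i] for i in rows}
        assert ents, "df filtering guarantees no empty column"
        term_to_entities[term] = ents
    entity_to_terms: dict[str, set[str]] = {e: set() for e in matrix.entities}
    for term, ents in term_to_entities.items():
        for e in ents:
            entity_to_terms[e].add(term)
    return term_to_entities, entity_to_terms


def _pearson_to_centroid(vectors: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of embedding vectors with a centroid."""
    vc = vectors - vectors.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    denom = np.linalg.norm(vc, axis=1) * np.linalg.norm(cc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ cc) / denom
    return np.nan_to_num(r, nan=0.0)


def derive_stopwords(
    matrix: TermMatrix,
    common_words: Sequence[str],
    embedder: TokenEmbedder,
    synonym_sets: Sequence[SynonymSet] = (),
    *,
    corr_threshold: float = 0.65,
    gene_fraction: float = 0.15,
    synonym_fraction: float = 0.5,
) -> StopwordList:
    """Derive custom stopwords from four cumulative rules.

    1. centroid-correlation: terms whose embedding correlates (Pearson
       r > corr_threshold) with the mean embedding of the common-word list;
    2. all-stopword-phrase: phrases made up entirely of rule-1 stopwords;
    3. majority-stopword-synonym: synonym labels whose members are more than
       ``synonym_fraction`` stopwords;
    4. high-gene-fraction: terms present in more than ``gene_fraction`` of
       entities.

    Fully-uppercase terms and chromosomal-location terms are exempt: they
    are symbols/bands whose ubiquity is still informative.
    """
    if not len(common_words):
        raise ParameterError("common word list must be non-empty")
    centroid = embedder.embed(list(common_words)).mean(axis=0)
    provenance: dict[str, str] = {}

    unigrams = [t for t in matrix.terms if " " not in t and not t.startswith("~")]
    if unigrams:
        corr = _pearson_to_centroid(embedder.embed(unigrams), centroid)
        for t, r in zip(unigrams, corr):
            if r > corr_threshold:
                provenance[t] = "centroid-correlation"
    rule1 = set(provenance)

    for t in matrix.terms:
        if " " in t and t not in provenance:
            words = t.split()
            if words and all(w in rule1 for w in words):
                provenance[t] = "all-stopword-phrase"
    # synonym members were replaced by their label and are no longer matrix
    # terms, so they are scored against the centroid directly (a multi-word
    # member counts as a stopword when all its words do)
    member_words = sorted(
        {w for s in synonym_sets for m in s.members for w in m.split()}
    )
    common_word: dict[str, bool] = {}
    if member_words:
        corr = _pearson_to_centroid(embedder.embed(member_words), centroid)
        common_word = {w: r > corr_threshold for w, r in zip(member_words, corr)}
    for s in synonym_sets:
        if s.label in matrix._term_pos and s.label not in provenance:
            n_stop = sum(
                1
                for m in s.members
                if m.split() and all(common_word.get(w, False) for w in m.split())
            )
            if n_stop / len(s.members) > synonym_fraction:
                provenance[s.label] = "majority-stopword-synonym"

    frac_df = matrix.df / matrix.n_entities
    for t, f in zip(matrix.terms, frac_df):
        if f > gene_fraction and t not in provenance:
            provenance[t] = "high-gene-fraction"

    for t in list(provenance):
        bare = t.lstrip("~")
        if (bare.isupper() and bare.isalpha()) or CHROMOSOME_LOCATION.match(bare):
            del provenance[t]

    return StopwordList(terms=set(provenance), provenance=provenance)


def lsa(
    matrix: TermMatrix, k: int = 500, rows: Iterable[str] | None = None
) -> LsaEmbedding:
    """Latent semantic embedding: rank-k truncated SVD, then unit-norm rows."""
    if rows is None:
        entities = list(matrix.entities)
        X = matrix.values
    else:
        entities = [e for e in rows]
        idx = [matrix.entity_index(e) for e in entities]
        X = matrix.values[idx]
    if not (0 < k < min(X.shape)):
        raise ParameterError(
            f"k={k} must satisfy 0 < k < min(n_entities, n_terms)={min(X.shape)}"
        )
    svd = TruncatedSVD(n_components=k, algorithm="arpack", random_state=0)
    Z = svd.fit_transform(X)
    Z = normalize(Z)
    return LsaEmbedding(entities=entities, vectors=Z, k=k)


def gene_similarity(embedding: LsaEmbedding, a: str, b: str) -> float:
    """Cosine similarity of two entities in the LSA embedding."""
    return float(np.clip(embedding.row(a) @ embedding.row(b), -1.0, 1.0))
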