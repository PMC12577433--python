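"""Overrepresentation testing of query gene lists against the learned model.

Per candidate term the number of query genes whose description contains the
term is compared with its prevalence in the background using the upper-tail
hypergeometric probability P(X >= k); Benjamini-Hochberg step-up correction
converts p-values to FDRs.  The BH family is the full model vocabulary —
every term is tested on every query, so the family does not depend on the
observed overlaps (conditioning the family on k >= 2 would select exactly
the small p-values and destroy null calibration for short queries).  The
stopword and single-gene (k < 2) filters are applied to the thresholded
results afterwards; the family size m is reported in the result metadata.

Effect size is the sum of a term's tf-idf values over the query genes (its
information content within the query); the same sum over all genes is the
total information.  tf-idf values are frozen at training time: a custom
background changes K and N but never re-weights the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import LookupError_, ParameterError, QueryError
from . import termgraph

__all__ = [
    "Query",
    "EnrichmentRow",
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
    "excerpts_for",
]


@dataclass
class Query:
    """A gene list to test, with optional custom background universe."""

    genes: set[str]
    background: set[str] | None = None
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if self.background is not None:
            self.background = set(self.background)
        if not 0 < self.fdr_threshold <= 1:
            raise ParameterError("fdr_threshold must be in (0, 1]")


@dataclass
class EnrichmentRow:
    """One enriched term with its test statistics."""

    term: str
    k: int            # query genes containing the term
    K: int            # background genes containing the term
    n: int            # query size (after intersection)
    N: int            # background size
    p_value: float
    fdr: float
    effect_size: float
    total_info: float
    matching_genes: list[str] = field(default_factory=list)
    group_label: str | None = None


@dataclass
class EnrichmentResult:
    """Enriched rows, their term groups, and query provenance metadata."""

    rows: list[EnrichmentRow]
    groups: list[termgraph.TermGroup] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        cols = [
            "term", "k", "K", "n", "N", "p_value", "fdr",
            "effect_size", "total_info", "matching_genes", "group_label",
        ]
        data = [
            {
                **{c: getattr(r, c) for c in cols if c != "matching_genes"},
                "matching_genes": ";".join(r.matching_genes),
            }
            for r in self.rows
        ]
        return pd.DataFrame(data, columns=cols)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts how many of n draws (without replacement, from a universe of N
    containing K marked items) are marked.  k = 0 gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ParameterError(f"invalid margins K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ParameterError(f"k={k} outside [0, min(n={n}, K={K})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _hypergeom_tail_vec(k: np.ndarray, K: np.ndarray, n: int, N: int) -> np.ndarray:
    return stats.hypergeom.sf(k - 1, N, K, n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ParameterError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return np.asarray(stats.false_discovery_control(p, method="bh"))


def enrich(
    model,
    query: Query,
    *,
    apply_graph: bool = True,
    keep_all: bool = False,
) -> EnrichmentResult:
    """Run the full overrepresentation pipeline for a query.

    ``model`` supplies ``matrix`` (TermMatrix), ``stopwords`` (StopwordList)
    and optionally synonym sets and excerpts.  With ``keep_all`` the
    unfiltered candidate rows are returned (no FDR threshold, no graph
    post-processing) — useful for p-value calibration audits.
    """
    matrix = model.matrix
    stopwords = model.stopwords
    model_entities = set(matrix.entities)

    genes_in = sorted(query.genes & model_entities)
    dropped = sorted(query.genes - model_entities)
    if not genes_in:
        raise QueryError("no query gene is present in the model")

    if query.background is None:
        background = sorted(model_entities)
    else:
        background = sorted(query.background & model_entities)
        missing = sorted(set(genes_in) - set(background))
        if missing:
            raise ParameterError(
                f"query genes outside the background: {', '.join(missing)}"
            )
    n, N = len(genes_in), len(background)
    if N < n:
        raise ParameterError("background smaller than query")

    B = (matrix.values > 0).astype(np.int8)  # binary incidence
    q_idx = [matrix.entity_index(g) for g in genes_in]
    b_idx = [matrix.entity_index(g) for g in background]
    k_vec = np.asarray(B[q_idx].sum(axis=0)).ravel()
    K_vec = np.asarray(B[b_idx].sum(axis=0)).ravel()
    # a query gene outside a custom background could make k exceed K; the
    # precondition genes ⊆ background (checked above) rules that out
    k_vec = np.minimum(k_vec, K_vec)

    # the whole vocabulary is tested on every query: the BH family must not
    # depend on the observed overlaps
    p = _hypergeom_tail_vec(k_vec, K_vec, n, N)
    fdr = bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0))

    not_stop = np.array([t not in stopwords for t in matrix.terms])
    metadata = {
        "n_query": n,
        "n_background": N,
        "dropped_symbols": dropped,
        "m_tests": len(matrix.terms),
        "fdr_threshold": query.fdr_threshold,
        "bh_family": "all model terms; stopword and k<2 filters applied after thresholding",
    }
    if keep_all:
        selected = np.arange(len(matrix.terms))
    else:
        selected = np.flatnonzero(
            (fdr < query.fdr_threshold) & (k_vec >= 2) & (K_vec >= 2) & not_stop
        )

    effect = np.asarray(matrix.values[q_idx].sum(axis=0)).ravel()
    total = np.asarray(matrix.values.sum(axis=0)).ravel()
    Bq = B[q_idx].tocsc()

    rows: list[EnrichmentRow] = []
    for j in selected:
        members = Bq.indices[Bq.indptr[j] : Bq.indptr[j + 1]]
        rows.append(
            EnrichmentRow(
                term=matrix.terms[j],
                k=int(k_vec[j]),
                K=int(K_vec[j]),
                n=n,
                N=N,
                p_value=float(p[j]),
                fdr=float(fdr[j]),
                effect_size=float(effect[j]),
                total_info=float(total[j]),
                matching_genes=sorted(genes_in[i] for i in members),
            )
        )

    groups: list[termgraph.TermGroup] = []
    if rows and apply_graph and not keep_all:
        term_sets = getattr(model, "gene_sets", None)
        if term_sets is None:
            from .vectorize import binarize

            term_sets, _ = binarize(matrix)
        gene_sets = {r.term: term_sets[r.term] for r in rows}
        synonyms = getattr(model, "synonym_members", None)
        rows = termgraph.filter_subterms(rows, gene_sets, synonyms)
        groups, label_of = termgraph.group_terms(rows, matrix, genes_in)
        for r in rows:
            r.group_label = label_of.get(r.term)

    rows.sort(key=termgraph.rank_key)
    return EnrichmentResult(rows=rows, groups=groups, metadata=metadata)


def excerpts_for(model, term: str, genes: Sequence[str]) -> list[dict]:
    """Source-sentence excerpts for a term, restricted to the given genes."""
    if not model.matrix.has_term(term):
        raise LookupError_(f"term {term!r} is not in the model vocabulary")
    return model.excerpt_index.lookup(term, entities=genes)
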