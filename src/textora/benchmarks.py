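"""Offline evaluation procedures for a fitted model.

These audits quantify the statistical behaviour of the whole pipeline:
whether random gene lists (which should find nothing) ever produce enriched
terms; whether gene sets drawn from the model's own database are
distinguished from size-matched random sets; how overlapping the de novo
gene sets are; and whether two independently trained models place the same
entities near each other in term space (cross-model k-nearest-neighbour
recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.neighbors import NearestNeighbors

from .enrich import Query, enrich
from .errors import ParameterError
from .vectorize import TermMatrix

__all__ = [
    "FdrAuditResult",
    "KnnRecovery",
    "DEFAULT_QUERY_LENGTHS",
    "fdr_audit",
    "sensitivity_audit",
    "overlap_probability",
    "knn_cross_model",
]

DEFAULT_QUERY_LENGTHS = (3, 5, 10, 15, 20, 25, 50, 100, 250, 500, 1000)


@dataclass
class FdrAuditResult:
    """Outcome of the random-query false-discovery audit."""

    query_lengths: list[int]
    per_query_discoveries: list[dict]  # {"length", "rep", "n_discoveries"}
    fraction_with_any: float
    total_false_discoveries: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "query_lengths": self.query_lengths,
            "per_query_discoveries": self.per_query_discoveries,
            "fraction_with_any": self.fraction_with_any,
            "total_false_discoveries": self.total_false_discoveries,
            "seed": self.seed,
        }


@dataclass
class KnnRecovery:
    """Cross-model nearest-neighbour recovery at several k."""

    k_values: list[int]
    fraction_recovered: dict[int, float]
    excluded_terms: int
    n_pairs_evaluated: int = 0
    n_pairs_skipped: int = 0


def fdr_audit(
    model,
    lengths: Sequence[int] = DEFAULT_QUERY_LENGTHS,
    reps: int = 10,
    seed: int = 0,
) -> FdrAuditResult:
    """Query the model with random gene lists and count (false) discoveries.

    Lists are uniform samples without replacement from the model's entities;
    every run goes through the full default query pipeline.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    entities = np.asarray(model.matrix.entities)
    if max(lengths) > entities.size:
        raise ParameterError(
            f"query length {max(lengths)} exceeds entity count {entities.size}"
        )
    rng = np.random.default_rng(seed)
    detail: list[dict] = []
    for length in lengths:
        for rep in range(reps):
            genes = set(rng.choice(entities, size=length, replace=False))
            res = enrich(model, Query(genes=genes))
            detail.append(
                {"length": int(length), "rep": rep, "n_discoveries": len(res)}
            )
    with_any = sum(1 for d in detail if d["n_discoveries"] > 0)
    return FdrAuditResult(
        query_lengths=list(lengths),
        per_query_discoveries=detail,
        fraction_with_any=with_any / len(detail),
        total_false_discoveries=sum(d["n_discoveries"] for d in detail),
        seed=seed,
    )


def sensitivity_audit(
    model,
    n_sets: int = 25,
    max_len: int = 100,
    reps: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Classify the model's own gene sets vs size-matched random sets.

    A query is called 'real' when any term is enriched.  Returns one
    precision/recall/F1 record (for the 'real' class) per repetition; when
    no query is predicted real, precision is reported as 0 with a flag.
    """
    eligible = [
        (t, sorted(s))
        for t, s in model.gene_sets.items()
        if 2 < len(s) < max_len and t not in model.stopwords
    ]
    if len(eligible) < n_sets:
        raise ParameterError(
            f"only {len(eligible)} eligible gene sets (need {n_sets})"
        )
    eligible.sort()
    entities = np.asarray(model.matrix.entities)
    rng = np.random.default_rng(seed)
    out: list[dict] = []
    for rep in range(reps):
        idx = rng.choice(len(eligible), size=n_sets, replace=False)
        y_true, y_pred = [], []
        for i in idx:
            _, members = eligible[i]
            random_set = set(rng.choice(entities, size=len(members), replace=False))
            for genes, label in ((set(members), 1), (random_set, 0)):
                res = enrich(model, Query(genes=genes))
                y_true.append(label)
                y_pred.append(1 if len(res) else 0)
        degenerate = sum(y_pred) == 0
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=1, zero_division=0
        )
        out.append(
            {
                "rep": rep,
                "precision": float(p),
                "recall": float(r),
                "f1": float(f1),
                "no_positive_predictions": degenerate,
            }
        )
    return out


def _highly_overlapping(a: set, b: set) -> bool:
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    return len(small & large) >= 0.5 * len(small)


def overlap_probability(
    gene_sets: Mapping[str, set],
    sample_size: int = 500,
    reps: int = 10,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Mean fraction of highly-overlapping gene-set pairs, ± SEM over reps.

    A pair is highly overlapping when the smaller set shares at least half
    its members with the larger.
    """
    keys = sorted(gene_sets)
    if len(keys) < sample_size:
        raise ParameterError(
            f"need at least sample_size={sample_size} gene sets, have {len(keys)}"
        )
    rng = np.random.default_rng(seed)
    fractions: list[float] = []
    for _ in range(reps):
        picked = rng.choice(keys, size=sample_size, replace=False)
        sets = [gene_sets[k] for k in picked]
        n_pairs = 0
        n_high = 0
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                n_pairs += 1
                if _highly_overlapping(sets[i], sets[j]):
                    n_high += 1
        fractions.append(n_high / n_pairs if n_pairs else 0.0)
    arr = np.asarray(fractions)
    sem = float(arr.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return float(arr.mean()), sem, fractions


def knn_cross_model(
    model_a: TermMatrix,
    model_b: TermMatrix,
    pairs: Mapping[str, set],
    k_values: Sequence[int] = (1, 5, 10, 20, 50, 100),
    excluded: Callable[[str], bool] | None = None,
) -> KnnRecovery:
    """Nearest-neighbour recovery of expected a-entities for b-entities.

    Both matrices are restricted to their shared vocabulary minus excluded
    terms (by default, terms matching either model's entity symbols, which
    would connect neighbours trivially).  For each b-entity with expectations
    in ``pairs``, recovery at k means at least one expected a-entity lies
    within its k nearest a-neighbours by cosine distance.
    """
    if excluded is None:
        symbols = {e.lower() for e in model_a.entities} | {
            e.lower() for e in model_b.entities
        }
        excluded = lambda t: t.lstrip("~").lower() in symbols  # noqa: E731
    shared = [t for t in model_a.terms if model_b.has_term(t)]
    kept = [t for t in shared if not excluded(t)]
    n_excluded = len(shared) - len(kept)
    if not kept:
        raise ParameterError("no shared vocabulary after exclusion")

    Xa = model_a.values[:, [model_a.term_index(t) for t in kept]]
    Xb = model_b.values[:, [model_b.term_index(t) for t in kept]]
    max_k = min(max(k_values), Xa.shape[0])
    nn = NearestNeighbors(metric="cosine", n_neighbors=max_k).fit(Xa)

    b_entities = [e for e in pairs if model_b.has_entity(e)]
    a_entity_set = set(model_a.entities)
    evaluated: list[tuple[str, set]] = []
    skipped = 0
    for e in b_entities:
        expected = set(pairs[e]) & a_entity_set
        if expected:
            evaluated.append((e, expected))
        else:
            skipped += 1
    skipped += len(pairs) - len(b_entities)
    if not evaluated:
        raise ParameterError("no evaluable pairs (all expectations missing)")

    rows = Xb[[model_b.entity_index(e) for e, _ in evaluated]]
    _, neigh = nn.kneighbors(rows, n_neighbors=max_k)
    fraction: dict[int, float] = {}
    for k in k_values:
        kk = min(k, max_k)
        hits = 0
        for (e, expected), nbrs in zip(evaluated, neigh):
            names = {model_a.entities[i] for i in nbrs[:kk]}
            if names & expected:
                hits += 1
        fraction[int(k)] = hits / len(evaluated)
    return KnnRecovery(
        k_values=list(k_values),
        fraction_recovered=fraction,
        excluded_terms=n_excluded,
        n_pairs_evaluated=len(evaluated),
        n_pairs_skipped=skipped,
    )
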