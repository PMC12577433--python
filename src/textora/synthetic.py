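"""Synthetic description corpora with known ground truth.

The generator emulates the statistical skeleton of a description corpus:
every gene's text is sentences of background words drawn from a Zipf
distribution over a shared vocabulary (a handful of words dominate, with a
long rare tail, as in natural prose); genes assigned to a planted module
additionally mention that module's reserved marker terms; and a configurable
number of background words come in spelling-variant pairs (``word`` /
``words``) used interchangeably, giving the synonym clustering a recoverable
target.  Marker and background vocabularies are disjoint, so ground truth is
unambiguous.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .corpus import DescriptionRecord
from .errors import ParameterError

__all__ = ["SyntheticSpec", "GroundTruth", "generate_corpus", "write_corpus",
           "generate_null_pvalues_check"]


@dataclass
class SyntheticSpec:
    """Study conditions for a generated corpus.

    Defaults describe a modest expression-atlas-sized study: 200 genes of
    which half belong to 5 planted functional modules of 20 genes, each
    module tagged by 3 reserved marker terms; a 2,000-word Zipf background
    vocabulary (exponent 1.1); 3-6 sentences of 5-12 words per gene; and 5
    planted spelling-variant pairs.
    """

    n_genes: int = 200
    n_modules: int = 5
    genes_per_module: int = 20
    marker_terms_per_module: int = 3
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.1
    sentences_per_gene: tuple[int, int] = (3, 6)
    words_per_sentence: tuple[int, int] = (5, 12)
    synonym_pairs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ParameterError("module genes exceed n_genes")
        for name in ("n_genes", "n_modules", "genes_per_module",
                     "marker_terms_per_module", "background_vocab_size",
                     "synonym_pairs"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.zipf_exponent <= 0:
            raise ParameterError("zipf_exponent must be positive")
        lo, hi = self.sentences_per_gene
        if not (0 < lo <= hi):
            raise ParameterError("invalid sentences_per_gene range")
        lo, hi = self.words_per_sentence
        if not (0 < lo <= hi):
            raise ParameterError("invalid words_per_sentence range")
        if self.background_vocab_size < 1:
            raise ParameterError("background vocabulary must be non-empty")


@dataclass
class GroundTruth:
    """What was planted: gene → module, module → markers, synonym pairs."""

    modules: dict[str, int] = field(default_factory=dict)
    markers: dict[int, list[str]] = field(default_factory=dict)
    synonym_pairs: list[tuple[str, str]] = field(default_factory=list)

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.modules.items() if m == module)

    def to_json(self) -> str:
        return json.dumps(
            {
                "modules": self.modules,
                "markers": {str(k): v for k, v in self.markers.items()},
                "synonym_pairs": [list(p) for p in self.synonym_pairs],
            },
            indent=1,
            sort_keys=True,
        )


def _random_words(rng: np.random.Generator, count: int, taken: set[str],
                  lengths: tuple[int, int] = (5, 8)) -> list[str]:
    letters = np.array(list(string.ascii_lowercase))
    out: list[str] = []
    while len(out) < count:
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        w = "".join(rng.choice(letters, size=L))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def generate_corpus(spec: SyntheticSpec) -> tuple[list[DescriptionRecord], GroundTruth]:
    """Generate the corpus and its ground truth, deterministically under seed."""
    rng = np.random.default_rng(spec.seed)
    taken: set[str] = set()
    vocab = _random_words(rng, spec.background_vocab_size, taken)
    n_markers = spec.n_modules * spec.marker_terms_per_module
    marker_vocab = _random_words(rng, n_markers, taken)

    # Zipf probabilities over the background vocabulary (rank 1 = vocab[0])
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()

    # spelling-variant pairs among moderately frequent background words so
    # both variants clear typical min_df cuts
    pair_base_ranks = range(10, 10 + spec.synonym_pairs)
    variant_of: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for r in pair_base_ranks:
        if r >= len(vocab):
            raise ParameterError("background vocabulary too small for synonym_pairs")
        base = vocab[r]
        var = base + "s"
        if var in taken:
            var = base + "es"
        taken.add(var)
        variant_of[base] = var
        pairs.append((base, var))

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    truth = GroundTruth(synonym_pairs=pairs)
    for m in range(spec.n_modules):
        start = m * spec.genes_per_module
        for g in genes[start : start + spec.genes_per_module]:
            truth.modules[g] = m
        truth.markers[m] = marker_vocab[
            m * spec.marker_terms_per_module : (m + 1) * spec.marker_terms_per_module
        ]

    records: list[DescriptionRecord] = []
    lo_s, hi_s = spec.sentences_per_gene
    lo_w, hi_w = spec.words_per_sentence
    for g in genes:
        n_sent = int(rng.integers(lo_s, hi_s + 1))
        sentences: list[list[str]] = []
        for _ in range(n_sent):
            n_words = int(rng.integers(lo_w, hi_w + 1))
            idx = rng.choice(len(vocab), size=n_words, p=probs)
            words = [vocab[i] for i in idx]
            # planted variants substitute their base word half the time
            words = [
                variant_of[w] if w in variant_of and rng.random() < 0.5 else w
                for w in words
            ]
            sentences.append(words)
        if g in truth.modules:
            for marker in truth.markers[truth.modules[g]]:
                # two mentions in distinct sentences (>=1 guaranteed)
                slots = rng.choice(n_sent, size=min(2, n_sent), replace=False)
                for s_i in slots:
                    pos = int(rng.integers(0, len(sentences[s_i]) + 1))
                    sentences[s_i].insert(pos, marker)
        text = " ".join(
            " ".join(words).capitalize() + "." for words in sentences
        )
        records.append(DescriptionRecord(entity=g, source="synthetic", text=text))
    return records, truth


def write_corpus(records: Sequence[DescriptionRecord], truth: GroundTruth,
                 tsv_path, truth_path=None) -> None:
    """Write the standard descriptions TSV and, optionally, ground-truth JSON."""
    import pandas as pd

    pd.DataFrame(
        [{"entity": r.entity, "source": r.source, "text": r.text} for r in records]
    ).to_csv(tsv_path, sep="\t", index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(truth.to_json() + "\n")


def generate_null_pvalues_check(
    model, n_queries: int, query_size: int, seed: int
) -> tuple[np.ndarray, "np.ufunc"]:
    """Pool candidate-term p-values from random queries against a null model.

    Returns the sorted pooled p-values and an ECDF callable.  Under the null
    (no planted structure, queries sampled uniformly without replacement)
    the hypergeometric test is exact, so ECDF(alpha) <= alpha up to binomial
    noise — and typically far below it, because the statistic is discrete.
    """
    from .enrich import Query, enrich

    rng = np.random.default_rng(seed)
    entities = model.matrix.entities
    pooled: list[float] = []
    for _ in range(n_queries):
        genes = set(rng.choice(entities, size=query_size, replace=False))
        res = enrich(model, Query(genes=genes), keep_all=True)
        pooled.extend(r.p_value for r in res.rows)
    ps = np.sort(np.asarray(pooled))

    def ecdf(x: float) -> float:
        return float(np.searchsorted(ps, x, side="right") / max(1, ps.size))

    return ps, ecdf
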