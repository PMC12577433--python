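"""End-to-end training pipeline and the on-disk model bundle.

``train`` runs corpus → synonym clustering → tf-idf → stopword derivation
and returns an :class:`EnrichmentModel`, the object queries are run
against.  A fitted model serializes to a plain-text directory bundle
(Matrix Market values + TSV/JSON sidecars) that is portable, inspectable
and diff-able; ``load(save(model))`` reproduces the matrix bit-exactly and
a second save is byte-identical to the first.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .corpus import (
    DescriptionRecord,
    ExcerptIndex,
    PhraseLexicon,
    SentenceRecord,
    build_excerpt_index,
    sentences_of,
    tokenize_corpus,
)
from .errors import FitError, FormatError, ParameterError
from .synonyms import (
    HashingNgramEmbedder,
    SynonymSet,
    TokenEmbedder,
    apply_synonyms,
    cluster_synonyms,
    embed_tokens,
)
from .vectorize import StopwordList, TermMatrix, binarize, derive_stopwords, fit_tfidf

__all__ = ["TrainConfig", "EnrichmentModel", "train", "load_common_words"]


@dataclass
class TrainConfig:
    """Tunable parameters of the training pipeline, with the defaults used
    throughout: df bounds 3 ≤ df ≤ 0.6·N, smoothed log idf with L2 row norm,
    HDBSCAN(min_cluster_size=2, min_samples=2) for synonyms, and the
    stopword thresholds (Pearson r > 0.65 to the common-word centroid,
    > 50% stopword members, present in > 15% of genes)."""

    max_df: float = 0.6
    min_df: int = 3
    binary: bool = False
    idf: str = "smooth"
    norm: str | None = "l2"
    sublinear_tf: bool = False
    learn_synonyms: bool = True
    min_cluster_size: int = 2
    min_samples: int = 2
    synonym_max_distance: float | None = 0.3
    corr_threshold: float = 0.65
    gene_fraction: float = 0.15
    synonym_fraction: float = 0.5
    embedder_dim: int = 256
    embedder_ngram: int = 3


def load_common_words() -> list[str]:
    """The packaged high-frequency word list used for stopword derivation."""
    from importlib.resources import files

    text = files("textora").joinpath("data/common_words.txt").read_text()
    words = [w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")]
    return list(dict.fromkeys(words))


class EnrichmentModel:
    """A fitted model: term matrix, stopwords, synonym sets and excerpts."""

    def __init__(
        self,
        sentences: list[SentenceRecord],
        lexicon: PhraseLexicon | None,
        synonym_sets: list[SynonymSet],
        matrix: TermMatrix,
        stopwords: StopwordList,
        config: TrainConfig,
    ):
        self.sentences = sentences
        self.lexicon = lexicon
        self.synonym_sets = synonym_sets
        self.matrix = matrix
        self.stopwords = stopwords
        self.config = config
        self._excerpt_index: ExcerptIndex | None = None
        self._gene_sets: dict[str, set[str]] | None = None

    # -- derived views -------------------------------------------------
    @property
    def synonym_members(self) -> dict[str, list[str]]:
        return {s.label: list(s.members) for s in self.synonym_sets}

    @property
    def excerpt_index(self) -> ExcerptIndex:
        if self._excerpt_index is None:
            tokenized = tokenize_corpus(self.sentences, self.lexicon)
            self._excerpt_index = build_excerpt_index(
                tokenized, synonyms=self.synonym_members
            )
        return self._excerpt_index

    @property
    def gene_sets(self) -> dict[str, set[str]]:
        """The binarized de novo gene-set database (term → entities)."""
        if self._gene_sets is None:
            self._gene_sets, _ = binarize(self.matrix)
        return self._gene_sets

    @property
    def corpus_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.sentences:
            h.update(f"{s.entity}\t{s.source}\t{s.sentence_index}\t{s.text}\n".encode())
        return h.hexdigest()

    # -- serialization -------------------------------------------------
    def save(self, directory) -> None:
        """Write the bundle atomically (a partial bundle is never left behind)."""
        directory = str(directory)
        tmp = tempfile.mkdtemp(prefix=".bundle-", dir=os.path.dirname(directory) or ".")
        try:
            self._write(tmp)
            if os.path.isdir(directory):
                shutil.rmtree(directory)
            os.replace(tmp, directory)
        except Exception:
            shutil.rmtree(tmp, ignore_errors=True)
            raise

    def _write(self, d: str) -> None:
        # precision=17 makes the float64 text round trip exact
        scipy.io.mmwrite(
            os.path.join(d, "values.mtx"), self.matrix.values.tocoo(), precision=17
        )
        pd.DataFrame({"entity": self.matrix.entities}).to_csv(
            os.path.join(d, "entities.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"term": self.matrix.terms}).to_csv(
            os.path.join(d, "terms.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"term": self.matrix.terms, "df": self.matrix.df}).to_csv(
            os.path.join(d, "df.tsv"), sep="\t", index=False
        )
        with open(os.path.join(d, "synonyms.json"), "w") as fh:
            json.dump(
                [
                    {"label": s.label, "members": s.members, "member_df": s.member_df}
                    for s in self.synonym_sets
                ],
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        with open(os.path.join(d, "stopwords.txt"), "w") as fh:
            for t in sorted(self.stopwords.terms):
                fh.write(f"{t}\t{self.stopwords.provenance.get(t, '')}\n")
        pd.DataFrame(
            [
                {
                    "entity": s.entity,
                    "source": s.source,
                    "sentence_index": s.sentence_index,
                    "text": s.text,
                }
                for s in self.sentences
            ]
        ).to_csv(os.path.join(d, "sentences.tsv"), sep="\t", index=False)
        with open(os.path.join(d, "lexicon.json"), "w") as fh:
            json.dump(
                {
                    "min_sources": self.lexicon.min_sources if self.lexicon else None,
                    "phrases": sorted(
                        " ".join(p) for p in (self.lexicon.phrases if self.lexicon else ())
                    ),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        with open(os.path.join(d, "params.json"), "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "matrix_params": self.matrix.params,
                    "tool_version": __version__,
                    "corpus_hash": self.corpus_hash,
                    "n_entities": self.matrix.n_entities,
                    "n_terms": len(self.matrix.terms),
                    "n_synonym_sets": len(self.synonym_sets),
                    "n_stopwords": len(self.stopwords),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "EnrichmentModel":
        d = str(directory)
        with open(os.path.join(d, "params.json")) as fh:
            params = json.load(fh)
        config = TrainConfig(**params["config"])
        values = sp.csr_matrix(scipy.io.mmread(os.path.join(d, "values.mtx")))
        values.sort_indices()
        entities = pd.read_csv(
            os.path.join(d, "entities.tsv"), sep="\t", dtype=str
        )["entity"].tolist()
        terms = pd.read_csv(os.path.join(d, "terms.tsv"), sep="\t", dtype=str)[
            "term"
        ].tolist()
        df_tab = pd.read_csv(os.path.join(d, "df.tsv"), sep="\t", dtype={"term": str})
        matrix = TermMatrix(
            entities=entities,
            terms=terms,
            values=values,
            df=df_tab["df"].to_numpy(dtype=int),
            params=params["matrix_params"],
        )
        with open(os.path.join(d, "synonyms.json")) as fh:
            synonym_sets = [
                SynonymSet(
                    label=s["label"],
                    members=list(s["members"]),
                    member_df={k: int(v) for k, v in s["member_df"].items()},
                )
                for s in json.load(fh)
            ]
        provenance: dict[str, str] = {}
        with open(os.path.join(d, "stopwords.txt")) as fh:
            for line in fh:
                if line.rstrip("\n"):
                    term, _, prov = line.rstrip("\n").partition("\t")
                    provenance[term] = prov
        stopwords = StopwordList(terms=set(provenance), provenance=provenance)
        sent_tab = pd.read_csv(
            os.path.join(d, "sentences.tsv"), sep="\t", dtype={"entity": str, "source": str, "text": str}
        )
        sentences = [
            SentenceRecord(r.entity, r.source, int(r.sentence_index), r.text)
            for r in sent_tab.itertuples(index=False)
        ]
        with open(os.path.join(d, "lexicon.json")) as fh:
            lex = json.load(fh)
        lexicon = None
        if lex["min_sources"] is not None:
            lexicon = PhraseLexicon(
                phrases={tuple(p.split()) for p in lex["phrases"]},
                min_sources=lex["min_sources"],
            )
        return cls(
            sentences=sentences,
            lexicon=lexicon,
            synonym_sets=synonym_sets,
            matrix=matrix,
            stopwords=stopwords,
            config=config,
        )


def train(
    records: Sequence[DescriptionRecord],
    lexicon: PhraseLexicon | None = None,
    embedder: TokenEmbedder | None = None,
    common_words: Sequence[str] | None = None,
    config: TrainConfig | None = None,
    log=None,
) -> EnrichmentModel:
    """Fit the full pipeline on a description corpus.

    ``embedder`` defaults to the deterministic hashing embedder;
    ``common_words`` to the packaged high-frequency word list.  ``log`` is an
    optional callable receiving one (stage, info) pair per pipeline stage.
    """
    config = config or TrainConfig()
    embedder = embedder or HashingNgramEmbedder(
        dim=config.embedder_dim, ngram=config.embedder_ngram
    )
    common_words = list(common_words) if common_words is not None else load_common_words()
    emit = log or (lambda stage, info: None)

    if not records:
        raise FitError("empty corpus")
    sentences = sentences_of(records)
    tokenized = tokenize_corpus(sentences, lexicon)
    emit("corpus", {
        "documents": len({r.entity for r in records}),
        "sentences": len(sentences),
        "tokens": sum(len(ts.tokens) for ts in tokenized),
    })

    # document frequency per observed term (pre-filter, pre-replacement)
    df_raw: dict[str, set[str]] = {}
    for ts in tokenized:
        for term in set(ts.tokens) | {p for p, _, _ in ts.phrases}:
            df_raw.setdefault(term, set()).add(ts.entity)
    token_df = {t: len(es) for t, es in df_raw.items()}

    synonym_sets: list[SynonymSet] = []
    if config.learn_synonyms and len(token_df) >= 2:
        vocab = sorted(token_df)
        table = embed_tokens(vocab, embedder)
        synonym_sets = cluster_synonyms(
            table,
            token_df,
            min_cluster_size=config.min_cluster_size,
            min_samples=config.min_samples,
            max_distance=config.synonym_max_distance,
        )
    emit("synonyms", {"synonym_sets": len(synonym_sets)})

    applied = apply_synonyms(tokenized, synonym_sets)
    matrix = fit_tfidf(
        applied,
        max_df=config.max_df,
        min_df=config.min_df,
        binary=config.binary,
        idf=config.idf,
        norm=config.norm,
        sublinear_tf=config.sublinear_tf,
    )
    emit("tfidf", {"entities": matrix.n_entities, "terms": len(matrix.terms)})

    stopwords = derive_stopwords(
        matrix,
        common_words,
        embedder,
        synonym_sets,
        corr_threshold=config.corr_threshold,
        gene_fraction=config.gene_fraction,
        synonym_fraction=config.synonym_fraction,
    )
    emit("stopwords", {"stopwords": len(stopwords)})

    return EnrichmentModel(
        sentences=sentences,
        lexicon=lexicon,
        synonym_sets=synonym_sets,
        matrix=matrix,
        stopwords=stopwords,
        config=config,
    )
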