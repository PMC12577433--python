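"""Corpus ingestion, sentence splitting, tokenization and excerpt indexing.

Free-text entity descriptions (one row per entity/source pair) are split into
sentences, then into word tokens by splitting on spaces.  Casing carries
signal in this domain — gene symbols and abbreviations such as ``DNA`` or
``UPR`` must not be collapsed onto common words — so a token is lowercased
only when exactly one of its characters is uppercase (``Protein`` →
``protein``; ``DNA`` stays).  Multi-word concepts are recovered by matching
sentences against a phrase lexicon, and every (term, entity) → sentence link
is retained in an :class:`ExcerptIndex` so enrichment results can always be
traced back to the source text.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "DescriptionRecord",
    "SentenceRecord",
    "PhraseLexicon",
    "TokenizedSentence",
    "ExcerptIndex",
    "read_descriptions",
    "split_sentences",
    "casefold_token",
    "strip_token",
    "tokenize_sentence",
    "tokenize_corpus",
    "build_excerpt_index",
]

# characters allowed at token edges; everything else is stripped from the
# ends only, so "Ca2+", "anti-apoptotic" and "~oncogene" survive intact.
_EDGE_STRIP = re.compile(r"^[^A-Za-z0-9+~-]+|[^A-Za-z0-9+~-]+$")

# sentence boundary: terminal punctuation, whitespace, then an upper-case
# letter or digit.  Abbreviations are vetoed post hoc.
_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")

#: tokens (lowercased, including the trailing period) that never end a sentence
ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "vs.", "etc.", "cf.", "ca.", "approx.", "al.",
        "dr.", "fig.", "figs.", "no.", "ref.", "refs.", "resp.", "spp.",
        "st.", "mr.", "mrs.", "ms.",
    }
)


@dataclass(frozen=True)
class DescriptionRecord:
    """One (entity, source, free text) row of the corpus."""

    entity: str
    source: str
    text: str
    url: str | None = None

    def __post_init__(self) -> None:
        if not self.entity.strip():
            raise ParameterError("DescriptionRecord.entity must be non-empty")
        if not self.text:
            raise ParameterError("DescriptionRecord.text must be non-empty")


@dataclass(frozen=True)
class SentenceRecord:
    """A single sentence of a description, with its ordinal position."""

    entity: str
    source: str
    sentence_index: int
    text: str


@dataclass
class PhraseLexicon:
    """Multi-word phrases worth keeping as single terms.

    Only phrases attested by at least ``min_sources`` independent sources are
    admitted, mirroring how concept vocabularies define trustworthy n-grams.
    """

    phrases: set[tuple[str, ...]] = field(default_factory=set)
    min_sources: int = 2

    def __post_init__(self) -> None:
        for p in self.phrases:
            if len(p) < 2:
                raise ParameterError(f"phrase {p!r} has fewer than 2 tokens")
        # index by first word for fast scanning
        self._by_first: dict[str, list[tuple[str, ...]]] = defaultdict(list)
        for p in self.phrases:
            self._by_first[p[0]].append(p)
        for lst in self._by_first.values():
            lst.sort()

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: tuple[str, ...]) -> bool:
        return phrase in self.phrases

    @classmethod
    def from_tsv(cls, path, min_sources: int = 2) -> "PhraseLexicon":
        """Load a lexicon from a TSV with columns ``phrase`` and ``n_sources``."""
        df = pd.read_csv(path, sep="\t", dtype={"phrase": str})
        for col in ("phrase", "n_sources"):
            if col not in df.columns:
                raise FormatError(f"phrase lexicon is missing column {col!r}")
        keep = df[df["n_sources"].astype(int) >= min_sources]["phrase"]
        phrases = {
            tuple(p.lower().split())
            for p in keep
            if isinstance(p, str) and len(p.split()) >= 2
        }
        return cls(phrases=phrases, min_sources=min_sources)


@dataclass
class TokenizedSentence:
    """Word tokens plus matched lexicon phrases for one sentence.

    ``token_spans`` holds the character span of each token inside ``text``
    (after edge punctuation stripping), enabling exact excerpt highlighting.
    ``phrases`` are (phrase string, start, end) with 0-based half-open word
    offsets into ``tokens``.
    """

    entity: str
    source: str
    sentence_index: int
    text: str
    tokens: list[str]
    token_spans: list[tuple[int, int]]
    phrases: list[tuple[str, int, int]] = field(default_factory=list)

    def term_counts(self) -> dict[str, int]:
        """Occurrence counts of every term (unigrams plus phrase terms).

        A phrase occurrence also counts its constituent unigrams: redundancy
        between a phrase and its sub-terms is resolved later by the sub-term
        filter, not here.
        """
        counts: dict[str, int] = {}
        for t in self.tokens:
            counts[t] = counts.get(t, 0) + 1
        for p, _, _ in self.phrases:
            counts[p] = counts.get(p, 0) + 1
        return counts


def read_descriptions(path) -> tuple[list[DescriptionRecord], dict]:
    """Read a descriptions TSV with columns entity, source, text[, url].

    Returns the records plus a skip report: rows whose entity or text is
    empty are dropped and counted, never silently ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("entity", "source", "text"):
        if col not in df.columns:
            raise FormatError(f"descriptions table is missing column {col!r}")
    records: list[DescriptionRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        entity = str(row.entity).strip()
        text = str(row.text)
        if not entity or not text.strip():
            skipped += 1
            continue
        url = getattr(row, "url", None) or None
        records.append(
            DescriptionRecord(entity=entity, source=str(row.source), text=text, url=url)
        )
    return records, {"n_rows": int(len(df)), "n_records": len(records), "n_skipped": skipped}


def split_sentences(text: str) -> list[str]:
    """Split free text into sentences.

    Boundary rule: sentence-final punctuation followed by whitespace and an
    upper-case letter or digit, unless the word ending at the boundary is a
    known abbreviation ("e.g.", "i.e.", ...).  Deterministic, no model.
    Falls back to the whole text as a single sentence.
    """
    if not text:
        raise ParameterError("cannot split empty text")
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        prev = text[: end].rsplit(None, 1)[-1].lower()
        if prev in ABBREVIATIONS:
            continue
        cuts.append(end)
    sentences = []
    start = 0
    for c in cuts:
        s = text[start:c].strip()
        if s:
            sentences.append(s)
        start = c
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences or [text.strip()]


def strip_token(raw: str) -> str:
    """Strip leading/trailing punctuation, keeping internal hyphens/pluses."""
    return _EDGE_STRIP.sub("", raw)


def casefold_token(token: str) -> str:
    """Lowercase a token iff exactly one of its characters is uppercase.

    Tokens with two or more capitals (``DNA``, ``BRaf``) keep their case:
    multi-capital tokens are almost always symbols or abbreviations whose
    case is meaningful.
    """
    n_upper = sum(1 for c in token if c.isupper())
    return token.lower() if n_upper == 1 else token


def tokenize_sentence(
    sentence: str,
    lexicon: PhraseLexicon | None = None,
    *,
    entity: str = "",
    source: str = "",
    sentence_index: int = 0,
) -> TokenizedSentence:
    """Tokenize one sentence by splitting on spaces and matching phrases.

    Every occurrence of every lexicon phrase is reported (overlapping matches
    of different phrases included); matching is case-insensitive and the
    stored phrase term is the lowercase lexicon form.
    """
    if not sentence:
        raise ParameterError("cannot tokenize an empty sentence")
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in re.finditer(r"\S+", sentence):
        raw = m.group()
        stripped = strip_token(raw)
        if not stripped:
            continue
        # only edge characters were removed, so the stripped form occurs
        # verbatim inside raw; find() locates it exactly
        pos = raw.find(stripped)
        start = m.start() + pos
        tokens.append(casefold_token(stripped))
        spans.append((start, start + len(stripped)))
    phrases: list[tuple[str, int, int]] = []
    if lexicon is not None and len(lexicon) and tokens:
        lowered = [t.lower() for t in tokens]
        for i, first in enumerate(lowered):
            for cand in lexicon._by_first.get(first, ()):
                L = len(cand)
                if i + L <= len(lowered) and tuple(lowered[i : i + L]) == cand:
                    phrases.append((" ".join(cand), i, i + L))
    return TokenizedSentence(
        entity=entity,
        source=source,
        sentence_index=sentence_index,
        text=sentence,
        tokens=tokens,
        token_spans=spans,
        phrases=phrases,
    )


def sentences_of(records: Iterable[DescriptionRecord]) -> list[SentenceRecord]:
    """Split every description into ordered SentenceRecords."""
    out: list[SentenceRecord] = []
    for rec in records:
        for i, s in enumerate(split_sentences(rec.text)):
            out.append(SentenceRecord(rec.entity, rec.source, i, s))
    return out


def tokenize_corpus(
    sentences: Sequence[SentenceRecord], lexicon: PhraseLexicon | None = None
) -> list[TokenizedSentence]:
    """Tokenize a whole corpus of SentenceRecords."""
    return [
        tokenize_sentence(
            s.text,
            lexicon,
            entity=s.entity,
            source=s.source,
            sentence_index=s.sentence_index,
        )
        for s in sentences
    ]


class ExcerptIndex:
    """Mapping (term, entity) → source sentences containing the term.

    The index is built on pre-synonym-replacement tokens; a synonym label
    (``~``-prefixed) resolves to the union of its members' excerpts, so the
    text → term link survives synonym collapsing.
    """

    def __init__(self, synonyms: Mapping[str, Sequence[str]] | None = None):
        # term -> entity -> list of {source, sentence_index, sentence, spans}
        self._index: dict[str, dict[str, list[dict]]] = defaultdict(dict)
        self._synonyms = {k: list(v) for k, v in (synonyms or {}).items()}

    def add_sentence(self, ts: TokenizedSentence) -> None:
        per_term: dict[str, list[list[int]]] = defaultdict(list)
        for tok, (a, b) in zip(ts.tokens, ts.token_spans):
            per_term[tok].append([a, b])
        for phrase, i, j in ts.phrases:
            a = ts.token_spans[i][0]
            b = ts.token_spans[j - 1][1]
            per_term[phrase].append([a, b])
        for term, spans in per_term.items():
            self._index[term].setdefault(ts.entity, []).append(
                {
                    "source": ts.source,
                    "sentence_index": ts.sentence_index,
                    "sentence": ts.text,
                    "spans": spans,
                }
            )

    def set_synonyms(self, synonyms: Mapping[str, Sequence[str]]) -> None:
        self._synonyms = {k: list(v) for k, v in synonyms.items()}

    def _member_terms(self, term: str) -> list[str]:
        if term in self._synonyms:
            return list(self._synonyms[term])
        return [term]

    def lookup(self, term: str, entities: Iterable[str] | None = None) -> list[dict]:
        """All excerpt records for a term (or synonym label), optionally
        restricted to the given entities.  Unknown terms yield an empty list.
        """
        wanted = None if entities is None else set(entities)
        out: list[dict] = []
        for member in self._member_terms(term):
            for entity, recs in self._index.get(member, {}).items():
                if wanted is not None and entity not in wanted:
                    continue
                for r in recs:
                    out.append({"term": term, "entity": entity, **r})
        out.sort(key=lambda r: (r["entity"], r["source"], r["sentence_index"]))
        return out

    def entities_with(self, term: str) -> set[str]:
        """Entities having at least one excerpt for the term."""
        ents: set[str] = set()
        for member in self._member_terms(term):
            ents.update(self._index.get(member, {}))
        return ents


def build_excerpt_index(
    sentences: Iterable[TokenizedSentence],
    synonyms: Mapping[str, Sequence[str]] | None = None,
) -> ExcerptIndex:
    """Build the excerpt index over a tokenized corpus."""
    idx = ExcerptIndex(synonyms=synonyms)
    for ts in sentences:
        idx.add_sentence(ts)
    return idx
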