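"""tf-idf fitting, the binarized gene-set database, stopwords and LSA."""

import math

import numpy as np
import pytest

from textora.corpus import tokenize_sentence
from textora.errors import FitError, LookupError_, ParameterError
from textora.synonyms import HashingNgramEmbedder, SynonymSet
from textora.vectorize import (
    CHROMOSOME_LOCATION,
    StopwordList,
    binarize,
    count_terms,
    derive_stopwords,
    fit_tfidf,
    gene_similarity,
    lsa,
)


def _corpus(docs):
    """docs: {entity: text or [texts]} -> tokenized sentences."""
    out = []
    for entity, texts in docs.items():
        if isinstance(texts, str):
            texts = [texts]
        for i, t in enumerate(texts):
            out.append(tokenize_sentence(t, entity=entity, sentence_index=i))
    return out


def _reference_tfidf(corpus, max_df, min_df, idf, norm, binary=False):
    """Independent dense per-cell recomputation from raw counts."""
    entities, terms, X = count_terms(corpus)
    X = np.asarray(X.todense())
    n = len(entities)
    df = (X > 0).sum(axis=0)
    keep = (df >= min_df) & (df <= max_df * n)
    X, df = X[:, keep], df[keep]
    terms = [t for t, k in zip(terms, keep) if k]
    if binary:
        X = (X > 0).astype(float)
    out = np.zeros_like(X, dtype=float)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            if idf == "smooth":
                w = math.log((1 + n) / (1 + df[j])) + 1
            else:
                w = math.log(n / df[j]) + 1
            out[i, j] = X[i, j] * w
        if norm == "l2":
            nrm = math.sqrt(sum(v * v for v in out[i]))
            if nrm > 0:
                out[i] /= nrm
    return entities, terms, out


class TestFitTfidf:
    def test_hand_computed_idf_value(self):
        corpus = _corpus(
            {"g1": "alpha alpha beta", "g2": "beta gamma", "g3": "beta delta",
             "g4": "beta epsilon"}
        )
        m = fit_tfidf(corpus, max_df=1.0, min_df=1, norm=None)
        # alpha: tf=2 in g1, df=1, N=4 -> 2*(ln(5/2)+1)
        val = m.values[m.entity_index("g1"), m.term_index("alpha")]
        assert val == pytest.approx(2 * (math.log(5 / 2) + 1), abs=1e-4)
        assert val == pytest.approx(3.8326, abs=1e-4)

    def test_term_above_max_df_dropped(self):
        corpus = _corpus({f"g{i}": "ubiquitous special" + str(i % 2) for i in range(10)})
        m = fit_tfidf(corpus, max_df=0.6, min_df=1)
        assert not m.has_term("ubiquitous")

    def test_binary_flag_makes_nonzeros_equal_row_constant_modulo_idf(self):
        corpus = _corpus({"g1": "a a a b", "g2": "a b b c", "g3": "c d"})
        m = fit_tfidf(corpus, max_df=1.0, min_df=1, binary=True, norm=None)
        row = m.values[m.entity_index("g1")].toarray().ravel()
        tf = np.zeros_like(row)
        tf[row > 0] = 1
        # binary: value = idf exactly, so value/idf == 1 wherever nonzero
        n, df = m.n_entities, m.df
        idf = np.log((1 + n) / (1 + df)) + 1
        assert np.allclose(row[row > 0], idf[row > 0])

    @pytest.mark.parametrize("idf", ["smooth", "plain"])
    @pytest.mark.parametrize("norm", ["l2", None])
    def test_matches_per_cell_reference_on_random_corpora(self, idf, norm):
        rng = np.random.default_rng(42)
        vocab = [f"w{i}" for i in range(40)]
        docs = {
            f"g{i}": " ".join(rng.choice(vocab, size=rng.integers(5, 30)))
            for i in range(50)
        }
        corpus = _corpus(docs)
        m = fit_tfidf(corpus, max_df=0.6, min_df=3, idf=idf, norm=norm)
        entities, terms, ref = _reference_tfidf(corpus, 0.6, 3, idf, norm)
        assert m.entities == entities and m.terms == terms
        assert np.allclose(np.asarray(m.values.todense()), ref, atol=1e-12)

    def test_too_few_entities_is_fit_error(self):
        corpus = _corpus({"g1": "a b", "g2": "a c"})
        with pytest.raises(FitError):
            fit_tfidf(corpus, min_df=3)

    def test_empty_vocabulary_is_fit_error(self):
        corpus = _corpus({"g1": "a", "g2": "b", "g3": "c"})
        with pytest.raises(FitError):
            fit_tfidf(corpus, max_df=0.1, min_df=1)


class TestBinarize:
    def test_sets_equal_bruteforce_recount(self):
        docs = {"g1": "a b c", "g2": "a b", "g3": "a d", "g4": "b d"}
        corpus = _corpus(docs)
        m = fit_tfidf(corpus, max_df=1.0, min_df=1)
        term_sets, entity_sets = binarize(m)
        for term, ents in term_sets.items():
            expected = {e for e, text in docs.items() if term in text.split()}
            assert ents == expected
        for e, terms in entity_sets.items():
            assert terms == set(docs[e].split()) & set(m.terms)

    def test_single_nonzero(self):
        corpus = _corpus({"g1": "special a", "g2": "a b", "g3": "a b"})
        m = fit_tfidf(corpus, max_df=1.0, min_df=1)
        term_sets, _ = binarize(m)
        assert term_sets["special"] == {"g1"}


class _EchoEmbedder(HashingNgramEmbedder):
    """The hashing embedder: common words embed to themselves, so a term
    equal to a common word correlates ~1 with a centroid of that word."""


class TestStopwords:
    def _matrix(self, docs, **kw):
        return fit_tfidf(_corpus(docs), max_df=kw.pop("max_df", 1.0),
                         min_df=kw.pop("min_df", 1), **kw)

    def test_high_gene_fraction_rule(self):
        docs = {f"g{i}": ("everywhere rare" + str(i) if i < 3 else "everywhere x") for i in range(10)}
        m = self._matrix(docs)
        sw = derive_stopwords(m, ["the"], HashingNgramEmbedder(), gene_fraction=0.15)
        assert "everywhere" in sw
        assert sw.provenance["everywhere"] == "high-gene-fraction"

    def test_chromosomal_location_exempt(self):
        docs = {f"g{i}": "19q13 other" + str(i) for i in range(10)}
        m = self._matrix(docs)
        sw = derive_stopwords(m, ["the"], HashingNgramEmbedder(), gene_fraction=0.15)
        assert "19q13" not in sw

    @pytest.mark.parametrize("term", ["19q13", "1p36.3", "Xp21", "Yq11.2"])
    def test_location_pattern_matches(self, term):
        assert CHROMOSOME_LOCATION.match(term)

    @pytest.mark.parametrize("term", ["q13", "19x13", "ribosome", "19q"])
    def test_location_pattern_rejects(self, term):
        assert not CHROMOSOME_LOCATION.match(term)

    def test_fully_uppercase_exempt(self):
        docs = {f"g{i}": "DNA other" + str(i) for i in range(10)}
        m = self._matrix(docs)
        sw = derive_stopwords(m, ["the"], HashingNgramEmbedder(), gene_fraction=0.15)
        assert "DNA" not in sw

    def test_centroid_correlation_and_phrase_rules(self):
        # terms identical to the common words correlate 1 with their centroid
        from textora.corpus import PhraseLexicon, tokenize_sentence as tok

        lex = PhraseLexicon(phrases={("several", "several")})
        sents = [
            tok("several several other" + str(i), lex, entity=f"g{i}") for i in range(4)
        ]
        m = fit_tfidf(sents, max_df=1.0, min_df=1)
        sw = derive_stopwords(
            m, ["several"], HashingNgramEmbedder(), corr_threshold=0.65,
            gene_fraction=2.0,
        )
        assert sw.provenance.get("several") == "centroid-correlation"
        assert sw.provenance.get("several several") == "all-stopword-phrase"

    def test_majority_stopword_synonym_rule(self):
        sents = [
            tokenize_sentence("several severals unrelated" + str(i), entity=f"g{i}")
            for i in range(4)
        ]
        from textora.synonyms import apply_synonyms

        ss = SynonymSet("~several", ["several", "severals"], {"several": 4})
        m = fit_tfidf(apply_synonyms(sents, [ss]), max_df=1.0, min_df=1)
        sw = derive_stopwords(
            m, ["several", "severals"], HashingNgramEmbedder(),
            synonym_sets=[ss], gene_fraction=2.0,
        )
        assert sw.provenance.get("~several") == "majority-stopword-synonym"

    def test_monotone_in_thresholds(self, planted):
        _, _, _, model = planted
        emb = HashingNgramEmbedder()
        base = derive_stopwords(
            model.matrix, ["the", "of", "and"], emb, model.synonym_sets,
            corr_threshold=0.5, gene_fraction=0.10,
        )
        stricter = derive_stopwords(
            model.matrix, ["the", "of", "and"], emb, model.synonym_sets,
            corr_threshold=0.8, gene_fraction=0.25,
        )
        assert stricter.terms <= base.terms


class TestLsa:
    def test_exact_rank_preserves_cosines(self):
        rng = np.random.default_rng(0)
        # rank-2 matrix, 8 entities x 6 terms
        A = rng.random((8, 2)) @ rng.random((2, 6))
        corpus = _corpus({f"g{i}": "x" for i in range(8)})
        m = fit_tfidf(corpus, max_df=1.0, min_df=1)
        # wrap A in a TermMatrix shell
        import scipy.sparse as sp
        from textora.vectorize import TermMatrix

        tm = TermMatrix(
            entities=[f"g{i}" for i in range(8)],
            terms=[f"t{j}" for j in range(6)],
            values=sp.csr_matrix(A),
            df=np.full(6, 8),
            params={},
        )
        emb = lsa(tm, k=2)
        full = A / np.linalg.norm(A, axis=1, keepdims=True)
        for i in range(8):
            for j in range(8):
                assert emb.vectors[i] @ emb.vectors[j] == pytest.approx(
                    full[i] @ full[j], abs=1e-8
                )

    def test_duplicate_rows_have_similarity_one(self):
        corpus = _corpus({"g1": "a b c", "g2": "a b c", "g3": "d e f", "g4": "a d"})
        m = fit_tfidf(corpus, max_df=1.0, min_df=1)
        emb = lsa(m, k=2)
        assert gene_similarity(emb, "g1", "g2") == pytest.approx(1.0, abs=1e-9)

    def test_self_similarity_and_symmetry(self, planted):
        _, _, _, model = planted
        emb = lsa(model.matrix, k=20)
        e = model.matrix.entities
        assert gene_similarity(emb, e[0], e[0]) == pytest.approx(1.0)
        assert gene_similarity(emb, e[0], e[1]) == pytest.approx(
            gene_similarity(emb, e[1], e[0])
        )

    def test_unknown_entity_is_lookup_error(self, planted):
        _, _, _, model = planted
        emb = lsa(model.matrix, k=5)
        with pytest.raises(LookupError_):
            gene_similarity(emb, "NOPE", model.matrix.entities[0])

    def test_k_too_large_rejected(self, planted):
        _, _, _, model = planted
        with pytest.raises(ParameterError):
            lsa(model.matrix, k=10_000)

    def test_planted_modules_within_above_between(self, planted):
        _, _, truth, model = planted
        emb = lsa(model.matrix, k=50)
        within, between = [], []
        mods = {m: truth.module_genes(m) for m in truth.markers}
        for m, genes in mods.items():
            for i, a in enumerate(genes[:8]):
                for b in genes[i + 1 : 8]:
                    within.append(gene_similarity(emb, a, b))
            other = mods[(m + 1) % len(mods)]
            for a in genes[:8]:
                for b in other[:8]:
                    between.append(gene_similarity(emb, a, b))
        assert np.mean(within) > np.mean(between)
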