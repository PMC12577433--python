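# Methods

`textora` learns a de novo gene-set database from free-text entity
descriptions and uses it for overrepresentation analysis (ORA).  This note
documents the model, its parameters and numerical choices, what the
synthetic corpus generator does and does not emulate, and the design
decisions taken where more than one reasonable choice existed.

## Corpus model

Each entity (gene, drug, …) contributes one *document*: the concatenation
of all its free-text descriptions across sources.  Descriptions are split
into sentences by a deterministic rule — terminal punctuation followed by
whitespace and an upper-case letter or digit, with a built-in abbreviation
veto list ("e.g.", "i.e.", "vs.", …).  No statistical sentence model is
used; splitting is reproducible everywhere and requires no downloads.

Words are obtained by splitting on spaces.  Characters outside
`[A-Za-z0-9+~-]` are stripped from token edges only, so `(Ca2+).` becomes
`Ca2+` and internal hyphens survive.  Casing carries signal in biomedical
text: a token is lowercased only when exactly one of its characters is
uppercase (`Protein` → `protein`), so symbols and abbreviations (`DNA`,
`BRaf`, `UPR`) keep their case.  Multi-word concepts are matched against a
phrase lexicon (phrases attested by ≥ 2 sources); every occurrence of every
lexicon phrase is recorded, nested and overlapping matches included, and a
phrase occurrence also counts its constituent unigrams.  The sub-term
filter downstream is the mechanism that resolves the resulting redundancy,
so counting both is deliberate.

Every (term, entity) → sentence link is retained in an excerpt index with
exact character spans, so any reported term can be traced to the sentences
that produced it.  The index is built on pre-synonym-replacement tokens; a
synonym label resolves to the union of its members' excerpts.

## Synonym sets

Vocabularies are full of interchangeable surface forms (plural/singular,
abbreviation/expansion).  Every token and phrase is embedded, embeddings
are L2-normalized, and HDBSCAN (`min_cluster_size=2`, `min_samples=2`) is
run over pairwise cosine distance.  Each cluster becomes a synonym set
labelled `~` + its most document-frequent member (ties broken
lexicographically); members are replaced by the label throughout the
corpus, conserving token counts.

Two refinements beyond the bare library call:

* **Near-duplicate refinement** (`synonym_max_distance`, default 0.3).
  Density clustering is relative: on a vocabulary whose bulk is mutually
  near-orthogonal it happily chains unrelated tokens into clusters.  Since
  synonyms are near-duplicates in embedding space, each raw cluster is
  split into connected components of its `distance ≤ 0.3` graph and
  undersized components revert to noise.  The default was chosen from
  embedding geometry: spelling variants sit at cosine distance ≤ ~0.27
  under the shipped embedder while unrelated tokens stay ≥ ~0.35.  Set to
  `None` to disable (e.g. for a transformer embedder with a different
  geometry, where a larger value may also be appropriate).
* **Deterministic embedder.**  The embedder is a pluggable contract; the
  shipped default hashes padded character 3-grams into 256 signed buckets
  and L2-normalizes.  It is fully deterministic, needs no network or model
  weights, and places spelling variants close together — which is the
  signal the clustering consumes.  A pretrained biomedical transformer
  encoder (mean pooling over the attention mask) can be dropped in through
  the same contract; nothing else changes.

Clustering runs over the full observed vocabulary (before document-
frequency filtering), which is quadratic in vocabulary size; at the corpus
sizes this package targets (up to a few thousand distinct terms per study)
the distance matrix stays small.

## tf-idf embedding

The entity-by-term matrix uses raw counts for tf and smoothed logarithmic
idf, `idf(t) = ln((1+N)/(1+df_t)) + 1`, followed by L2 row normalization
(`sklearn` `TfidfTransformer` semantics).  Terms with `df < 3` or
`df/N > 0.6` are dropped before weighting.  The idf variant
(`smooth`/`plain`), row norm (`l2`/none), `binary` and `sublinear_tf` are
explicit configuration recorded in the fitted matrix; sublinear tf is off
by default.  Note that row normalization changes effect sizes (sums of
tf-idf values) but never p-values, which depend only on the nonzero
pattern.

Binarizing the matrix yields the de novo gene-set database: term → set of
entities whose document contains it.  By construction a retained term's
gene set is never empty, and a nonzero at (g, t) exists exactly when the
excerpt index holds a sentence of g containing t (asserted in tests).

## Custom stopwords

Four cumulative rules flag generic terms, mirroring how uninteresting
reporting vocabulary ("exhibits", "several") leaks into enrichments:

1. terms whose embedding's Pearson correlation with the centroid (mean
   embedding) of a high-frequency word list exceeds 0.65 (raw vectors, not
   re-normalized);
2. phrases composed entirely of rule-1 stopwords;
3. synonym labels more than 50% of whose members are stopwords by the
   rule-1/rule-2 criteria (members are scored against the centroid
   directly, since replacement removed them from the vocabulary);
4. terms present in more than 15% of entities.

Fully-uppercase terms and cytogenetic band names
(`^([0-9]{1,2}|[XY])[pq][0-9]+(\.[0-9]+)?$`) are exempt: their ubiquity is
still informative.  The packaged high-frequency list is a synthetic
stand-in (generic English plus biomedical reporting vocabulary) for a
corpus-derived top-500 list; any list can be supplied.  The rules are
monotone in their thresholds: raising a threshold never adds a stopword.

## Overrepresentation testing

For a query of n genes against a background of N (default: all modelled
entities), each term with K background occurrences and k query occurrences
is scored with the upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeom(N, K, n); k = 0 gives exactly 1.

Benjamini-Hochberg step-up correction is applied over the **full
vocabulary** — every term is tested on every query.  Conditioning the test
family on the observed overlap (say, k ≥ 2) selects exactly the small
p-values and destroys null calibration for short queries: in a 3-gene
random query the conditional family collapses to a handful of terms whose
p-values approximate their own selection probabilities, and the measured
fraction of null queries with a "discovery" rises to tens of percent.
With the unconditional family the hypergeometric test is exact under
uniform sampling without replacement, and the null audit behaves (below).
The family size m is reported in the result metadata.

Enriched terms are those with FDR < 0.05 that also pass the post-filters:
k ≥ 2 (a single mentioning gene is anecdote, not enrichment) and not a
stopword.  Effect size = sum of the term's tf-idf values over the query;
total info = the same sum over all genes.  With a custom background, K and
N are recomputed by masking rows while tf-idf values stay frozen from
training — effect size is a corpus-level information measure, not a
query-time quantity.  Query symbols absent from the model are dropped and
listed in the metadata; a query gene outside a supplied background is an
error.

## Sub-term filtering and term grouping

Redundant sub-terms ("olfactory" next to "olfactory receptor") are removed
by a single pass over a graph on enriched terms: an edge connects two terms
when their gene sets are in a subset relation (the smaller wholly contained
in the larger — the reading consistent with sub-term/super-phrase pairs
whose super-phrase is rarer) *and* one term's whitespace-token sequence is
a contiguous subsequence of the other's ("rib" does not match "ribosome";
synonym labels are compared through their member strings).  A term survives
only if it is the highest-ranked among itself and its neighbours, under the
strict total order: effect size desc, FDR asc, total info desc, term asc.
The subset relation is computed over all model genes (a switchable choice;
the alternative is query genes only).

Surviving terms are grouped by communities of a weighted graph with
`w(t1,t2) = cossim(v(q,t1), v(q,t2)) · cossim(v(g,t1), v(g,t2))` — the
product of cosine similarities of the terms' tf-idf vectors restricted to
the query and over all genes.  Edges with w < 0.15 are removed; greedy
modularity maximization (edge-weighted) finds communities per connected
component, with nodes inserted in rank order so ties resolve
deterministically; isolated terms form singletons.  Each group is labelled
by its top three ranked members joined by " | ".  Results are invariant to
input row order.

## Synthetic corpora

The generator emulates the statistical skeleton of a description corpus:

* background words drawn from a Zipf distribution (default exponent 1.1
  over a 2,000-word vocabulary) arranged into period-terminated,
  capitalized sentences (3-6 per gene, 5-12 words each), so the splitter
  and casefold rule are exercised;
* optional planted modules: disjoint groups of genes (default 5 × 20 out
  of 200) whose documents each mention the module's reserved marker terms
  (default 3, two mentions each), with marker vocabulary disjoint from
  background so ground truth is unambiguous.  Half the genes belong to no
  module, as in real corpora where most genes share no annotated function
  with a given query — this also keeps marker prevalence (10% of genes)
  clear of the 15% stopword rule, which is a property of real marker terms
  too (terms specific enough to be interesting are rare);
* optional planted synonym pairs: spelling variants (`word`/`words`) of
  moderately frequent background words, substituted for their base with
  probability 0.5.

Everything is deterministic under the seed.  The generator does **not**
emulate biomedical prose: no grammar, no polysemy, no correlated topics,
no source-specific style, and marker terms are planted exactly rather than
paraphrased.  Passing tests therefore demonstrate the statistical and
algorithmic correctness of the pipeline — calibration, recovery of planted
signal, determinism — not linguistic robustness on real descriptions.

## Evaluation procedures

* **False-discovery audit**: 110 random queries (lengths 3, 5, 10, 15, 20,
  25, 50, 100, 250, 500, 1000; 10 replicates each) sampled uniformly
  without replacement from the model's entities and run through the full
  pipeline.  On a 2,000-gene null corpus at most ~1% of queries return any
  enriched term (typically 0-3 of 110, seed-dependent); this is the
  quantity `scripts/acceptance.py` recomputes.
* **Sensitivity audit**: gene sets sampled from the model's own binarized
  database (sizes 3-99) vs size-matched random sets, classified by
  any-enrichment; precision/recall/F1 for the "real" class per repetition.
* **Overlap probability**: fraction of sampled gene-set pairs in which the
  smaller set shares at least half its members with the larger.
* **Cross-model kNN recovery**: two models restricted to shared vocabulary
  (minus terms matching entity symbols, which would connect neighbours
  trivially), cosine nearest neighbours of each target entity, fraction of
  entities with an expected counterpart within k.

## Problem sizes and degenerate inputs

Default test and audit sizes (200-2,000 genes, ~1,000-2,000-term
vocabularies) were chosen as the smallest scales at which the planted
structure and the null calibration are comfortably resolvable; all scale
knobs are public.  Degenerate inputs fail loudly: empty corpora, a
vocabulary emptied by df filtering, fewer entities than `min_df`, queries
with no known gene, zero-vector cosine similarities and out-of-range
p-values all raise typed errors rather than returning silently wrong
numbers.  Bundles are written atomically (never a partial directory) with
Matrix Market floats at 17 significant digits, making save → load → save
byte-identical.

## Known limitations

* The deterministic embedder captures spelling variation only; it cannot
  cluster an abbreviation with its expansion ("UPR" with "unfolded protein
  response") — that requires a semantic encoder plugged into the same
  contract.
* Synonym clustering materializes a dense V×V distance matrix; very large
  vocabularies (≫ 10⁴) would need a blocked or approximate-neighbour
  variant.
* Entity symbols are taken at face value; symbol harmonization is assumed
  done upstream.
* The stopword centroid rule inherits the character of the supplied
  embedder: with the hashing embedder it measures orthographic, not
  semantic, similarity to the common-word list.
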