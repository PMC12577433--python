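"""Sub-term filtering and graph-based term grouping."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from textora.enrich import EnrichmentRow
from textora.errors import ParameterError
from textora.termgraph import (
    filter_subterms,
    group_terms,
    group_weight,
    is_subterm,
    rank_key,
)
from textora.vectorize import TermMatrix


def _row(term, effect, fdr=0.01, total=1.0):
    return EnrichmentRow(
        term=term, k=2, K=2, n=2, N=10, p_value=fdr, fdr=fdr,
        effect_size=effect, total_info=total,
    )


class TestIsSubterm:
    def test_token_subsequence_not_substring(self):
        assert is_subterm("olfactory", "olfactory receptor")
        assert not is_subterm("rib", "ribosome")

    def test_symmetric(self):
        assert is_subterm("olfactory receptor", "olfactory")

    def test_synonym_labels_compared_via_members(self):
        syn = {"~UPR": ["UPR", "unfolded protein response"]}
        assert is_subterm("~UPR", "unfolded protein", syn)
        assert not is_subterm("~UPR", "ribosome biogenesis", syn)


class TestFilterSubterms:
    def test_redundant_subterm_removed(self):
        rows = [_row("olfactory receptor", 5.0), _row("olfactory", 2.0)]
        sets = {"olfactory": {"g1", "g2"}, "olfactory receptor": {"g1", "g2"}}
        kept = filter_subterms(rows, sets)
        assert [r.term for r in kept] == ["olfactory receptor"]

    def test_disjoint_gene_sets_both_kept(self):
        rows = [_row("alpha", 5.0), _row("beta", 2.0)]
        sets = {"alpha": {"g1"}, "beta": {"g2"}}
        assert len(filter_subterms(rows, sets)) == 2

    def test_higher_ranked_subterm_drops_superphrase(self):
        rows = [_row("olfactory", 9.0), _row("olfactory receptor", 2.0)]
        sets = {"olfactory": {"g1", "g2", "g3"}, "olfactory receptor": {"g1", "g2"}}
        kept = filter_subterms(rows, sets)
        assert [r.term for r in kept] == ["olfactory"]

    def test_subset_without_string_relation_keeps_both(self):
        rows = [_row("kinase", 5.0), _row("phosphatase", 2.0)]
        sets = {"kinase": {"g1", "g2"}, "phosphatase": {"g1", "g2"}}
        assert len(filter_subterms(rows, sets)) == 2

    def _bruteforce(self, rows, sets):
        """Independent restatement: a term survives iff no connected term
        (subset gene sets + string sub-term) outranks it."""
        kept = []
        for r in rows:
            beaten = False
            for o in rows:
                if o.term == r.term:
                    continue
                s1, s2 = sets[r.term], sets[o.term]
                if (s1 <= s2 or s2 <= s1) and is_subterm(r.term, o.term):
                    if rank_key(o) < rank_key(r):
                        beaten = True
            if not beaten:
                kept.append(r.term)
        return kept

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(13)
        words = ["olfactory", "receptor", "kinase", "signal"]
        for _ in range(100):
            n_terms = int(rng.integers(2, 12))
            terms = set()
            while len(terms) < n_terms:
                length = int(rng.integers(1, 3))
                terms.add(" ".join(rng.choice(words, size=length, replace=False)))
            genes = [f"g{i}" for i in range(6)]
            sets = {
                t: set(rng.choice(genes, size=int(rng.integers(1, 6)), replace=False))
                for t in terms
            }
            rows = [
                _row(t, float(rng.integers(1, 5)), float(rng.choice([0.01, 0.02])))
                for t in terms
            ]
            got = sorted(r.term for r in filter_subterms(rows, sets))
            want = sorted(self._bruteforce(rows, sets))
            assert got == want

    def test_invariant_terms_without_subset_relation_survive(self):
        rng = np.random.default_rng(3)
        rows = [_row(t, float(i)) for i, t in enumerate(["a", "a b", "c", "c d"])]
        sets = {"a": {"g1"}, "a b": {"g2"}, "c": {"g3"}, "c d": {"g4"}}
        assert len(filter_subterms(rows, sets)) == 4


def _matrix(values, entities=None, terms=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    return TermMatrix(
        entities=entities or [f"g{i}" for i in range(n)],
        terms=terms or [f"t{j}" for j in range(t)],
        values=sp.csr_matrix(values),
        df=(values > 0).sum(axis=0).astype(int),
        params={},
    )


class TestGroupWeight:
    def test_identical_vectors_weight_one(self):
        m = _matrix([[1, 1], [2, 2], [0.5, 0.5]])
        w = group_weight("t0", "t1", m, ["g0", "g1"])
        assert w == pytest.approx(1.0)

    def test_orthogonal_query_vectors_zero(self):
        # identical across the corpus except inside the query
        m = _matrix([[1, 0], [0, 1], [1, 1], [1, 1]])
        assert group_weight("t0", "t1", m, ["g0", "g1"]) == pytest.approx(0.0)

    def test_hand_computed_product(self):
        vals = [[1, 2], [2, 1], [1, 0]]
        m = _matrix(vals)
        q = ["g0", "g1"]
        vq1, vq2 = np.array([1, 2.0]), np.array([2, 1.0])
        vg1, vg2 = np.array([1, 2, 1.0]), np.array([2, 1, 0.0])
        cos = lambda a, b: a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert group_weight("t0", "t1", m, q) == pytest.approx(
            cos(vq1, vq2) * cos(vg1, vg2)
        )

    def test_zero_vector_rejected(self):
        m = _matrix([[0, 1], [0, 1]])
        with pytest.raises(ParameterError):
            group_weight("t0", "t1", m, ["g0", "g1"])


class TestGroupTerms:
    def test_two_cliques_two_groups(self):
        # t0,t1 identical; t2,t3 identical; cliques orthogonal
        m = _matrix([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        rows = [_row(f"t{j}", 4.0 - j) for j in range(4)]
        groups, label_of = group_terms(rows, m, ["g0", "g1", "g2", "g3"])
        assert len(groups) == 2
        assert label_of["t0"] == "t0 | t1"
        assert label_of["t2"] == "t2 | t3"

    def test_all_weak_edges_all_singletons(self):
        m = _matrix(np.eye(4))
        rows = [_row(f"t{j}", 4.0 - j) for j in range(4)]
        groups, label_of = group_terms(rows, m, [f"g{i}" for i in range(4)])
        assert len(groups) == 4
        assert all(label_of[r.term] == r.term for r in rows)

    def test_label_uses_three_top_ranked(self):
        m = _matrix(np.ones((3, 4)))
        rows = [_row("t0", 1.0), _row("t1", 9.0), _row("t2", 5.0), _row("t3", 3.0)]
        groups, label_of = group_terms(rows, m, ["g0", "g1"])
        assert len(groups) == 1
        assert groups[0].label == "t1 | t2 | t3"

    def test_groups_partition_terms(self, planted):
        from textora.enrich import Query, enrich

        _, _, truth, model = planted
        res = enrich(model, Query(genes=set(truth.module_genes(0))))
        seen = [t for g in res.groups for t in g.members]
        assert sorted(seen) == sorted(r.term for r in res.rows)
        assert all(r.group_label for r in res.rows)

    def test_threshold_above_one_gives_singletons(self):
        m = _matrix(np.ones((3, 3)))
        rows = [_row(f"t{j}", 3.0 - j) for j in range(3)]
        groups, _ = group_terms(rows, m, ["g0", "g1"], weight_threshold=1.0 + 1e-9)
        assert len(groups) == 3

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        vals = rng.random((6, 8))
        m = _matrix(vals)
        rows = [_row(f"t{j}", float(rng.integers(1, 10))) for j in range(8)]
        q = [f"g{i}" for i in range(3)]
        g1, l1 = group_terms(rows, m, q)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        g2, l2 = group_terms(shuffled, m, q)
        assert l1 == l2
        assert [g.label for g in g1] == [g.label for g in g2]

    def test_zero_threshold_groups_refine_components(self):
        rng = np.random.default_rng(9)
        vals = rng.random((5, 7)) * (rng.random((5, 7)) > 0.4)
        vals[:, 0] += 0.01  # avoid zero columns
        vals[0, :] += 0.01
        m = _matrix(vals)
        rows = [_row(f"t{j}", float(j)) for j in range(7)]
        q = [f"g{i}" for i in range(5)]
        groups, _ = group_terms(rows, m, q, weight_threshold=0.0)
        # every group must live inside one connected component of the
        # positive-weight graph
        import networkx as nx
        from textora.termgraph import _pairwise_weights

        W = _pairwise_weights([f"t{j}" for j in range(7)], m, q)
        G = nx.Graph()
        G.add_nodes_from(range(7))
        for i, j in itertools.combinations(range(7), 2):
            if W[i, j] > 0:
                G.add_edge(i, j)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(G)):
            for node in comp:
                comp_of[f"t{node}"] = ci
        for g in groups:
            assert len({comp_of[t] for t in g.members}) == 1
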