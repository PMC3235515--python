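import numpy as np
import pytest

from dbcbin.sequence_io import SequenceRecord, reverse_complement
from dbcbin.signature import (
    DBCSignature,
    KmerCountTable,
    UnsignableSequenceError,
    build_chain,
    compute_signature,
    connectivity_weights,
    count_words,
    index_word,
    signature_distance,
    stationary_distribution,
    word_index,
)
from conftest import random_acgt


def eigen_stationary(P: np.ndarray) -> np.ndarray:
    """Oracle: leading left eigenvector of P from a dense eigendecomposition."""
    vals, vecs = np.linalg.eig(P.T)
    lead = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, lead])
    return pi / pi.sum()


def random_chain(rng, k, length=None):
    length = length or int(rng.integers(200, 2000))
    rec = SequenceRecord("r", random_acgt(rng, length))
    return build_chain(count_words(rec, k), lam=0.01)


class TestWordIndexing:
    def test_lexicographic_order(self):
        assert [index_word(i, 2) for i in range(4)] == ["AA", "AC", "AG", "AT"]
        assert word_index("TT") == 15
        assert word_index(index_word(137, 4)) == 137


class TestCountWords:
    def test_palindromic_site_counts_double(self):
        t = count_words(SequenceRecord("x", "ACGT"), 2)
        assert t.nonzero_nodes() == {"AC": 2, "CG": 2, "GT": 2}
        assert t.nonzero_edges() == {"ACG": 2, "CGT": 2}
        assert t.total_edges == 4

    def test_homopolymer_counts_both_strands(self):
        t = count_words(SequenceRecord("x", "AAAAA"), 2)
        assert t.nonzero_nodes() == {"AA": 4, "TT": 4}
        assert t.nonzero_edges() == {"AAA": 3, "TTT": 3}

    def test_too_short_for_edges_gives_empty_table(self):
        t = count_words(SequenceRecord("x", "AC"), 2)
        assert t.nonzero_nodes() == {"AC": 1, "GT": 1}
        assert t.total_edges == 0

    def test_windows_never_span_ambiguity_splits(self):
        # ACGTNNACG: segment words only; no word contains the junction
        t = count_words(SequenceRecord("x", "ACGTNNACG"), 2)
        assert "TA" not in t.nonzero_nodes()
        assert t.nonzero_edges()["ACG"] == 3  # ACGT, ACG forward + revcomp CGT of ACG...

    def test_rejects_k_below_one(self):
        with pytest.raises(ValueError):
            count_words(SequenceRecord("x", "ACGT"), 0)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_strand_symmetry_of_counts(self, rng, k):
        seq = random_acgt(rng, 500)
        t = count_words(SequenceRecord("x", seq), k)
        for words, kk in ((t.nonzero_nodes(), k), (t.nonzero_edges(), k + 1)):
            for w, c in words.items():
                assert words[reverse_complement(w)] == c


class TestBuildChain:
    def test_homopolymer_chain_structure(self):
        chain = build_chain(count_words(SequenceRecord("x", "AAAAA"), 2), lam=0.01)
        assert chain.node_words() == ["AA", "TT"]
        assert np.allclose(chain.P_raw, np.eye(2))
        # two singleton strongly connected components, each holding half the mass
        assert len(set(chain.component_labels)) == 2
        assert np.allclose(np.sort(chain.component_mass), [0.5, 0.5])

    def test_damped_rows_sum_to_one(self, rng):
        for k in (2, 3, 4):
            chain = random_chain(rng, k)
            assert np.allclose(chain.P.sum(axis=1), 1.0, atol=1e-12)

    def test_component_masses_sum_to_one(self, rng):
        chain = random_chain(rng, 3)
        assert abs(chain.component_mass.sum() - 1.0) < 1e-12

    def test_uniform_edge_counts_give_uniform_chain(self):
        k = 2
        t = KmerCountTable(
            k=k,
            node_counts=np.ones(4**k, dtype=np.int64),
            edge_counts=np.ones(4 ** (k + 1), dtype=np.int64),
        )
        chain = build_chain(t, lam=0.01)
        assert chain.n_nodes == 4**k
        # each node has exactly its 4 legal successors at probability 1/4
        assert np.allclose(chain.P_raw[chain.P_raw > 0], 0.25)
        assert (chain.P_raw > 0).sum() == 4 ** (k + 1)
        assert len(chain.component_mass) == 1 and chain.component_mass[0] == 1.0

    def test_empty_table_signals_too_short(self):
        t = count_words(SequenceRecord("x", "AC"), 2)
        with pytest.raises(UnsignableSequenceError, match="too short"):
            build_chain(t)

    def test_invalid_damping_rejected(self):
        t = count_words(SequenceRecord("x", "ACGTACGT"), 2)
        for lam in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                build_chain(t, lam=lam)

    def test_components_match_networkx_oracle(self, rng):
        import networkx as nx

        for k in (2, 3):
            chain = random_chain(rng, k)
            g = nx.DiGraph()
            g.add_nodes_from(range(chain.n_nodes))
            # raw positive-probability edges excluding dead-row uniform fill
            out_deg = (chain.P_raw > 0).sum(axis=1)
            for u in range(chain.n_nodes):
                if out_deg[u] == chain.n_nodes:  # dead row made uniform
                    continue
                for v in np.nonzero(chain.P_raw[u])[0]:
                    g.add_edge(u, int(v))
            ours = {frozenset(np.nonzero(chain.component_labels == c)[0].tolist())
                    for c in set(chain.component_labels)}
            theirs = {frozenset(c) for c in nx.strongly_connected_components(g)}
            assert ours == theirs


class TestStationaryDistribution:
    def test_uniform_chain_is_uniform(self):
        k = 2
        t = KmerCountTable(k, np.ones(16, np.int64), np.ones(64, np.int64))
        pi = stationary_distribution(build_chain(t, lam=0.01))
        assert np.allclose(pi, 1 / 16, atol=1e-10)

    def test_homopolymer_symmetry(self):
        for lam in (0.01, 0.2):
            chain = build_chain(count_words(SequenceRecord("x", "AAAAA"), 2), lam=lam)
            pi = stationary_distribution(chain)
            assert np.allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_matches_eigen_oracle_on_random_chains(self, rng):
        for i in range(30):
            chain = random_chain(rng, [2, 3, 4][i % 3])
            pi = stationary_distribution(chain, tol=1e-12)
            assert np.max(np.abs(pi @ chain.P - pi)) <= 1e-10
            assert np.max(np.abs(pi - eigen_stationary(chain.P))) < 1e-8

    def test_nonconvergence_raises(self, rng):
        chain = random_chain(rng, 3)
        with pytest.raises(RuntimeError, match="power iteration"):
            stationary_distribution(chain, tol=0.0, max_iter=2)


class TestConnectivityWeights:
    def test_single_component_weight_is_one(self, rng):
        k = 2
        t = KmerCountTable(k, np.ones(16, np.int64), np.ones(64, np.int64))
        assert np.allclose(connectivity_weights(build_chain(t)), 1.0)

    def test_homopolymer_weights(self):
        chain = build_chain(count_words(SequenceRecord("x", "AAAAA"), 2))
        assert np.allclose(connectivity_weights(chain), [0.5, 0.5])

    def test_three_components_carry_their_mass_shares(self):
        # three self-loop nodes AA, CC, GG with edge counts 6/3/1
        edge = np.zeros(64, dtype=np.int64)
        edge[word_index("AAA")] = 6
        edge[word_index("CCC")] = 3
        edge[word_index("GGG")] = 1
        chain = build_chain(KmerCountTable(2, np.zeros(16, np.int64), edge))
        w = dict(zip(chain.node_words(), connectivity_weights(chain)))
        assert w == pytest.approx({"AA": 0.6, "CC": 0.3, "GG": 0.1})


class TestComputeSignature:
    def test_homopolymer_signature(self):
        s = compute_signature(SequenceRecord("x", "AAAAA"), k=2)
        expected = np.zeros(16)
        expected[word_index("AA")] = 0.5
        expected[word_index("TT")] = 0.5
        assert np.allclose(s.vector, expected, atol=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_strand_invariance(self, rng, k):
        seq = random_acgt(rng, 800)
        a = compute_signature(SequenceRecord("f", seq), k=k)
        b = compute_signature(SequenceRecord("r", reverse_complement(seq)), k=k)
        assert np.max(np.abs(a.vector - b.vector)) <= 1e-12

    def test_simplex_membership_on_random_sequences(self, rng):
        for _ in range(20):
            s = compute_signature(SequenceRecord("x", random_acgt(rng, 5000)), k=3)
            assert np.all(s.vector >= 0)
            assert abs(s.vector.sum() - 1.0) <= 1e-9

    def test_too_short_record_is_unsignable(self):
        with pytest.raises(UnsignableSequenceError):
            compute_signature(SequenceRecord("x", "ACN"), k=3)


class TestSignatureDistance:
    def unit(self, word, k=2):
        v = np.zeros(4**k)
        v[word_index(word)] = 1.0
        return DBCSignature(k=k, vector=v)

    def test_identity_and_symmetry(self, rng):
        a = compute_signature(SequenceRecord("a", random_acgt(rng, 300)), k=2)
        b = compute_signature(SequenceRecord("b", random_acgt(rng, 300)), k=2)
        assert signature_distance(a, a) == 0.0
        assert signature_distance(a, b) == signature_distance(b, a) > 0

    def test_disjoint_unit_masses_are_sqrt2_apart(self):
        assert signature_distance(self.unit("AA"), self.unit("AC")) == pytest.approx(np.sqrt(2))

    def test_order_mismatch_rejected(self):
        with pytest.raises(ValueError, match="order mismatch"):
            signature_distance(self.unit("AA", 2), self.unit("AAA", 3))

    def test_cosine_metric_option(self):
        assert signature_distance(self.unit("AA"), self.unit("AC"), metric="cosine") == pytest.approx(1.0)
        assert signature_distance(self.unit("AA"), self.unit("AA"), metric="cosine") == pytest.approx(0.0)
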