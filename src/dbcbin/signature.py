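"""De Bruijn chain (DBC) genomic signatures.

A double-stranded sequence is treated as a walk in a de Bruijn graph whose
nodes are the order-k words it contains and whose edges are its (k+1)-words.
The signature of the sequence is derived from two artifacts of the induced
Markov chain:

* the stationary distribution pi of the damped transition matrix, and
* a per-node connectivity weight w equal to the share of total (k+1)-word
  mass carried by the node's strongly connected component.

The signature entry for an observed word u is pi(u) * w(u); unobserved words
get 0 and the vector is renormalized to sum to 1, indexed lexicographically
(A < C < G < T) over all 4**k words. Counting both strands makes the
signature of a sequence and of its reverse complement identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .sequence_io import SequenceRecord, reverse_complement, sanitize

__all__ = [
    "UnsignableSequenceError",
    "KmerCountTable",
    "DeBruijnChain",
    "DBCSignature",
    "word_index",
    "index_word",
    "count_words",
    "build_chain",
    "stationary_distribution",
    "connectivity_weights",
    "compute_signature",
    "signature_distance",
]

ALPHABET = "ACGT"

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class UnsignableSequenceError(ValueError):
    """Sequence has no A/C/G/T segment of length >= k+1; no chain exists."""


def word_index(word: str) -> int:
    """Lexicographic index (A<C<G<T) of a word, i.e. its base-4 value."""
    idx = 0
    for ch in word:
        code = "ACGT".find(ch)
        if code < 0:
            raise ValueError(f"non-ACGT character {ch!r} in word {word!r}")
        idx = idx * 4 + code
    return idx


def index_word(index: int, k: int) -> str:
    """Inverse of :func:`word_index` for words of length k."""
    chars = []
    for _ in range(k):
        chars.append(ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(chars))


def _encode(segment: str) -> np.ndarray:
    return _CODE[np.frombuffer(segment.encode("ascii"), dtype=np.uint8)]


def _word_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Indices of all length-k sliding windows of a code array (len >= k)."""
    n = len(codes) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : j + n]
    return idx


@dataclass
class KmerCountTable:
    """Double-stranded counts of order-k and order-(k+1) words.

    Counts are dense arrays indexed lexicographically; they satisfy
    count(w) == count(reverse_complement(w)) by construction because both
    the sequence and its reverse complement are counted.
    """

    k: int
    node_counts: np.ndarray  # length 4**k
    edge_counts: np.ndarray  # length 4**(k+1)

    @property
    def total_edges(self) -> int:
        return int(self.edge_counts.sum())

    def node_count(self, word: str) -> int:
        return int(self.node_counts[word_index(word)])

    def edge_count(self, word: str) -> int:
        return int(self.edge_counts[word_index(word)])

    def nonzero_nodes(self) -> dict[str, int]:
        nz = np.nonzero(self.node_counts)[0]
        return {index_word(i, self.k): int(self.node_counts[i]) for i in nz}

    def nonzero_edges(self) -> dict[str, int]:
        nz = np.nonzero(self.edge_counts)[0]
        return {index_word(i, self.k + 1): int(self.edge_counts[i]) for i in nz}


def count_words(record: SequenceRecord | str, k: int) -> KmerCountTable:
    """Count order-k and order-(k+1) words on both strands of a record.

    The sequence is first split into A/C/G/T segments; windows never span a
    segment boundary. Returns an empty table (total_edges == 0) when every
    segment is shorter than k+1.
    """
    if k < 1:
        raise ValueError(f"word length k must be >= 1, got {k}")
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    nk = 4**k
    node = np.zeros(nk, dtype=np.int64)
    edge = np.zeros(4 * nk, dtype=np.int64)
    for segment in sanitize(seq):
        for strand in (segment, reverse_complement(segment)):
            codes = _encode(strand)
            if len(codes) >= k:
                node += np.bincount(_word_indices(codes, k), minlength=nk)
            if len(codes) >= k + 1:
                edge += np.bincount(_word_indices(codes, k + 1), minlength=4 * nk)
    return KmerCountTable(k=k, node_counts=node, edge_counts=edge)


@dataclass
class DeBruijnChain:
    """Markov chain over the observed order-k words of one sequence.

    `nodes` holds the lexicographic word indices of observed nodes (words
    appearing as prefix or suffix of a counted (k+1)-word), sorted. `P_raw`
    is the undamped row-stochastic matrix (rows without outgoing counted
    edges are uniform); `P` is the damped matrix (1-lam)*P_raw + lam/n.
    Strongly connected components are computed on the counted-edge graph
    only; `component_mass[c]` is that component's share of total
    (k+1)-word count mass.
    """

    k: int
    lam: float
    nodes: np.ndarray
    P_raw: np.ndarray
    P: np.ndarray
    component_labels: np.ndarray
    component_mass: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_words(self) -> list[str]:
        return [index_word(int(i), self.k) for i in self.nodes]


def build_chain(counts: KmerCountTable, lam: float = 0.01) -> DeBruijnChain:
    """Build the (damped) de Bruijn chain from a word-count table."""
    if not 0.0 < lam < 1.0:
        raise ValueError(f"damping must lie in (0, 1), got {lam}")
    total = counts.total_edges
    if total == 0:
        raise UnsignableSequenceError(
            f"sequence too short for order k={counts.k}: no (k+1)-word observed"
        )
    nk = 4**counts.k
    edge_words = np.nonzero(counts.edge_counts)[0]
    weights = counts.edge_counts[edge_words].astype(float)
    prefixes = edge_words // 4
    suffixes = edge_words % nk

    nodes = np.unique(np.concatenate([prefixes, suffixes]))
    n = len(nodes)
    pos = np.full(nk, -1, dtype=np.int64)
    pos[nodes] = np.arange(n)

    M = np.zeros((n, n))
    np.add.at(M, (pos[prefixes], pos[suffixes]), weights)
    out = M.sum(axis=1)
    P_raw = np.empty_like(M)
    live = out > 0
    P_raw[live] = M[live] / out[live, None]
    P_raw[~live] = 1.0 / n

    graph = sparse.csr_matrix(
        (np.ones(len(edge_words)), (pos[prefixes], pos[suffixes])), shape=(n, n)
    )
    n_comp, labels = csgraph.connected_components(
        graph, directed=True, connection="strong"
    )
    mass = np.zeros(n_comp)
    np.add.at(mass, labels, out)
    mass /= out.sum()

    P = (1.0 - lam) * P_raw + lam / n
    return DeBruijnChain(
        k=counts.k,
        lam=lam,
        nodes=nodes,
        P_raw=P_raw,
        P=P,
        component_labels=labels,
        component_mass=mass,
    )


def stationary_distribution(
    chain: DeBruijnChain, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Stationary distribution of the damped chain by power iteration.

    Starts from the uniform vector and iterates pi <- pi @ P until
    successive iterates differ by at most `tol` in max norm (which is also
    the stationarity residual ||pi P - pi||_inf at exit). Damping makes the
    chain irreducible and aperiodic, so convergence is guaranteed; the
    iteration cap exists only to turn a numerical surprise into a loud
    error instead of a silent truncation.
    """
    n = chain.n_nodes
    pi = np.full(n, 1.0 / n)
    P = chain.P
    for _ in range(max_iter):
        nxt = pi @ P
        if np.max(np.abs(nxt - pi)) <= tol:
            return nxt
        pi = nxt
    raise RuntimeError(
        f"power iteration did not reach tol={tol} within {max_iter} iterations"
    )


def connectivity_weights(chain: DeBruijnChain) -> np.ndarray:
    """Per-node weight: mass share of the node's strongly connected component."""
    return chain.component_mass[chain.component_labels]


@dataclass
class DBCSignature:
    """Normalized signature vector over all 4**k order-k words.

    `vector` sums to 1 and is strand-invariant. `nodes`, `pi` and `weights`
    record the observed words, their stationary probabilities and their
    component weights for provenance.
    """

    k: int
    vector: np.ndarray
    nodes: np.ndarray = field(repr=False, default=None)
    pi: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)


def compute_signature(
    record: SequenceRecord | str,
    k: int = 3,
    lam: float = 0.01,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> DBCSignature:
    """DBC signature of one sequence: embed pi(u)*w(u), renormalized."""
    counts = count_words(record, k)
    chain = build_chain(counts, lam=lam)
    pi = stationary_distribution(chain, tol=tol, max_iter=max_iter)
    w = connectivity_weights(chain)
    raw = pi * w
    s = np.zeros(4**k)
    s[chain.nodes] = raw
    s /= s.sum()
    return DBCSignature(k=k, vector=s, nodes=chain.nodes, pi=pi, weights=w)


def signature_distance(a: DBCSignature, b: DBCSignature, metric: str = "euclidean") -> float:
    """Distance between two signatures of the same order."""
    if a.k != b.k:
        raise ValueError(f"signature order mismatch: {a.k} != {b.k}")
    return vector_distance(a.vector, b.vector, metric=metric)


def vector_distance(u: np.ndarray, v: np.ndarray, metric: str = "euclidean") -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cosine":
        nu = np.linalg.norm(u)
        nv = np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - np.dot(u, v) / (nu * nv))
    raise ValueError(f"unknown distance metric {metric!r}")
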