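"""Bipartite network embedding by joint explicit/implicit optimisation.

The trainer learns one embedding per drug and per target from the bipartite
interaction matrix alone.  Two kinds of relation are modelled jointly:

* explicit relations — observed drug-target edges, pulled together through a
  KL-divergence term on the edge reconstruction probability
  sigma(u_i . v_j), ascended with weight ``gamma``;
* implicit transition relations — second-order proximity between two drugs
  (or two targets) that share interaction partners.  These are materialised
  as the co-citation style homogeneous matrices ``G_b G_b^T`` (drugs) and
  ``G_b^T G_b`` (targets), turned into corpora of truncated random walks
  with restart, and fitted with skip-gram negative sampling under weights
  ``alpha`` (drug corpus) and ``beta`` (target corpus).

All randomness flows through a single ``numpy`` generator derived from the
hyper-parameter seed, so training is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .network import BipartiteDTINetwork

__all__ = [
    "CoHitsMatrix",
    "BineHyperparams",
    "WalkCorpus",
    "EmbeddingTable",
    "cohits_homogeneous",
    "generate_walks",
    "explicit_update",
    "implicit_update",
    "train_bine",
]

logger = logging.getLogger(__name__)

# hard cap on walk length so stop_prob=0 cannot loop forever
_MAX_WALK_LEN = 100


@dataclass
class CoHitsMatrix:
    """Second-type homogeneous network: shared-partner weights per side."""

    side: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("co-citation matrix must be square")
        self.values = vals


@dataclass(frozen=True)
class BineHyperparams:
    """Training knobs for the bipartite embedder.

    Defaults follow the smallest benchmark profile: 64-dimensional
    embeddings, learning rate 0.1, 4 negative samples, window 5, trade-off
    weights alpha=0.01 / beta=0.1 / gamma=0.1, walk stopping probability
    0.15 and restart probability 0.7, 100 training epochs.
    """

    dim: int = 64
    max_iter: int = 100
    lr: float = 0.1
    ns: int = 4
    ws: int = 5
    alpha: float = 0.01
    beta: float = 0.1
    gamma: float = 0.1
    stop_prob: float = 0.15
    restart_prob: float = 0.7
    max_walks: int = 32
    min_walks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.ns < 0:
            raise ValueError("ns must be >= 0")
        if self.ws < 1:
            raise ValueError("ws must be >= 1")
        for nm in ("stop_prob", "restart_prob"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        for nm in ("alpha", "beta", "gamma"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not 1 <= self.min_walks <= self.max_walks:
            raise ValueError("need 1 <= min_walks <= max_walks")

    def with_seed(self, seed: int) -> "BineHyperparams":
        return replace(self, seed=seed)


@dataclass
class WalkCorpus:
    """Vertex-index sequences produced by truncated walks on one side."""

    side: str
    sequences: list[list[int]]

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.sequences):
            raise ValueError("corpus sequences must be non-empty")


@dataclass
class EmbeddingTable:
    """Per-vertex embeddings plus the paired skip-gram context vectors."""

    side: str
    vectors: np.ndarray
    context_vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape != self.context_vectors.shape:
            raise ValueError("vectors and context_vectors must share a shape")
        if not (np.isfinite(self.vectors).all() and np.isfinite(self.context_vectors).all()):
            raise ValueError("embedding table has non-finite entries")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def cohits_homogeneous(network: BipartiteDTINetwork, side: str) -> CoHitsMatrix:
    """Shared-partner homogeneous matrix for one side of the network.

    With binary interaction weights, entry (i, j) of the drug-side matrix
    ``G_b G_b^T`` counts the targets shared by drugs i and j (and the
    target-side matrix ``G_b^T G_b`` counts shared drugs).
    """
    gb = network.adjacency
    if side == "drug":
        return CoHitsMatrix("drug", gb @ gb.T)
    if side == "target":
        return CoHitsMatrix("target", gb.T @ gb)
    raise ValueError(f"side must be 'drug' or 'target', got {side!r}")


def _walks_per_vertex(homo: CoHitsMatrix, params: BineHyperparams) -> np.ndarray:
    """Centrality-scaled walk counts in [min_walks, max_walks] per vertex.

    Centrality is the vertex's total shared-partner weight (row sum); counts
    are allocated proportionally, so hub vertices seed more sequences.
    Vertices without any off-diagonal weight get 0 (they are skipped).
    """
    vals = homo.values
    off = vals - np.diag(np.diag(vals))
    centrality = off.sum(axis=1)
    counts = np.zeros(len(vals), dtype=int)
    eligible = centrality > 0
    if eligible.any():
        cmax = centrality[eligible].max()
        scaled = params.min_walks + np.rint(
            (params.max_walks - params.min_walks) * centrality[eligible] / cmax
        ).astype(int)
        counts[eligible] = scaled
    return counts


def generate_walks(
    homo: CoHitsMatrix,
    params: BineHyperparams,
    rng: np.random.Generator | None = None,
) -> WalkCorpus:
    """Truncated random walks with restart over a homogeneous matrix.

    Each eligible start vertex seeds between ``min_walks`` and ``max_walks``
    sequences.  At every step the walk stops with probability ``stop_prob``;
    otherwise the next vertex is drawn among the current vertex's non-zero
    off-diagonal neighbours with probability proportional to edge weight,
    and is then replaced by the start vertex with probability
    ``restart_prob`` (keeping sequences local to their start).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vals = homo.values
    k = vals.shape[0]
    if k == 0:
        raise ValueError("no walkable vertices: empty matrix")
    off = vals.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    if not (row_sums > 0).any():
        raise ValueError("no walkable vertices: all off-diagonal weights are zero")

    # per-vertex cumulative transition distributions, built once
    neighbors: list[np.ndarray | None] = [None] * k
    cumprobs: list[np.ndarray | None] = [None] * k
    for v in range(k):
        if row_sums[v] > 0:
            nz = np.nonzero(off[v])[0]
            neighbors[v] = nz
            cumprobs[v] = np.cumsum(off[v, nz] / row_sums[v])

    counts = _walks_per_vertex(homo, params)
    skipped = int((counts == 0).sum())
    if skipped:
        logger.info("generate_walks(%s): skipping %d isolated vertices", homo.side, skipped)

    sequences: list[list[int]] = []
    for start in range(k):
        for _ in range(counts[start]):
            seq = [start]
            cur = start
            while len(seq) < _MAX_WALK_LEN:
                if rng.random() < params.stop_prob:
                    break
                if cumprobs[cur] is None:
                    break
                nxt = int(neighbors[cur][np.searchsorted(cumprobs[cur], rng.random())])
                if rng.random() < params.restart_prob:
                    nxt = start
                seq.append(nxt)
                cur = nxt
            sequences.append(seq)
    return WalkCorpus(homo.side, sequences)


def explicit_update(
    u: np.ndarray, v: np.ndarray, w_ij: float, gamma: float, lr: float
) -> tuple[np.ndarray, np.ndarray]:
    """One ascent step on the explicit-edge term for a single edge.

    Returns ``u + lr * gamma * w_ij * (1 - sigma(u.v)) * v`` and the
    symmetric update of ``v``; the inputs are not mutated.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same length")
    if w_ij < 0:
        raise ValueError("edge weight must be non-negative")
    coeff = gamma * w_ij * (1.0 - _sigmoid(u @ v))
    return u + lr * coeff * v, v + lr * coeff * u


def implicit_update(
    tables: EmbeddingTable,
    center: int,
    context: int,
    negatives,
    weight: float,
    lr: float,
) -> EmbeddingTable:
    """One negative-sampling skip-gram ascent step on an implicit pair.

    The center embedding moves by
    ``lr * sum_z weight * (I(z) - sigma(u . theta_z)) * theta_z`` over
    ``z in {context} + negatives`` (indicator I = 1 only for the true
    context), and each context vector ``theta_z`` moves by the symmetric
    rule computed at the pre-update center.  Returns a new table.
    """
    n = tables.vectors.shape[0]
    zs = [context, *negatives]
    for z in (center, *zs):
        if not 0 <= z < n:
            raise ValueError(f"unknown vertex index {z}")
    vectors = tables.vectors.copy()
    contexts = tables.context_vectors.copy()
    u = vectors[center].copy()
    theta = contexts[zs]                       # (1 + ns, dim)
    indic = np.zeros(len(zs))
    indic[0] = 1.0
    coeff = weight * (indic - _sigmoid(theta @ u))
    vectors[center] = u + lr * (coeff @ theta)
    contexts[zs] += lr * np.outer(coeff, u)
    return EmbeddingTable(tables.side, vectors, contexts)


def _context_pairs(corpus: WalkCorpus, ws: int) -> np.ndarray:
    """All (center, context) pairs within the window, as an (N, 2) array."""
    pairs: list[tuple[int, int]] = []
    for seq in corpus.sequences:
        L = len(seq)
        for pos, center in enumerate(seq):
            lo, hi = max(0, pos - ws), min(L, pos + ws + 1)
            for q in range(lo, hi):
                if q != pos:
                    pairs.append((center, seq[q]))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


class _NegativeSampler:
    """Unigram^0.75 sampler over corpus vertex frequencies.

    A drawn negative equal to the center or the true context is redrawn a
    bounded number of times and dropped if still colliding.
    """

    _RETRIES = 10

    def __init__(self, corpus: WalkCorpus, n_vertices: int):
        freq = np.zeros(n_vertices)
        for seq in corpus.sequences:
            np.add.at(freq, seq, 1.0)
        weights = freq**0.75
        total = weights.sum()
        if total == 0:
            weights = np.ones(n_vertices)
            total = float(n_vertices)
        self._cum = np.cumsum(weights / total)

    def draw(self, rng: np.random.Generator, ns: int, center: int, context: int) -> list[int]:
        out: list[int] = []
        for _ in range(ns):
            for _ in range(self._RETRIES):
                z = int(np.searchsorted(self._cum, rng.random()))
                if z != center and z != context:
                    out.append(z)
                    break
        return out


def _run_implicit_epoch(
    vectors: np.ndarray,
    contexts: np.ndarray,
    pairs: np.ndarray,
    sampler: _NegativeSampler,
    weight: float,
    params: BineHyperparams,
    rng: np.random.Generator,
) -> None:
    """In-place skip-gram epoch over a shuffled pair list (fast path)."""
    if weight == 0.0 or len(pairs) == 0:
        return
    order = rng.permutation(len(pairs))
    for idx in order:
        center, context = int(pairs[idx, 0]), int(pairs[idx, 1])
        zs = [context, *sampler.draw(rng, params.ns, center, context)]
        u = vectors[center]
        theta = contexts[zs]
        indic = np.zeros(len(zs))
        indic[0] = 1.0
        coeff = weight * (indic - _sigmoid(theta @ u))
        unew = u + params.lr * (coeff @ theta)
        contexts[zs] += params.lr * np.outer(coeff, u)
        vectors[center] = unew


def train_bine(
    network: BipartiteDTINetwork, params: BineHyperparams
) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Joint training of drug and target embeddings on a bipartite network.

    Builds both shared-partner homogeneous matrices, converts them into walk
    corpora once, initialises embeddings uniformly in
    ``[-0.5/dim, 0.5/dim]`` with zeroed context vectors, then for
    ``max_iter`` epochs interleaves one explicit pass over the observed
    edges with one skip-gram pass over each corpus.  Fully reproducible
    under the hyper-parameter seed.
    """
    rng = np.random.default_rng(params.seed)
    m, n = network.registry.n_drugs, network.registry.n_targets
    dim = params.dim

    U = rng.uniform(-0.5 / dim, 0.5 / dim, size=(m, dim))
    V = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    TH = np.zeros((m, dim))
    VTH = np.zeros((n, dim))

    homo_d = cohits_homogeneous(network, "drug")
    homo_t = cohits_homogeneous(network, "target")

    def _corpus(homo: CoHitsMatrix) -> WalkCorpus:
        try:
            return generate_walks(homo, params, rng)
        except ValueError:
            logger.warning("no walkable vertices on the %s side; empty corpus", homo.side)
            return WalkCorpus(homo.side, [[0]])

    corpus_d = _corpus(homo_d)
    corpus_t = _corpus(homo_t)
    pairs_d = _context_pairs(corpus_d, params.ws)
    pairs_t = _context_pairs(corpus_t, params.ws)
    sampler_d = _NegativeSampler(corpus_d, m)
    sampler_t = _NegativeSampler(corpus_t, n)

    edges = np.array(sorted(network.edges), dtype=int).reshape(-1, 2)

    for _ in range(params.max_iter):
        for idx in rng.permutation(len(edges)):
            i, j = int(edges[idx, 0]), int(edges[idx, 1])
            U[i], V[j] = explicit_update(U[i], V[j], 1.0, params.gamma, params.lr)
        _run_implicit_epoch(U, TH, pairs_d, sampler_d, params.alpha, params, rng)
        _run_implicit_epoch(V, VTH, pairs_t, sampler_t, params.beta, params, rng)

    return EmbeddingTable("drug", U, TH), EmbeddingTable("target", V, VTH)
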