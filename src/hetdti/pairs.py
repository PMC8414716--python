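"""Path-augmented embeddings of drug-target pairs.

Each pair (d, t) is represented by a 2*dim vector built from four pieces of
the heterogeneous network:

* a drug similarity component — d's own embedding scaled by the summed
  composite-similarity weights of its k nearest drugs,
* a drug path component — t's embedding scaled by the total interaction
  weight between those nearest drugs and t (the "similar drugs bind the
  same target" pathway),
* the two symmetric target-side components.

Drug-side half: ``d_part = (sum_z w_z) * u_d + (sum_z G_b[z, t]) * v_t``,
target-side half symmetric; the pair vector is ``concat(d_part, t_part)``,
so its dimension is always twice the per-vertex embedding size.

By default each component scales the entity's own fixed vector by summed
neighbour weights; ``neighbor_mix="neighbor_embeddings"`` instead mixes the
neighbours' embeddings (``sum_z w_z * u_z``), a plausible variant kept
behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bine import EmbeddingTable
from .network import BipartiteDTINetwork, SimilarityMatrix

__all__ = [
    "NeighborSet",
    "PairEmbedding",
    "top_k_neighbors",
    "similarity_component",
    "path_component",
    "build_pair_embedding",
    "build_all_pairs",
]


@dataclass
class NeighborSet:
    """The k nearest same-side neighbours of one entity, self excluded."""

    entity: int
    side: str
    neighbors: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ws = [w for _, w in self.neighbors]
        if any(b > a for a, b in zip(ws, ws[1:])):
            raise ValueError("neighbor weights must be non-increasing")
        if any(z == self.entity for z, _ in self.neighbors):
            raise ValueError("entity itself cannot be its own neighbor")

    @property
    def indices(self) -> list[int]:
        return [z for z, _ in self.neighbors]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.neighbors], dtype=float)


@dataclass
class PairEmbedding:
    """Fused 2*dim representation of one drug-target pair."""

    drug: int
    target: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if not np.isfinite(vec).all():
            raise ValueError("pair embedding has non-finite entries")
        self.vector = vec


def top_k_neighbors(
    entity: int, composite: SimilarityMatrix, k: int = 5
) -> NeighborSet:
    """The k entities most similar to ``entity`` in the composite matrix.

    Self is excluded; zero-weight entities are never neighbours, so fewer
    than k may be returned (an all-zero row yields an empty set with a
    warning).  Ties are broken by ascending index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    row = composite.values[entity].copy()
    row[entity] = -np.inf
    candidates = [(z, row[z]) for z in range(len(row)) if z != entity and row[z] > 0]
    if not candidates:
        warnings.warn(
            f"entity {entity} has no positive similarity to any other "
            f"{composite.side}; empty neighbor set",
            stacklevel=2,
        )
        return NeighborSet(entity, composite.side, [])
    candidates.sort(key=lambda zw: (-zw[1], zw[0]))
    return NeighborSet(entity, composite.side, [(z, float(w)) for z, w in candidates[:k]])


def similarity_component(entity_vec: np.ndarray, neighbors: NeighborSet) -> np.ndarray:
    """Entity's own embedding scaled by each neighbour weight and summed.

    Equals ``(sum_z w_z) * entity_vec``; an empty neighbour set gives the
    zero vector.
    """
    entity_vec = np.asarray(entity_vec, dtype=float)
    if not neighbors.neighbors:
        return np.zeros_like(entity_vec)
    return float(neighbors.weights.sum()) * entity_vec


def path_component(
    partner_vec: np.ndarray,
    neighbors: NeighborSet,
    network: BipartiteDTINetwork,
    partner: int,
    partner_side: str,
) -> np.ndarray:
    """Partner's embedding scaled by total neighbour-partner interaction.

    For a drug-side neighbour set and target partner t, this is
    ``sum_z G_b[z, t] * v_t`` over the nearest drugs z — the weight of
    known-interaction paths from d's similar drugs to t.  Symmetric for a
    target-side neighbour set and drug partner.
    """
    if partner_side not in ("drug", "target"):
        raise ValueError(f"unknown partner side {partner_side!r}")
    if neighbors.side == partner_side:
        raise ValueError(
            "neighbors must be on the opposite side of the partner "
            f"(both are {partner_side!r})"
        )
    partner_vec = np.asarray(partner_vec, dtype=float)
    if not neighbors.neighbors:
        return np.zeros_like(partner_vec)
    gb = network.adjacency
    if partner_side == "target":
        total = float(sum(gb[z, partner] for z in neighbors.indices))
    else:
        total = float(sum(gb[partner, z] for z in neighbors.indices))
    return total * partner_vec


def _component_pair(
    own_vecs: np.ndarray,
    entity: int,
    neighbors: NeighborSet,
    neighbor_mix: str,
) -> np.ndarray:
    """Similarity component under either mixing convention."""
    if neighbor_mix == "as_printed":
        return similarity_component(own_vecs[entity], neighbors)
    if neighbor_mix == "neighbor_embeddings":
        if not neighbors.neighbors:
            return np.zeros_like(own_vecs[entity])
        return neighbors.weights @ own_vecs[neighbors.indices]
    raise ValueError(f"unknown neighbor_mix {neighbor_mix!r}")


def build_pair_embedding(
    d: int,
    t: int,
    drug_table: EmbeddingTable,
    target_table: EmbeddingTable,
    drug_composite: SimilarityMatrix,
    target_composite: SimilarityMatrix,
    network: BipartiteDTINetwork,
    k: int = 5,
    neighbor_mix: str = "as_printed",
) -> PairEmbedding:
    """Fused embedding of one (drug, target) pair."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nd = top_k_neighbors(d, drug_composite, k)
        nt = top_k_neighbors(t, target_composite, k)
    d_part = _component_pair(drug_table.vectors, d, nd, neighbor_mix) + path_component(
        target_table.vectors[t], nd, network, t, "target"
    )
    t_part = _component_pair(target_table.vectors, t, nt, neighbor_mix) + path_component(
        drug_table.vectors[d], nt, network, d, "drug"
    )
    return PairEmbedding(d, t, np.concatenate([d_part, t_part]))


def build_all_pairs(
    drug_table: EmbeddingTable,
    target_table: EmbeddingTable,
    drug_composite: SimilarityMatrix,
    target_composite: SimilarityMatrix,
    network: BipartiteDTINetwork,
    k: int = 5,
    neighbor_mix: str = "as_printed",
    mask_edges=None,
) -> np.ndarray:
    """Pair embeddings for every (d, t), as an (m*n, 2*dim) array.

    Row ``i * n + j`` holds the embedding of pair (drug i, target j).  If
    ``mask_edges`` is given, those interactions are treated as 0 inside the
    path components (leakage control when the pairs are evaluation
    targets).  Vectorised but bit-equal to ``build_pair_embedding`` per
    pair.
    """
    net = network.masked(mask_edges) if mask_edges else network
    gb = net.adjacency
    m, n = gb.shape
    U, V = drug_table.vectors, target_table.vectors
    dim = U.shape[1]

    sum_w_d = np.zeros(m)
    mix_d = np.zeros((m, dim))
    neigh_gb_d = np.zeros((m, n))           # (d, t) -> sum of Gb over d's neighbors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in range(m):
            nd = top_k_neighbors(d, drug_composite, k)
            if nd.neighbors:
                sum_w_d[d] = nd.weights.sum()
                mix_d[d] = nd.weights @ U[nd.indices]
                neigh_gb_d[d] = gb[nd.indices].sum(axis=0)
        sum_w_t = np.zeros(n)
        mix_t = np.zeros((n, dim))
        neigh_gb_t = np.zeros((m, n))
        for t in range(n):
            nt = top_k_neighbors(t, target_composite, k)
            if nt.neighbors:
                sum_w_t[t] = nt.weights.sum()
                mix_t[t] = nt.weights @ V[nt.indices]
                neigh_gb_t[:, t] = gb[:, nt.indices].sum(axis=1)

    if neighbor_mix == "as_printed":
        d_sim = sum_w_d[:, None] * U                     # (m, dim)
        t_sim = sum_w_t[:, None] * V                     # (n, dim)
    elif neighbor_mix == "neighbor_embeddings":
        d_sim, t_sim = mix_d, mix_t
    else:
        raise ValueError(f"unknown neighbor_mix {neighbor_mix!r}")

    # d_part[d,t,:] = d_sim[d] + neigh_gb_d[d,t] * V[t]
    d_part = d_sim[:, None, :] + neigh_gb_d[:, :, None] * V[None, :, :]
    t_part = t_sim[None, :, :] + neigh_gb_t[:, :, None] * U[:, None, :]
    out = np.concatenate([d_part, t_part], axis=2)
    return out.reshape(m * n, 2 * dim)
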