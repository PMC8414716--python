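"""Core data types and file formats for heterogeneous DTI networks.

A heterogeneous drug-target interaction (DTI) network is decomposed into a
bipartite interaction network (drugs on one side, protein targets on the
other, weight 1 for every known interaction) plus square drug-drug and
target-target similarity matrices.  This module holds the registries that fix
entity ordering, the bipartite adjacency container, the similarity-matrix
container, and plain-TSV readers/writers for all of them.

File formats
------------
* Edge list: TSV, no header, columns ``drug_id, target_id[, weight]``;
  lines starting with ``#`` are comments.  Weights must be 0 or 1.
* Similarity matrix: TSV with a header row of entity ids and an id-labelled
  first column.
* Embeddings: TSV, ``id`` followed by one float column per dimension.
* Predictions: TSV, ``drug_id, target_id, score, label``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EntityRegistry",
    "BipartiteDTINetwork",
    "SimilarityMatrix",
    "PredictionMatrix",
    "load_bipartite_edges",
    "write_bipartite_edges",
    "load_similarity_matrix",
    "write_similarity_matrix",
    "normalize_similarity_01",
    "interaction_stats",
    "write_embeddings",
    "load_embeddings",
    "write_predictions",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered, unique drug and target identifiers.

    The order is stable and defines the row/column index of every matrix in
    the pipeline; files always carry string ids, never indices.
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (("drug", self.drug_ids), ("target", self.target_ids)):
            if len(ids) < 1:
                raise ValueError(f"registry needs at least one {name} id")
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids in registry")
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def ids(self, side: str) -> tuple[str, ...]:
        _check_side(side)
        return self.drug_ids if side == "drug" else self.target_ids

    def drug_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}

    def target_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.target_ids)}


@dataclass
class BipartiteDTINetwork:
    """Binary m x n drug-target interaction matrix with its registry."""

    registry: EntityRegistry
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        m, n = self.registry.n_drugs, self.registry.n_targets
        if adj.shape != (m, n):
            raise ValueError(f"adjacency shape {adj.shape} != registry ({m}, {n})")
        if not np.isin(adj, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = adj
        iso_d = int((adj.sum(axis=1) == 0).sum())
        iso_t = int((adj.sum(axis=0) == 0).sum())
        if iso_d or iso_t:
            warnings.warn(
                f"network has {iso_d} drugs and {iso_t} targets without any "
                "known interaction",
                stacklevel=2,
            )

    @property
    def edges(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.adjacency)
        return set(zip(ii.tolist(), jj.tolist()))

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())

    def masked(self, mask_edges) -> "BipartiteDTINetwork":
        """Copy with the given (drug, target) index pairs set to 0."""
        adj = self.adjacency.copy()
        for i, j in mask_edges:
            adj[i, j] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return BipartiteDTINetwork(self.registry, adj)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one side of the network.

    ``side`` is ``"drug"`` or ``"target"``; ``name`` labels the similarity
    source (e.g. a chemical-fingerprint or GO-semantic kernel).  Values are
    expected in [0, 1] after normalisation.
    """

    side: str
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_side(self.side)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {vals.shape}")
        asym = np.abs(vals - vals.T).max() if vals.size else 0.0
        if asym > _SYM_TOL:
            warnings.warn(
                f"similarity matrix {self.name!r} asymmetric by {asym:.3g}; "
                "symmetrized by averaging",
                stacklevel=2,
            )
            vals = (vals + vals.T) / 2.0
        self.values = vals

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass
class PredictionMatrix:
    """Interaction probability scores and thresholded binary decisions."""

    scores: np.ndarray
    labels: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must share a shape")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if (scores[labels == 1] < self.threshold).any():
            raise ValueError("positive label below decision threshold")
        self.scores, self.labels = scores, labels

    @classmethod
    def from_scores(cls, scores: np.ndarray, threshold: float = 0.5) -> "PredictionMatrix":
        scores = np.asarray(scores, dtype=float)
        return cls(scores, (scores >= threshold).astype(int), threshold)


def _check_side(side: str) -> None:
    if side not in ("drug", "target"):
        raise ValueError(f"side must be 'drug' or 'target', got {side!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_bipartite_edges(
    path, registry_mode: str = "from_file", registry: EntityRegistry | None = None
) -> BipartiteDTINetwork:
    """Read a TSV edge list into a bipartite network.

    Duplicate edges collapse to a single interaction; with
    ``registry_mode="from_file"`` registries are built in first-appearance
    order, with ``"given"`` the supplied registry fixes the index space.
    """
    if registry_mode not in ("from_file", "given"):
        raise ValueError(f"unknown registry_mode {registry_mode!r}")
    if registry_mode == "given" and registry is None:
        raise ValueError("registry_mode='given' requires a registry")

    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"malformed weight on line {lineno}: {line!r}") from exc
                if w not in (0.0, 1.0):
                    raise ValueError(f"weight on line {lineno} must be 0 or 1, got {w}")
                if w == 0.0:
                    continue
            pairs.append((parts[0].strip(), parts[1].strip()))

    if not pairs:
        raise ValueError("no edges in edge-list file")

    if registry_mode == "from_file":
        drug_ids = list(dict.fromkeys(d for d, _ in pairs))
        target_ids = list(dict.fromkeys(t for _, t in pairs))
        registry = EntityRegistry(tuple(drug_ids), tuple(target_ids))

    di, ti = registry.drug_index(), registry.target_index()
    adj = np.zeros((registry.n_drugs, registry.n_targets))
    for d, t in pairs:
        if d not in di or t not in ti:
            raise ValueError(f"edge ({d}, {t}) not covered by the given registry")
        adj[di[d], ti[t]] = 1.0
    return BipartiteDTINetwork(registry, adj)


def write_bipartite_edges(network: BipartiteDTINetwork, path) -> None:
    reg = network.registry
    with open(path, "w") as fh:
        for i, j in sorted(network.edges):
            fh.write(f"{reg.drug_ids[i]}\t{reg.target_ids[j]}\t1\n")


def load_similarity_matrix(
    path, side: str, registry: EntityRegistry, name: str | None = None
) -> SimilarityMatrix:
    """Read a header+index TSV similarity matrix, reordered to registry order.

    Asymmetry beyond 1e-8 is resolved by averaging (M + M^T)/2 with a warning.
    """
    _check_side(side)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {df.shape}")
    ids = registry.ids(side)
    missing = [e for e in ids if e not in df.index or e not in df.columns]
    if missing or len(df.index) != len(ids):
        raise ValueError(f"similarity ids do not match registry; missing {missing}")
    df = df.loc[list(ids), list(ids)]
    return SimilarityMatrix(side, name or str(path), df.to_numpy(dtype=float))


def write_similarity_matrix(matrix: SimilarityMatrix, registry: EntityRegistry, path) -> None:
    ids = list(registry.ids(matrix.side))
    pd.DataFrame(matrix.values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def normalize_similarity_01(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max map all entries onto exactly [0, 1] (the 0-1 normalisation)."""
    vals = matrix.values
    if not np.isfinite(vals).all():
        raise ValueError("similarity matrix has non-finite values")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("zero range: constant matrix cannot be 0-1 normalized")
    return SimilarityMatrix(matrix.side, matrix.name, (vals - lo) / (hi - lo))


def interaction_stats(network: BipartiteDTINetwork) -> dict:
    """Counts and proportions of known (positive) vs unknown (negative) pairs.

    The positive proportion is reported as a percentage rounded to two
    decimals, matching the printing convention of benchmark dataset tables.
    """
    m, n = network.registry.n_drugs, network.registry.n_targets
    total = m * n
    pos = network.n_interactions
    neg = total - pos
    return {
        "n_drugs": m,
        "n_targets": n,
        "n_pairs": total,
        "n_positive": pos,
        "n_negative": neg,
        "positive_pct": round(100.0 * pos / total, 2),
        "negative_pct": round(100.0 * neg / total, 2),
    }


def write_embeddings(ids, vectors: np.ndarray, path) -> None:
    vectors = np.asarray(vectors, dtype=float)
    df = pd.DataFrame(vectors, index=list(ids))
    df.columns = [f"e{k}" for k in range(vectors.shape[1])]
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def load_embeddings(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_predictions(
    network: BipartiteDTINetwork, predictions: PredictionMatrix, path
) -> None:
    reg = network.registry
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\tlabel\n")
        for i, d in enumerate(reg.drug_ids):
            for j, t in enumerate(reg.target_ids):
                fh.write(
                    f"{d}\t{t}\t{predictions.scores[i, j]:.17g}"
                    f"\t{int(predictions.labels[i, j])}\n"
                )
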