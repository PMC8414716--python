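"""Synthetic heterogeneous DTI datasets with planted block structure.

The generator emulates the structure of the public DTI benchmarks: a sparse
binary bipartite interaction matrix (positive rates in the low single-digit
percent range) plus similarity matrices per side that align with the
interaction pattern.  Drugs and targets are assigned to matching blocks
("drug families" binding the same "target families"); an interaction is
drawn with probability ``p_within`` when the blocks match and ``p_between``
otherwise, so similar drugs genuinely share similar targets and every
pipeline stage has a recoverable planted signal.

Similarity matrices are block-indicator matrices (1 within a block, 0
between) perturbed by truncated Gaussian noise and 0-1 normalised.  On
request the generator also injects near-duplicate copies of the first
informative view (to exercise the redundancy screen) and near-uniform
matrices (to exercise the entropy screen), and can relabel a fraction of
realised positives as unknown, recording them as hidden ground truth for
retrieval experiments.

Defaults (30 drugs, 24 targets, 12 near-equal blocks, noise sd 0.003, one
informative view per side, no injections, no holdout) are chosen so the
entropy of an informative view sits below the screening threshold
0.7*ln(k) with a comfortable analytic margin while a near-uniform view
sits essentially at ln(k); see the methods note for the closed-form
estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fusion import SimilarityCollection
from .network import (
    BipartiteDTINetwork,
    EntityRegistry,
    SimilarityMatrix,
    load_bipartite_edges,
    load_similarity_matrix,
    normalize_similarity_01,
    write_bipartite_edges,
    write_similarity_matrix,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "write_fixture",
           "load_fixture", "shuffle_edges"]

_DUP_NOISE_SD = 1e-4
_UNIFORM_NOISE_SD = 1e-3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic heterogeneous DTI dataset."""

    n_drugs: int = 30
    n_targets: int = 24
    n_blocks: int = 12
    p_within: float = 0.3
    p_between: float = 0.01
    n_drug_sims: int = 1
    n_target_sims: int = 1
    sim_noise_sd: float = 0.003
    n_redundant: int = 0
    n_uniform: int = 0
    holdout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_between < self.p_within <= 1.0:
            raise ValueError("need 0 <= p_between < p_within <= 1")
        for nm in ("n_drugs", "n_targets", "n_blocks", "n_drug_sims", "n_target_sims"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")
        for nm in ("n_redundant", "n_uniform"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in [0, 1)")
        if self.sim_noise_sd < 0:
            raise ValueError("sim_noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    spec: SyntheticSpec
    network: BipartiteDTINetwork
    drug_sims: SimilarityCollection
    target_sims: SimilarityCollection
    drug_blocks: np.ndarray
    target_blocks: np.ndarray
    held_out_pairs: list[tuple[int, int]] = field(default_factory=list)


def _balanced_blocks(rng: np.random.Generator, count: int, b: int) -> np.ndarray:
    """Random assignment with near-equal block sizes (difference <= 1).

    Balanced blocks keep the within-block entry count of the indicator
    similarity matrices at its minimum ``~count^2 / b``, which is what makes
    the entropy screen's behaviour on generated data analytically
    predictable.
    """
    labels = np.resize(np.arange(b), count)
    return labels[rng.permutation(count)]


def _sym_noise(rng: np.random.Generator, k: int, sd: float) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=(k, k))
    return (noise + noise.T) / 2.0


def _block_similarity(
    rng: np.random.Generator, blocks: np.ndarray, sd: float, side: str, name: str
) -> SimilarityMatrix:
    """Block-indicator matrix + truncated Gaussian noise, 0-1 normalised."""
    base = (blocks[:, None] == blocks[None, :]).astype(float)
    vals = np.clip(base + _sym_noise(rng, len(blocks), sd), 0.0, None)
    mat = SimilarityMatrix(side, name, vals)
    return normalize_similarity_01(mat) if vals.max() > vals.min() else mat


def _similarity_collection(
    rng: np.random.Generator, blocks: np.ndarray, spec: SyntheticSpec, side: str
) -> SimilarityCollection:
    n_views = spec.n_drug_sims if side == "drug" else spec.n_target_sims
    k = len(blocks)
    mats = [
        _block_similarity(rng, blocks, spec.sim_noise_sd, side, f"{side}_sim_{v}")
        for v in range(1, n_views + 1)
    ]
    base = mats[0].values
    for r in range(1, spec.n_redundant + 1):
        vals = np.clip(base + _sym_noise(rng, k, _DUP_NOISE_SD), 0.0, 1.0)
        mats.append(SimilarityMatrix(side, f"{side}_sim_1_dup{r}", vals))
    for u in range(1, spec.n_uniform + 1):
        vals = np.clip(0.5 + _sym_noise(rng, k, _UNIFORM_NOISE_SD), 0.0, 1.0)
        mats.append(SimilarityMatrix(side, f"{side}_uniform_{u}", vals))
    return SimilarityCollection(side, mats)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset: planted-block network, similarities, ground truth.

    Reproducible under ``spec.seed``.  Isolated vertices are re-wired with
    one random interaction (mirroring the benchmark property that every
    node has at least one edge), avoiding held-out pairs.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, b = spec.n_drugs, spec.n_targets, spec.n_blocks

    drug_blocks = _balanced_blocks(rng, m, b)
    target_blocks = _balanced_blocks(rng, n, b)
    match = drug_blocks[:, None] == target_blocks[None, :]
    probs = np.where(match, spec.p_within, spec.p_between)
    adj = (rng.random((m, n)) < probs).astype(float)
    if adj.sum() == 0:
        raise ValueError("interaction probabilities produced an empty edge set")

    # hold out a fraction of realised positives as hidden truth
    held_out: list[tuple[int, int]] = []
    if spec.holdout_fraction > 0:
        pos = np.argwhere(adj == 1)
        n_hold = int(round(spec.holdout_fraction * len(pos)))
        n_hold = min(n_hold, len(pos) - 1)      # keep at least one known edge
        if n_hold > 0:
            chosen = pos[rng.choice(len(pos), size=n_hold, replace=False)]
            for i, j in chosen:
                adj[i, j] = 0.0
                held_out.append((int(i), int(j)))
    held_set = set(held_out)

    # re-wire isolated vertices with one random edge (never a held-out pair)
    for i in np.nonzero(adj.sum(axis=1) == 0)[0]:
        choices = [j for j in range(n) if (int(i), j) not in held_set]
        adj[i, rng.choice(choices)] = 1.0
    for j in np.nonzero(adj.sum(axis=0) == 0)[0]:
        choices = [i for i in range(m) if (i, int(j)) not in held_set]
        adj[rng.choice(choices), j] = 1.0

    registry = EntityRegistry(
        tuple(f"d{i+1}" for i in range(m)), tuple(f"t{j+1}" for j in range(n))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        network = BipartiteDTINetwork(registry, adj)

    drug_sims = _similarity_collection(rng, drug_blocks, spec, "drug")
    target_sims = _similarity_collection(rng, target_blocks, spec, "target")
    return SyntheticDataset(
        spec, network, drug_sims, target_sims, drug_blocks, target_blocks, held_out
    )


def shuffle_edges(network: BipartiteDTINetwork, seed: int = 0) -> BipartiteDTINetwork:
    """Null model: same interaction count, uniformly random placement.

    Used for label-permutation calibration — the planted structure in the
    similarity matrices then carries no information about the labels.
    """
    rng = np.random.default_rng(seed)
    m, n = network.adjacency.shape
    k = network.n_interactions
    rows = rng.choice(m * n, size=k, replace=False)
    adj = np.zeros(m * n)
    adj[rows] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BipartiteDTINetwork(network.registry, adj.reshape(m, n))


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write edge list, similarity TSVs and ground-truth JSON to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    edges_path = directory / "edges.tsv"
    write_bipartite_edges(dataset.network, edges_path)
    files["edges"] = edges_path

    reg = dataset.network.registry
    for coll in (dataset.drug_sims, dataset.target_sims):
        for mat in coll.matrices:
            p = directory / f"{mat.name}.tsv"
            write_similarity_matrix(mat, reg, p)
            files[mat.name] = p

    truth_path = directory / "ground_truth.json"
    truth = {
        "drug_blocks": dataset.drug_blocks.tolist(),
        "target_blocks": dataset.target_blocks.tolist(),
        "held_out_pairs": [
            [reg.drug_ids[i], reg.target_ids[j]] for i, j in dataset.held_out_pairs
        ],
        "drug_sim_names": dataset.drug_sims.names,
        "target_sim_names": dataset.target_sims.names,
        "spec": dataset.spec.__dict__,
    }
    truth_path.write_text(json.dumps(truth, indent=1))
    files["ground_truth"] = truth_path
    return files


def load_fixture(directory) -> SyntheticDataset:
    """Read back a fixture written by :func:`write_fixture` (exact values)."""
    directory = Path(directory)
    truth = json.loads((directory / "ground_truth.json").read_text())
    spec = SyntheticSpec(**truth["spec"])
    registry = EntityRegistry(
        tuple(f"d{i+1}" for i in range(spec.n_drugs)),
        tuple(f"t{j+1}" for j in range(spec.n_targets)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        network = load_bipartite_edges(
            directory / "edges.tsv", registry_mode="given", registry=registry
        )
    di, ti = registry.drug_index(), registry.target_index()

    def _coll(side: str, names: list[str]) -> SimilarityCollection:
        mats = [
            load_similarity_matrix(directory / f"{nm}.tsv", side, registry, name=nm)
            for nm in names
        ]
        return SimilarityCollection(side, mats)

    return SyntheticDataset(
        spec,
        network,
        _coll("drug", truth["drug_sim_names"]),
        _coll("target", truth["target_sim_names"]),
        np.asarray(truth["drug_blocks"]),
        np.asarray(truth["target_blocks"]),
        [(di[d], ti[t]) for d, t in truth["held_out_pairs"]],
    )
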