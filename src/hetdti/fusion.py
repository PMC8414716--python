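"""Screening and fusion of multiple similarity matrices into one composite.

Several similarity sources per side (chemical fingerprints, side-effect
profiles, sequence kernels, interaction-profile kernels, ...) are first
screened heuristically and then merged:

1. *Entropy screen* — matrices whose flattened, sum-normalised Shannon
   entropy exceeds ``c1 * ln(k)`` (k = number of entries) are discarded as
   near-uniform, information-poor views.
2. *Redundancy screen* — remaining matrices are ordered by ascending
   entropy; walking from the most structured one, any later matrix whose
   redundancy index ``Es = 1 / (1 + d)`` (d = Euclidean distance between
   the flattened matrices) with the current matrix exceeds ``c2`` is
   removed as a near-duplicate.
3. *Similarity network fusion (SNF)* — the survivors are merged by
   iterative cross-diffusion between a row-normalised full kernel and a
   K-nearest-neighbour local kernel.

The `FusionReport` records every decision so a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SimilarityMatrix

__all__ = [
    "SimilarityCollection",
    "FusionReport",
    "matrix_entropy",
    "entropy_screen",
    "redundancy_screen",
    "snf_fuse",
    "build_composite",
]


@dataclass
class SimilarityCollection:
    """A named list of same-shape similarity matrices for one side."""

    side: str
    matrices: list[SimilarityMatrix]

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("collection needs at least one matrix")
        dims = {m.dim for m in self.matrices}
        if len(dims) != 1:
            raise ValueError(f"inconsistent matrix shapes in collection: {dims}")
        sides = {m.side for m in self.matrices}
        if sides != {self.side}:
            raise ValueError(f"matrix sides {sides} inconsistent with collection side")
        names = [m.name for m in self.matrices]
        if len(set(names)) != len(names):
            raise ValueError("matrix names must be unique within a collection")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.matrices]

    def subset(self, names) -> "SimilarityCollection":
        keep = set(names)
        return SimilarityCollection(
            self.side, [m for m in self.matrices if m.name in keep]
        )


@dataclass
class FusionReport:
    """Audit trail of the screen-and-fuse pipeline."""

    entropies: dict[str, float] = field(default_factory=dict)
    entropy_threshold: float = float("nan")
    removed_by_entropy: list[str] = field(default_factory=list)
    es_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    removed_by_redundancy: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "entropies": self.entropies,
            "entropy_threshold": self.entropy_threshold,
            "removed_by_entropy": self.removed_by_entropy,
            "es_pairs": {f"{a}|{b}": v for (a, b), v in self.es_pairs.items()},
            "removed_by_redundancy": self.removed_by_redundancy,
            "retained": self.retained,
        }


def matrix_entropy(matrix: SimilarityMatrix) -> float:
    """Shannon entropy (natural log) of the flattened, sum-normalised matrix.

    The flat entries are treated as an unnormalised probability mass
    function; ``0 * ln 0`` counts as 0.  Ranges over [0, ln k] for a
    non-negative matrix with k entries.
    """
    vals = matrix.values.ravel()
    if (vals < 0).any():
        raise ValueError("entropy requires a non-negative matrix")
    total = vals.sum()
    if total == 0:
        raise ValueError("entropy undefined for an all-zero matrix")
    p = vals / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_screen(
    collection: SimilarityCollection,
    c1: float = 0.7,
    entropy_reference: str = "max_possible",
) -> tuple[SimilarityCollection, FusionReport]:
    """Drop matrices whose entropy exceeds ``c1`` times the reference entropy.

    ``entropy_reference="max_possible"`` uses ln(k), the attainable maximum
    for a k-entry matrix; ``"max_observed"`` uses the largest entropy among
    the input matrices.  Removal uses a strict > comparison.
    """
    if entropy_reference not in ("max_possible", "max_observed"):
        raise ValueError(f"unknown entropy_reference {entropy_reference!r}")
    report = FusionReport()
    report.entropies = {m.name: matrix_entropy(m) for m in collection.matrices}
    k = collection.matrices[0].values.size
    if entropy_reference == "max_possible":
        reference = float(np.log(k))
    else:
        reference = max(report.entropies.values())
    report.entropy_threshold = c1 * reference
    report.removed_by_entropy = [
        name for name, h in report.entropies.items() if h > report.entropy_threshold
    ]
    retained = [n for n in collection.names if n not in report.removed_by_entropy]
    if not retained:
        raise ValueError(
            "entropy screen removed every matrix; raise c1 (all views exceed "
            f"threshold {report.entropy_threshold:.4g})"
        )
    report.retained = retained
    return collection.subset(retained), report


def redundancy_screen(
    collection: SimilarityCollection,
    c2: float = 0.6,
    entropies: dict[str, float] | None = None,
) -> tuple[SimilarityCollection, FusionReport]:
    """Sequentially drop near-duplicate matrices by the Es redundancy index.

    Matrices are ordered by ascending entropy (ties broken by name for
    determinism).  Starting from the lowest-entropy retained matrix, every
    later matrix whose ``Es = 1/(1 + d)`` with the current matrix exceeds
    ``c2`` is removed; the cursor then advances to the next still-retained
    matrix until all have been processed.
    """
    report = FusionReport()
    if entropies is None:
        entropies = {m.name: matrix_entropy(m) for m in collection.matrices}
    report.entropies = dict(entropies)
    by_name = {m.name: m for m in collection.matrices}
    order = sorted(collection.names, key=lambda nm: (entropies[nm], nm))
    removed: set[str] = set()
    for pos, current in enumerate(order):
        if current in removed:
            continue
        flat_cur = by_name[current].values.ravel()
        for other in order[pos + 1:]:
            if other in removed:
                continue
            d = float(np.linalg.norm(flat_cur - by_name[other].values.ravel()))
            es = 1.0 / (1.0 + d)
            report.es_pairs[(current, other)] = es
            if es > c2:
                removed.add(other)
    report.removed_by_redundancy = [n for n in order if n in removed]
    report.retained = [n for n in collection.names if n not in removed]
    return collection.subset(report.retained), report


# ---------------------------------------------------------------------------
# similarity network fusion
# ---------------------------------------------------------------------------

def _row_normalize(w: np.ndarray) -> np.ndarray:
    sums = w.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    w = w / sums
    return (w + w.T) / 2.0


def _dominate_set(w: np.ndarray, K: int) -> np.ndarray:
    """Keep the K largest entries of each row, zero the rest, row-normalise."""
    out = np.zeros_like(w)
    idx = np.argsort(w, axis=1)[:, ::-1][:, :K]
    rows = np.arange(w.shape[0])[:, None]
    out[rows, idx] = w[rows, idx]
    sums = out.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return out / sums


def _b0_normalize(w: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    w = w + alpha * np.eye(w.shape[0])
    return (w + w.T) / 2.0


def snf_fuse(
    collection: SimilarityCollection,
    K: int = 20,
    t: int = 20,
    alpha: float = 1.0,
) -> SimilarityMatrix:
    """Similarity network fusion of all matrices in the collection.

    Standard cross-diffusion: each view is row-normalised into a full
    kernel and sparsified into a K-nearest-neighbour kernel; for ``t``
    rounds every full kernel is diffused through its own local kernel
    against the average of the other views, with diagonal regularisation
    ``alpha``; the fused matrix is the final average, row-normalised and
    symmetrised.  A single-view input diffuses against itself, so fusing
    one matrix (or several identical ones) returns that matrix's SNF
    normalisation.

    ``K`` is clipped to ``dim - 1`` for small matrices.
    """
    k_dim = collection.matrices[0].dim
    if K >= k_dim:
        K = k_dim - 1
    if K < 1:
        raise ValueError("K must be >= 1 (matrix too small)")

    views = [_row_normalize(m.values.astype(float)) for m in collection.matrices]
    locals_ = [_dominate_set(v, K) for v in views]
    n_views = len(views)

    wsum = np.sum(views, axis=0)
    for _ in range(t):
        new_views = []
        for v, (P, S) in enumerate(zip(views, locals_)):
            if n_views > 1:
                others = (wsum - P) / (n_views - 1)
            else:
                others = P
            new_views.append(_b0_normalize(S @ others @ S.T, alpha))
        views = new_views
        wsum = np.sum(views, axis=0)

    fused = wsum / n_views
    sums = fused.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    fused = fused / sums
    fused = (fused + fused.T + np.eye(k_dim)) / 2.0
    name = "snf(" + "+".join(collection.names) + ")"
    return SimilarityMatrix(collection.side, name, fused)


def build_composite(
    collection: SimilarityCollection,
    c1: float = 0.7,
    c2: float = 0.6,
    K: int = 20,
    t: int = 20,
    alpha: float = 1.0,
    entropy_reference: str = "max_possible",
) -> tuple[SimilarityMatrix, FusionReport]:
    """Entropy screen -> redundancy screen -> SNF, with a full audit report."""
    kept, ent_report = entropy_screen(collection, c1, entropy_reference)
    kept, red_report = redundancy_screen(kept, c2, entropies=ent_report.entropies)
    composite = snf_fuse(kept, K=K, t=t, alpha=alpha)
    report = FusionReport(
        entropies=ent_report.entropies,
        entropy_threshold=ent_report.entropy_threshold,
        removed_by_entropy=ent_report.removed_by_entropy,
        es_pairs=red_report.es_pairs,
        removed_by_redundancy=red_report.removed_by_redundancy,
        retained=red_report.retained,
    )
    return composite, report
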