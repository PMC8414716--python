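"""Model/Results facade over the staged DTI prediction pipeline.

`DTIPredictionModel` bundles the data (bipartite interaction network plus
similarity collections per side) with a `RunConfig`; ``fit()`` executes the
learning stages — bipartite embedding on the known-interaction network and
screen-and-fuse of the similarity views — and returns a
`DTIPredictionResults` carrying the learned embeddings, the composite
similarity matrices and the fusion audit reports.  Evaluation
(``cross_validate``) and unknown-pair ranking (``rank_unknown_pairs``) hang
off the results object, statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as eval_mod
from . import pairs as pairs_mod
from .bine import EmbeddingTable, train_bine
from .config import RunConfig
from .fusion import FusionReport, SimilarityCollection, build_composite
from .network import BipartiteDTINetwork, SimilarityMatrix, interaction_stats

__all__ = ["DTIPredictionModel", "DTIPredictionResults"]


class DTIPredictionModel:
    """Heterogeneous-network DTI predictor bound to one dataset."""

    def __init__(
        self,
        network: BipartiteDTINetwork,
        drug_sims: SimilarityCollection | SimilarityMatrix,
        target_sims: SimilarityCollection | SimilarityMatrix,
        config: RunConfig | None = None,
    ):
        if isinstance(drug_sims, SimilarityMatrix):
            drug_sims = SimilarityCollection("drug", [drug_sims])
        if isinstance(target_sims, SimilarityMatrix):
            target_sims = SimilarityCollection("target", [target_sims])
        if drug_sims.matrices[0].dim != network.registry.n_drugs:
            raise ValueError("drug similarity dimension does not match the network")
        if target_sims.matrices[0].dim != network.registry.n_targets:
            raise ValueError("target similarity dimension does not match the network")
        self.network = network
        self.drug_sims = drug_sims
        self.target_sims = target_sims
        self.config = config or RunConfig()

    @classmethod
    def from_dataset(cls, dataset, config: RunConfig | None = None) -> "DTIPredictionModel":
        """Build from a :class:`~hetdti.simulate.SyntheticDataset`."""
        return cls(dataset.network, dataset.drug_sims, dataset.target_sims, config)

    def fit(self) -> "DTIPredictionResults":
        """Run the learning stages and return the fitted results."""
        cfg = self.config
        fus = cfg.fusion
        drug_composite, drug_report = build_composite(
            self.drug_sims, c1=fus.c1, c2=fus.c2, K=fus.K, t=fus.t,
            alpha=fus.alpha, entropy_reference=fus.entropy_reference,
        )
        target_composite, target_report = build_composite(
            self.target_sims, c1=fus.c1, c2=fus.c2, K=fus.K, t=fus.t,
            alpha=fus.alpha, entropy_reference=fus.entropy_reference,
        )
        bine_params = cfg.bine.with_seed(cfg.stage_seed("bine"))
        drug_table, target_table = train_bine(self.network, bine_params)
        return DTIPredictionResults(
            model=self,
            drug_embeddings=drug_table,
            target_embeddings=target_table,
            drug_composite=drug_composite,
            target_composite=target_composite,
            drug_fusion_report=drug_report,
            target_fusion_report=target_report,
        )


@dataclass
class DTIPredictionResults:
    """Learned embeddings, composites, and evaluation entry points."""

    model: DTIPredictionModel
    drug_embeddings: EmbeddingTable
    target_embeddings: EmbeddingTable
    drug_composite: SimilarityMatrix
    target_composite: SimilarityMatrix
    drug_fusion_report: FusionReport
    target_fusion_report: FusionReport

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def pair_features(self, mask_edges=None) -> np.ndarray:
        """Pair embeddings for the whole interaction space, (m*n, 2*dim)."""
        cfg = self.config
        return pairs_mod.build_all_pairs(
            self.drug_embeddings, self.target_embeddings,
            self.drug_composite, self.target_composite, self.model.network,
            k=cfg.pairing.k_near, neighbor_mix=cfg.pairing.neighbor_mix,
            mask_edges=mask_edges,
        )

    def cross_validate(self, task: str | None = None, n_folds: int | None = None):
        """Entity-wise CV under the configured protocol."""
        cfg = self.config
        task = task or cfg.eval.task
        n_folds = n_folds or cfg.eval.folds
        honest = cfg.honest_cv
        return eval_mod.run_cv(
            self.model.network, self.drug_composite, self.target_composite,
            task=task, n_folds=n_folds,
            bine_params=cfg.bine.with_seed(cfg.stage_seed("bine")),
            k_near=cfg.pairing.k_near, neighbor_mix=cfg.pairing.neighbor_mix,
            honest_cv=honest,
            rf_params={
                "n_estimators": cfg.rf.n_estimators,
                "criterion": cfg.rf.criterion,
                "class_weight": cfg.rf.class_weight,
                "min_samples_leaf": cfg.rf.min_samples_leaf,
            },
            seed=cfg.stage_seed("folds"),
            embeddings=None if honest else (self.drug_embeddings, self.target_embeddings),
        )

    def rank_unknown_pairs(self, n_groups: int | None = None, top_k: int | None = None):
        """Score every unknown pair once; return the case-study ranking."""
        cfg = self.config
        return eval_mod.case_study(
            self.model.network, self.drug_composite, self.target_composite,
            n_groups=n_groups or cfg.eval.case_groups,
            top_k=top_k or cfg.eval.top_k,
            bine_params=cfg.bine.with_seed(cfg.stage_seed("bine")),
            k_near=cfg.pairing.k_near, neighbor_mix=cfg.pairing.neighbor_mix,
            rf_params={
                "n_estimators": cfg.rf.n_estimators,
                "criterion": cfg.rf.criterion,
                "class_weight": cfg.rf.class_weight,
                "min_samples_leaf": cfg.rf.min_samples_leaf,
            },
            seed=cfg.stage_seed("case_study"),
            embeddings=(self.drug_embeddings, self.target_embeddings),
        )

    def summary(self) -> str:
        """Human-readable account of the data, screens, and model settings."""
        stats = interaction_stats(self.model.network)
        cfg = self.config
        lines = [
            "Heterogeneous-network DTI prediction results",
            "=" * 44,
            f"drugs: {stats['n_drugs']}   targets: {stats['n_targets']}   "
            f"pairs: {stats['n_pairs']}",
            f"known interactions: {stats['n_positive']} "
            f"({stats['positive_pct']:.2f}%)   unknown: {stats['n_negative']}",
            "",
            f"embedding dim: {cfg.bine.dim}  (pair embedding dim: {2 * cfg.bine.dim})",
            f"epochs: {cfg.bine.max_iter}  lr: {cfg.bine.lr}  ns: {cfg.bine.ns}  "
            f"ws: {cfg.bine.ws}",
            f"walk stop/restart prob: {cfg.bine.stop_prob}/{cfg.bine.restart_prob}",
            "",
            "similarity views (drug side): "
            f"retained {self.drug_fusion_report.retained} | "
            f"entropy-removed {self.drug_fusion_report.removed_by_entropy} | "
            f"redundancy-removed {self.drug_fusion_report.removed_by_redundancy}",
            "similarity views (target side): "
            f"retained {self.target_fusion_report.retained} | "
            f"entropy-removed {self.target_fusion_report.removed_by_entropy} | "
            f"redundancy-removed {self.target_fusion_report.removed_by_redundancy}",
            "",
            f"CV protocol: {cfg.eval.task}, {cfg.eval.folds} folds, "
            f"{'leakage-controlled (per-fold retraining + edge masking)' if cfg.honest_cv else 'transductive (train once on full network)'}",
            f"forest: {cfg.rf.n_estimators} trees, {cfg.rf.criterion}, "
            f"class_weight={cfg.rf.class_weight}",
            f"master seed: {cfg.master_seed}",
        ]
        return "\n".join(lines)
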