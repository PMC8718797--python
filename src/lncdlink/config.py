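"""Pipeline configuration: every tunable knob with its default, validated on load."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
import yaml

__all__ = ["PipelineConfig", "stage_seed"]

_STAGE_IDS = {
    "world": 1, "walks": 2, "embedding": 3, "kmeans": 4,
    "negatives": 5, "cv": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) derived from the master seed."""
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All pipeline defaults.

    Similarity: semantic decay ``delta`` per ontology level; GIP base
    bandwidths for the lncRNA and disease kernels.
    Network/walks: per-node ``top_k`` similarity neighbours; walk count,
    length cap.
    Embedding: dimension, window, negatives per context, SGD rates, epochs,
    negative-noise law.
    Sampling: number of K-means clusters, iteration/restart caps, quota
    allocation across clusters.
    Classifier: boosting rounds, shrinkage, tree depth, leaf minimum, and
    the logistic head's L2/step caps.
    Evaluation: fold count, stratification, and whether embeddings and
    negative selection are recomputed per fold with test positives masked
    (``strict_cv``).
    """

    # similarity
    delta: float = 0.5
    gip_bandwidth_lnc: float = 1.0
    gip_bandwidth_dis: float = 1.0
    # network + walks
    top_k: int = 10
    walks_per_node: int = 10
    walk_length: int = 80
    # embedding
    dim: int = 64
    window: int = 5
    negatives: int = 5
    embed_lr: float = 0.025
    embed_lr_min: float = 1e-4
    epochs: int = 5
    noise: str = "unigram75"
    # negative sampling
    k_clusters: int = 10
    kmeans_max_iter: int = 300
    kmeans_restarts: int = 10
    allocation: str = "proportional"
    # classifier
    pair_features: str = "hadamard"  # or "concat"
    n_estimators: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    min_leaf: int = 5
    l2: float = 1e-4
    lr_max_steps: int = 3000
    # evaluation
    folds: int = 10
    stratified: bool = True
    strict_cv: bool = False
    # master seed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie strictly between 0 and 1")
        if min(self.gip_bandwidth_lnc, self.gip_bandwidth_dis) <= 0:
            raise ValueError("GIP base bandwidths must be positive")
        if self.top_k < 1 or self.walks_per_node < 1 or self.walk_length < 2:
            raise ValueError("invalid walk/network parameters")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be at least 1")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")

    def seeds(self) -> dict[str, int]:
        return {s: stage_seed(self.seed, s) for s in _STAGE_IDS}

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain a key: value mapping")
        return cls.from_dict(d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
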