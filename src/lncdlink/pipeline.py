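"""End-to-end orchestration of the prediction pipeline.

Stage order: deduplicated association matrix -> semantic (SSD) and
functional (FSL) similarities -> GIP kernels (GSD, GSL) -> fused networks
(SL, SD) -> heterogeneous network, metagraph walks and embeddings ->
K-means negative selection -> boosted-tree/logistic cascade with k-fold
cross-validation -> ranked scores for every unknown pair.

Embeddings and negative selection are computed once on the full network and
cross-validation splits the labelled pairs only; ``strict_cv`` instead
recomputes the network stages per fold with the test positives masked, for
leakage-sensitive use.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .embedding import EmbeddingTable, TrainConfig, train
from .evaluation import CVResult, confusion, cross_validate, metrics, roc_auc
from .gbdt_lr import GBDTLRClassifier
from .network import (HeterogeneousNetwork, MetaGraph, WalkCorpus,
                      build_network, default_metagraph, generate_corpus)
from .sampling import (LabeledPairSet, assemble_training_set,
                       build_pair_features, kmeans, select_negatives,
                       unknown_pairs)
from .similarity import (AssociationMatrix, DiseaseDAGSet,
                         disease_semantic_similarity, fuse, gip_similarity,
                         lncrna_functional_similarity)

__all__ = ["PipelineResult", "compute_similarities", "embed_network",
           "select_training_pairs", "pair_embedding_features", "run_pipeline"]

log = logging.getLogger("lncdlink")


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    A: AssociationMatrix
    similarities: dict            # role -> SimilarityMatrix
    network: HeterogeneousNetwork
    corpus: WalkCorpus
    embeddings: EmbeddingTable
    training_set: LabeledPairSet
    cv: CVResult
    model: GBDTLRClassifier
    predictions: pd.DataFrame     # ranked unknown pairs: lncRNA, disease, score
    config: PipelineConfig
    seeds: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.resolved.yaml").write_text(
            self.config.to_yaml()
            + "# derived stage seeds\n"
            + "".join(f"# {k}: {v}\n" for k, v in sorted(self.seeds.items())))
        for role, sim in self.similarities.items():
            _io.save_matrix(sim, outdir / f"{role}.tsv")
        (outdir / "walks.txt").write_text(self.corpus.to_text())
        (outdir / "embeddings.w2v").write_text(self.embeddings.to_word2vec_text())
        self.training_set.to_tsv(outdir / "training_set.tsv")
        self.cv.to_frame().to_csv(outdir / "cv_metrics.tsv", sep="\t", index=False)
        grid, tpr = self.cv.mean_roc
        pd.DataFrame({"FPR": grid, "TPR": tpr}).to_csv(
            outdir / "mean_roc.tsv", sep="\t", index=False)
        _io.save_predictions(self.predictions, outdir / "predictions.tsv")
        (outdir / "model.json").write_text(self.model.to_json())


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("[%s] finished in %.2fs", stage, time.perf_counter() - self.t0)

    log.info("[%s] starting", stage)
    return _Ctx()


def compute_similarities(A: AssociationMatrix, dags: DiseaseDAGSet,
                         cfg: PipelineConfig) -> dict:
    """SSD, FSL, GSD, GSL and the fused SL/SD for one association matrix."""
    with _timed("similarity"):
        ssd = disease_semantic_similarity(dags, cfg.delta, A.disease_ids)
        fsl = lncrna_functional_similarity(A, ssd)
        gsl = gip_similarity(A, "lncRNA", cfg.gip_bandwidth_lnc)
        gsd = gip_similarity(A, "disease", cfg.gip_bandwidth_dis)
        sl = fuse(fsl, gsl)
        sd = fuse(ssd, gsd)
        log.info("[similarity] nl=%d nd=%d", A.nl, A.nd)
    return {"SSD": ssd, "FSL": fsl, "GSL": gsl, "GSD": gsd, "SL": sl, "SD": sd}


def embed_network(A: AssociationMatrix, sims: dict, cfg: PipelineConfig,
                  seeds: dict, metagraph: MetaGraph | None = None):
    """Network assembly, metagraph walks and skip-gram training."""
    mg = metagraph or default_metagraph()
    with _timed("network"):
        G = build_network(sims["SL"], sims["SD"], A, top_k=cfg.top_k)
        log.info("[network] %d nodes", G.n_nodes)
    with _timed("walks"):
        corpus = generate_corpus(G, mg, walks_per_node=cfg.walks_per_node,
                                 length=cfg.walk_length, seed=seeds["walks"])
        log.info("[walks] %d walks", len(corpus.walks))
    with _timed("embedding"):
        tc = TrainConfig(window=cfg.window, dim=cfg.dim, negatives=cfg.negatives,
                         lr=cfg.embed_lr, lr_min=cfg.embed_lr_min,
                         epochs=cfg.epochs, seed=seeds["embedding"],
                         noise=cfg.noise)
        types = dict(zip(G.node_ids, G.node_types))
        table = train(corpus, types, tc, node_ids=G.node_ids)
    return G, corpus, table


def select_training_pairs(A: AssociationMatrix, sims: dict,
                          cfg: PipelineConfig, seeds: dict):
    """K-means over unknown-pair features; balanced labelled training set."""
    with _timed("sampling"):
        unk = unknown_pairs(A)
        feats = build_pair_features(sims["SL"], sims["SD"], A, unk)
        model = kmeans(feats, cfg.k_clusters, seed=seeds["kmeans"],
                       max_iter=cfg.kmeans_max_iter,
                       restarts=cfg.kmeans_restarts)
        n_pos = int(A.values.sum())
        negatives = select_negatives(
            model, unk, n_pos, seed=seeds["negatives"],
            pair_ids=lambda m, j: (A.lncrna_ids[m], A.disease_ids[j]),
            allocation=cfg.allocation)
        training = assemble_training_set(A, negatives)
        log.info("[sampling] %d positives + %d negatives", n_pos, len(negatives))
    return training, model, unk


def pair_embedding_features(table: EmbeddingTable, pairs,
                            mode: str = "hadamard") -> np.ndarray:
    """Classifier input built from the two node embeddings.

    ``hadamard`` (default): the elementwise product Psi(l) * Psi(d), whose
    coordinates align with the inner-product affinity the embedding was
    trained on -- axis-aligned tree splits can read it directly.
    ``concat``: the stacked [Psi(l), Psi(d)] (twice the width; the trees must
    reconstruct the interaction themselves).
    """
    pairs = list(pairs)
    idx_l = np.array([table.index(l) for l, _ in pairs], dtype=int)
    idx_d = np.array([table.index(d) for _, d in pairs], dtype=int)
    if mode == "hadamard":
        return table.Psi[idx_l] * table.Psi[idx_d]
    if mode == "concat":
        return np.hstack([table.Psi[idx_l], table.Psi[idx_d]])
    raise ValueError("mode must be 'hadamard' or 'concat'")


def _make_classifier(cfg: PipelineConfig) -> GBDTLRClassifier:
    return GBDTLRClassifier(n_estimators=cfg.n_estimators,
                            learning_rate=cfg.learning_rate,
                            max_depth=cfg.max_depth, min_leaf=cfg.min_leaf,
                            l2=cfg.l2, lr_max_steps=cfg.lr_max_steps)


def run_pipeline(A: AssociationMatrix, dags: DiseaseDAGSet,
                 cfg: PipelineConfig | None = None,
                 metagraph: MetaGraph | None = None,
                 outdir=None) -> PipelineResult:
    """Run every stage and return (optionally also write) the artifacts."""
    cfg = cfg or PipelineConfig()
    seeds = cfg.seeds()
    sims = compute_similarities(A, dags, cfg)
    G, corpus, table = embed_network(A, sims, cfg, seeds, metagraph)
    training, km_model, unk = select_training_pairs(A, sims, cfg, seeds)

    with _timed("classifier"):
        X = pair_embedding_features(table, training.pairs(), cfg.pair_features)
        y = training.labels
        if cfg.strict_cv:
            cv = _strict_cv(A, dags, training, cfg, metagraph)
        else:
            cv = cross_validate(X, y, _make_classifier(cfg), folds=cfg.folds,
                                seed=seeds["cv"], stratified=cfg.stratified)
        model = _make_classifier(cfg).fit(X, y)
        log.info("[classifier] mean CV AUC %.4f", cv.mean.AUC)

    with _timed("prediction"):
        unk_ids = [(A.lncrna_ids[m], A.disease_ids[j]) for m, j in unk]
        Xu = pair_embedding_features(table, unk_ids, cfg.pair_features)
        scores = model.predict_proba(Xu)[:, 1]
        predictions = pd.DataFrame({
            "lncRNA": [p[0] for p in unk_ids],
            "disease": [p[1] for p in unk_ids],
            "score": scores,
        }).sort_values(["score", "lncRNA", "disease"],
                       ascending=[False, True, True], kind="mergesort",
                       ignore_index=True)

    result = PipelineResult(A, sims, G, corpus, table, training, cv, model,
                            predictions, cfg, seeds)
    if outdir is not None:
        result.save(outdir)
    return result


def _strict_cv(A: AssociationMatrix, dags: DiseaseDAGSet,
               training: LabeledPairSet, cfg: PipelineConfig,
               metagraph: MetaGraph | None) -> CVResult:
    """Leakage-free CV: recompute similarities, embeddings and negatives per
    fold with the fold's test positives removed from the association matrix."""
    from .evaluation import MetricsRecord, kfold_split

    seeds = cfg.seeds()
    frame = training.frame
    y = training.labels
    assign = kfold_split(y, folds=cfg.folds, seed=seeds["cv"],
                         stratified=cfg.stratified)
    grid = np.linspace(0.0, 1.0, 101)
    per_fold, tprs = [], []
    oof = np.full(len(frame), np.nan)
    li = {l: i for i, l in enumerate(A.lncrna_ids)}
    di = {d: j for j, d in enumerate(A.disease_ids)}
    for f in range(cfg.folds):
        test = assign == f
        masked = A.values.copy()
        for _, row in frame[test & (y == 1)].iterrows():
            masked[li[row["lncRNA"]], di[row["disease"]]] = 0
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            A_f = AssociationMatrix(masked, A.lncrna_ids, A.disease_ids)
        sims_f = compute_similarities(A_f, dags, cfg)
        _, _, table_f = embed_network(A_f, sims_f, cfg, seeds, metagraph)
        X = pair_embedding_features(table_f, training.pairs(), cfg.pair_features)
        clf = _make_classifier(cfg).fit(X[~test], y[~test])
        p = clf.predict_proba(X[test])[:, 1]
        oof[test] = p
        rec = metrics(confusion(p, y[test]))
        rec.AUC, fpr, tpr = roc_auc(p, y[test])
        per_fold.append(rec)
        tprs.append(np.interp(grid, fpr, tpr))
    mean = MetricsRecord(
        ACC=float(np.mean([m.ACC for m in per_fold])),
        Recall=float(np.mean([m.Recall for m in per_fold])),
        F1=float(np.mean([m.F1 for m in per_fold])),
        MCC=float(np.mean([m.MCC for m in per_fold])),
        AUC=float(np.mean([m.AUC for m in per_fold])))
    mean_tpr = np.mean(np.vstack(tprs), axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return CVResult(per_fold, mean, assign, (grid, mean_tpr), oof)
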