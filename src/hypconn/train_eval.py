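"""Training harness and link-prediction evaluation.

Evaluation follows a participant-grouped five-fold protocol: all sessions
of a subject share a fold, so a held-out subject's networks never touch
the gradients.  The HGCN and Euclidean GCN are evaluated inductively (the
trained model embeds unseen test graphs and MAP is computed over all node
pairs); the shallow Poincaré model is transductive, so it is fit per test
graph on 80% of the edges and scored on the held-out 20% with the
training edges excluded from the candidate ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import BrainGraph
from .models import EuclideanGCN, HyperbolicGCN, PoincareEmbedding

__all__ = [
    "TrainConfig",
    "weighted_link_loss",
    "train_model",
    "predict_links",
    "map_score",
    "average_precision",
    "grouped_kfold",
    "link_prediction_experiment",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the deep models."""

    epochs: int = 100
    lr: float = 0.02
    batch_size: int = 1
    seed: int = 0
    curvature_mode: str = "learned"
    dim: int = 3
    hidden_dim: int = 6
    optimizer: str = "riemannian_adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def weighted_link_loss(pred_prob: np.ndarray, target_prob: np.ndarray) -> float:
    """Mean squared error over off-diagonal upper-triangle node pairs."""
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    target_prob = np.asarray(target_prob, dtype=np.float64)
    if pred_prob.shape != target_prob.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_prob.shape} vs target {target_prob.shape}"
        )
    iu = np.triu_indices(pred_prob.shape[0], k=1)
    diff = pred_prob[iu] - target_prob[iu]
    return float(np.mean(diff * diff))


def train_model(graphs, cfg: TrainConfig, model: str = "hgcn", verbose: bool = False):
    """Fit an inductive model on the training graphs.

    ``model`` is ``"hgcn"`` (curvature mode from ``cfg``) or ``"gcn"``.
    Returns the fitted results object (loss trace under ``.loss_trace``).
    """
    if model == "hgcn":
        m = HyperbolicGCN(graphs, dim=cfg.dim, hidden_dim=cfg.hidden_dim,
                          curvature=cfg.curvature_mode, seed=cfg.seed)
    elif model == "gcn":
        m = EuclideanGCN(graphs, dim=cfg.dim, hidden_dim=cfg.hidden_dim,
                         seed=cfg.seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    return m.fit(epochs=cfg.epochs, lr=cfg.lr, verbose=verbose)


def predict_links(results, graph: BrainGraph) -> np.ndarray:
    """Predicted link-probability matrix for a graph (symmetric, (0,1))."""
    return results.predict_links(graph)


def average_precision(scores: np.ndarray, positives: np.ndarray,
                      candidates: np.ndarray) -> float:
    """AP of ``positives`` within ``candidates`` ranked by descending score.

    Ties are broken by candidate index (stable sort), so the result is
    deterministic.
    """
    order = candidates[np.argsort(-scores[candidates], kind="stable")]
    is_pos = np.isin(order, positives)
    hits = np.flatnonzero(is_pos)
    if hits.size == 0:
        return 0.0
    precision_at_hits = (np.arange(hits.size) + 1) / (hits + 1)
    return float(precision_at_hits.mean())


def map_score(predicted: np.ndarray, adjacency: np.ndarray,
              exclude: np.ndarray | None = None) -> float:
    """Mean averaged precision of true neighbors under score ranking.

    For every node with at least one neighbor, all other nodes are ranked
    by predicted score (descending, ties by node index) and the average
    precision of its true neighbors is computed; the per-node APs are then
    averaged.  ``exclude`` is an optional boolean matrix of pairs to drop
    from the candidate set (used for masked-edge protocols).
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    adjacency = np.asarray(adjacency)
    R = adjacency.shape[0]
    if predicted.shape != (R, R):
        raise ValueError("predicted and adjacency shapes differ")
    deg = adjacency.sum(axis=1)
    if deg.sum() == 0:
        raise ValueError("adjacency has no edges")
    aps = []
    all_nodes = np.arange(R)
    for i in range(R):
        if deg[i] == 0:
            continue
        cand = all_nodes[all_nodes != i]
        if exclude is not None:
            cand = cand[~exclude[i, cand]]
        pos = np.flatnonzero(adjacency[i])
        pos = pos[np.isin(pos, cand)]
        if pos.size == 0:
            continue
        aps.append(average_precision(predicted[i], pos, cand))
    return float(np.mean(aps))


def grouped_kfold(subjects, k: int = 5, seed: int = 0) -> dict:
    """Deterministic subject -> fold assignment (all sessions share a fold)."""
    unique = sorted(set(subjects))
    if len(unique) < k:
        raise ValueError(f"need at least {k} subjects, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds = {}
    for pos, idx in enumerate(order):
        folds[unique[idx]] = pos % k
    return folds


def _split_graphs(graphs, folds, test_fold):
    train = [g for g in graphs if folds[g.subject_id] != test_fold]
    test = [g for g in graphs if folds[g.subject_id] == test_fold]
    return train, test


def _mask_edges(adjacency, fraction, rng):
    """Hold out a random fraction of edges; returns (train_edges, held_out)."""
    edges = np.argwhere(np.triu(adjacency, k=1))
    n_hold = max(1, int(round(fraction * edges.shape[0])))
    perm = rng.permutation(edges.shape[0])
    held = edges[perm[:n_hold]]
    kept = edges[perm[n_hold:]]
    return kept, held


def link_prediction_experiment(
    graphs,
    models=("hgcn_learned", "hgcn_fixed", "gcn", "shallow"),
    dims=(2, 3),
    cfg: TrainConfig | None = None,
    k: int = 5,
    folds_to_run=None,
    shallow_epochs: int = 200,
    mask_fraction: float = 0.2,
) -> pd.DataFrame:
    """Cross-validated link-prediction benchmark.

    Returns one row per model x dimension with per-fold and mean MAP plus
    the learned curvatures (HGCN only).  ``folds_to_run`` restricts
    evaluation to a subset of the k folds (all by default).
    """
    cfg = cfg or TrainConfig()
    folds = grouped_kfold([g.subject_id for g in graphs], k=k, seed=cfg.seed)
    run_folds = list(range(k)) if folds_to_run is None else list(folds_to_run)
    rows = []
    for model in models:
        for dim in dims:
            per_fold, k1s, k2s = [], [], []
            for fold in run_folds:
                train, test = _split_graphs(graphs, folds, fold)
                fold_maps = []
                if model == "shallow":
                    for g in test:
                        rng = np.random.default_rng(cfg.seed * 10007 + fold)
                        kept, held = _mask_edges(g.adjacency, mask_fraction, rng)
                        res = PoincareEmbedding(
                            g, dim=dim, epochs=shallow_epochs,
                            seed=cfg.seed * 997 + fold,
                        ).fit(train_edges=kept)
                        pred = res.predict_links()
                        adj_eval = np.zeros_like(g.adjacency)
                        adj_eval[held[:, 0], held[:, 1]] = 1
                        adj_eval |= adj_eval.T
                        excl = np.zeros_like(g.adjacency, dtype=bool)
                        excl[kept[:, 0], kept[:, 1]] = True
                        excl |= excl.T
                        fold_maps.append(map_score(pred, adj_eval, exclude=excl))
                else:
                    mcfg = TrainConfig(
                        epochs=cfg.epochs, lr=cfg.lr, seed=cfg.seed,
                        curvature_mode="fixed" if model == "hgcn_fixed" else "learned",
                        dim=dim, hidden_dim=cfg.hidden_dim,
                    )
                    res = train_model(
                        train, mcfg, model="gcn" if model == "gcn" else "hgcn"
                    )
                    for g in test:
                        fold_maps.append(map_score(res.predict_links(g), g.adjacency))
                    if model == "hgcn_learned":
                        k1s.append(res.K1)
                        k2s.append(res.K2)
                per_fold.append(float(np.mean(fold_maps)))
            rows.append({
                "model": model,
                "dim": dim,
                "mean_map": float(np.mean(per_fold)),
                "per_fold_map": per_fold,
                "K1": float(np.mean(k1s)) if k1s else np.nan,
                "K2": float(np.mean(k2s)) if k2s else np.nan,
                "protocol": "masked_edges_20pct" if model == "shallow" else "inductive",
            })
    return pd.DataFrame(rows)
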