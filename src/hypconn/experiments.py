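"""Benchmark drivers: overfit capacity, model comparison, hierarchy recovery.

These functions reproduce the package's main computational experiments at
desk scale (problem sizes chosen to run on a single CPU in minutes; see
docs/methods.md).  They are used both by the validation suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .hierarchy import fit_radius_embedder, group_difference, radius_table
from .models import EuclideanGCN, HyperbolicGCN
from .synthdata import (
    SynthCohortSpec,
    make_graph_cohort,
    make_two_cluster_graph,
    make_two_group_cohort,
)
from .train_eval import grouped_kfold, map_score

__all__ = [
    "overfit_capacity",
    "hgcn_vs_gcn_linkpred",
    "hierarchy_recovery",
]


def overfit_capacity(epochs: int = 120, seed: int = 0) -> np.ndarray:
    """Loss trace of an HGCN overfitting the 10-node two-cluster fixture."""
    g = make_two_cluster_graph(seed=3)
    res = HyperbolicGCN([g], dim=2, curvature="learned", seed=seed).fit(
        epochs=epochs, lr=0.02)
    return res.loss_trace


def hgcn_vs_gcn_linkpred(n_graphs: int = 20, seeds=(0, 1, 2, 3, 4),
                         epochs: int = 70, n_train: int = 4, dim: int = 2,
                         cohort_seed: int = 42, R: int = 90) -> dict:
    """Held-out link-prediction MAP: learned-curvature HGCN vs Euclidean GCN.

    A cohort of related scale-free graphs is split subject-wise; per seed,
    both models are trained on ``n_train`` training-fold graphs and scored
    (mean averaged precision over all pairs) on the held-out fold.
    """
    graphs = make_graph_cohort(n_graphs, R=R, seed=cohort_seed)
    out = {"hgcn": [], "gcn": [], "K1": [], "K2": []}
    for seed in seeds:
        folds = grouped_kfold([g.subject_id for g in graphs], k=5, seed=seed)
        fold = seed % 5
        test = [g for g in graphs if folds[g.subject_id] == fold]
        train = [g for g in graphs if folds[g.subject_id] != fold][:n_train]
        h = HyperbolicGCN(train, dim=dim, curvature="learned", seed=seed).fit(
            epochs=epochs, lr=0.02)
        out["hgcn"].append(float(np.mean(
            [map_score(h.predict_links(g), g.adjacency) for g in test])))
        out["K1"].append(h.K1)
        out["K2"].append(h.K2)
        e = EuclideanGCN(train, dim=dim, seed=seed).fit(epochs=epochs, lr=0.02)
        out["gcn"].append(float(np.mean(
            [map_score(e.predict_links(g), g.adjacency) for g in test])))
    out["mean_hgcn"] = float(np.mean(out["hgcn"]))
    out["mean_gcn"] = float(np.mean(out["gcn"]))
    return out


def _one_recovery_rep(delta: float, cohort_seed: int, train_seed: int,
                      n_per_group: int, epochs: int) -> set:
    spec = SynthCohortSpec(n_per_group=n_per_group, hierarchy_shift=delta,
                           seed=cohort_seed)
    graphs, _ = make_two_group_cohort(spec)
    pre = [g for g in graphs if g.session == "pre"]
    train = pre[:2] + pre[n_per_group:n_per_group + 2]  # 2 per group
    res = fit_radius_embedder(train, dim=3, seed=train_seed, epochs=epochs,
                              max_restarts=1)
    embs = [res.embed(g) for g in graphs]
    rt = radius_table(embs)
    rt["age"] = rt["subject_id"].map({g.subject_id: g.age for g in graphs})
    report = group_difference(rt, method="linear_adjusted")
    return set(report[report["significant"]]["subnetwork"])


def hierarchy_recovery(n_reps: int = 6, null_reps: int = 3,
                       n_per_group: int = 20, delta: float | None = None,
                       epochs: int = 30, seed: int = 0) -> dict:
    """Full-pipeline recovery of implanted subnetwork hierarchy differences.

    Per replicate: generate a two-group cohort (designated subnetworks of
    group 2 receive a hub-propensity boost), train an HGCN, embed every
    graph, and test the eight subnetwork mean radii with the
    covariate-adjusted contrast under BH-FDR.  Reports sensitivity (all
    designated subnetworks flagged), exact-set rate (flagged set equals the
    designated set), and the null flag rate at ``delta = 0``.
    """
    spec_default = SynthCohortSpec()
    if delta is None:
        delta = spec_default.hierarchy_shift
    designated = set(spec_default.shifted_subnets)
    sens = exact = 0
    det = offt = 0.0
    per_rep = []
    for rep in range(n_reps):
        flagged = _one_recovery_rep(delta, seed * 1009 + rep, seed + rep,
                                    n_per_group, epochs)
        sens += designated <= flagged
        exact += flagged == designated
        det += len(flagged & designated) / len(designated)
        offt += len(flagged - designated) / (8 - len(designated))
        per_rep.append(sorted(flagged))
    null_flags = 0
    for rep in range(null_reps):
        flagged = _one_recovery_rep(0.0, seed * 2003 + 500 + rep, seed + rep,
                                    n_per_group, epochs)
        null_flags += len(flagged)
    return {
        "sensitivity": sens / n_reps,
        "exact_rate": exact / n_reps,
        "designated_detection_rate": det / n_reps,
        "offtarget_flag_rate": offt / n_reps,
        "null_flag_rate": null_flags / (null_reps * 8),
        "flagged_per_rep": per_rep,
        "designated": sorted(designated),
        "delta": delta,
    }
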