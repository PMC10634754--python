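"""Synthetic fixtures with known ground truth.

Brain functional networks are scale-free and tree-like; the generator here
samples 90-node graphs from a popularity-similarity rule (the S1 geometric
model): node ``i`` carries a hidden expected degree ``kappa_i`` drawn from
a heavy-tailed (Pareto-like) sequence, nodes sit at uniform angular
positions on a circle, and a pair connects with probability

    p_ij = 1 / (1 + (d_ij / (mu * kappa_i * kappa_j))**(1/T))

where ``d_ij`` is the arc distance and ``T`` the temperature controlling
clustering randomness.  ``mu`` is calibrated by bisection so the expected
mean degree matches the request.  Connection propensities double as
continuous PLV-like edge weights, so the full pipeline (graph -> HGCN ->
radius -> statistics) can be exercised without any external data.

Two-group cohorts implant a hierarchy difference by boosting the hub
propensity ``kappa`` of designated-subnetwork nodes in group 2, which
raises their degrees and (after embedding) shrinks their hyperbolic
radii — the generator never touches the embeddings directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import (
    SUBNETWORKS,
    BrainGraph,
    SourcePhases,
    default_subnetwork_map,
    scale_probabilities,
    synthetic_node_meta,
)

__all__ = [
    "SynthCohortSpec",
    "make_binary_tree",
    "make_hierarchical_network",
    "make_graph_cohort",
    "make_oscillator_cohort",
    "make_two_group_cohort",
    "make_radius_table",
    "make_two_cluster_graph",
]


def make_two_cluster_graph(n: int = 10, seed: int = 3) -> BrainGraph:
    """Small two-cluster graph with nearly binary edge probabilities.

    Within-cluster PLVs are drawn from [0.85, 0.95], across-cluster from
    [0.02, 0.10], so after min-max scaling the targets sit near 0/1 and are
    trivially realizable by a distance decoder — the standard fixture for
    overfit/capacity checks.
    """
    rng = np.random.default_rng(seed)
    plv = np.zeros((n, n))
    half = n // 2
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < half) == (j < half)
            plv[i, j] = plv[j, i] = (
                rng.uniform(0.85, 0.95) if same else rng.uniform(0.02, 0.10)
            )
    from .connectivity import build_graph

    return build_graph(plv, node_meta=synthetic_node_meta(n), threshold=0.5,
                       subject_id="two_cluster")

#: Subnetworks that carry the implanted hierarchy difference by default.
DEFAULT_SHIFTED_SUBNETS = ("DAN", "FPN", "VAN")


@dataclass
class SynthCohortSpec:
    """Conditions of a synthetic two-group cohort.

    ``hierarchy_shift`` is the fractional hub-propensity boost applied to
    designated-subnetwork nodes of group 2 (0 = exchangeable groups).
    """

    n_per_group: int = 20
    R: int = 90
    edge_density: float = 0.20
    hierarchy_shift: float = 0.5
    shifted_subnets: tuple = DEFAULT_SHIFTED_SUBNETS
    noise_sd: float = 0.02
    gamma: float = 2.5
    temperature: float = 0.3
    two_sessions: bool = True
    rewire_fraction: float = 0.05
    age_mean: float = 71.0
    age_sd: float = 4.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        if self.hierarchy_shift < 0:
            raise ValueError("hierarchy_shift must be >= 0")


def make_binary_tree(depth: int) -> BrainGraph:
    """Perfect binary tree with ``2**(depth+1) - 1`` nodes; weights = adjacency."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    G = nx.balanced_tree(2, depth)
    A = nx.to_numpy_array(G, dtype=np.uint8)
    meta = synthetic_node_meta(A.shape[0])
    return BrainGraph(adjacency=A, edge_prob=A.astype(np.float64), node_meta=meta,
                      subject_id="tree", connected=True)


def _pareto_kappas(R: int, gamma: float, avg_degree: float) -> np.ndarray:
    """Deterministic heavy-tailed hidden-degree sequence, largest first."""
    u = (np.arange(R) + 0.5) / R
    kap = u ** (-1.0 / (gamma - 1.0))
    return kap * (avg_degree / kap.mean())


def _connection_probs(kappas: np.ndarray, thetas: np.ndarray, mu: float,
                      temperature: float) -> np.ndarray:
    R = kappas.shape[0]
    thetas = np.mod(thetas, 2 * np.pi)
    dtheta = np.abs(thetas[:, None] - thetas[None, :])
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
    d = dtheta * R / (2 * np.pi)  # arc distance at unit node density
    kk = mu * np.outer(kappas, kappas)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(kk > 0, d / kk, np.inf)
        if temperature <= 1e-6:  # zero-temperature step-function limit
            p = (ratio < 1.0).astype(np.float64)
        else:
            p = 1.0 / (1.0 + ratio ** (1.0 / temperature))
    np.fill_diagonal(p, 0.0)
    return p


def _calibrate_mu(kappas, thetas, temperature, avg_degree) -> float:
    """Bisection on log(mu) so the expected mean degree hits avg_degree."""
    def mean_deg(mu):
        return _connection_probs(kappas, thetas, mu, temperature).sum() / kappas.shape[0]

    lo, hi = 1e-8, 1e4
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_deg(mid) < avg_degree:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    return float(np.sqrt(lo * hi))


def make_hierarchical_network(R: int = 90, avg_degree: float | None = None,
                              gamma: float = 2.5, temperature: float = 0.3,
                              seed: int = 0, noise_sd: float = 0.02,
                              node_meta: pd.DataFrame | None = None,
                              kappa_boost: np.ndarray | None = None,
                              thetas: np.ndarray | None = None,
                              subject_id: str | None = None,
                              session: str = "pre", group: str | None = None,
                              age: float | None = None) -> BrainGraph:
    """Sample one scale-free, tree-like weighted graph.

    ``kappa_boost`` multiplies the hidden degree of selected nodes (used to
    implant hubness); ``thetas`` fixes the angular layout (used to make
    cohort members share a common latent topology, the way participant
    brain networks do).  Edge weights are the connection propensities plus
    Gaussian noise, min-max scaled to [0, 1].  Disconnected samples are
    allowed but flagged via ``graph.connected``.
    """
    if R < 10:
        raise ValueError("R must be >= 10")
    if avg_degree is None:
        avg_degree = 0.20 * (R - 1)
    rng = np.random.default_rng(seed)
    kappas = _pareto_kappas(R, gamma, avg_degree)
    if thetas is None:
        thetas = rng.uniform(0, 2 * np.pi, size=R)
    else:
        thetas = np.asarray(thetas, dtype=np.float64)
    # a hub boost shifts RELATIVE popularity; mu is recalibrated afterwards so
    # both groups share the same expected density (a gross density difference
    # would confound every radius comparison)
    if kappa_boost is not None:
        kappas = kappas * np.asarray(kappa_boost, dtype=np.float64)
    mu = _calibrate_mu(kappas, thetas, temperature, avg_degree)
    p = _connection_probs(kappas, thetas, mu, temperature)
    iu = np.triu_indices(R, k=1)
    adj = np.zeros((R, R), dtype=np.uint8)
    adj[iu] = rng.random(iu[0].size) < p[iu]
    adj |= adj.T
    weights = p.copy()
    if noise_sd > 0:
        noise = rng.normal(0, noise_sd, size=(R, R))
        weights = np.clip(p + (noise + noise.T) / np.sqrt(2), 0.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    edge_prob = scale_probabilities(weights, scope="per_graph")
    if node_meta is None:
        node_meta = default_subnetwork_map() if R == 90 else synthetic_node_meta(R)
    connected = bool(nx.is_connected(nx.from_numpy_array(adj))) if adj.sum() else False
    return BrainGraph(adjacency=adj, edge_prob=edge_prob, node_meta=node_meta,
                      subject_id=subject_id, session=session, group=group,
                      age=age, plv=None, connected=connected,
                      extras={"propensity": p, "kappas": kappas})


def _rewire(adjacency: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Rewire a fraction of edges to random non-edges (session noise)."""
    adj = adjacency.copy()
    edges = np.argwhere(np.triu(adj, k=1))
    non_edges = np.argwhere(np.triu(1 - adj, k=1) & ~np.eye(adj.shape[0], dtype=bool))
    n = int(round(fraction * edges.shape[0]))
    if n == 0 or non_edges.shape[0] == 0:
        return adj
    drop = edges[rng.choice(edges.shape[0], size=n, replace=False)]
    add = non_edges[rng.choice(non_edges.shape[0], size=min(n, non_edges.shape[0]),
                               replace=False)]
    adj[drop[:, 0], drop[:, 1]] = adj[drop[:, 1], drop[:, 0]] = 0
    adj[add[:, 0], add[:, 1]] = adj[add[:, 1], add[:, 0]] = 1
    return adj


def make_graph_cohort(n: int, R: int = 90, edge_density: float = 0.20,
                      gamma: float = 2.5, temperature: float = 0.3,
                      noise_sd: float = 0.02, subject_jitter: float = 0.1,
                      seed: int = 0, node_meta: pd.DataFrame | None = None,
                      prefix: str = "s") -> list[BrainGraph]:
    """Cohort of related scale-free graphs (one per subject).

    All subjects share a latent angular layout (as participant brain
    networks share most of their topology); each subject perturbs the node
    angles by Gaussian jitter of ``subject_jitter`` radians and redraws the
    edges, so networks are similar but not identical across the cohort.
    """
    rng = np.random.default_rng(seed)
    avg_degree = edge_density * (R - 1)
    base_thetas = rng.uniform(0, 2 * np.pi, size=R)
    graphs = []
    for s in range(n):
        gseed = int(rng.integers(0, 2**31 - 1))
        jit = np.random.default_rng(gseed).normal(0, subject_jitter, size=R)
        graphs.append(make_hierarchical_network(
            R=R, avg_degree=avg_degree, gamma=gamma, temperature=temperature,
            seed=gseed, noise_sd=noise_sd, node_meta=node_meta,
            thetas=base_thetas + jit, subject_id=f"{prefix}{s:03d}",
        ))
    return graphs


def make_two_group_cohort(spec: SynthCohortSpec):
    """Two-group cohort with an implanted subnetwork hierarchy difference.

    Returns ``(graphs, truth)`` where ``truth`` records the designated
    subnetworks, the boost ``delta``, and the per-group subject ids.
    Group 1 graphs are plain popularity-similarity draws; group 2 boosts
    the hub propensity of designated-subnetwork nodes by ``1 + delta``.
    """
    avg_degree = spec.edge_density * (spec.R - 1)
    meta = default_subnetwork_map() if spec.R == 90 else synthetic_node_meta(spec.R)
    designated = meta["subnetwork"].isin(spec.shifted_subnets).to_numpy()
    boost = np.where(designated, 1.0 + spec.hierarchy_shift, 1.0)
    # guard: the boost must keep the graph in a sane density regime
    kap = _pareto_kappas(spec.R, spec.gamma, avg_degree)
    boosted_deg = avg_degree * (kap * boost).sum() / kap.sum()
    if boosted_deg / (spec.R - 1) > 0.5:
        raise ValueError("hierarchy_shift too large: boosted density leaves (0, 0.5]")
    root = np.random.default_rng(spec.seed)
    base_thetas = root.uniform(0, 2 * np.pi, size=spec.R)  # shared cohort layout
    graphs = []
    truth = {
        "shifted_subnets": tuple(spec.shifted_subnets),
        "delta": spec.hierarchy_shift,
        "designated_nodes": np.flatnonzero(designated),
        "groups": {"HC": [], "G2": []},
    }
    for group, gboost in (("HC", None), ("G2", boost)):
        for s in range(spec.n_per_group):
            sid = f"{group.lower()}{s:03d}"
            truth["groups"][group].append(sid)
            age = float(root.normal(spec.age_mean, spec.age_sd))
            gseed = int(root.integers(0, 2**31 - 1))
            jit = np.random.default_rng(gseed).normal(0, 0.1, size=spec.R)
            g = make_hierarchical_network(
                R=spec.R, avg_degree=avg_degree, gamma=spec.gamma,
                temperature=spec.temperature, seed=gseed, noise_sd=spec.noise_sd,
                node_meta=meta, kappa_boost=gboost, thetas=base_thetas + jit,
                subject_id=sid, session="pre", group=group, age=age,
            )
            graphs.append(g)
            if spec.two_sessions:
                rng2 = np.random.default_rng(gseed + 1)
                adj2 = _rewire(g.adjacency, spec.rewire_fraction, rng2)
                graphs.append(BrainGraph(
                    adjacency=adj2, edge_prob=g.edge_prob.copy(),
                    node_meta=meta, subject_id=sid, session="post",
                    group=group, age=age, connected=g.connected,
                ))
    return graphs, truth


def make_oscillator_cohort(coupling: np.ndarray, T: int = 1000, n_epochs: int = 1,
                           noise_sd: float = 0.0, seed: int = 0,
                           sources_per_region: int = 1) -> SourcePhases:
    """Phase time series whose expected pairwise PLV increases with coupling.

    The symmetric coupling matrix is reduced to its best rank-one
    factorization ``w w^T`` (top eigenpair); region ``r`` mixes a shared
    oscillator with weight ``w_r`` against independent phase noise, so
    pairs with larger ``w_p * w_q`` phase-lock more tightly.  Exact for
    rank-one couplings; monotone (not exact) otherwise.
    """
    C = np.asarray(coupling, dtype=np.float64)
    if not np.allclose(C, C.T):
        raise ValueError("coupling must be symmetric")
    R = C.shape[0]
    Cd = C.copy()
    np.fill_diagonal(Cd, 1.0)
    evals, evecs = np.linalg.eigh(Cd)
    w = np.clip(np.sqrt(max(evals[-1], 0.0)) * np.abs(evecs[:, -1]), 0.0, 1.0)
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0, 2 * np.pi, size=(n_epochs, T))  # shared oscillator
    phases = []
    for r in range(R):
        eta = rng.uniform(0, 2 * np.pi, size=(sources_per_region, n_epochs, T))
        z = (w[r] * np.exp(1j * psi)[None] + (1.0 - w[r]) * np.exp(1j * eta))
        if noise_sd > 0:
            z = z + noise_sd * (rng.standard_normal(z.shape)
                                + 1j * rng.standard_normal(z.shape))
        phases.append(np.angle(z))
    return SourcePhases(phases=phases)


def make_radius_table(n_per_group: int = 20, shift: float = 0.15,
                      noise_sd: float = 0.05, seed: int = 0,
                      shifted_subnets: tuple = DEFAULT_SHIFTED_SUBNETS,
                      base_radius: float = 1.85, two_sessions: bool = True,
                      age_mean: float = 71.0, age_sd: float = 4.5) -> pd.DataFrame:
    """Synthetic subject x session table of subnetwork mean radii.

    Direct statistical fixture (no graphs or embeddings): group 2 radii in
    the designated subnetworks are lowered by ``shift`` on top of
    subject-level noise ``noise_sd``.  Used to calibrate the
    group-difference inference in isolation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("HC", "G2"):
        for s in range(n_per_group):
            sid = f"{group.lower()}{s:03d}"
            age = float(rng.normal(age_mean, age_sd))
            subj_effect = rng.normal(0, noise_sd, size=len(SUBNETWORKS))
            for session in ("pre", "post") if two_sessions else ("pre",):
                sess_noise = rng.normal(0, noise_sd / 2, size=len(SUBNETWORKS))
                row = {"subject_id": sid, "session": session, "group": group,
                       "age": age}
                for j, net in enumerate(SUBNETWORKS):
                    val = base_radius + subj_effect[j] + sess_noise[j]
                    if group == "G2" and net in shifted_subnets:
                        val -= shift
                    row[f"radius_{net}"] = val
                rows.append(row)
    return pd.DataFrame(rows)
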