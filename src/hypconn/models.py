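"""Graph embedding models: hyperbolic GCN, Euclidean GCN, shallow Poincaré.

The central model, :class:`HyperbolicGCN`, is a two-layer graph
convolutional network operating on the Poincaré ball.  Per layer, node
features are transformed with Möbius matrix multiplication and bias
addition, aggregated over the closed neighborhood ``{N(i), i}`` with the
differentiable Fréchet mean, and passed through a ReLU applied in the
tangent space at the origin.  A Fermi-Dirac decoder converts squared
output-embedding distances into link probabilities, which are regressed
(mean squared error) onto min-max-scaled PLV values — so the continuous
connectivity information lost in the adjacency thresholding still shapes
the embedding.

Model classes follow a fit/results split: a model is constructed from
data (a list of :class:`~hypconn.connectivity.BrainGraph`), ``fit()``
runs the optimizer and returns a results object that carries the learned
parameters, loss trace and curvatures, and knows how to embed new graphs
(`HGCN`/`GCN` are inductive; the shallow Poincaré model is transductive
and is fit per graph).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _ad, geometry
from ._ad import Adam, parameter, relu, reshape, sigmoid, value_of
from .connectivity import BrainGraph

__all__ = [
    "fermi_dirac",
    "hgcn_layer",
    "HGCNParams",
    "EmbeddingResult",
    "TrainingDivergedError",
    "HyperbolicGCN",
    "HGCNResults",
    "EuclideanGCN",
    "GCNResults",
    "PoincareEmbedding",
    "PoincareResults",
]

#: Fermi-Dirac decoder defaults (inflection r, temperature t).
FD_R = 2.0
FD_T = 1.0

_SOFTPLUS_INV_1 = float(np.log(np.expm1(1.0)))  # raw value mapping to K = -1


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch, value):
        super().__init__(f"training diverged at epoch {epoch}: loss = {value}")
        self.epoch = epoch


def fermi_dirac(d_sq, r: float = FD_R, t: float = FD_T):
    """Link probability from squared embedding distance.

    ``p = 1 / (exp((d_sq - r)/t) + 1)``; strictly decreasing in ``d_sq``.
    """
    if t <= 0:
        raise ValueError(f"Fermi-Dirac temperature must be positive, got {t}")
    return sigmoid((r - d_sq) / t)


def _closed_neighborhood_weights(adjacency: np.ndarray) -> np.ndarray:
    """Uniform aggregation weights over {N(i), i} (rows of A + I)."""
    A = np.asarray(adjacency, dtype=np.float64)
    return A + np.eye(A.shape[0])


def hgcn_layer(x, adjacency, W, b, K_prev, K_next, activation: bool = True,
               frechet_tol: float = 1e-6, frechet_max_iter: int = 100):
    """One hyperbolic graph convolution layer.

    ``h_i = (W ⊗_{K_prev} x_i) ⊕_{K_prev} exp_map0(b)`` followed by
    Fréchet-mean aggregation over the closed neighborhood, then (optionally)
    a tangent-space ReLU mapping from curvature ``K_prev`` to ``K_next``.
    Isolated nodes aggregate over themselves alone.
    """
    bias = geometry.exp_map0(b, K_prev)
    h = geometry.mobius_add(geometry.mobius_matvec(W, x, K_prev), bias, K_prev)
    agg_w = _closed_neighborhood_weights(adjacency)
    y = geometry.frechet_mean_batch(h, agg_w, K_prev, tol=frechet_tol,
                                    max_iter=frechet_max_iter, on_max_iter="return")
    if activation:
        y = geometry.hyp_activation(y, K_prev, K_next, relu)
    return geometry.project_to_ball(y, K_next if activation else K_prev)


@dataclass
class HGCNParams:
    """Learnable parameters of the two-layer HGCN."""

    W1: _ad.Tensor
    b1: _ad.Tensor
    W2: _ad.Tensor
    b2: _ad.Tensor
    c1: _ad.Tensor | None  # raw curvature params (None when fixed)
    c2: _ad.Tensor | None
    curvature_mode: str = "learned"

    @classmethod
    def init(cls, n_nodes: int, hidden_dim: int, dim: int, curvature_mode: str,
             rng: np.random.Generator) -> "HGCNParams":
        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return parameter(rng.uniform(-lim, lim, size=shape))

        learned = curvature_mode == "learned"
        return cls(
            W1=glorot((hidden_dim, n_nodes)),
            b1=parameter(np.zeros(hidden_dim)),
            W2=glorot((dim, hidden_dim)),
            b2=parameter(np.zeros(dim)),
            c1=parameter(np.full((), _SOFTPLUS_INV_1)) if learned else None,
            c2=parameter(np.full((), _SOFTPLUS_INV_1)) if learned else None,
            curvature_mode=curvature_mode,
        )

    def trainable(self):
        ps = [self.W1, self.b1, self.W2, self.b2]
        if self.curvature_mode == "learned":
            ps += [self.c1, self.c2]
        return ps

    def K1(self, numeric: bool = False):
        """Hidden-layer curvature ``-softplus(c1)`` (or fixed -1)."""
        if self.curvature_mode != "learned":
            return -1.0
        K = -_ad.softplus(self.c1)
        return float(value_of(K)) if numeric else K

    def K2(self, numeric: bool = False):
        if self.curvature_mode != "learned":
            return -1.0
        K = -_ad.softplus(self.c2)
        return float(value_of(K)) if numeric else K

    def numpy_values(self) -> dict:
        out = {k: getattr(self, k).data.copy() for k in ("W1", "b1", "W2", "b2")}
        out["K1"] = self.K1(numeric=True)
        out["K2"] = self.K2(numeric=True)
        out["curvature_mode"] = self.curvature_mode
        return out


@dataclass
class EmbeddingResult:
    """Per-node output coordinates of one graph plus the final curvature."""

    coords: np.ndarray
    curvature: float
    node_meta: object = None
    subject_id: str | None = None
    session: str = "pre"
    group: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def radius(self) -> np.ndarray:
        """Geodesic distance of each node from the ball center."""
        origin = np.zeros_like(self.coords)
        return np.asarray(geometry.hyp_distance(origin, self.coords, self.curvature))

    def plot(self, ax=None, **scatter_kw):
        """Scatter the first two embedding coordinates, colored by subnetwork."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xy = self.coords[:, :2]
        if self.node_meta is not None and "subnetwork" in getattr(self.node_meta, "columns", []):
            for net, idx in self.node_meta.groupby("subnetwork").groups.items():
                ax.scatter(xy[list(idx), 0], xy[list(idx), 1], label=net, **scatter_kw)
            ax.legend(fontsize=7)
        else:
            ax.scatter(xy[:, 0], xy[:, 1], **scatter_kw)
        R = geometry.ball_radius(self.curvature)
        circle = plt.Circle((0, 0), R, fill=False, ls="--", color="gray")
        ax.add_patch(circle)
        ax.set_aspect("equal")
        return ax


def _pairwise_dsq_hyp(coords, K):
    R, D = value_of(coords).shape
    u = reshape(coords, (R, 1, D))
    v = reshape(coords, (1, R, D))
    d = geometry.hyp_distance(u, v, K)
    return d * d


def _pairwise_dsq_euc(coords):
    R, D = value_of(coords).shape
    u = reshape(coords, (R, 1, D))
    v = reshape(coords, (1, R, D))
    diff = u - v
    return _ad.asum(diff * diff, axis=-1)


def _masked_mse(pred, target, mask):
    diff = (pred - target) * mask
    return _ad.asum(diff * diff) / mask.sum()


class _GCNBase:
    """Shared fit loop of the hyperbolic and Euclidean two-layer GCNs."""

    def __init__(self, graphs, dim: int = 3, hidden_dim: int = 6,
                 curvature: str = "learned", seed: int = 0,
                 frechet_tol: float = 1e-4, frechet_max_iter: int = 30):
        if isinstance(graphs, BrainGraph):
            graphs = [graphs]
        if not graphs:
            raise ValueError("need at least one training graph")
        n = {g.n_nodes for g in graphs}
        if len(n) != 1:
            raise ValueError(f"all graphs must share a node set; got sizes {sorted(n)}")
        self.graphs = list(graphs)
        self.n_nodes = n.pop()
        self.dim = dim
        self.hidden_dim = hidden_dim
        self.curvature_mode = curvature
        self.seed = seed
        self.frechet_tol = frechet_tol
        self.frechet_max_iter = frechet_max_iter
        self._mask = np.triu(np.ones((self.n_nodes, self.n_nodes)), k=1)

    # subclasses: _forward(adjacency, params) -> coords, _dsq(coords, params)

    def fit(self, epochs: int = 100, lr: float = 0.02, verbose: bool = False):
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        opt = Adam(params.trainable(), lr=lr)
        trace = []
        for epoch in range(epochs):
            losses = []
            for g in self.graphs:
                opt.zero_grad()
                coords = self._forward(g.adjacency, params)
                prob = fermi_dirac(self._dsq(coords, params))
                loss = _masked_mse(prob, g.edge_prob, self._mask)
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(epoch, float(loss.data))
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
            if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:.6f}")
        return self._make_results(params, np.asarray(trace))


class HyperbolicGCN(_GCNBase):
    """Two-layer hyperbolic GCN on the Poincaré ball.

    Parameters
    ----------
    graphs : BrainGraph or list of BrainGraph
        Training graphs over a common node set.
    dim : int
        Output embedding dimension ``D``.
    hidden_dim : int
        Hidden-layer dimension (default 6).
    curvature : {"learned", "fixed"}
        ``"fixed"`` pins both layer curvatures to -1; ``"learned"`` trains
        two free curvatures ``K1`` (hidden) and ``K2`` (output) through a
        ``-softplus`` reparameterization (negativity guaranteed).
    seed : int
        Seed for the parameter initialization (training is deterministic
        given seed and data).
    """

    def _init_params(self, rng):
        return HGCNParams.init(self.n_nodes, self.hidden_dim, self.dim,
                               self.curvature_mode, rng)

    def _forward(self, adjacency, params, numeric: bool = False):
        if adjacency.shape[0] != self.n_nodes:
            raise ValueError(
                f"graph has {adjacency.shape[0]} nodes, model expects {self.n_nodes}"
            )
        K1 = params.K1(numeric=numeric)
        K2 = params.K2(numeric=numeric)
        W1, b1, W2, b2 = params.W1, params.b1, params.W2, params.b2
        if numeric:
            W1, b1, W2, b2 = W1.data, b1.data, W2.data, b2.data
        feats = np.eye(self.n_nodes)  # one-hot identity features
        x0 = geometry.exp_map0(feats, K1)  # lift into the ball
        x1 = hgcn_layer(x0, adjacency, W1, b1, K1, K2, activation=True,
                        frechet_tol=self.frechet_tol,
                        frechet_max_iter=self.frechet_max_iter)
        out = hgcn_layer(x1, adjacency, W2, b2, K2, K2, activation=False,
                         frechet_tol=self.frechet_tol,
                         frechet_max_iter=self.frechet_max_iter)
        return out

    def _dsq(self, coords, params, numeric: bool = False):
        return _pairwise_dsq_hyp(coords, params.K2(numeric=numeric))

    def _make_results(self, params, trace):
        return HGCNResults(model=self, params=params, loss_trace=trace)


@dataclass
class HGCNResults:
    """Fitted HGCN: learned weights, curvatures, loss trace, embedding API."""

    model: HyperbolicGCN
    params: HGCNParams
    loss_trace: np.ndarray

    @property
    def K1(self) -> float:
        return self.params.K1(numeric=True)

    @property
    def K2(self) -> float:
        return self.params.K2(numeric=True)

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def embed(self, graph: BrainGraph) -> EmbeddingResult:
        coords = self.model._forward(graph.adjacency, self.params, numeric=True)
        return EmbeddingResult(coords=np.asarray(coords), curvature=self.K2,
                               node_meta=graph.node_meta, subject_id=graph.subject_id,
                               session=graph.session, group=graph.group)

    def predict_links(self, graph: BrainGraph) -> np.ndarray:
        coords = self.model._forward(graph.adjacency, self.params, numeric=True)
        dsq = np.asarray(_pairwise_dsq_hyp(coords, self.K2))
        prob = np.asarray(fermi_dirac(dsq))
        np.fill_diagonal(prob, 0.0)
        return prob

    def summary(self) -> str:
        lines = [
            "Hyperbolic GCN results",
            "=" * 46,
            f"nodes: {self.model.n_nodes}   hidden dim: {self.model.hidden_dim}   "
            f"output dim: {self.model.dim}",
            f"curvature mode: {self.params.curvature_mode}",
            f"K1 (hidden): {self.K1:+.4f}   K2 (output): {self.K2:+.4f}",
            f"training graphs: {len(self.model.graphs)}   epochs: {len(self.loss_trace)}",
            f"initial loss: {self.loss_trace[0]:.6f}   final loss: {self.final_loss:.6f}",
        ]
        return "\n".join(lines)

    def save(self, path):
        """Binary checkpoint (.npz) with a JSON sidecar of dims/mode/seed."""
        vals = self.params.numpy_values()
        np.savez(path, W1=vals["W1"], b1=vals["b1"], W2=vals["W2"], b2=vals["b2"],
                 loss_trace=self.loss_trace,
                 curvatures=np.array([self.K1, self.K2]))
        sidecar = {
            "n_nodes": self.model.n_nodes,
            "hidden_dim": self.model.hidden_dim,
            "dim": self.model.dim,
            "curvature_mode": self.params.curvature_mode,
            "seed": self.model.seed,
            "K1": self.K1,
            "K2": self.K2,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


class EuclideanGCN(_GCNBase):
    """Flat-geometry twin of :class:`HyperbolicGCN`.

    Identical architecture with Euclidean linear layers, arithmetic-mean
    aggregation over the closed neighborhood and ReLU; the decoder uses the
    Euclidean distance.  This is the flat-curvature limit of the HGCN
    (as ``|K| -> 0`` the Fréchet mean reduces to the arithmetic mean).
    """

    def _init_params(self, rng):
        return HGCNParams.init(self.n_nodes, self.hidden_dim, self.dim,
                               "fixed", rng)

    def _forward(self, adjacency, params, numeric: bool = False):
        if adjacency.shape[0] != self.n_nodes:
            raise ValueError(
                f"graph has {adjacency.shape[0]} nodes, model expects {self.n_nodes}"
            )
        W1, b1, W2, b2 = params.W1, params.b1, params.W2, params.b2
        if numeric:
            W1, b1, W2, b2 = W1.data, b1.data, W2.data, b2.data
        agg = _closed_neighborhood_weights(adjacency)
        agg = agg / agg.sum(axis=1, keepdims=True)
        x0 = np.eye(self.n_nodes)
        h1 = _ad.matmul(x0, geometry._transpose(W1)) + b1
        y1 = _ad.matmul(agg, h1)
        x1 = relu(y1)
        h2 = _ad.matmul(x1, geometry._transpose(W2)) + b2
        out = _ad.matmul(agg, h2)
        return out

    def _dsq(self, coords, params, numeric: bool = False):
        return _pairwise_dsq_euc(coords)

    def _make_results(self, params, trace):
        return GCNResults(model=self, params=params, loss_trace=trace)


@dataclass
class GCNResults:
    model: EuclideanGCN
    params: HGCNParams
    loss_trace: np.ndarray

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def embed(self, graph: BrainGraph) -> EmbeddingResult:
        coords = self.model._forward(graph.adjacency, self.params, numeric=True)
        # Euclidean coords; curvature recorded as 0-like sentinel is not
        # meaningful, so store NaN-safe flat marker via curvature=-0.0
        return EmbeddingResult(coords=np.asarray(coords), curvature=-1e-12,
                               node_meta=graph.node_meta, subject_id=graph.subject_id,
                               session=graph.session, group=graph.group)

    def predict_links(self, graph: BrainGraph) -> np.ndarray:
        coords = self.model._forward(graph.adjacency, self.params, numeric=True)
        dsq = np.asarray(_pairwise_dsq_euc(coords))
        prob = np.asarray(fermi_dirac(dsq))
        np.fill_diagonal(prob, 0.0)
        return prob

    def summary(self) -> str:
        return (
            "Euclidean GCN results\n"
            + "=" * 46
            + f"\nnodes: {self.model.n_nodes}   hidden dim: {self.model.hidden_dim}"
            f"   output dim: {self.model.dim}"
            f"\ntraining graphs: {len(self.model.graphs)}   epochs: {len(self.loss_trace)}"
            f"\ninitial loss: {self.loss_trace[0]:.6f}   final loss: {self.final_loss:.6f}"
        )


class PoincareEmbedding:
    """Shallow Poincaré embedding of a single graph (transductive).

    Per-node free coordinates on the unit ball (K = -1) trained by
    Riemannian SGD with negative sampling: for each edge ``(i, j)`` the
    loss is the softmax cross-entropy of ``-d(i, j)`` against
    ``-d(i, k)`` over ``j`` plus ``n_negatives`` sampled nodes.  A burn-in
    phase with a reduced learning rate stabilizes the initial layout.
    """

    def __init__(self, graph: BrainGraph, dim: int = 2, epochs: int = 200,
                 lr: float = 0.5, n_negatives: int = 10, burn_in: int = 10,
                 seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.graph = graph
        self.dim = dim
        self.epochs = epochs
        self.lr = lr
        self.n_negatives = n_negatives
        self.burn_in = burn_in
        self.seed = seed

    def fit(self, train_edges: np.ndarray | None = None) -> "PoincareResults":
        """Fit; ``train_edges`` (E, 2) restricts training to an edge subset."""
        rng = np.random.default_rng(self.seed)
        R = self.graph.n_nodes
        theta = parameter(rng.uniform(-1e-3, 1e-3, size=(R, self.dim)))
        if train_edges is None:
            train_edges = np.argwhere(np.triu(self.graph.adjacency, k=1))
        edges = np.vstack([train_edges, train_edges[:, ::-1]])  # both directions
        trace = []
        for epoch in range(self.epochs):
            lr_t = self.lr / 10.0 if epoch < self.burn_in else self.lr
            # uniform negatives excluding the source node itself
            negs = rng.integers(0, R - 1, size=(edges.shape[0], self.n_negatives))
            negs = negs + (negs >= edges[:, :1])
            loss = self._loss(theta, edges, negs)
            theta.grad = None
            loss.backward()
            # Riemannian SGD on the ball: rescale by the inverse metric
            norm_sq = np.sum(theta.data ** 2, axis=1, keepdims=True)
            rgrad = theta.grad * ((1.0 - norm_sq) ** 2 / 4.0)
            theta.data = np.asarray(
                value_of(geometry.project_to_ball(theta.data - lr_t * rgrad, -1.0))
            )
            trace.append(float(loss.data))
        coords = theta.data.copy()
        emb = EmbeddingResult(coords=coords, curvature=-1.0,
                              node_meta=self.graph.node_meta,
                              subject_id=self.graph.subject_id,
                              session=self.graph.session, group=self.graph.group)
        return PoincareResults(model=self, embedding=emb,
                               loss_trace=np.asarray(trace),
                               train_edges=train_edges)

    def _loss(self, theta, edges, negs):
        R = self.graph.n_nodes
        D = (_pairwise_dsq_hyp(theta, -1.0) + 1e-12) ** 0.5
        ei, ej = edges[:, 0], edges[:, 1]
        d_pos = _ad.take2d(D, ei, ej)
        rows = np.repeat(ei, negs.shape[1])
        d_neg = reshape(_ad.take2d(D, rows, negs.ravel()), negs.shape)
        # stable log-sum-exp over {j} ∪ negatives with a detached max shift
        m = np.maximum(np.max(-d_neg.data, axis=1), -d_pos.data)
        lse = _ad.log(
            _ad.exp(-d_pos - m) + _ad.asum(_ad.exp(-d_neg - reshape(m, (-1, 1))), axis=1)
        ) + m
        return _ad.asum(d_pos + lse) / edges.shape[0]


@dataclass
class PoincareResults:
    model: PoincareEmbedding
    embedding: EmbeddingResult
    loss_trace: np.ndarray
    train_edges: np.ndarray

    def predict_links(self) -> np.ndarray:
        dsq = np.asarray(_pairwise_dsq_hyp(self.embedding.coords, -1.0))
        prob = np.asarray(fermi_dirac(dsq))
        np.fill_diagonal(prob, 0.0)
        return prob

    def summary(self) -> str:
        return (
            "Shallow Poincaré embedding\n" + "=" * 46 +
            f"\nnodes: {self.embedding.n_nodes}   dim: {self.embedding.dim}" +
            f"\nepochs: {len(self.loss_trace)}   final loss: {self.loss_trace[-1]:.6f}"
        )
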