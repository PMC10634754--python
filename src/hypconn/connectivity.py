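"""PLV functional connectivity and construction of brain graphs.

A connectivity matrix is a symmetric ``R x R`` array of phase-locking
values in ``[0, 1]`` (``R = 90`` AAL regions by default, diagonal ignored).
A :class:`BrainGraph` couples the binarized adjacency used by the graph
network with the min-max-scaled edge probabilities used as regression
targets, plus per-node metadata (region name, hemisphere, subnetwork).

The phase-locking value between regions A and B averages, over all source
pairs ``(p, q)`` drawn from the two regions, the magnitude of the
time-averaged unit phasor of the instantaneous phase difference:

    PLV_AB = (1 / N_A N_B) sum_p sum_q | (1/T) sum_t e^{-i (phi_Ap(t) - phi_Bq(t))} |

Epochs are handled by computing the per-epoch PLV and averaging the
magnitudes across epochs (pass ``pool_epochs=True`` to concatenate epochs
into one window instead).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SUBNETWORKS",
    "SourcePhases",
    "BrainGraph",
    "compute_plv",
    "roi_plv_matrix",
    "binarize",
    "scale_probabilities",
    "load_subnetwork_map",
    "default_subnetwork_map",
    "build_graph",
    "validate_connectivity",
    "load_connectivity",
    "PLV_THRESHOLD",
]

#: The eight resting-state subnetworks used for hierarchy analysis.
SUBNETWORKS = ("pDMN", "aDMN", "DAN", "FPN", "VN", "VAN", "SN", "SMN")

#: Default PLV binarization threshold (retains roughly 20% of edges on
#: alpha-band resting-state cohorts).
PLV_THRESHOLD = 0.329


@dataclass
class SourcePhases:
    """Epoched instantaneous phases for every source of every region.

    ``phases[r]`` is an array of shape ``(n_sources_r, n_epochs, T)`` in
    radians; regions may have different source counts but must share
    ``n_epochs`` and ``T``.
    """

    phases: list
    region_names: list | None = None

    def __post_init__(self):
        self.phases = [np.asarray(p, dtype=np.float64) for p in self.phases]
        if not self.phases:
            raise ValueError("SourcePhases needs at least one region")
        shapes = {p.shape[1:] for p in self.phases}
        if len(shapes) != 1:
            raise ValueError(f"regions disagree on (n_epochs, T): {sorted(shapes)}")
        (self.n_epochs, self.T) = self.phases[0].shape[1:]
        if self.T < 2:
            raise ValueError("need at least 2 samples per epoch")
        for r, p in enumerate(self.phases):
            if p.ndim != 3:
                raise ValueError(f"region {r}: phases must be (sources, epochs, T)")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"region {r}: non-finite phases")

    @property
    def n_regions(self) -> int:
        return len(self.phases)


def compute_plv(phases: SourcePhases, region_a: int, region_b: int,
                pool_epochs: bool = False) -> float:
    """ROI-averaged phase-locking value between two regions."""
    za = np.exp(-1j * phases.phases[region_a])  # (Sa, E, T)
    zb = np.exp(-1j * phases.phases[region_b])
    if pool_epochs:
        za = za.reshape(za.shape[0], 1, -1)
        zb = zb.reshape(zb.shape[0], 1, -1)
    # cross[p, q, e] = (1/T) sum_t za[p,e,t] * conj(zb[q,e,t])
    cross = np.einsum("pet,qet->pqe", za, np.conj(zb)) / za.shape[-1]
    return float(np.mean(np.abs(cross)))


def roi_plv_matrix(phases: SourcePhases, pool_epochs: bool = False) -> np.ndarray:
    """Symmetric PLV matrix over all region pairs (diagonal set to 0)."""
    R = phases.n_regions
    if R < 2:
        raise ValueError("need at least 2 regions")
    plv = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            plv[i, j] = plv[j, i] = compute_plv(phases, i, j, pool_epochs=pool_epochs)
    return plv


def validate_connectivity(plv: np.ndarray) -> np.ndarray:
    plv = np.asarray(plv, dtype=np.float64)
    if plv.ndim != 2 or plv.shape[0] != plv.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {plv.shape}")
    if not np.allclose(plv, plv.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    off = plv[~np.eye(plv.shape[0], dtype=bool)]
    if off.size and (off.min() < 0 or off.max() > 1):
        raise ValueError("PLV values must lie in [0, 1]")
    return plv


def _offdiag_mask(R: int) -> np.ndarray:
    return ~np.eye(R, dtype=bool)


def binarize(plv: np.ndarray, threshold: float | None = None,
             target_density: float | None = None) -> np.ndarray:
    """Binary adjacency from a PLV matrix.

    Exactly one of ``threshold`` / ``target_density`` must be given.  In
    threshold mode an edge is kept iff ``plv > threshold`` (strict, so ties
    at the threshold are dropped).  In density mode the empirical
    ``1 - density`` quantile is realized by count: exactly
    ``round(density * n_pairs)`` of the off-diagonal upper-triangle values
    are kept (deterministic for distinct values).
    """
    plv = validate_connectivity(plv)
    if (threshold is None) == (target_density is None):
        raise ValueError("give exactly one of threshold / target_density")
    if target_density is not None:
        if not 0 < target_density < 1:
            raise ValueError(f"target_density must be in (0, 1), got {target_density}")
        iu = np.triu_indices_from(plv, k=1)
        vals = np.sort(plv[iu])
        k = int(round(target_density * vals.size))
        threshold = -np.inf if k >= vals.size else float(vals[vals.size - k - 1])
    adj = (plv > threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def scale_probabilities(plv, scope: str = "per_graph"):
    """Min-max scale PLV values to edge probabilities in [0, 1].

    ``scope="per_graph"`` scales a single matrix by its own off-diagonal
    min/max.  ``scope="global"`` accepts a list of matrices and scales all
    of them by the pooled min/max.  Diagonals stay zero.
    """
    if scope == "per_graph":
        mats = [validate_connectivity(plv)]
    elif scope == "global":
        mats = [validate_connectivity(m) for m in plv]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    offs = np.concatenate([m[_offdiag_mask(m.shape[0])] for m in mats])
    lo, hi = offs.min(), offs.max()
    if hi - lo <= 0:
        raise ValueError("cannot min-max scale a constant connectivity matrix")
    out = []
    for m in mats:
        s = (m - lo) / (hi - lo)
        np.fill_diagonal(s, 0.0)
        out.append(np.clip(s, 0.0, 1.0))
    return out[0] if scope == "per_graph" else out


def default_subnetwork_map() -> pd.DataFrame:
    """The shipped approximate AAL-90 to subnetwork assignment.

    The assignment is a literature-based approximation by spatial proximity
    of AAL regions to canonical functional subnetworks, and is meant to be
    replaced with a study-specific table via :func:`load_subnetwork_map`.
    """
    with resources.files("hypconn.data").joinpath("aal90_subnetworks.csv").open() as fh:
        return _validate_subnetwork_table(pd.read_csv(fh))


def load_subnetwork_map(path=None) -> pd.DataFrame:
    """Load and validate an ROI -> subnetwork table.

    CSV columns: ``roi_name, hemisphere, subnetwork``.  Every ROI must
    appear exactly once and each subnetwork label must be one of
    :data:`SUBNETWORKS`.
    """
    if path is None:
        return default_subnetwork_map()
    return _validate_subnetwork_table(pd.read_csv(path))


def _validate_subnetwork_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"roi_name", "hemisphere", "subnetwork"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subnetwork table missing columns: {sorted(missing)}")
    dup = df["roi_name"][df["roi_name"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate ROIs in subnetwork table: {dup}")
    bad = sorted(set(df["subnetwork"]) - set(SUBNETWORKS))
    if bad:
        raise ValueError(f"unknown subnetwork labels: {bad} (expected {list(SUBNETWORKS)})")
    return df.reset_index(drop=True)


@dataclass
class BrainGraph:
    """One participant/session network: adjacency, edge probabilities, metadata."""

    adjacency: np.ndarray
    edge_prob: np.ndarray
    node_meta: pd.DataFrame
    subject_id: str | None = None
    session: str = "pre"
    group: str | None = None
    age: float | None = None
    plv: np.ndarray | None = None
    connected: bool | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        self.edge_prob = np.asarray(self.edge_prob, dtype=np.float64)
        R = self.adjacency.shape[0]
        if self.adjacency.shape != (R, R) or self.edge_prob.shape != (R, R):
            raise ValueError("adjacency and edge_prob must be square and same shape")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if len(self.node_meta) != R:
            raise ValueError(
                f"node_meta has {len(self.node_meta)} rows for {R} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def density(self) -> float:
        R = self.n_nodes
        return float(self.adjacency.sum() / (R * (R - 1)))

    def save_npz(self, path):
        """Serialize arrays plus JSON-encoded metadata to one ``.npz``."""
        meta = {
            "subject_id": self.subject_id,
            "session": self.session,
            "group": self.group,
            "age": self.age,
            "connected": self.connected,
            "node_meta": self.node_meta.to_dict(orient="list"),
        }
        arrays = dict(adjacency=self.adjacency, edge_prob=self.edge_prob,
                      meta=np.bytes_(json.dumps(meta).encode()))
        if self.plv is not None:
            arrays["plv"] = self.plv
        np.savez(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "BrainGraph":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return cls(
                adjacency=z["adjacency"],
                edge_prob=z["edge_prob"],
                node_meta=pd.DataFrame(meta["node_meta"]),
                subject_id=meta["subject_id"],
                session=meta["session"],
                group=meta["group"],
                age=meta["age"],
                plv=z["plv"] if "plv" in z.files else None,
                connected=meta["connected"],
            )


def build_graph(plv: np.ndarray, node_meta: pd.DataFrame | None = None,
                threshold: float | None = PLV_THRESHOLD,
                target_density: float | None = None,
                subject_id: str | None = None, session: str = "pre",
                group: str | None = None, age: float | None = None) -> BrainGraph:
    """Build a :class:`BrainGraph` from a PLV connectivity matrix."""
    plv = validate_connectivity(plv)
    if target_density is not None:
        threshold = None
    adj = binarize(plv, threshold=threshold, target_density=target_density)
    prob = scale_probabilities(plv, scope="per_graph")
    if node_meta is None:
        if plv.shape[0] == 90:
            node_meta = default_subnetwork_map()
        else:
            node_meta = synthetic_node_meta(plv.shape[0])
    return BrainGraph(adjacency=adj, edge_prob=prob, node_meta=node_meta,
                      subject_id=subject_id, session=session, group=group,
                      age=age, plv=plv)


def synthetic_node_meta(R: int) -> pd.DataFrame:
    """Round-robin subnetwork labels for non-AAL node counts (synthetic use)."""
    return pd.DataFrame({
        "roi_name": [f"node_{i:03d}" for i in range(R)],
        "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(R)],
        "subnetwork": [SUBNETWORKS[i % len(SUBNETWORKS)] for i in range(R)],
    })


def load_connectivity(path) -> np.ndarray:
    """Read a connectivity matrix from delimited text (CSV) or ``.npy``."""
    path = Path(path)
    if path.suffix == ".npy":
        return validate_connectivity(np.load(path))
    df = pd.read_csv(path, index_col=0)
    return validate_connectivity(df.to_numpy(dtype=np.float64))
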