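"""Numerically safe Poincaré-ball operations at arbitrary negative curvature.

The ball of curvature ``K < 0`` is the open set ``{x : |K| ||x||^2 < 1}``
with radius ``1/sqrt(|K|)``.  All operations here accept points as arrays
whose last axis is the coordinate dimension (a single vector or a batch of
row vectors) and accept either plain ndarrays or autodiff
:class:`~hypconn._ad.Tensor` objects, so the same code serves inference and
training.  Curvature may likewise be a python float or a Tensor (for
learnable curvature).

Conventions
-----------
* Only the exponential/logarithmic maps at the origin are part of the
  public surface; every network operation is defined through the tangent
  space at the origin.  The Fréchet-mean solver uses base-point maps
  internally.
* Points are clamped to radius ``(1 - eps)/sqrt(|K|)`` with ``eps = 1e-5``;
  ``artanh``/``arccosh`` arguments are clamped to their open domains.
"""

from __future__ import annotations

import numpy as np

from . import _ad
from ._ad import asum, clip, exp, is_tensor, log, relu, reshape, sqrt, take_rows, tanh, value_of

__all__ = [
    "BOUNDARY_EPS",
    "FrechetConvergenceError",
    "ball_radius",
    "check_in_ball",
    "project_to_ball",
    "hyp_distance",
    "exp_map0",
    "log_map0",
    "mobius_add",
    "mobius_matvec",
    "hyp_activation",
    "frechet_mean",
    "frechet_mean_batch",
]

BOUNDARY_EPS = 1e-5
_TINY = 1e-30
_DOMAIN_EPS = 1e-15


class FrechetConvergenceError(RuntimeError):
    """Fréchet-mean solver failed to converge; carries the last objective."""

    def __init__(self, message, last_objective):
        super().__init__(message)
        self.last_objective = last_objective


def _abs_curv(K):
    """|K| for float or Tensor curvature; validates negativity for floats."""
    if is_tensor(K):
        return -K
    K = float(K)
    if not K < 0:
        raise ValueError(f"curvature must be strictly negative, got {K}")
    return -K


def ball_radius(K) -> float:
    """Euclidean radius ``1/sqrt(|K|)`` of the Poincaré ball."""
    return 1.0 / np.sqrt(float(value_of(_abs_curv(K))))


def _sqnorm(x):
    return asum(x * x, axis=-1, keepdims=True)


def _safe_norm(x):
    """Euclidean norm along the last axis, kept differentiable at 0."""
    return sqrt(_sqnorm(x) + _TINY)


def _artanh(x):
    x = clip(x, -1.0 + _DOMAIN_EPS, 1.0 - _DOMAIN_EPS)
    return 0.5 * (log(1.0 + x) - log(1.0 - x))


def _arccosh(x):
    x = _ad.maximum_scalar(x, 1.0)
    return log(x + sqrt(x * x - 1.0 + _TINY))


def check_in_ball(x, K, name: str = "point") -> None:
    """Raise ``ValueError`` if any point lies on/outside the ball boundary."""
    norms = np.sqrt(np.sum(value_of(x) ** 2, axis=-1))
    R = ball_radius(K)
    worst = float(np.max(norms)) if norms.size else 0.0
    if worst >= R:
        raise ValueError(
            f"{name} lies on or outside the Poincaré ball: "
            f"norm {worst:.6g} >= ball radius {R:.6g}"
        )


def project_to_ball(x, K, eps: float = BOUNDARY_EPS):
    """Clamp points to radius ``(1 - eps)/sqrt(|K|)``; interior points pass through."""
    c = _abs_curv(K)
    max_norm = (1.0 - eps) / sqrt(c)
    n = _safe_norm(x)
    # factor = min(1, max_norm / n), written with a 0-subgradient kink
    scale = 1.0 / _ad.maximum_scalar(n / max_norm, 1.0)
    return x * scale


def hyp_distance(u, v, K, validate: bool = False):
    """Geodesic distance on the ball of curvature K.

    ``d_K(u, v) = arccosh(1 + 2|K| ||u-v||^2 / ((1-|K|||u||^2)(1-|K|||v||^2))) / sqrt(|K|)``

    Broadcasts over leading axes; returns shape ``broadcast(u, v).shape[:-1]``.
    """
    if validate:
        check_in_ball(u, K, "u")
        check_in_ball(v, K, "v")
    c = _abs_curv(K)
    diff = u - v
    num = 2.0 * c * _sqnorm(diff)
    den = (1.0 - c * _sqnorm(u)) * (1.0 - c * _sqnorm(v))
    den = _ad.maximum_scalar(den, _DOMAIN_EPS)
    arg = 1.0 + num / den
    d = _arccosh(arg) / sqrt(c)
    return reshape(d, value_of(d).shape[:-1])


def exp_map0(v, K):
    """Exponential map at the origin: tangent vector -> ball point."""
    if not np.all(np.isfinite(value_of(v))):
        raise ValueError("exp_map0: non-finite tangent vector")
    c = _abs_curv(K)
    sc = sqrt(c)
    n = _safe_norm(v)
    coef = tanh(sc * n) / (sc * n)
    return project_to_ball(coef * v, K)


def log_map0(x, K, validate: bool = False):
    """Logarithmic map at the origin: ball point -> tangent vector."""
    if validate:
        check_in_ball(x, K, "x")
    c = _abs_curv(K)
    sc = sqrt(c)
    n = _safe_norm(x)
    coef = _artanh(sc * n) / (sc * n)
    return coef * x


def mobius_add(u, v, K, project: bool = True):
    """Möbius (gyrovector) addition ``u ⊕_K v``."""
    c = _abs_curv(K)
    uv = asum(u * v, axis=-1, keepdims=True)
    nu = _sqnorm(u)
    nv = _sqnorm(v)
    num = (1.0 + 2.0 * c * uv + c * nv) * u + (1.0 - c * nu) * v
    den = 1.0 + 2.0 * c * uv + (c * nu) * (c * nv)
    den = _ad.maximum_scalar(den, _DOMAIN_EPS)
    out = num / den
    return project_to_ball(out, K) if project else out


def mobius_matvec(W, x, K):
    """Möbius matrix-vector multiplication ``W ⊗_K x``.

    Equals ``exp_map0(W · log_map0(x))`` via the norm-rescaled closed form.
    ``x`` may be a single vector or rows of vectors; ``W`` has shape
    ``(d_out, d_in)``.  ``W x = 0`` (or ``x = 0``) maps to the origin.
    """
    Wv = value_of(W)
    xv = value_of(x)
    if Wv.shape[-1] != xv.shape[-1]:
        raise ValueError(
            f"mobius_matvec: W has {Wv.shape[-1]} columns but x has dimension {xv.shape[-1]}"
        )
    c = _abs_curv(K)
    sc = sqrt(c)
    Wx = _ad.matmul(x, _transpose(W))
    nx = _safe_norm(x)
    nWx = _safe_norm(Wx)
    coef = tanh((nWx / nx) * _artanh(sc * nx)) / (sc * nWx)
    return project_to_ball(coef * Wx, K)


def _transpose(W):
    if not is_tensor(W):
        return np.asarray(W).T
    out = _ad.Tensor._make(W.data.T, (W,), None)
    if out.requires_grad:
        out._backward = lambda g: W._accum(np.asarray(g).T)
    return out


def hyp_activation(x, K_in, K_out, sigma=relu):
    """Apply a Euclidean activation through the tangent space at the origin.

    ``exp_map0^{K_out}(sigma(log_map0^{K_in}(x)))``
    """
    return exp_map0(sigma(log_map0(x, K_in)), K_out)


# ---------------------------------------------------------------------------
# Fréchet (Karcher) mean
# ---------------------------------------------------------------------------

def _lambda_factor(x, c):
    """Conformal factor λ_x = 2 / (1 - |K| ||x||²)."""
    return 2.0 / _ad.maximum_scalar(1.0 - c * _sqnorm(x), _DOMAIN_EPS)


def _log_map(base, x, K):
    """log_base(x) for arbitrary base point (internal to the solver)."""
    c = _abs_curv(K)
    sc = sqrt(c)
    a = mobius_add(-base, x, K, project=False)
    na = _safe_norm(a)
    lam = _lambda_factor(base, c)
    return (2.0 / (sc * lam)) * _artanh(sc * na) * (a / na)


def _exp_map(base, v, K):
    """exp_base(v) for arbitrary base point (internal to the solver)."""
    c = _abs_curv(K)
    sc = sqrt(c)
    nv = _safe_norm(v)
    lam = _lambda_factor(base, c)
    second = tanh(sc * lam * nv / 2.0) * (v / (sc * nv))
    return mobius_add(base, second, K)


def _frechet_objective(m, points, weights, K):
    """Weighted sum of squared geodesic distances (plain numpy)."""
    d = hyp_distance(value_of(m)[..., None, :], value_of(points), K=float(value_of(_abs_curv(K)) * -1.0))
    d = np.asarray(d)
    return np.sum(weights * d * d, axis=-1), d


def _lorentz_centroid(points: np.ndarray, Wn: np.ndarray, c: float) -> np.ndarray:
    """Weighted Lorentzian centroid mapped back to the ball (detached init).

    Lift ball points to the hyperboloid of curvature -c, take the weighted
    Minkowski mean, renormalize onto the hyperboloid, and project back.
    An excellent starting point for the Karcher iteration.
    """
    sc = np.sqrt(c)
    r2 = np.sum(points**2, axis=-1, keepdims=True)
    denom = np.maximum(1.0 - c * r2, _DOMAIN_EPS)
    X0 = (1.0 + c * r2) / denom / sc  # (N, 1)
    Xi = 2.0 * points / denom / sc  # (N, d)
    s0 = Wn @ X0  # (B, 1)
    si = Wn @ Xi  # (B, d)
    nu = np.maximum(s0[:, 0] ** 2 - np.sum(si**2, axis=1), _DOMAIN_EPS)  # -<s,s>_L
    scale = 1.0 / (sc * np.sqrt(nu))
    mu0 = s0[:, 0] * scale
    mui = si * scale[:, None]
    ball = mui / (mu0[:, None] + 1.0 / sc)
    return np.asarray(value_of(project_to_ball(ball, -c)))


def frechet_mean_batch(points, weight_matrix, K, tol: float = 1e-8, max_iter: int = 1000,
                       init: str = "lorentz", on_max_iter: str = "raise"):
    """Weighted Fréchet means of one point set under many weightings.

    Parameters
    ----------
    points : (N, d) array or Tensor
        Candidate points on the ball of curvature ``K``.
    weight_matrix : (B, N) ndarray
        Non-negative weights; row ``b`` defines the b-th mean.  Each row must
        have positive sum.
    K : float or Tensor
        Negative curvature.
    tol, max_iter
        Convergence tolerance on the change of the objective, and iteration
        cap of the Karcher fixed-point solver.

    Returns
    -------
    (B, d) array or Tensor of minimizers of ``sum_j w_bj d_K(m, x_j)^2``.

    Notes
    -----
    Damped Karcher fixed-point iteration: map the point set to the tangent
    space at the current iterate, take the weighted Euclidean mean scaled by
    a Hessian-bound step, and map back; backtracking keeps the objective
    non-increasing.  ``init`` selects the warm start: ``"lorentz"`` (default,
    detached weighted Lorentzian centroid) or ``"largest_weight"`` (the
    input point of largest weight, first index on ties).  Both are
    deterministic; gradients flow through the unrolled iterations.
    ``on_max_iter="return"`` yields the (monotone-improved) last iterate
    instead of raising — used by the network layers, where a truncated
    solve is an acceptable aggregation.
    """
    W = np.asarray(value_of(weight_matrix), dtype=np.float64)
    if W.ndim != 2 or W.shape[1] != value_of(points).shape[0]:
        raise ValueError("weight_matrix must be (B, N) matching points (N, d)")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    rowsum = W.sum(axis=1)
    if W.shape[1] == 0 or np.any(rowsum <= 0):
        raise ValueError("each weight row needs at least one positive weight")

    Wn = W / rowsum[:, None]
    c = float(value_of(_abs_curv(K)))
    Kf = -c
    if init == "largest_weight":
        m = take_rows(points, np.argmax(W, axis=1))  # (B, d)
    else:  # detached Lorentz-centroid warm start (default: much faster)
        m = _ad.constant(_lorentz_centroid(value_of(points), Wn, c)) \
            if _ad.is_tensor(points) or _ad.is_tensor(K) \
            else _lorentz_centroid(value_of(points), Wn, c)

    npW = Wn[:, :, None]  # (B, N, 1) for broadcasting
    prev, dists = _frechet_objective(m, points, Wn, Kf)
    prev = np.atleast_1d(prev)
    B, d = W.shape[0], value_of(points).shape[1]
    sc = np.sqrt(c)
    for _ in range(max_iter):
        base = reshape(m, (B, 1, d))
        logs = _log_map(base, points, K)  # (B, N, d)
        t = asum(npW * logs, axis=1)  # (B, d) tangent step = -grad F / 2
        # step size from the Hessian bound: eigenvalues of Hess(d^2/2) lie in
        # [1, z coth z] with z = sqrt(c) d, so a per-row step 1/E[z coth z]
        # is safe; backtracking (detached) guards the remaining cases
        z = sc * np.atleast_2d(dists)
        zcoth = np.where(z > 1e-8, z / np.tanh(np.maximum(z, 1e-8)), 1.0)
        L = np.maximum((Wn * zcoth).sum(axis=1), 1.0)[:, None]  # (B, 1)
        t_np, m_np, p_np = value_of(t), value_of(m), value_of(points)
        step = 1.0 / L
        for _ in range(40):
            cand = value_of(_exp_map(m_np, step * t_np, Kf))
            obj = np.atleast_1d(_frechet_objective(cand, p_np, Wn, Kf)[0])
            worse = obj > prev + 1e-15
            if not worse.any():
                break
            step[worse] *= 0.5
        m = _exp_map(m, step * t, K)  # mobius_add inside already projects
        cur, dists = _frechet_objective(m, points, Wn, Kf)
        cur = np.atleast_1d(cur)
        if np.all(np.abs(prev - cur) < tol):
            return m
        prev = cur
    if on_max_iter == "return":
        return m
    raise FrechetConvergenceError(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(last objective max {float(np.max(prev)):.6g})",
        last_objective=prev,
    )


def frechet_mean(points, weights=None, K=-1.0, tol: float = 1e-8, max_iter: int = 1000):
    """Weighted Fréchet mean of a point set on the ball of curvature ``K``.

    Minimizes the weighted sum of *squared* geodesic distances (the
    differentiable Karcher mean).  ``weights`` defaults to uniform.
    """
    pts = value_of(points)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("frechet_mean requires a non-empty (N, d) point set")
    if weights is None:
        weights = np.ones(pts.shape[0])
    out = frechet_mean_batch(points, np.asarray(weights, dtype=np.float64)[None, :], K,
                             tol=tol, max_iter=max_iter)
    return reshape(out, (pts.shape[1],))
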