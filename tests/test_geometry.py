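"""Poincaré-ball operations: closed forms, metric axioms, Fréchet mean."""

import numpy as np
import pytest

from hypconn import geometry as geo
from hypconn._ad import value_of

from conftest import random_ball_points


class TestDistance:
    def test_identity_of_indiscernibles(self, rng):
        p = random_ball_points(rng, 20, 3)
        assert np.allclose(geo.hyp_distance(p, p, -1.0), 0.0)

    @pytest.mark.parametrize(
        "v,K,expected",
        [
            # d(0, v) = (2/sqrt(c)) artanh(sqrt(c)||v||)
            ((0.5, 0.0), -1.0, np.log(3.0)),
            ((0.25, 0.0), -4.0, np.arccosh(5.0 / 3.0) / 2.0),
        ],
    )
    def test_closed_form_from_origin(self, v, K, expected):
        d = geo.hyp_distance(np.zeros(2), np.array(v), K)
        assert np.isclose(float(d), expected, atol=1e-12)
        closed = 2.0 / np.sqrt(-K) * np.arctanh(np.sqrt(-K) * np.linalg.norm(v))
        assert np.isclose(float(d), closed, atol=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        for K in (-0.5, -1.0, -2.0):
            u = random_ball_points(rng, 1000, 3, K)
            v = random_ball_points(rng, 1000, 3, K)
            w = random_ball_points(rng, 1000, 3, K)
            duv = np.asarray(geo.hyp_distance(u, v, K))
            dvu = np.asarray(geo.hyp_distance(v, u, K))
            duw = np.asarray(geo.hyp_distance(u, w, K))
            dvw = np.asarray(geo.hyp_distance(v, w, K))
            assert np.allclose(duv, dvu, atol=1e-12)
            assert np.all(duw <= duv + dvw + 1e-9)
            assert np.all(duv >= 0)

    def test_flat_limit_recovers_scaled_euclidean(self, rng):
        # for |K| -> 0, d_K(u, v) -> 2||u - v|| (the GCN-as-flat-HGCN limit)
        K = -1e-6
        u = rng.normal(size=(50, 3)) * 3.0  # norms up to ~10 well inside ball
        v = rng.normal(size=(50, 3)) * 3.0
        d = np.asarray(geo.hyp_distance(u, v, K))
        d_euc = 2.0 * np.linalg.norm(u - v, axis=-1)
        assert np.allclose(d, d_euc, rtol=1e-3)

    def test_boundary_point_raises(self):
        with pytest.raises(ValueError, match="norm"):
            geo.hyp_distance(np.array([1.0, 0.0]), np.zeros(2), -1.0, validate=True)

    def test_positive_curvature_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            geo.hyp_distance(np.zeros(2), np.zeros(2), 1.0)


class TestExpLogMaps:
    def test_exp_of_zero_is_origin(self):
        assert np.allclose(value_of(geo.exp_map0(np.zeros(3), -1.0)), 0.0)

    def test_round_trip_inverse(self, rng):
        for K in (-0.5, -1.0, -2.0):
            v = rng.normal(size=(100, 3))
            v *= rng.uniform(0, 2, size=(100, 1)) / np.linalg.norm(v, axis=1, keepdims=True)
            back = value_of(geo.log_map0(geo.exp_map0(v, K), K))
            assert np.allclose(back, v, atol=1e-6)

    def test_exp_map_stays_in_ball(self):
        x = value_of(geo.exp_map0(np.array([10.0, 0.0]), -1.0))
        assert np.linalg.norm(x) < 1.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            geo.exp_map0(np.array([np.nan, 0.0]), -1.0)


class TestMobius:
    def test_identity_and_inverse_elements(self, rng):
        u = random_ball_points(rng, 10, 3)
        zero = np.zeros(3)
        assert np.allclose(value_of(geo.mobius_add(u, zero, -1.0)), u, atol=1e-12)
        assert np.allclose(value_of(geo.mobius_add(u, -u, -1.0)), 0.0, atol=1e-12)

    def test_collinear_addition_matches_1d_formula(self):
        u = np.array([0.3, 0.0])
        out = value_of(geo.mobius_add(u, u, -1.0))
        assert np.allclose(out, [0.6 / 1.09, 0.0], atol=1e-12)

    def test_matvec_identity(self, rng):
        x = random_ball_points(rng, 10, 4)
        out = value_of(geo.mobius_matvec(np.eye(4), x, -1.0))
        assert np.allclose(out, x, atol=1e-6)

    def test_matvec_origin_maps_to_origin(self, rng):
        W = rng.normal(size=(3, 4))
        out = value_of(geo.mobius_matvec(W, np.zeros(4), -1.0))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_matvec_radial_scaling_law(self):
        # W = 2I acts radially: new norm = tanh(2 artanh(r))
        x = np.array([0.3, 0.0])
        out = value_of(geo.mobius_matvec(2.0 * np.eye(2), x, -1.0))
        assert np.isclose(np.linalg.norm(out), np.tanh(2 * np.arctanh(0.3)), atol=1e-12)

    def test_matvec_dimension_mismatch(self):
        with pytest.raises(ValueError, match="columns"):
            geo.mobius_matvec(np.eye(3), np.zeros(4), -1.0)

    def test_matvec_equals_exp_log_sandwich(self, rng):
        W = rng.normal(size=(3, 3))
        x = random_ball_points(rng, 5, 3, max_rel=0.8)
        direct = value_of(geo.mobius_matvec(W, x, -1.0))
        sandwich = value_of(geo.exp_map0(value_of(geo.log_map0(x, -1.0)) @ W.T, -1.0))
        assert np.allclose(direct, sandwich, atol=1e-8)


class TestProjection:
    def test_interior_point_unchanged(self):
        x = np.array([0.3, 0.4])
        assert np.allclose(value_of(geo.project_to_ball(x, -1.0)), x)

    def test_exterior_point_clamped(self):
        x = np.array([3.0, 4.0])
        out = value_of(geo.project_to_ball(x, -1.0, eps=1e-5))
        assert np.isclose(np.linalg.norm(out), 1 - 1e-5)
        assert np.allclose(out / np.linalg.norm(out), x / 5.0)

    def test_origin_unchanged(self):
        assert np.allclose(value_of(geo.project_to_ball(np.zeros(3), -1.0)), 0.0)


class TestActivation:
    def test_identity_sigma_same_curvature_is_identity(self, rng):
        x = random_ball_points(rng, 10, 3)
        out = value_of(geo.hyp_activation(x, -1.0, -1.0, lambda t: t))
        assert np.allclose(out, x, atol=1e-6)

    def test_origin_fixed_under_relu(self):
        out = value_of(geo.hyp_activation(np.zeros(3), -1.0, -2.0))
        assert np.allclose(out, 0.0)

    def test_all_negative_tangent_collapses_to_origin(self):
        x = value_of(geo.exp_map0(np.array([-0.5, -0.2, -0.9]), -1.0))
        out = value_of(geo.hyp_activation(x, -1.0, -1.0))
        assert np.allclose(out, 0.0, atol=1e-12)


def _frechet_oracle(points, weights, K, steps=10000, lr=1e-3):
    """Independent Riemannian gradient-descent minimizer of the weighted
    sum of squared geodesic distances (brute force, numpy only)."""
    c = -K
    m = np.average(points, axis=0, weights=weights)  # Euclidean init
    nrm = np.linalg.norm(m)
    cap = 0.99 / np.sqrt(c)
    if nrm > cap:
        m = m / nrm * cap
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    sc = np.sqrt(c)
    prev = None
    for _ in range(steps):
        # Riemannian grad of sum w d^2: -2 sum w log_m(x)
        lam = 2.0 / (1.0 - c * np.sum(m * m))
        a = _mobius_rows_np(-m, points, c)
        na = np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-15)
        logs = (2.0 / (sc * lam)) * np.arctanh(np.minimum(sc * na, 1 - 1e-15)) * a / na
        grad = -2.0 * np.sum(w[:, None] * logs, axis=0)
        m_new = _exp_np(m, -lr * grad, c)
        obj = _objective_np(m_new, points, w, c)
        if prev is not None and abs(prev - obj) < 1e-14:
            m = m_new
            break
        prev = obj
        m = m_new
    return m


def _mobius_rows_np(u, V, c):
    """Möbius addition of one point u with every row of V (numpy)."""
    uv = V @ u
    nu = np.sum(u * u)
    nv = np.sum(V * V, axis=1)
    num = (1 + 2 * c * uv + c * nv)[:, None] * u[None, :] + (1 - c * nu) * V
    den = 1 + 2 * c * uv + c * c * nu * nv
    return num / den[:, None]


def _mobius_np(u, v, c):
    return _mobius_rows_np(u, v[None, :], c)[0]


def _exp_np(base, t, c):
    nt = np.linalg.norm(t)
    if nt < 1e-15:
        return base
    lam = 2.0 / (1.0 - c * np.sum(base * base))
    second = np.tanh(np.sqrt(c) * lam * nt / 2.0) * t / (np.sqrt(c) * nt)
    out = _mobius_np(base, second, c)
    n = np.linalg.norm(out)
    cap = (1 - 1e-7) / np.sqrt(c)
    return out if n < cap else out / n * cap


def _objective_np(m, points, w, c):
    d = np.asarray(geo.hyp_distance(m[None, :], points, -c))
    return float(np.sum(w * d * d))


class TestFrechetMean:
    def test_single_point_returns_that_point(self):
        p = np.array([[0.2, -0.4]])
        out = value_of(geo.frechet_mean(p, K=-1.0))
        assert np.allclose(out, p[0], atol=1e-8)

    def test_antipodal_pair_averages_to_origin(self):
        p = np.array([[0.4, 0.1], [-0.4, -0.1]])
        out = value_of(geo.frechet_mean(p, K=-1.0))
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            geo.frechet_mean(np.zeros((0, 2)))

    def test_matches_gradient_descent_oracle(self, rng):
        for K in (-0.5, -1.0, -2.0):
            for _ in range(5):
                n = int(rng.integers(5, 11))
                pts = random_ball_points(rng, n, 2, K, max_rel=0.85)
                w = rng.uniform(0.2, 1.0, size=n)
                ours = value_of(geo.frechet_mean(pts, w, K))
                oracle = _frechet_oracle(pts, w, K)
                gap = float(geo.hyp_distance(ours, oracle, K))
                assert gap < 1e-4

    def test_objective_not_above_any_input_point(self, rng):
        pts = random_ball_points(rng, 8, 3, max_rel=0.9)
        w = np.ones(8)
        m = value_of(geo.frechet_mean(pts, w, -1.0))
        obj_m = _objective_np(m, pts, w / w.sum(), 1.0)
        for p in pts:
            assert obj_m <= _objective_np(p, pts, w / w.sum(), 1.0) + 1e-10

    def test_flat_limit_equals_arithmetic_mean(self, rng):
        pts = rng.normal(size=(6, 3)) * 0.3
        m = value_of(geo.frechet_mean(pts, K=-1e-6))
        assert np.allclose(m, pts.mean(axis=0), atol=1e-3)

    def test_largest_weight_init_agrees_with_default(self, rng):
        pts = random_ball_points(rng, 7, 2, max_rel=0.7)
        w = rng.uniform(0.1, 1.0, size=(1, 7))
        a = value_of(geo.frechet_mean_batch(pts, w, -1.0))
        b = value_of(geo.frechet_mean_batch(pts, w, -1.0, init="largest_weight"))
        # the 1e-8 objective tolerance bounds coordinates only to ~sqrt(tol)
        assert np.allclose(a, b, atol=1e-4)


class TestBallContainment:
    def test_all_operations_respect_ball_invariant(self, rng):
        K = -1.5
        cap = 1.0 / np.sqrt(1.5)
        u = random_ball_points(rng, 50, 3, K, max_rel=0.999)
        v = random_ball_points(rng, 50, 3, K, max_rel=0.999)
        W = rng.normal(size=(3, 3)) * 3
        for out in (
            geo.mobius_add(u, v, K),
            geo.mobius_matvec(W, u, K),
            geo.exp_map0(rng.normal(size=(50, 3)) * 10, K),
            geo.hyp_activation(u, K, K),
        ):
            norms = np.linalg.norm(value_of(out), axis=-1)
            assert np.all(norms < cap)
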