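"""Divergence core: kernels, ridge algebra, plug-ins, and the quadrature oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plsbd.divergence import (
    DensitySpec,
    GramPair,
    KernelModel,
    RatioValues,
    alpha_pe_from_ratios,
    alpha_pe_quadrature,
    build_H_hat,
    build_h_hat,
    evaluate_ratio,
    gaussian_kernel,
    kernel_matrix,
    plsbd_from_ratios,
    plsbd_quadrature,
    solve_theta,
)

G = lambda m, s: DensitySpec("gaussian", (m, s))


# ---------------------------------------------------------------------------
# Gaussian kernel and Gram machinery


@pytest.mark.parametrize(
    "u, v, sigma, expected",
    [
        ((1.0, -2.0), (1.0, -2.0), 0.7, 1.0),
        ((0.0,), (math.sqrt(2.0) * 3.0,), 3.0, math.exp(-1.0)),
        ((0.0, 0.0), (3.0, 4.0), 5.0, math.exp(-0.5)),
    ],
)
def test_gaussian_kernel_values(u, v, sigma, expected):
    assert gaussian_kernel(u, v, sigma) == pytest.approx(expected, abs=1e-12)


def test_gaussian_kernel_rejects_bad_inputs():
    with pytest.raises(ValueError, match="dimension"):
        gaussian_kernel([0.0], [0.0, 1.0], 1.0)
    with pytest.raises(ValueError, match="sigma"):
        gaussian_kernel([0.0], [1.0], 0.0)


def test_kernel_matrix_elementwise_and_limits():
    X = np.array([[0.0], [1.0]])
    K = kernel_matrix(X, X, 1.0)
    e = math.exp(-0.5)
    assert np.allclose(K, [[1.0, e], [e, 1.0]])
    assert kernel_matrix([[2.0, 3.0]], [[2.0, 3.0]], 0.1) == pytest.approx(1.0)
    # sigma -> infinity flattens every entry to 1
    assert np.allclose(kernel_matrix(X, X, 1e12), 1.0)
    with pytest.raises(ValueError, match="dimension"):
        kernel_matrix(np.ones((2, 2)), np.ones((2, 3)), 1.0)


def test_build_h_hat_column_means():
    assert np.allclose(build_h_hat(np.ones((4, 3))), 1.0)
    assert np.allclose(build_h_hat(np.eye(2)), [0.5, 0.5])
    row = np.array([[0.2, 0.9, 0.4]])
    assert np.allclose(build_h_hat(row), row[0])
    with pytest.raises(ValueError):
        build_h_hat(np.empty((0, 0)))


def test_build_H_hat_collapses_and_symmetry():
    rng = np.random.default_rng(0)
    Kp = rng.uniform(0.1, 1.0, (6, 4))
    Kq = rng.uniform(0.1, 1.0, (9, 4))
    assert np.allclose(build_H_hat(Kp, Kq, 1.0), Kp.T @ Kp / 6)
    assert np.allclose(build_H_hat(Kp, Kq, 0.0), Kq.T @ Kq / 9)
    one = np.array([[1.0]])
    for alpha in (0.0, 0.3, 1.0):
        assert build_H_hat(one, one, alpha) == pytest.approx(1.0)
    H = build_H_hat(Kp, Kq, 0.4)
    assert np.max(np.abs(H - H.T)) == 0.0
    assert np.linalg.eigvalsh(H).min() >= -1e-10
    with pytest.raises(ValueError, match="alpha"):
        build_H_hat(Kp, Kq, 1.5)


def test_solve_theta_examples_and_residual():
    assert solve_theta(np.array([[1.0]]), np.array([1.0]), 1.0) == pytest.approx(0.5)
    h = np.array([0.3, -0.7, 1.1])
    assert np.allclose(solve_theta(np.zeros((3, 3)), h, 1.0), h)
    rng = np.random.default_rng(1)
    A = rng.normal(size=(8, 8))
    H = A @ A.T
    h = rng.normal(size=8)
    for lam in (1e-3, 1.0):
        theta = solve_theta(H, h, lam)
        resid = np.linalg.norm((H + lam * np.eye(8)) @ theta - h)
        assert resid <= 1e-8 * np.linalg.norm(h)
    with pytest.raises(ValueError):
        solve_theta(np.array([[np.nan]]), np.array([1.0]), 1.0)


def test_evaluate_ratio_kernel_expansion():
    c = np.array([[1.5, -2.0]])
    m = KernelModel(centers=c, sigma=0.8, lam=0.1, theta=np.array([2.0]))
    assert evaluate_ratio(m, c) == pytest.approx(2.0)
    m0 = KernelModel(centers=np.zeros((3, 1)), sigma=1.0, lam=0.1, theta=np.zeros(3))
    assert np.allclose(evaluate_ratio(m0, np.array([[5.0]])), 0.0)
    m2 = KernelModel(
        centers=np.array([[0.0], [1.0]]), sigma=1.0, lam=0.1, theta=np.array([1.0, 1.0])
    )
    assert evaluate_ratio(m2, np.array([[0.0]])) == pytest.approx(1.0 + math.exp(-0.5))


def test_gram_pair_rejects_nan_and_mismatch():
    with pytest.raises(ValueError, match="NaN"):
        GramPair(np.array([[np.nan]]), np.array([[1.0]]))
    with pytest.raises(ValueError, match="centers"):
        GramPair(np.ones((2, 2)), np.ones((2, 3)))


# ---------------------------------------------------------------------------
# divergence plug-ins


def test_plsbd_unit_ratios_exactly_zero_over_alpha_grid():
    """A distribution compared with itself gives unit ratios and divergence 0, exactly."""
    for alpha in np.arange(0.0, 1.0, 0.1):
        r = RatioValues(np.ones(13), np.ones(7), float(alpha))
        assert plsbd_from_ratios(r) == 0.0
        assert alpha_pe_from_ratios(r) == 0.0


@pytest.mark.parametrize(
    "rp, rq, alpha, expected",
    [
        ((2.0, 2.0), (0.5, 0.5), 0.0, 1.0),
        ((1.5, 1.5), (0.5, 0.5), 0.5, 1.0),
    ],
)
def test_plsbd_direct_values(rp, rq, alpha, expected):
    assert plsbd_from_ratios(RatioValues(rp, rq, alpha)) == pytest.approx(expected, abs=1e-12)


def test_alpha_pe_is_first_moment_of_rp():
    r = RatioValues((2.0, 2.0), (0.3, 1.7), 0.35)
    assert alpha_pe_from_ratios(r) == pytest.approx(0.5, abs=1e-12)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    rp=st.lists(st.floats(-3.0, 8.0), min_size=1, max_size=30),
    rq=st.lists(st.floats(-3.0, 8.0), min_size=1, max_size=30),
    alpha=st.floats(0.0, 0.95),
)
def test_plsbd_alpha_pe_identity(rp, rq, alpha):
    """The PLsBD exceeds the alpha-relative Pearson plug-in by (2-a)/(2(1-a))*(1-E_q r)."""
    r = RatioValues(rp, rq, alpha)
    offset = (2.0 - alpha) / (2.0 * (1.0 - alpha)) * (1.0 - float(np.mean(r.rq)))
    assert plsbd_from_ratios(r) == pytest.approx(alpha_pe_from_ratios(r) + offset, abs=1e-12)


def test_identity_on_thousand_random_ratio_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n_p, n_q = rng.integers(1, 40, size=2)
        r = RatioValues(
            rng.uniform(-2, 6, n_p), rng.uniform(-2, 6, n_q), float(rng.uniform(0, 0.99))
        )
        offset = (2 - r.alpha) / (2 * (1 - r.alpha)) * (1 - r.rq.mean())
        assert abs(plsbd_from_ratios(r) - (alpha_pe_from_ratios(r) + offset)) <= 1e-12


def test_ratio_values_validation():
    with pytest.raises(ValueError, match="alpha"):
        RatioValues([1.0], [1.0], 1.0)  # division by 1-alpha in the plug-in
    with pytest.raises(ValueError, match="at least one"):
        RatioValues([], [1.0], 0.5)
    with pytest.raises(ValueError, match="finite"):
        RatioValues([np.inf], [1.0], 0.5)


# ---------------------------------------------------------------------------
# quadrature oracle


def test_quadrature_self_divergence_vanishes():
    for alpha in (0.0, 0.3, 0.5, 0.9):
        assert abs(plsbd_quadrature(G(0, 1), G(0, 1), alpha=alpha)) <= 1e-10


def test_quadrature_frozen_regression_value():
    """Independently recomputed once on a 4e6-point trapezoid grid and frozen."""
    assert plsbd_quadrature(G(0, 1), G(1, 1), alpha=0.5) == pytest.approx(
        0.4081085312670007, abs=1e-8
    )


def test_quadrature_symmetry_at_half():
    rng = np.random.default_rng(3)
    for _ in range(10):
        m1, m2 = rng.uniform(-3, 3, 2)
        s1, s2 = rng.uniform(0.3, 3.0, 2)
        a = plsbd_quadrature(G(m1, s1), G(m2, s2), alpha=0.5)
        b = plsbd_quadrature(G(m2, s2), G(m1, s1), alpha=0.5)
        assert a == pytest.approx(b, abs=1e-8)


def test_quadrature_uniform_measure_reduces_to_l2():
    """With a uniform scaling measure of density c, D_PL = (1/2c) * ||p - q||_2^2.

    The L2 norm is evaluated in closed form for Gaussian pairs:
    int p^2 = 1/(2 sqrt(pi) s), int p q = N(mu1 - mu2; 0, s1^2 + s2^2).
    """
    from scipy.stats import norm

    p, q = G(0, 1), G(1.5, 0.8)
    lo, hi = -30.0, 30.0
    c = 1.0 / (hi - lo)
    l2 = (
        1.0 / (2 * math.sqrt(math.pi) * 1.0)
        + 1.0 / (2 * math.sqrt(math.pi) * 0.8)
        - 2.0 * norm.pdf(1.5, scale=math.sqrt(1.0 + 0.64))
    )
    got = plsbd_quadrature(p, q, m=DensitySpec("uniform", (lo, hi)))
    assert got == pytest.approx(l2 / (2 * c), abs=1e-6)


def test_quadrature_lower_bound_of_lemma():
    """PLsBD >= alpha-relative Pearson + (alpha-2)/(2 alpha) on a Gaussian grid."""
    for alpha in np.arange(0.1, 1.0, 0.2):
        for mu, sd in [(0.5, 1.0), (2.0, 1.0), (1.0, 2.0)]:
            dpl = plsbd_quadrature(G(0, 1), G(mu, sd), alpha=float(alpha))
            dpe = alpha_pe_quadrature(G(0, 1), G(mu, sd), float(alpha))
            assert dpl >= dpe + (alpha - 2.0) / (2.0 * alpha) - 1e-9


def test_relative_ratio_bounded_by_inverse_alpha():
    """r_alpha = p / (alpha p + (1-alpha) q) <= 1/alpha wherever the mixture is positive."""
    y = np.linspace(-12.0, 14.0, 40001)
    for alpha in (0.1, 0.3, 0.5, 0.9, 1.0):
        for mu, sd in [(1.0, 1.0), (5.0, 0.5), (-3.0, 2.0)]:
            p = G(0, 1).pdf(y)
            q = G(mu, sd).pdf(y)
            m = alpha * p + (1 - alpha) * q
            mask = m > 0
            assert np.max(p[mask] / m[mask]) <= 1.0 / alpha + 1e-9


def test_quadrature_monotone_in_separation():
    vals = [plsbd_quadrature(G(0, 1), G(mu, 1), alpha=0.5) for mu in np.arange(0, 4.5, 0.5)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_quadrature_rejects_vanishing_measure():
    with pytest.raises(ValueError, match="vanishes"):
        plsbd_quadrature(G(0, 1), G(1, 1), m=DensitySpec("uniform", (0.0, 1.0)))


def test_density_spec_validation():
    with pytest.raises(ValueError, match="family"):
        DensitySpec("laplace", (0, 1))
    with pytest.raises(ValueError, match="sd"):
        DensitySpec("gaussian", (0, -1))
    with pytest.raises(ValueError, match="lower"):
        DensitySpec("uniform", (2, 1))
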