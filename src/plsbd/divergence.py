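"""Pearson-like scaled Bregman divergence (PLsBD) primitives.

The PLsBD compares two densities ``p`` and ``q`` through a third, scaling
measure ``m``:

    D_PL(p || q; m) = 1/2 * integral of m(y) * (p(y)/m(y) - q(y)/m(y))^2 dy.

With the mixture measure ``m_alpha = alpha*p + (1-alpha)*q`` the divergence
admits a plug-in estimator written purely in terms of the relative density
ratio ``r_alpha = p / m_alpha``:

    D_PL = 1/2 E_p[r_alpha] - (2-alpha)/(2(1-alpha)) E_q[r_alpha]
           + 1/(2(1-alpha)),

so no individual density ever needs to be estimated.  This module houses
that plug-in, the alpha-relative Pearson baseline derived from the same
ratios, the Gaussian-kernel ridge machinery used to fit ``r_alpha`` from
samples, and a one-dimensional quadrature oracle that evaluates the
divergence definition directly for known densities (used for testing the
plug-in, never by the detection pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "RatioValues",
    "KernelModel",
    "GramPair",
    "DensitySpec",
    "gaussian_kernel",
    "kernel_matrix",
    "build_h_hat",
    "build_H_hat",
    "solve_theta",
    "evaluate_ratio",
    "plsbd_from_ratios",
    "alpha_pe_from_ratios",
    "plsbd_quadrature",
    "alpha_pe_quadrature",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RatioValues:
    """Estimated relative density ratios at the two segment samples.

    ``rp`` holds r_alpha-hat evaluated at the n_p samples drawn from the
    "p" (post-change) segment, ``rq`` at the n_q samples from the "q"
    (pre-change) segment.  ``alpha`` is the mixture weight of the scaling
    measure; alpha = 1 is rejected because the plug-in divides by 1-alpha.
    """

    rp: np.ndarray
    rq: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        rp = np.asarray(self.rp, dtype=float).ravel()
        rq = np.asarray(self.rq, dtype=float).ravel()
        object.__setattr__(self, "rp", rp)
        object.__setattr__(self, "rq", rq)
        if rp.size < 1 or rq.size < 1:
            raise ValueError("rp and rq must each contain at least one value")
        if not (np.isfinite(rp).all() and np.isfinite(rq).all()):
            raise ValueError("ratio values must be finite")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class KernelModel:
    """A fitted Gaussian-kernel density-ratio model r(y) = sum_l theta_l K(y, c_l)."""

    centers: np.ndarray
    sigma: float
    lam: float
    theta: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        theta = np.asarray(self.theta, dtype=float).ravel()
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "theta", theta)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if centers.shape[0] != theta.size:
            raise ValueError("theta length must equal the number of centers")
        if not np.isfinite(theta).all():
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class GramPair:
    """Kernel matrices of the p- and q-segment samples against shared centers."""

    Kp: np.ndarray
    Kq: np.ndarray

    def __post_init__(self) -> None:
        Kp = np.atleast_2d(np.asarray(self.Kp, dtype=float))
        Kq = np.atleast_2d(np.asarray(self.Kq, dtype=float))
        object.__setattr__(self, "Kp", Kp)
        object.__setattr__(self, "Kq", Kq)
        if Kp.shape[1] != Kq.shape[1]:
            raise ValueError("Kp and Kq must share the number of centers")
        for name, K in (("Kp", Kp), ("Kq", Kq)):
            if np.isnan(K).any():
                raise ValueError(f"{name} contains NaN")


@dataclass(frozen=True)
class DensitySpec:
    """A 1-D density for the quadrature oracle: gaussian(mean, sd) or uniform(lower, upper)."""

    family: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform"):
            raise ValueError(f"unsupported density family: {self.family!r}")
        a, b = self.params
        if self.family == "gaussian" and b <= 0:
            raise ValueError("gaussian sd must be positive")
        if self.family == "uniform" and a >= b:
            raise ValueError("uniform requires lower < upper")

    def pdf(self, y: np.ndarray) -> np.ndarray:
        a, b = self.params
        if self.family == "gaussian":
            return stats.norm.pdf(y, loc=a, scale=b)
        return stats.uniform.pdf(y, loc=a, scale=b - a)

    def support(self, n_sd: float = 12.0) -> tuple[float, float]:
        a, b = self.params
        if self.family == "gaussian":
            return a - n_sd * b, a + n_sd * b
        return a, b


# ---------------------------------------------------------------------------
# kernel machinery (Gaussian kernel, ridge system)


def gaussian_kernel(u: Sequence[float], v: Sequence[float], sigma: float) -> float:
    """K(u, v) = exp(-||u - v||^2 / (2 sigma^2)); equals 1 iff u == v."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    d2 = float(np.sum((u - v) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(samples: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix with entry (i, l) = K(sample_i, center_l)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if samples.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: samples have {samples.shape[1]} features, "
            f"centers have {centers.shape[1]}"
        )
    d2 = cdist(samples, centers, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def build_h_hat(Kp: np.ndarray) -> np.ndarray:
    """Column means of the p-segment kernel matrix (the linear term of the ridge fit)."""
    Kp = np.atleast_2d(np.asarray(Kp, dtype=float))
    if Kp.size == 0:
        raise ValueError("Kp must be non-empty")
    return Kp.mean(axis=0)


def build_H_hat(Kp: np.ndarray, Kq: np.ndarray, alpha: float) -> np.ndarray:
    """Mixture Gram matrix alpha * Kp'Kp / n_p + (1-alpha) * Kq'Kq / n_q.

    Symmetric PSD by construction; the quadratic term of the ridge fit.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    Kp = np.atleast_2d(np.asarray(Kp, dtype=float))
    Kq = np.atleast_2d(np.asarray(Kq, dtype=float))
    if Kp.shape[1] != Kq.shape[1]:
        raise ValueError("Kp and Kq must have the same number of columns")
    H = np.zeros((Kp.shape[1], Kp.shape[1]))
    if alpha > 0:
        H += alpha * (Kp.T @ Kp) / Kp.shape[0]
    if alpha < 1:
        H += (1.0 - alpha) * (Kq.T @ Kq) / Kq.shape[0]
    return 0.5 * (H + H.T)


def solve_theta(H: np.ndarray, h: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients theta = (H + lam I)^-1 h via a Cholesky factorization.

    H is PSD and lam > 0, so the shifted system is positive definite; an
    explicit inverse is never formed.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    H = np.atleast_2d(np.asarray(H, dtype=float))
    h = np.asarray(h, dtype=float).ravel()
    if not (np.isfinite(H).all() and np.isfinite(h).all()):
        raise ValueError("H and h must be finite")
    A = H + lam * np.eye(H.shape[0])
    try:
        c, low = cho_factor(A, lower=True, check_finite=False)
        return cho_solve((c, low), h, check_finite=False)
    except np.linalg.LinAlgError:  # pragma: no cover - severe ill-conditioning
        return np.linalg.solve(A, h)


def evaluate_ratio(model: KernelModel, points: np.ndarray) -> np.ndarray:
    """Kernel expansion sum_l theta_l K(point, center_l) at each query point.

    Values may be negative: the ridge solution is unconstrained and no
    clipping is applied here (see `fit.FitConfig.clip_ratios`).
    """
    K = kernel_matrix(points, model.centers, model.sigma)
    return K @ model.theta


# ---------------------------------------------------------------------------
# divergence plug-ins


def plsbd_from_ratios(r: RatioValues) -> float:
    """Plug-in PLsBD from fitted relative density ratios.

    Evaluated as mean(rp)/2 - mean(rq)/2 + c*(1 - mean(rq)) with
    c = 1/(2(1-alpha)), an exact regrouping of the textbook form
    mean(rp)/2 - (2-alpha)/(2(1-alpha)) * mean(rq) + 1/(2(1-alpha))
    that returns exactly 0.0 when every ratio equals one.
    """
    c = 1.0 / (2.0 * (1.0 - r.alpha))
    mean_rp = float(np.mean(r.rp))
    mean_rq = float(np.mean(r.rq))
    return 0.5 * (mean_rp - mean_rq) + c * (1.0 - mean_rq)


def alpha_pe_from_ratios(r: RatioValues) -> float:
    """Plug-in alpha-relative Pearson divergence from the same fitted ratios.

    The PLsBD exceeds this quantity by (2-alpha)/(2(1-alpha)) * (1 - E_q[r]),
    which algebraically reduces the alpha-relative Pearson plug-in to
    mean(rp)/2 - 1/2.  Scoring with this function at alpha = 0 is the uLSIF
    (plain Pearson divergence) baseline; at alpha > 0 it is the RuLSIF
    baseline.
    """
    if not 0.0 <= r.alpha < 1.0:  # alpha validated by RatioValues; kept for clarity
        raise ValueError("alpha must lie in [0, 1)")
    return 0.5 * float(np.mean(r.rp)) - 0.5


# ---------------------------------------------------------------------------
# quadrature oracle (1-D, testing only)


def _resolve_measure(
    p: DensitySpec, q: DensitySpec, m: "DensitySpec | None", alpha: "float | None"
):
    if (m is None) == (alpha is None):
        raise ValueError("provide exactly one of m (a DensitySpec) or alpha")
    if m is not None:
        return m.pdf, m.support()
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    def mix(y):
        return alpha * p.pdf(y) + (1.0 - alpha) * q.pdf(y)

    return mix, None


def _integration_bounds(p: DensitySpec, q: DensitySpec) -> tuple[float, float]:
    (lo_p, hi_p), (lo_q, hi_q) = p.support(), q.support()
    return min(lo_p, lo_q), max(hi_p, hi_q)


def plsbd_quadrature(
    p: DensitySpec,
    q: DensitySpec,
    m: "DensitySpec | None" = None,
    alpha: "float | None" = None,
    tol: float = 1e-10,
) -> float:
    """Numerically integrate D_PL(p || q; m) = 1/2 * int (p - q)^2 / m dy.

    Independent oracle for 1-D densities; the scaling measure is either an
    explicit density or the alpha-mixture of p and q.  Raises if the measure
    vanishes somewhere p and q differ (divergent integrand).
    """
    m_pdf, m_support = _resolve_measure(p, q, m, alpha)
    lo, hi = _integration_bounds(p, q)
    if m_support is not None:
        m_lo, m_hi = m_support
        probe = np.linspace(lo, hi, 4001)
        bad = (m_pdf(probe) <= 0) & (np.abs(p.pdf(probe) - q.pdf(probe)) > 1e-300)
        if bad.any():
            raise ValueError("scaling measure vanishes where p != q: divergent integrand")
        lo, hi = min(lo, m_lo), max(hi, m_hi)

    def integrand(y):
        diff = p.pdf(y) - q.pdf(y)
        if diff == 0.0:
            return 0.0
        return 0.5 * diff * diff / m_pdf(y)

    pts = sorted(x for x in _breakpoints(p, q, m) if lo < x < hi)
    value, _ = integrate.quad(
        integrand, lo, hi, points=pts or None, epsabs=tol, epsrel=tol, limit=400
    )
    return value


def alpha_pe_quadrature(p: DensitySpec, q: DensitySpec, alpha: float, tol: float = 1e-10) -> float:
    """Numerically integrate the alpha-relative Pearson divergence.

    D_aPE(p || q_alpha) = 1/2 * int q_alpha (p/q_alpha - 1)^2 dy with
    q_alpha = alpha*p + (1-alpha)*q; the RuLSIF population objective.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lo, hi = _integration_bounds(p, q)

    def integrand(y):
        py = p.pdf(y)
        qa = alpha * py + (1.0 - alpha) * q.pdf(y)
        diff = py - qa
        if diff == 0.0:
            return 0.0
        return 0.5 * diff * diff / qa

    pts = sorted(x for x in _breakpoints(p, q, None) if lo < x < hi)
    value, _ = integrate.quad(
        integrand, lo, hi, points=pts or None, epsabs=tol, epsrel=tol, limit=400
    )
    return value


def _breakpoints(p: DensitySpec, q: DensitySpec, m: "DensitySpec | None") -> set[float]:
    """Integration breakpoints: density modes and uniform support edges."""
    pts: set[float] = set()
    for spec in (p, q, m):
        if spec is None:
            continue
        if spec.family == "gaussian":
            pts.add(spec.params[0])
        else:
            pts.update(spec.params)
    return pts
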