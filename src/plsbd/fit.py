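"""Hyperparameter selection and end-to-end density-ratio fitting.

For one pair of segments (Yq = pre-change samples, Yp = post-change
samples) the Gaussian-kernel ridge model of the relative density ratio is
fitted by:

1. choosing kernel centers from the segment samples,
2. selecting the bandwidth sigma and ridge weight lambda by n_f-fold
   cross-validation of the out-of-sample L2 ratio-matching loss
   J(theta) = 1/2 theta' H theta - h' theta (the ridge penalty enters the
   training solve but not the held-out evaluation), and
3. refitting on all samples with the selected (sigma, lambda).

The sigma grid is expressed, by default, as multipliers of the median
pairwise distance of the pooled samples (the "median heuristic"), which
makes the fit invariant to a global rescaling of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .divergence import KernelModel, RatioValues

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "CVResult",
    "median_heuristic",
    "choose_centers",
    "cv_objective",
    "select_hyperparams",
    "fit_ratio_model",
]

_DEFAULT_SIGMA_GRID = (0.6, 0.8, 1.0, 1.2, 1.4)
_DEFAULT_LAMBDA_GRID = (1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one density-ratio fit.

    sigma_grid entries are multipliers of the pooled-sample median pairwise
    distance when ``sigma_scale == "median"`` (the default) or absolute
    bandwidths when ``sigma_scale == "absolute"``.  ``clip_ratios`` floors
    fitted ratios at zero before scoring (off by default: the unconstrained
    ridge solution can legitimately go negative, and clipping would break
    the exact algebraic link between the PLsBD and alpha-relative-Pearson
    plug-ins).
    """

    alpha: float = 0.5
    n_basis: int = 50
    n_folds: int = 5
    sigma_grid: tuple[float, ...] = _DEFAULT_SIGMA_GRID
    sigma_scale: str = "median"
    lambda_grid: tuple[float, ...] = _DEFAULT_LAMBDA_GRID
    seed: int = 0
    clip_ratios: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.sigma_scale not in ("median", "absolute"):
            raise ValueError("sigma_scale must be 'median' or 'absolute'")
        for name, grid in (("sigma_grid", self.sigma_grid), ("lambda_grid", self.lambda_grid)):
            if len(grid) == 0 or any(g <= 0 for g in grid):
                raise ValueError(f"{name} must be non-empty and strictly positive")


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome: the winning grid point and the loss table."""

    sigma: float
    lam: float
    sigmas: np.ndarray
    lambdas: np.ndarray
    losses: np.ndarray  # shape (len(sigmas), len(lambdas)), fold-averaged


def median_heuristic(samples: np.ndarray, max_pairs: int = 2000, rng=None) -> float:
    """Median pairwise Euclidean distance, subsampled for large inputs.

    With n samples and n(n-1)/2 <= max_pairs all pairs are used; otherwise
    max_pairs index pairs are drawn deterministically from ``rng``.  An
    all-identical sample set has median zero and raises, directing the
    caller to supply an absolute sigma grid instead.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    if n < 2:
        raise ValueError("median_heuristic needs at least two samples")
    if n * (n - 1) // 2 <= max_pairs:
        d = pdist(samples)
    else:
        rng = np.random.default_rng(rng)
        pairs = rng.integers(0, n, size=(3 * max_pairs, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]][:max_pairs]
        d = np.linalg.norm(samples[pairs[:, 0]] - samples[pairs[:, 1]], axis=1)
    med = float(np.median(d))
    if med == 0.0:
        raise ValueError(
            "median pairwise distance is zero (samples are nearly all identical); "
            "supply an absolute sigma_grid via FitConfig(sigma_scale='absolute')"
        )
    return med


def choose_centers(Yp: np.ndarray, Yq: np.ndarray, n_basis: int, rng=None) -> np.ndarray:
    """Kernel centers: all of Yp first, then Yq rows in seeded random order.

    At most ``min(n_basis, n_p + n_q)`` centers are returned, drawn without
    replacement.  Preferring the post-change segment puts basis mass where
    the numerator density p lives, which is where the ratio must be
    expressive.
    """
    Yp = np.atleast_2d(np.asarray(Yp, dtype=float))
    Yq = np.atleast_2d(np.asarray(Yq, dtype=float))
    n_c = min(n_basis, Yp.shape[0] + Yq.shape[0])
    if n_c <= Yp.shape[0]:
        return Yp[:n_c].copy()
    rng = np.random.default_rng(rng)
    extra = rng.permutation(Yq.shape[0])[: n_c - Yp.shape[0]]
    return np.vstack([Yp, Yq[extra]])


def cv_objective(theta: np.ndarray, H_holdout: np.ndarray, h_holdout: np.ndarray) -> float:
    """Held-out L2 ratio-matching loss J = 1/2 theta' H theta - h' theta (smaller is better)."""
    theta = np.asarray(theta, dtype=float).ravel()
    return float(0.5 * theta @ H_holdout @ theta - h_holdout @ theta)


def _fold_indices(n: int, n_folds: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::n_folds] for f in range(n_folds)]


def _grid_stats(Kp, Kq, alpha, folds_p, folds_q):
    """Per-fold training/held-out (H, h) for one sigma; vectorized over folds."""
    n_c = Kp.shape[1]
    F = len(folds_p)
    H_tr = np.empty((F, n_c, n_c))
    h_tr = np.empty((F, n_c))
    H_ho = np.empty((F, n_c, n_c))
    h_ho = np.empty((F, n_c))
    Gp_full = Kp.T @ Kp
    Gq_full = Kq.T @ Kq
    sp_full = Kp.sum(axis=0)
    for f in range(F):
        Kp_ho = Kp[folds_p[f]]
        Kq_ho = Kq[folds_q[f]]
        n_p_ho, n_q_ho = Kp_ho.shape[0], Kq_ho.shape[0]
        n_p_tr = Kp.shape[0] - n_p_ho
        n_q_tr = Kq.shape[0] - n_q_ho
        Gp_ho = Kp_ho.T @ Kp_ho
        Gq_ho = Kq_ho.T @ Kq_ho
        H_tr[f] = alpha * (Gp_full - Gp_ho) / n_p_tr + (1 - alpha) * (Gq_full - Gq_ho) / n_q_tr
        h_tr[f] = (sp_full - Kp_ho.sum(axis=0)) / n_p_tr
        H_ho[f] = alpha * Gp_ho / n_p_ho + (1 - alpha) * Gq_ho / n_q_ho
        h_ho[f] = Kp_ho.mean(axis=0)
    return H_tr, h_tr, H_ho, h_ho


def resolve_sigma_grid(cfg: FitConfig, pooled: np.ndarray, rng) -> np.ndarray:
    """Absolute sigma grid: the configured grid, scaled by the median heuristic if relative."""
    grid = np.asarray(cfg.sigma_grid, dtype=float)
    if cfg.sigma_scale == "median":
        grid = grid * median_heuristic(pooled, rng=rng)
    return grid


def select_hyperparams(
    Yp: np.ndarray,
    Yq: np.ndarray,
    centers: np.ndarray,
    cfg: FitConfig,
    rng=None,
    sigmas: Optional[np.ndarray] = None,
) -> CVResult:
    """Pick (sigma, lambda) minimizing the fold-averaged held-out loss.

    p- and q-samples are partitioned into disjoint seeded folds separately,
    so every fold contains both kinds.  If min(n_p, n_q) < n_folds the fold
    count is reduced (with a logged warning) rather than failing: in the
    short-segment regime of high-dimensional runs there may be only a
    handful of samples per side.  Ties are broken toward the smallest
    sigma, then the smallest lambda.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    Yp = np.atleast_2d(np.asarray(Yp, dtype=float))
    Yq = np.atleast_2d(np.asarray(Yq, dtype=float))
    if sigmas is None:
        sigmas = resolve_sigma_grid(cfg, np.vstack([Yp, Yq]), rng)
    sigmas = np.asarray(sigmas, dtype=float)
    lambdas = np.asarray(cfg.lambda_grid, dtype=float)

    n_folds = min(cfg.n_folds, Yp.shape[0], Yq.shape[0])
    if n_folds < cfg.n_folds:
        logger.warning(
            "reducing n_folds from %d to %d (segment sizes n_p=%d, n_q=%d)",
            cfg.n_folds, n_folds, Yp.shape[0], Yq.shape[0],
        )
    if len(sigmas) == 1 and len(lambdas) == 1:
        losses = np.zeros((1, 1))
        return CVResult(float(sigmas[0]), float(lambdas[0]), sigmas, lambdas, losses)

    folds_p = _fold_indices(Yp.shape[0], n_folds, rng)
    folds_q = _fold_indices(Yq.shape[0], n_folds, rng)

    D2p = cdist(Yp, centers, metric="sqeuclidean")
    D2q = cdist(Yq, centers, metric="sqeuclidean")

    S, L, F = len(sigmas), len(lambdas), n_folds
    n_c = centers.shape[0]
    H_tr = np.empty((S, F, n_c, n_c))
    h_tr = np.empty((S, F, n_c))
    H_ho = np.empty((S, F, n_c, n_c))
    h_ho = np.empty((S, F, n_c))
    for si, sigma in enumerate(sigmas):
        Kp = np.exp(-D2p / (2.0 * sigma**2))
        Kq = np.exp(-D2q / (2.0 * sigma**2))
        H_tr[si], h_tr[si], H_ho[si], h_ho[si] = _grid_stats(
            Kp, Kq, cfg.alpha, folds_p, folds_q
        )

    eye = np.eye(n_c)
    A = H_tr[:, :, None] + lambdas[None, None, :, None, None] * eye  # (S,F,L,n,n)
    theta = np.linalg.solve(A, np.broadcast_to(h_tr[:, :, None, :, None], A.shape[:3] + (n_c, 1)))
    theta = theta[..., 0]  # (S,F,L,n)
    J = 0.5 * np.einsum("sfln,sfnm,sflm->sfl", theta, H_ho, theta) - np.einsum(
        "sfln,sfn->sfl", theta, h_ho
    )
    losses = J.mean(axis=1)  # (S, L)
    flat = int(np.argmin(losses))  # row-major: first min = smallest sigma, then lambda
    si, li = divmod(flat, L)
    return CVResult(float(sigmas[si]), float(lambdas[li]), sigmas, lambdas, losses)


def fit_ratio_model(
    Yp: np.ndarray,
    Yq: np.ndarray,
    cfg: FitConfig,
    rng=None,
) -> tuple[KernelModel, RatioValues]:
    """Full fit of one segment pair: centers, CV, final ridge solve, ratios.

    Returns the model refitted on all samples at the selected (sigma,
    lambda), and its ratio values at Yp and Yq ready for divergence
    scoring.  Deterministic given ``cfg.seed`` (or an explicit ``rng``).
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    Yp = np.atleast_2d(np.asarray(Yp, dtype=float))
    Yq = np.atleast_2d(np.asarray(Yq, dtype=float))
    centers = choose_centers(Yp, Yq, cfg.n_basis, rng)
    cv = select_hyperparams(Yp, Yq, centers, cfg, rng=rng)

    D2p = cdist(Yp, centers, metric="sqeuclidean")
    D2q = cdist(Yq, centers, metric="sqeuclidean")
    Kp = np.exp(-D2p / (2.0 * cv.sigma**2))
    Kq = np.exp(-D2q / (2.0 * cv.sigma**2))
    H = cfg.alpha * (Kp.T @ Kp) / Kp.shape[0] + (1 - cfg.alpha) * (Kq.T @ Kq) / Kq.shape[0]
    h = Kp.mean(axis=0)
    theta = np.linalg.solve(H + cv.lam * np.eye(H.shape[0]), h)

    model = KernelModel(centers=centers, sigma=cv.sigma, lam=cv.lam, theta=theta)
    rp = Kp @ theta
    rq = Kq @ theta
    if cfg.clip_ratios:
        rp = np.maximum(rp, 0.0)
        rq = np.maximum(rq, 0.0)
    return model, RatioValues(rp=rp, rq=rq, alpha=cfg.alpha)
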