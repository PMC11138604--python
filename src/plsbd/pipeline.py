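"""Sliding-window change-point detection scored by density-ratio divergences.

For each reference time point t the ``step`` embedded subsequences before
t form the "q" (pre-change) sample and the ``step`` subsequences starting
at t form the "p" (post-change) sample.  A relative density-ratio model is
fitted to the pair and scored with one of three divergences:

* ``plsbd``  - the Pearson-like scaled Bregman divergence plug-in,
* ``rulsif`` - the alpha-relative Pearson divergence plug-in,
* ``ulsif``  - the plain Pearson divergence plug-in (alpha forced to 0).

Candidates are time points whose score exceeds a threshold, by default
eta times the series maximum.  Time coordinates are 1-based and inclusive
throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .divergence import RatioValues, alpha_pe_from_ratios, plsbd_from_ratios
from .fit import FitConfig, fit_ratio_model

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesMatrix",
    "CPDConfig",
    "ScoreSeries",
    "Candidate",
    "ChangePointSet",
    "ThresholdWarning",
    "embed_subsequences",
    "segment_pair_at",
    "score_series",
    "detect_candidates",
]

_METHODS = ("plsbd", "rulsif", "ulsif")


class ThresholdWarning(UserWarning):
    """Warns that fraction-of-max thresholding flags a candidate unconditionally."""


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A T x d observation matrix with a 1-based time index."""

    values: np.ndarray
    time_index: np.ndarray = None
    covariate_names: tuple[str, ...] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        object.__setattr__(self, "values", values)
        T, d = values.shape
        if T < 2:
            raise ValueError("a time series needs at least two time points")
        if not np.isfinite(values).all():
            raise ValueError("time series values must be finite (missing data unsupported)")
        ti = self.time_index
        ti = np.arange(1, T + 1) if ti is None else np.asarray(ti, dtype=int)
        if ti.shape != (T,) or (np.diff(ti) <= 0).any():
            raise ValueError("time_index must be strictly increasing with one entry per row")
        object.__setattr__(self, "time_index", ti)
        names = self.covariate_names
        names = tuple(f"x{j + 1}" for j in range(d)) if names is None else tuple(names)
        if len(names) != d or len(set(names)) != d:
            raise ValueError("covariate_names must be unique, one per column")
        object.__setattr__(self, "covariate_names", names)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_covariates(self, indices) -> "TimeSeriesMatrix":
        indices = np.asarray(indices, dtype=int)
        return TimeSeriesMatrix(
            values=self.values[:, indices],
            time_index=self.time_index,
            covariate_names=tuple(self.covariate_names[j] for j in indices),
        )


@dataclass(frozen=True)
class CPDConfig:
    """Detection settings: divergence, window geometry, threshold rule.

    ``window_k`` is the subsequence length of the Hankel embedding;
    ``step`` the number of embedded samples on each side of the reference
    point (n_p = n_q = step); ``eta`` the threshold fraction; ``min_gap``
    the run-merge distance (defaults to ``window_k``).  ``symmetric`` adds
    the score with the segment roles exchanged.  ``threshold_mode`` is
    "maxfrac" (tau = eta * max score, the default) or "quantile"
    (tau = empirical eta-quantile).  ``score_floor`` optionally discards
    candidates whose peak falls below an absolute score.
    """

    method: str = "plsbd"
    alpha: float = 0.5
    window_k: int = 5
    step: int = 50
    eta: float = 0.9
    fit: FitConfig = None
    symmetric: bool = False
    min_gap: int = None
    stride: int = 1
    threshold_mode: str = "maxfrac"
    score_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")
        if self.step < 2:
            raise ValueError("step must be >= 2")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.threshold_mode not in ("maxfrac", "quantile"):
            raise ValueError("threshold_mode must be 'maxfrac' or 'quantile'")
        alpha = 0.0 if self.method == "ulsif" else self.alpha
        fit = self.fit if self.fit is not None else FitConfig(alpha=alpha)
        if fit.alpha != alpha:
            fit = replace(fit, alpha=alpha)
        object.__setattr__(self, "fit", fit)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "min_gap", self.window_k if self.min_gap is None else self.min_gap)


@dataclass(frozen=True)
class ScoreSeries:
    """Per-reference-time divergence scores."""

    t: np.ndarray
    score: np.ndarray
    method: str
    alpha: float
    config: CPDConfig = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        score = np.asarray(self.score, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "score", score)
        if t.size != score.size or t.size == 0:
            raise ValueError("t and score must be non-empty and of equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("t must be strictly increasing")
        if not np.isfinite(score).all():
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class Candidate:
    peak_time: int
    peak_score: float
    run_start: int
    run_end: int


@dataclass(frozen=True)
class ChangePointSet:
    candidates: tuple[Candidate, ...]
    threshold: float
    eta: float
    mode: str = "maxfrac"

    @property
    def peaks(self) -> np.ndarray:
        return np.array([c.peak_time for c in self.candidates], dtype=int)


def embed_subsequences(series: TimeSeriesMatrix, k: int) -> np.ndarray:
    """Hankel embedding: row t is (y(t), ..., y(t+k-1)) flattened covariate-major.

    Returns a (T-k+1) x (k*d) matrix; row i (0-based) covers times
    i+1 .. i+k.
    """
    T, d = series.values.shape
    if k > T:
        raise ValueError(f"window_k={k} exceeds series length T={T}")
    n_rows = T - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(series.values, (k, d))
    return windows.reshape(n_rows, k * d).copy()


def segment_pair_at(samples: np.ndarray, t: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (Yq, Yp) segments around reference time t (1-based on embedded rows).

    Yq holds the ``step`` embedded samples ending at t-1 (the past), Yp the
    ``step`` samples starting at t (the future); the score at t therefore
    contrasts the post-t distribution against the pre-t one.
    """
    samples = np.atleast_2d(samples)
    n_rows = samples.shape[0]
    if not (step + 1 <= t <= n_rows - step + 1):
        raise ValueError(
            f"reference point t={t} out of valid range [{step + 1}, {n_rows - step + 1}]"
        )
    Yq = samples[t - 1 - step : t - 1]
    Yp = samples[t - 1 : t - 1 + step]
    return Yq, Yp


def _score_func(method: str):
    return plsbd_from_ratios if method == "plsbd" else alpha_pe_from_ratios


def score_series(
    series: TimeSeriesMatrix,
    cfg: CPDConfig,
    seed: int = 0,
    hyperparams: Optional[dict[int, tuple[float, float]]] = None,
    return_hyperparams: bool = False,
):
    """Divergence score at every valid reference point.

    Each reference point gets its own RNG stream derived from ``seed`` and
    t, so per-t results do not depend on evaluation order.  ``hyperparams``
    optionally maps t -> (sigma, lambda) to bypass cross-validation (used
    by the random-sampling fast path); with ``return_hyperparams`` the
    selected pairs are returned alongside the scores.
    """
    emb = embed_subsequences(series, cfg.window_k)
    n_rows = emb.shape[0]
    t_lo, t_hi = cfg.step + 1, n_rows - cfg.step + 1
    if t_hi < t_lo:
        raise ValueError(
            f"series too short: need T >= window_k + 2*step = {cfg.window_k + 2 * cfg.step}, "
            f"got T={series.T}"
        )
    score_fn = _score_func(cfg.method)
    t_values = np.arange(t_lo, t_hi + 1, cfg.stride)
    scores = np.empty(t_values.size)
    chosen: dict[int, tuple[float, float]] = {}
    for i, t in enumerate(t_values):
        Yq, Yp = segment_pair_at(emb, int(t), cfg.step)
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(t)]))
        fit_cfg = cfg.fit
        if hyperparams is not None and int(t) in hyperparams:
            sig, lam = hyperparams[int(t)]
            fit_cfg = replace(
                fit_cfg, sigma_grid=(sig,), sigma_scale="absolute", lambda_grid=(lam,)
            )
        model, ratios = fit_ratio_model(Yp, Yq, fit_cfg, rng=rng)
        value = score_fn(ratios)
        if cfg.symmetric:
            rng_b = np.random.default_rng(np.random.SeedSequence([seed, int(t), 1]))
            _, ratios_b = fit_ratio_model(Yq, Yp, fit_cfg, rng=rng_b)
            value += score_fn(ratios_b)
        scores[i] = value
        chosen[int(t)] = (model.sigma, model.lam)
        logger.debug("t=%d score=%.6g sigma=%.4g lam=%.4g", t, value, model.sigma, model.lam)
    result = ScoreSeries(t=t_values, score=scores, method=cfg.method, alpha=cfg.alpha, config=cfg)
    if return_hyperparams:
        return result, chosen
    return result


def detect_candidates(
    scores: ScoreSeries,
    eta: float = 0.9,
    min_gap: int = 1,
    mode: str = "maxfrac",
    score_floor: Optional[float] = None,
) -> ChangePointSet:
    """Threshold the score series into candidate runs and peak times.

    tau = eta * max(score) ("maxfrac", the default) or the empirical
    eta-quantile ("quantile").  Maximal runs of consecutive evaluated
    points with score >= tau become candidates; runs separated by fewer
    than ``min_gap`` sub-threshold points are merged; each run reports its
    argmax time (earliest on ties).

    Fraction-of-max thresholding always flags at least one candidate, even
    on stationary data — a `ThresholdWarning` says so on every call unless
    an absolute ``score_floor`` is supplied.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must lie in (0, 1)")
    s = scores.score
    t = scores.t
    if mode == "maxfrac":
        tau = eta * float(np.max(s))
        if score_floor is None:
            warnings.warn(
                "fraction-of-max thresholding always yields at least one candidate, "
                "even on stationary data; set score_floor to require a minimum score",
                ThresholdWarning,
                stacklevel=2,
            )
    elif mode == "quantile":
        tau = float(np.quantile(s, eta))
    else:
        raise ValueError("mode must be 'maxfrac' or 'quantile'")

    above = s >= tau
    if above.all():
        logger.warning("all %d scores are at or above the threshold: single run spans everything", s.size)
    # maximal runs of consecutive above-threshold indices
    runs: list[list[int]] = []
    idx = np.flatnonzero(above)
    for i in idx:
        if runs and i == runs[-1][-1] + 1:
            runs[-1][-1] = i
        else:
            runs.append([i, i])
    # merge runs separated by fewer than min_gap sub-threshold points
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] - 1 < min_gap:
            merged[-1][-1] = run[-1]
        else:
            merged.append(run)
    candidates = []
    for start, end in merged:
        seg = s[start : end + 1]
        peak = start + int(np.argmax(seg))
        cand = Candidate(
            peak_time=int(t[peak]),
            peak_score=float(s[peak]),
            run_start=int(t[start]),
            run_end=int(t[end]),
        )
        if score_floor is not None and cand.peak_score < score_floor:
            continue
        candidates.append(cand)
    return ChangePointSet(candidates=tuple(candidates), threshold=tau, eta=eta, mode=mode)
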