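"""Random covariate subsampling for high-dimensional change-point detection.

In omics-style matrices only a small fraction of covariates shift at a
change point, and a single full-matrix run dilutes that signal.  Here the
detection pipeline is run many times on small random covariate subsets;
each iteration's candidate runs increment a per-time-point frequency
counter, and the per-iteration score series are averaged.  Time intervals
of high frequency are reported as change-point intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .pipeline import (
    ChangePointSet,
    CPDConfig,
    ThresholdWarning,
    TimeSeriesMatrix,
    detect_candidates,
    score_series,
)

logger = logging.getLogger(__name__)

__all__ = ["SamplingConfig", "SamplingResult", "Interval", "run_random_sampling", "frequency_intervals"]


@dataclass(frozen=True)
class SamplingConfig:
    """Settings for the covariate-subsampling ensemble.

    ``subset_size`` is either a fixed covariate count or an inclusive
    (low, high) range sampled uniformly per iteration.  ``count_mode``
    decides what increments the frequency histogram: every time point in a
    candidate run ("run", the default — the per-iteration candidates are
    interval-shaped) or only the run's peak ("peak").  With
    ``reuse_hyperparams`` cross-validation runs only on the first
    iteration and the selected (sigma, lambda) per reference point are
    reused afterwards.
    """

    n_samples: int = 300
    subset_size: Union[int, tuple[int, int]] = (3, 5)
    base: CPDConfig = None
    seed: int = 0
    interval_gamma: float = 0.5
    count_mode: str = "run"
    reuse_hyperparams: bool = False
    keep_scores: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.count_mode not in ("run", "peak"):
            raise ValueError("count_mode must be 'run' or 'peak'")
        if not 0.0 < self.interval_gamma <= 1.0:
            raise ValueError("interval_gamma must lie in (0, 1]")
        ss = self.subset_size
        if isinstance(ss, int):
            if ss < 1:
                raise ValueError("subset_size must be >= 1")
        else:
            lo, hi = ss
            if not (1 <= lo <= hi):
                raise ValueError("subset_size range must satisfy 1 <= low <= high")
            object.__setattr__(self, "subset_size", (int(lo), int(hi)))
        if self.base is None:
            object.__setattr__(self, "base", CPDConfig())


@dataclass(frozen=True)
class Interval:
    start_t: int
    end_t: int
    peak_frequency: int


@dataclass(frozen=True)
class SamplingResult:
    """Aggregated output of the subsampling ensemble."""

    t: np.ndarray
    frequency: np.ndarray
    mean_score: np.ndarray
    per_iteration: tuple[ChangePointSet, ...]
    intervals: tuple[Interval, ...]
    n_samples: int
    per_iteration_scores: Optional[tuple[np.ndarray, ...]] = None


def frequency_intervals(
    t: np.ndarray, frequency: np.ndarray, gamma: float = 0.5
) -> tuple[Interval, ...]:
    """Maximal runs of consecutive points with frequency >= gamma * max frequency.

    Sorted by peak frequency, descending (ties keep temporal order).
    All-zero frequencies yield an empty tuple.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    t = np.asarray(t, dtype=int)
    frequency = np.asarray(frequency)
    if t.size == 0 or t.size != frequency.size:
        raise ValueError("t and frequency must be non-empty and of equal length")
    fmax = frequency.max()
    if fmax <= 0:
        return ()
    above = frequency >= gamma * fmax
    intervals: list[Interval] = []
    start = None
    for i in range(t.size + 1):
        if i < t.size and above[i]:
            if start is None:
                start = i
        elif start is not None:
            peak = int(frequency[start:i].max())
            intervals.append(Interval(int(t[start]), int(t[i - 1]), peak))
            start = None
    intervals.sort(key=lambda iv: -iv.peak_frequency)
    return tuple(intervals)


def run_random_sampling(series: TimeSeriesMatrix, cfg: SamplingConfig) -> SamplingResult:
    """Run the detection pipeline on ``n_samples`` random covariate subsets.

    Every iteration draws its covariate subset (and, for a ranged
    ``subset_size``, the subset size) without replacement from an RNG
    stream derived from the master seed and the iteration counter, so
    results are reproducible and independent of execution order.
    """
    d = series.d
    ss = cfg.subset_size
    max_size = ss if isinstance(ss, int) else ss[1]
    if max_size > d:
        raise ValueError(f"subset_size {ss} exceeds the number of covariates d={d}")

    frequency = None
    score_sum = None
    t_grid = None
    per_iteration: list[ChangePointSet] = []
    kept_scores: list[np.ndarray] = []
    reused: Optional[dict[int, tuple[float, float]]] = None

    for it in range(cfg.n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, it]))
        size = ss if isinstance(ss, int) else int(rng.integers(ss[0], ss[1] + 1))
        subset = np.sort(rng.choice(d, size=size, replace=False))
        sub = series.select_covariates(subset)
        it_seed = int(rng.integers(0, 2**31 - 1))
        if cfg.reuse_hyperparams and reused is not None:
            scores = score_series(sub, cfg.base, seed=it_seed, hyperparams=reused)
        elif cfg.reuse_hyperparams:
            scores, reused = score_series(sub, cfg.base, seed=it_seed, return_hyperparams=True)
        else:
            scores = score_series(sub, cfg.base, seed=it_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ThresholdWarning)
            cps = detect_candidates(
                scores,
                eta=cfg.base.eta,
                min_gap=cfg.base.min_gap,
                mode=cfg.base.threshold_mode,
                score_floor=cfg.base.score_floor,
            )
        per_iteration.append(cps)

        if frequency is None:
            t_grid = scores.t
            frequency = np.zeros(t_grid.size, dtype=int)
            score_sum = np.zeros(t_grid.size)
        score_sum += scores.score
        if cfg.keep_scores:
            kept_scores.append(scores.score.copy())
        hit = np.zeros(t_grid.size, dtype=bool)
        for cand in cps.candidates:
            if cfg.count_mode == "run":
                hit |= (t_grid >= cand.run_start) & (t_grid <= cand.run_end)
            else:
                hit |= t_grid == cand.peak_time
        frequency += hit
        logger.info("iteration %d/%d: %d candidate run(s)", it + 1, cfg.n_samples, len(cps.candidates))

    mean_score = score_sum / cfg.n_samples
    intervals = frequency_intervals(t_grid, frequency, cfg.interval_gamma)
    return SamplingResult(
        t=t_grid,
        frequency=frequency,
        mean_score=mean_score,
        per_iteration=tuple(per_iteration),
        intervals=intervals,
        n_samples=cfg.n_samples,
        per_iteration_scores=tuple(kept_scores) if cfg.keep_scores else None,
    )
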