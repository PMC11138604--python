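"""Seeded synthetic benchmarks with known change points.

Three generators:

* ``gen_gaussian_segments`` — a univariate piecewise-Gaussian signal with
  four length-100 regimes N(0,1), N(10,1), N(-5,1), N(10,1), so the mean
  changes at times 101, 201 and 301.
* ``gen_ar2`` — an AR(2) process y_t = 0.6 y_{t-1} - 0.5 y_{t-2} + e_t
  with e_t ~ N(mu_t, 1) whose noise mean climbs by 2 every 100 steps,
  giving nine change points over T = 1000.
* ``gen_highdim`` — an omics-like matrix where only a small, seeded
  fraction of covariates undergoes mean shifts at shared change times
  while the rest stay i.i.d. noise.

All generators are bit-reproducible under a fixed seed and do not touch
the global NumPy RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pipeline import TimeSeriesMatrix

__all__ = ["GroundTruth", "gen_gaussian_segments", "gen_ar2", "gen_highdim"]


@dataclass(frozen=True)
class GroundTruth:
    """True change points: 1-based times at which the new regime's first sample appears."""

    change_times: tuple[int, ...]
    description: dict

    def __post_init__(self) -> None:
        ct = tuple(int(t) for t in self.change_times)
        object.__setattr__(self, "change_times", ct)
        if any(b <= a for a, b in zip(ct, ct[1:])):
            raise ValueError("change_times must be strictly increasing")
        if ct and ct[0] <= 1:
            raise ValueError("change_times must be > 1")


def gen_gaussian_segments(
    seed: int = 0,
    means: tuple[float, ...] = (0.0, 10.0, -5.0, 10.0),
    sd: float = 1.0,
    segment_length: int = 100,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """Piecewise-Gaussian univariate signal; defaults give T=400 with changes at 101/201/301."""
    rng = np.random.default_rng(seed)
    segments = [rng.normal(mu, sd, size=segment_length) for mu in means]
    values = np.concatenate(segments)[:, None]
    series = TimeSeriesMatrix(values=values, covariate_names=("y",))
    change_times = tuple(i * segment_length + 1 for i in range(1, len(means)))
    truth = GroundTruth(
        change_times=change_times,
        description={
            "kind": "gaussian_segments",
            "means": list(means),
            "sd": sd,
            "segment_length": segment_length,
        },
    )
    return series, truth


def gen_ar2(
    seed: int = 0,
    n_segments: int = 10,
    segment_length: int = 100,
    coeffs: tuple[float, float] = (0.6, -0.5),
    mean_step: float = 2.0,
    noise_sd: float = 1.0,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """AR(2) with staircase noise mean; defaults give T=1000 with changes at 101, 201, ..., 901.

    y_1 = y_2 = 0 and noise is injected from t = 3 on.  The noise mean is
    mu_t = mean_step * floor((t-1)/segment_length), i.e. it accumulates by
    ``mean_step`` at the start of each new segment (reaching 18 in the last
    one under the defaults).  The AR polynomial with coefficients
    (0.6, -0.5) has roots inside the unit circle, so each segment is a
    stationary process around level mu / (1 - 0.6 + 0.5).
    """
    rng = np.random.default_rng(seed)
    T = n_segments * segment_length
    a1, a2 = coeffs
    y = np.zeros(T)
    mu = mean_step * (np.arange(T) // segment_length).astype(float)
    eps = mu + noise_sd * rng.standard_normal(T)
    for t in range(2, T):
        y[t] = a1 * y[t - 1] + a2 * y[t - 2] + eps[t]
    series = TimeSeriesMatrix(values=y[:, None], covariate_names=("y",))
    change_times = tuple(n * segment_length + 1 for n in range(1, n_segments))
    truth = GroundTruth(
        change_times=change_times,
        description={
            "kind": "ar2",
            "coeffs": list(coeffs),
            "mean_step": mean_step,
            "noise_sd": noise_sd,
            "segment_length": segment_length,
        },
    )
    return series, truth


def gen_highdim(
    T: int = 100,
    d: int = 200,
    frac_changing: float = 0.05,
    change_times: tuple[int, ...] = (26, 51, 76),
    shift: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """High-dimensional matrix in which only a few covariates shift at shared change times.

    ceil(frac_changing * d) covariates (a seeded choice) gain a mean shift
    of +/- ``shift`` — the sign drawn once per covariate — at every change
    time, accumulating across changes; all other covariates stay i.i.d.
    N(0, noise_sd^2).  Changes are synchronous across the changing subset.
    """
    if not 0.0 < frac_changing <= 1.0:
        raise ValueError("frac_changing must lie in (0, 1]")
    for ct in change_times:
        if not 1 < ct <= T:
            raise ValueError(f"change time {ct} outside (1, T]")
    rng = np.random.default_rng(seed)
    n_change = math.ceil(frac_changing * d)
    changing = np.sort(rng.choice(d, size=n_change, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_change)
    values = rng.normal(0.0, noise_sd, size=(T, d))
    for ct in sorted(change_times):
        values[ct - 1 :, changing] += signs * shift
    names = tuple(f"g{j + 1}" for j in range(d))
    series = TimeSeriesMatrix(values=values, covariate_names=names)
    truth = GroundTruth(
        change_times=tuple(sorted(int(c) for c in change_times)),
        description={
            "kind": "highdim",
            "frac_changing": frac_changing,
            "shift": shift,
            "noise_sd": noise_sd,
            "changing_covariates": [int(j) for j in changing],
        },
    )
    return series, truth
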