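"""Bootstrap percentile confidence intervals for group-level statistics.

The group-level MSE of a factor model is a mean over per-participant MSE
values; its sampling variability is estimated non-parametrically by
resampling participants with replacement at full sample size, recomputing
the mean for each replicate, and taking the 2.5th and 97.5th percentiles of
the replicate distribution (10,000 replicates by default).  Percentiles use
numpy's linear interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BootstrapResult", "bootstrap_mean_ci"]


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def bootstrap_mean_ci(
    values: np.ndarray,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap CI for the mean of ``values``.

    Deterministic given ``seed``.  Resampling is chunked so that large
    (reps x n) index arrays never materialize at once.
    """
    values = np.asarray(values, float).ravel()
    n = values.size
    if n == 0:
        raise ValueError("cannot bootstrap an empty vector")
    rng = np.random.default_rng(seed)
    means = np.empty(reps)
    chunk = max(1, min(reps, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        idx = rng.integers(0, n, size=(b, n))
        means[done : done + b] = values[idx].mean(axis=1)
        done += b
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(float(values.mean()), float(lo), float(hi), reps, seed)
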