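"""Group-level summaries: score correlations and performance by subgroup.

Convergent validity between the two assessments is summarized by the
correlation between each participant's per-test accuracies, with a 95% CI
from the Fisher z-transform: z = atanh(r), SE = 1/sqrt(n - 3), interval
tanh(z +/- 1.96 SE).  Group summaries report mean accuracy and the standard
error of the mean per subgroup (sample group, or number of prior math
courses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "score_correlation", "group_means"]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.ci_low <= self.rho <= self.ci_high <= 1 + 1e-12):
            raise ValueError("correlation/CI ordering violated")


def score_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two score vectors with a Fisher-z 95% CI.

    ``method`` is "pearson" or "spearman" (for spearman the CI is the
    Fisher-z interval applied to the rank correlation, a standard
    large-sample approximation).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("score vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        rho = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        rho = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    # Fisher z interval; degenerate at |rho| = 1
    if abs(rho) >= 1.0:
        lo = hi = rho
    else:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return CorrelationResult(rho, float(lo), float(hi), n, method)


def group_means(scores: np.ndarray, grouping) -> pd.DataFrame:
    """Mean and SEM of ``scores`` per level of ``grouping``.

    Returns a tidy frame (group, mean, sem, n) with groups in sorted order.
    SEM uses the sample SD (ddof=1); a singleton group has SEM NaN.
    """
    scores = np.asarray(scores, float)
    grouping = np.asarray(grouping)
    if scores.shape[0] != grouping.shape[0]:
        raise ValueError("scores and grouping must align")
    df = pd.DataFrame({"group": grouping, "score": scores})
    if (df.groupby("group").size() == 0).any():  # pragma: no cover
        raise ValueError("empty group")
    out = (
        df.groupby("group")["score"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="size")
        .reset_index()
        .sort_values("group", kind="stable")
        .reset_index(drop=True)
    )
    return out
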