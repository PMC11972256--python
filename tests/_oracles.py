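"""Independent numerical oracles used by the test suite.

These stay deliberately naive (dense grids, explicit normal equations) so
they share no code path with the implementations they check.
"""

import numpy as np


def trapezoid_marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    grid: int = 20_001,
    width: float = 12.0,
) -> float:
    """Random-intercept logistic marginal log-likelihood by brute trapezoid."""
    us = np.linspace(-width * sigma, width * sigma, grid)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        eta = (X[sel] @ beta)[:, None] + us[None, :]
        lp = np.where(
            y[sel][:, None] > 0.5,
            -np.logaddexp(0.0, -eta),
            -np.logaddexp(0.0, eta),
        ).sum(axis=0)
        dens = np.exp(lp) * np.exp(-0.5 * (us / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi)
        )
        total += np.log(np.trapezoid(dens, us))
    return total


def normal_equation_scores(L: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Least-squares factor scores by explicitly formed normal equations."""
    return np.linalg.solve(L.T @ L, L.T @ Xc)
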