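"""Idealized and latent factor models of the binary error matrix.

Every model here is a low-rank account of the centered error matrix,

    X - mu = L F + eps

with X the m x n items-by-participants error matrix, mu the per-item error
means, L an m x f loading matrix, F an f x n matrix of per-participant
factor scores and eps residual error.  Two families are compared:

* **Idealized models** fix L up front as the binary indicator matrix of an
  item taxonomy — test membership (f=2), question type (f=11) or graph type
  (f=13) for the combined instrument — and estimate only the factor scores,
  per participant, by least squares.  For disjoint indicator loadings the
  least-squares score is simply the participant's mean centered error
  within each category.
* **The latent model** estimates L itself by Gaussian maximum-likelihood
  factor analysis (participants as observations, items as variables), with
  the number of factors selected by BIC.  Its predictive MSE is measured
  out-of-sample by five-fold cross-validation over participants: L and mu
  come from the training folds, held-out scores are estimated with that
  training L, and MSE is assembled from held-out predictions only.

Model quality is each participant's mean (or summed) squared prediction
error across items, averaged over participants into a group-level MSE;
confidence intervals come from the bootstrap over participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .item_bank import AssessmentBank, facet_labels
from .resampling import bootstrap_mean_ci
from .scoring import ErrorMatrix

__all__ = [
    "LoadingMatrix",
    "FactorScores",
    "LatentFaFit",
    "MseSummary",
    "center",
    "idealized_loading",
    "estimate_factor_scores",
    "fit_latent_fa",
    "select_n_factors",
    "predict_responses",
    "mse_summary",
    "make_folds",
    "cv_latent_mse",
    "cv_idealized_mse",
    "compare_factor_models",
    "varimax",
]

IDEALIZED_KINDS = {
    "idealized_test": "test",
    "idealized_question": "question_type",
    "idealized_graph": "graph_type",
}
_UNIQUENESS_FLOOR = 1e-3


@dataclass
class LoadingMatrix:
    L: np.ndarray
    kind: str  # idealized_test / idealized_question / idealized_graph / latent
    factor_labels: list[str]

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, float)
        if self.L.ndim != 2 or self.L.shape[1] != len(self.factor_labels):
            raise ValueError("loading matrix shape does not match labels")
        if self.kind in IDEALIZED_KINDS:
            binary = np.isin(self.L, (0.0, 1.0)).all()
            one_hot = np.all(self.L.sum(axis=1) == 1.0)
            if not (binary and one_hot):
                raise ValueError(
                    "idealized loadings must be binary with exactly one 1 per row"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


@dataclass
class FactorScores:
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, float)


@dataclass
class LatentFaFit:
    """Gaussian ML factor-analysis fit of the centered error matrix."""

    L: np.ndarray
    uniquenesses: np.ndarray
    loglik: float
    bic: float
    n_factors: int
    n_obs: int
    converged: bool = True

    def loading_matrix(self) -> LoadingMatrix:
        labels = [f"factor_{k + 1}" for k in range(self.n_factors)]
        return LoadingMatrix(self.L, "latent", labels)


@dataclass
class MseSummary:
    per_participant: np.ndarray
    mode: str = "mean_per_item"
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        self.per_participant = np.asarray(self.per_participant, float)
        if (self.per_participant < 0).any():
            raise ValueError("squared errors cannot be negative")

    @property
    def group_mse(self) -> float:
        return float(self.per_participant.mean())


# ---------------------------------------------------------------------------
# Centering and idealized loadings.
# ---------------------------------------------------------------------------

def center(matrix: ErrorMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center the error matrix; returns (Xc, mu)."""
    X = matrix.X if isinstance(matrix, ErrorMatrix) else np.asarray(matrix, float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 participants to center")
    mu = X.mean(axis=1)
    return X - mu[:, None], mu


def idealized_loading(bank: AssessmentBank, facet: str) -> LoadingMatrix:
    """Binary indicator loadings for an item taxonomy.

    ``facet`` is one of test / question_type / graph_type; row i carries a
    single 1 in the column of item i's category, columns in canonical label
    order (labels absent from the bank are dropped).
    """
    kind = {v: k for k, v in IDEALIZED_KINDS.items()}.get(facet)
    if kind is None:
        raise ValueError(f"unknown facet {facet!r}")
    labels = facet_labels(bank, facet)
    col = {lab: j for j, lab in enumerate(labels)}
    L = np.zeros((len(bank), len(labels)))
    for i, item in enumerate(bank):
        L[i, col[getattr(item, facet)]] = 1.0
    return LoadingMatrix(L, kind, labels)


def estimate_factor_scores(
    L: LoadingMatrix | np.ndarray, Xc: np.ndarray
) -> FactorScores:
    """Least-squares factor scores: F minimizing ||Xc - L F||_F column-wise."""
    Lm = L.L if isinstance(L, LoadingMatrix) else np.asarray(L, float)
    if Lm.shape[1] == 0:
        return FactorScores(np.zeros((0, Xc.shape[1])))
    if np.linalg.matrix_rank(Lm) < Lm.shape[1]:
        raise ValueError("loading matrix is rank deficient")
    F, *_ = np.linalg.lstsq(Lm, Xc, rcond=None)
    return FactorScores(F)


# ---------------------------------------------------------------------------
# Latent factor analysis (Gaussian ML) and BIC selection.
# ---------------------------------------------------------------------------

def _gaussian_fa_loglik(S: np.ndarray, L: np.ndarray, psi: np.ndarray, n: int) -> float:
    """Exact Gaussian log-likelihood of zero-mean data with cov LL' + diag(psi).

    Computed from the model covariance, so it is exactly invariant to
    orthogonal rotation of L.
    """
    m = S.shape[0]
    sigma = L @ L.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:  # pragma: no cover - psi floor prevents this
        raise np.linalg.LinAlgError("model covariance not positive definite")
    trace = float(np.trace(np.linalg.solve(sigma, S)))
    return -0.5 * n * (m * np.log(2.0 * np.pi) + logdet + trace)


def fa_free_params(m: int, f: int) -> int:
    """Free parameters of an m-variable, f-factor model (rotation removed)."""
    return m * f + m - f * (f - 1) // 2


def fit_latent_fa(
    Xc: np.ndarray, f: int, max_iter: int = 1000, tol: float = 1e-6
) -> LatentFaFit:
    """Gaussian ML factor analysis of the centered matrix with ``f`` factors.

    Participants (columns of Xc) are treated as observations and items as
    variables.  The EM estimator is deterministic given the data (LAPACK
    SVD, constant initialization).  Uniquenesses are floored at 1e-3 with a
    warning when the optimizer drives one to the boundary (Heywood case).
    ``f = 0`` is the means-only baseline (diagonal covariance).
    """
    Xc = np.asarray(Xc, float)
    m, n = Xc.shape
    if f < 0 or f >= m:
        raise ValueError("need 0 <= f < number of items")
    if n <= f:
        raise ValueError("need more participants than factors")
    S = (Xc @ Xc.T) / n
    if f == 0:
        psi = np.maximum(np.diag(S).copy(), _UNIQUENESS_FLOOR)
        L = np.zeros((m, 0))
        ll = _gaussian_fa_loglik(S, L, psi, n)
        return LatentFaFit(L, psi, ll, -2 * ll + fa_free_params(m, 0) * np.log(n), 0, n)
    fa = FactorAnalysis(
        n_components=f, svd_method="lapack", max_iter=max_iter, tol=tol
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence warnings handled below
        fa.fit(Xc.T)
    converged = fa.n_iter_ < max_iter
    L = fa.components_.T  # (m, f)
    psi = fa.noise_variance_.copy()
    if (psi < _UNIQUENESS_FLOOR).any():
        warnings.warn(
            "Heywood case: uniquenesses floored at 1e-3", RuntimeWarning, stacklevel=2
        )
        psi = np.maximum(psi, _UNIQUENESS_FLOOR)
    ll = _gaussian_fa_loglik(S, L, psi, n)
    bic = -2.0 * ll + fa_free_params(m, f) * np.log(n)
    return LatentFaFit(L, psi, ll, bic, f, n, converged)


def select_n_factors(
    Xc: np.ndarray, f_range, **fit_kwargs
) -> tuple[int, pd.DataFrame]:
    """BIC curve over ``f_range``; best f = smallest f attaining min BIC."""
    f_range = list(f_range)
    if not f_range:
        raise ValueError("f_range is empty")
    rows = []
    for f in f_range:
        fit = fit_latent_fa(Xc, f, **fit_kwargs)
        rows.append({"f": f, "bic": fit.bic, "loglik": fit.loglik,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    best_f = int(table.loc[table["bic"] == best_bic, "f"].min())
    return best_f, table


# ---------------------------------------------------------------------------
# Prediction and MSE.
# ---------------------------------------------------------------------------

def predict_responses(
    L: LoadingMatrix | np.ndarray,
    F: FactorScores | np.ndarray,
    mu: np.ndarray,
    clip: bool = False,
) -> np.ndarray:
    """Model prediction mu + L F, optionally clipped into [0, 1]."""
    Lm = L.L if isinstance(L, LoadingMatrix) else np.asarray(L, float)
    Fm = F.F if isinstance(F, FactorScores) else np.asarray(F, float)
    mu = np.asarray(mu, float)
    if Lm.shape[1] != Fm.shape[0] or Lm.shape[0] != mu.shape[0]:
        raise ValueError("incompatible shapes for prediction")
    pred = mu[:, None] + Lm @ Fm
    return np.clip(pred, 0.0, 1.0) if clip else pred


def mse_summary(
    X: ErrorMatrix | np.ndarray,
    predicted: np.ndarray,
    mode: str = "mean_per_item",
) -> MseSummary:
    """Per-participant squared prediction error, mean or summed over items."""
    Xm = X.X if isinstance(X, ErrorMatrix) else np.asarray(X, float)
    predicted = np.asarray(predicted, float)
    if Xm.shape != predicted.shape:
        raise ValueError("observed and predicted shapes differ")
    sq = (Xm - predicted) ** 2
    if mode == "mean_per_item":
        per = sq.mean(axis=0)
    elif mode == "sum_over_items":
        per = sq.sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MseSummary(per, mode=mode)


# ---------------------------------------------------------------------------
# Cross-validation.
# ---------------------------------------------------------------------------

def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded fold membership for n participants: a length-n integer array.

    Participants are randomly permuted and dealt into k nearly equal folds;
    the remainder is spread across the first folds.
    """
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    membership = np.empty(n, dtype=int)
    start = 0
    for fold, size in enumerate(sizes):
        membership[perm[start : start + size]] = fold
        start += size
    return membership


def _cv_mse(
    X: np.ndarray,
    fit_loadings,
    k: int,
    seed: int,
    mode: str,
    min_train: int,
) -> MseSummary:
    n = X.shape[1]
    membership = make_folds(n, k, seed)
    per = np.empty(n)
    for fold in range(k):
        test = membership == fold
        train = ~test
        if train.sum() < min_train:
            raise ValueError(f"fold {fold}: too few training participants")
        mu_train = X[:, train].mean(axis=1)
        L = fit_loadings(X[:, train] - mu_train[:, None])
        Xc_test = X[:, test] - mu_train[:, None]
        F_test = estimate_factor_scores(L, Xc_test)
        pred = predict_responses(L, F_test, mu_train)
        per[test] = mse_summary(X[:, test], pred, mode=mode).per_participant
    return MseSummary(per, mode=mode)


def cv_latent_mse(
    X: ErrorMatrix | np.ndarray,
    f: int,
    k: int = 5,
    seed: int = 0,
    mode: str = "mean_per_item",
) -> MseSummary:
    """Held-out MSE of the f-factor latent model under k-fold CV.

    For each fold the loading matrix and item means come from the training
    participants only; held-out factor scores are least-squares estimates
    against that training loading matrix.
    """
    Xm = X.X if isinstance(X, ErrorMatrix) else np.asarray(X, float)

    def fit_loadings(Xc_train: np.ndarray) -> np.ndarray:
        return fit_latent_fa(Xc_train, f).L

    return _cv_mse(Xm, fit_loadings, k, seed, mode, min_train=f + 1)


def cv_idealized_mse(
    X: ErrorMatrix | np.ndarray,
    bank: AssessmentBank,
    facet: str,
    k: int = 5,
    seed: int = 0,
    mode: str = "mean_per_item",
) -> MseSummary:
    """Cross-validated MSE for an idealized model (optional; L is fixed)."""
    Xm = X.X if isinstance(X, ErrorMatrix) else np.asarray(X, float)
    L = idealized_loading(bank, facet)
    return _cv_mse(Xm, lambda Xc: L.L, k, seed, mode, min_train=2)


def idealized_mse(
    X: ErrorMatrix | np.ndarray,
    bank: AssessmentBank,
    facet: str,
    mode: str = "mean_per_item",
) -> MseSummary:
    """In-sample MSE of an idealized model (scores fit on the full data)."""
    Xm = X.X if isinstance(X, ErrorMatrix) else np.asarray(X, float)
    Xc, mu = center(Xm)
    L = idealized_loading(bank, facet)
    F = estimate_factor_scores(L, Xc)
    pred = predict_responses(L, F, mu)
    return mse_summary(Xm, pred, mode=mode)


# ---------------------------------------------------------------------------
# The model comparison.
# ---------------------------------------------------------------------------

def compare_factor_models(
    X: ErrorMatrix | np.ndarray,
    bank: AssessmentBank,
    f_latent: int,
    seed: int = 0,
    mode: str = "mean_per_item",
    k: int = 5,
    bootstrap_reps: int = 10_000,
    cv_idealized: bool = False,
) -> pd.DataFrame:
    """Compare idealized (test / question / graph) and latent factor models.

    Idealized models are scored in-sample by default (``cv_idealized=True``
    cross-validates them too); the latent model is always cross-validated.
    Returns a frame (model, n_factors, group_mse, ci_low, ci_high) with
    percentile-bootstrap CIs over participants.
    """
    Xm = X.X if isinstance(X, ErrorMatrix) else np.asarray(X, float)
    rows = []
    for model, facet in IDEALIZED_KINDS.items():
        if cv_idealized:
            s = cv_idealized_mse(Xm, bank, facet, k=k, seed=seed, mode=mode)
        else:
            s = idealized_mse(Xm, bank, facet, mode=mode)
        f = len(facet_labels(bank, facet))
        rows.append((model, f, s))
    s_latent = cv_latent_mse(Xm, f_latent, k=k, seed=seed, mode=mode)
    rows.append(("latent", f_latent, s_latent))

    out = []
    for i, (model, f, s) in enumerate(rows):
        boot = bootstrap_mean_ci(
            s.per_participant, reps=bootstrap_reps, seed=seed + 7919 * (i + 1)
        )
        out.append(
            dict(model=model, n_factors=f, group_mse=s.group_mse,
                 ci_low=boot.ci_low, ci_high=boot.ci_high, mode=mode)
        )
    return pd.DataFrame(out)


def varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Varimax-rotated loadings, for interpretive heatmaps only.

    Predictions and likelihoods are invariant to orthogonal rotation, so
    rotation is never applied on the modeling path.
    """
    L = np.asarray(L, float).copy()
    m, f = L.shape
    if f < 2:
        return L
    R = np.eye(f)
    var_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        grad = L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / m)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R
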