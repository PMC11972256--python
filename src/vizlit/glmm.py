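"""Random-intercept logistic regression and nested likelihood-ratio tests.

Item-level correctness y_ij in {0,1} for participant j on item i is modeled

    logit P(y_ij = 1) = x_ij' beta + u_j,      u_j ~ N(0, sigma_u^2)

with fixed effects for item taxonomy (graph type, question type, test) and
participant covariates (math coursework, sample group), and a random
intercept per participant absorbing overall ability differences.  The
marginal likelihood integrates the random intercept out of each
participant's response likelihood; the integral is approximated by adaptive
Gauss-Hermite quadrature (the integrand is recentred at its per-participant
mode and rescaled by its curvature before applying the Hermite rule; one
node recovers the Laplace approximation).  Estimation is straight maximum
likelihood on (beta, log sigma_u) with a quasi-Newton optimizer, so nested
fits are directly comparable by the likelihood-ratio chi-square.

Categorical predictors use treatment contrasts with the alphabetically first
level as reference; LRT results are invariant to that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "LrtResult",
    "build_design_matrix",
    "marginal_loglik",
    "fit_logistic_glmm",
    "lrt",
    "run_predictor_suite",
]

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_rule(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    if nodes not in _GH_CACHE:
        _GH_CACHE[nodes] = np.polynomial.hermite.hermgauss(nodes)
    return _GH_CACHE[nodes]


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: fixed-effect terms over a long design table.

    ``fixed_terms`` are column names of the design table; ``"a:b"`` denotes
    the interaction of two categorical terms.  The random intercept is
    always on ``random_intercept_unit`` (default "participant").
    """

    fixed_terms: tuple[str, ...] = ()
    random_intercept_unit: str = "participant"

    def __init__(self, fixed_terms=(), random_intercept_unit="participant"):
        object.__setattr__(self, "fixed_terms", tuple(fixed_terms))
        object.__setattr__(self, "random_intercept_unit", random_intercept_unit)


@dataclass
class GlmmFit:
    beta: np.ndarray
    beta_labels: list[str]
    sigma_u: float
    loglik: float
    converged: bool
    nodes: int
    n_obs: int
    n_groups: int
    spec: GlmmSpec | None = None
    beta_se: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # + log sigma_u

    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.beta_labels, name="beta")


@dataclass(frozen=True)
class LrtResult:
    chisq: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Design matrices: treatment contrasts, alphabetical reference level.
# ---------------------------------------------------------------------------

def _expand_term(design: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    col = design[term]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return col.to_numpy(float)[:, None], [term]
    levels = sorted(pd.unique(col.astype(str)))
    ref, rest = levels[0], levels[1:]
    vals = col.astype(str).to_numpy()
    cols = np.column_stack([(vals == lev).astype(float) for lev in rest]) if rest else np.empty((len(col), 0))
    return cols, [f"{term}[{lev}]" for lev in rest]


def build_design_matrix(
    design: pd.DataFrame, terms: tuple[str, ...] | list[str]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects matrix (with intercept) for ``terms``.

    Interactions ``"a:b"`` are products of the reduced dummy blocks of
    ``a`` and ``b``, giving the usual (l_a - 1)(l_b - 1) columns.
    """
    blocks = [np.ones((len(design), 1))]
    labels = ["(Intercept)"]
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            Xa, la = _expand_term(design, a)
            Xb, lb = _expand_term(design, b)
            cols = [
                Xa[:, i] * Xb[:, j]
                for i in range(Xa.shape[1])
                for j in range(Xb.shape[1])
            ]
            if cols:
                blocks.append(np.column_stack(cols))
                labels += [f"{na}:{nb}" for na in la for nb in lb]
        else:
            Xt, lt = _expand_term(design, term)
            if Xt.shape[1]:
                blocks.append(Xt)
                labels += lt
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular fixed-effects design for terms {tuple(terms)}"
        )
    return X, labels


# ---------------------------------------------------------------------------
# Marginal likelihood by adaptive Gauss-Hermite quadrature.
# ---------------------------------------------------------------------------

def _group_index(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=False)
    return codes.astype(np.intp), len(uniques)


def _posterior_modes(
    eta: np.ndarray, y: np.ndarray, idx: np.ndarray, n_g: int, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group mode and curvature of the joint log density in u.

    The objective is concave in u (Bernoulli-logit log-likelihood plus a
    Gaussian log prior), so undamped Newton converges; steps are clipped for
    safety at extreme linear predictors.
    """
    u = np.zeros(n_g)
    inv_var = 1.0 / (sigma * sigma)
    for _ in range(50):
        p = special.expit(eta + u[idx])
        grad = np.bincount(idx, weights=y - p, minlength=n_g) - u * inv_var
        hess = -np.bincount(idx, weights=p * (1.0 - p), minlength=n_g) - inv_var
        step = grad / hess
        np.clip(step, -5.0, 5.0, out=step)
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(eta + u[idx])
    hess = -np.bincount(idx, weights=p * (1.0 - p), minlength=n_g) - inv_var
    return u, hess


def _bernoulli_ll_by_group(
    eta_u: np.ndarray, y: np.ndarray, idx: np.ndarray, n_g: int
) -> np.ndarray:
    # log p(y | eta + u) summed within group; stable log-sigmoid form
    ll = -np.logaddexp(0.0, np.where(y > 0.5, -eta_u, eta_u))
    return np.bincount(idx, weights=ll, minlength=n_g)


def marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    beta: np.ndarray,
    sigma_u: float,
    nodes: int = 10,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    Integrates the per-participant random intercept by adaptive
    Gauss-Hermite quadrature with ``nodes`` points (1 = Laplace).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    idx, n_g = _group_index(groups)
    eta = X @ np.asarray(beta, float)
    sigma = max(float(sigma_u), 1e-8)
    z, w = _gh_rule(nodes)
    u_hat, hess = _posterior_modes(eta, y, idx, n_g, sigma)
    tau = 1.0 / np.sqrt(-hess)  # per-group rescale

    # h(u) = loglik(u) + log phi(u; 0, sigma^2); evaluate at adapted nodes
    log_prior_const = -0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    hvals = np.empty((nodes, n_g))
    for k in range(nodes):
        u_k = u_hat + np.sqrt(2.0) * tau * z[k]
        ll_g = _bernoulli_ll_by_group(eta + u_k[idx], y, idx, n_g)
        hvals[k] = ll_g + log_prior_const - 0.5 * (u_k / sigma) ** 2 + z[k] ** 2
    # l_g = log( sqrt(2) tau_g  sum_k w_k exp(h_k) )
    hmax = hvals.max(axis=0)
    s = np.einsum("k,kg->g", w, np.exp(hvals - hmax))
    lg = hmax + np.log(s) + 0.5 * np.log(2.0) + np.log(tau)
    return float(lg.sum())


# ---------------------------------------------------------------------------
# Fitting.
# ---------------------------------------------------------------------------

def fit_logistic_glmm(
    design: pd.DataFrame,
    spec: GlmmSpec,
    outcome: str = "correct",
    nodes: int = 10,
    tol: float = 1e-6,
    compute_se: bool = False,
    _ridge: float = 0.0,
) -> GlmmFit:
    """ML fit of a random-intercept logistic model on a long design table.

    ``design`` must contain the outcome column (binary), the random-effect
    unit column, and every fixed-effect term.  Returns ``converged=False``
    rather than raising when the optimizer stalls.  Complete separation
    (diverging fixed effects) triggers a warning and a lightly penalized
    refit.
    """
    y = design[outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    idx_col = design[spec.random_intercept_unit]
    if idx_col.nunique() < 2:
        raise ValueError("need at least 2 random-effect groups")
    X, labels = build_design_matrix(design, spec.fixed_terms)
    idx, n_g = _group_index(idx_col)
    p = X.shape[1]

    # Moment-based start: plain logistic GLM coefficients, modest sigma.
    beta0 = _logistic_glm_start(X, y)
    theta0 = np.concatenate([beta0, [np.log(0.5)]])

    def negll(theta: np.ndarray) -> float:
        beta, logs = theta[:p], theta[p]
        sigma = np.exp(logs)
        ll = marginal_loglik(X, y, idx, beta, sigma, nodes=nodes)
        if _ridge > 0.0:
            ll -= _ridge * float(beta[1:] @ beta[1:])
        return -ll

    bounds = [(-30.0, 30.0)] * p + [(-8.0, 3.0)]
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
    )
    beta_hat, logs_hat = res.x[:p], res.x[p]
    sigma_hat = float(np.exp(logs_hat))
    converged = bool(res.success) or res.status == 0

    if _ridge == 0.0 and np.max(np.abs(beta_hat)) > 15.0:
        warnings.warn(
            "possible complete separation: refitting with a small ridge penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        return fit_logistic_glmm(
            design, spec, outcome=outcome, nodes=nodes, tol=tol,
            compute_se=compute_se, _ridge=1e-3,
        )

    beta_se = None
    if compute_se:
        beta_se = _observed_information_se(negll, res.x)[:p]

    ll = marginal_loglik(X, y, idx, beta_hat, sigma_hat, nodes=nodes)
    return GlmmFit(
        beta=beta_hat,
        beta_labels=labels,
        sigma_u=sigma_hat,
        loglik=ll,
        converged=converged,
        nodes=nodes,
        n_obs=len(y),
        n_groups=n_g,
        spec=spec,
        beta_se=beta_se,
    )


def _observed_information_se(negll, theta: np.ndarray) -> np.ndarray:
    """Wald standard errors from a central-difference observed information."""
    q = len(theta)
    h = 1e-4 * (1.0 + np.abs(theta))
    H = np.empty((q, q))
    for a in range(q):
        for b in range(a, q):
            ea = np.zeros(q); ea[a] = h[a]
            eb = np.zeros(q); eb[b] = h[b]
            H[a, b] = H[b, a] = (
                negll(theta + ea + eb) - negll(theta + ea - eb)
                - negll(theta - ea + eb) + negll(theta - ea - eb)
            ) / (4.0 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(q, np.nan)
    return se


def _logistic_glm_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """A few IRLS steps of plain logistic regression for a warm start."""
    beta = np.zeros(X.shape[1])
    for _ in range(8):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-6)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = np.clip(beta_new, -10, 10)
    return beta


def lrt(null_fit: GlmmFit, alt_fit: GlmmFit) -> LrtResult:
    """Likelihood-ratio test of two nested fits on the same data.

    chisq is floored at 0 (finite-sample optimizer noise can make the
    richer model's log-likelihood infinitesimally smaller).
    """
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("fits are not on the same data")
    null_terms = set(null_fit.beta_labels)
    if not null_terms.issubset(set(alt_fit.beta_labels)):
        raise ValueError("null model is not nested in the alternative")
    df = alt_fit.n_params - null_fit.n_params
    if df < 0:
        raise ValueError("alternative has fewer parameters than the null")
    chisq = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else (1.0 if chisq == 0 else 0.0)
    return LrtResult(chisq, df, p)


# ---------------------------------------------------------------------------
# The predictor suite.
# ---------------------------------------------------------------------------

def make_design_table(matrix, bank, demographics: pd.DataFrame) -> pd.DataFrame:
    """Long table (participant, item, correct, item facets, covariates)."""
    from .scoring import ErrorMatrix  # local to avoid cycle at import time

    assert isinstance(matrix, ErrorMatrix)
    if list(matrix.item_order) != list(bank.item_ids):
        raise ValueError("matrix rows do not match bank order")
    m, n = matrix.shape
    demo = demographics.set_index(demographics["participant_id"].astype(str))
    missing = [p for p in matrix.participant_order if p not in demo.index]
    if missing:
        raise ValueError(f"demographics missing for participants {missing[:5]}")
    rows = {
        "participant": np.repeat(matrix.participant_order, m),
        "item": np.tile(matrix.item_order, n),
        "correct": (1.0 - matrix.X.T).ravel(),
        "test": np.tile([it.test for it in bank], n),
        "graph_type": np.tile([it.graph_type for it in bank], n),
        "question_type": np.tile([it.question_type for it in bank], n),
        "math_courses": np.repeat(
            demo.loc[matrix.participant_order, "math_courses"].astype(str).to_numpy(), m
        ),
        "sample_group": np.repeat(
            demo.loc[matrix.participant_order, "sample_group"].astype(str).to_numpy(), m
        ),
    }
    return pd.DataFrame(rows)


def run_predictor_suite(
    matrix,
    bank,
    demographics: pd.DataFrame,
    nodes: int = 10,
    per_test: bool = True,
) -> pd.DataFrame:
    """Nested LRTs for each predictor, overall and per test.

    Main effects are each compared against the intercept-only baseline
    (random intercept always included); ``predictor x sample_group``
    interactions are compared against the additive model containing both
    main effects.  Returns a frame (scope, effect, chisq, df, p,
    sigma_u_alt, converged).
    """
    table = make_design_table(matrix, bank, demographics)
    scopes: list[tuple[str, pd.DataFrame]] = [("combined", table)]
    if per_test:
        for t in sorted(table["test"].unique()):
            scopes.append((t, table[table["test"] == t].reset_index(drop=True)))

    rows = []

    def _fit(tab, terms):
        return fit_logistic_glmm(tab, GlmmSpec(terms), nodes=nodes)

    for scope, tab in scopes:
        effects = ["graph_type", "question_type", "math_courses", "sample_group"]
        if scope == "combined":
            effects.insert(2, "test")
        base = _fit(tab, ())
        fits: dict[tuple[str, ...], GlmmFit] = {(): base}
        for eff in effects:
            if tab[eff].nunique() < 2:
                continue
            alt = _fit(tab, (eff,))
            fits[(eff,)] = alt
            r = lrt(base, alt)
            rows.append(
                dict(scope=scope, effect=eff, chisq=r.chisq, df=r.df, p=r.p,
                     sigma_u_alt=alt.sigma_u, converged=alt.converged)
            )
        # predictor x sample_group interactions
        if tab["sample_group"].nunique() >= 2:
            for eff in effects:
                if eff == "sample_group" or tab[eff].nunique() < 2:
                    continue
                add = _fit(tab, (eff, "sample_group"))
                full = _fit(tab, (eff, "sample_group", f"{eff}:sample_group"))
                r = lrt(add, full)
                rows.append(
                    dict(scope=scope, effect=f"{eff}:sample_group", chisq=r.chisq,
                         df=r.df, p=r.p, sigma_u_alt=full.sigma_u,
                         converged=full.converged)
                )
    return pd.DataFrame(rows)
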