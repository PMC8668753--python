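"""Gamma GLM with log link, fitted by IRLS, plus AIC search and VIF screening.

Purpose-built for the foraging-range model: the response (minimum enclosing
circle diameter, km) is strictly positive and right-skewed, which the gamma
family with a log link handles naturally.  Categorical covariates are coded
by treatment contrasts against explicit reference levels; candidate two-way
interactions are searched exhaustively by AIC.

For gamma with log link the IRLS working weights are identically 1
(W = (dmu/deta)^2 / V(mu) = mu^2/mu^2), so each iteration is an ordinary
least-squares solve on the working response z = eta + (y - mu)/mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, gammaln


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _term_columns(df: pd.DataFrame, var: str, reference: str | None = None):
    """Treatment-coded columns for one variable (numeric passes through)."""
    col = df[var]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
        return {var: col.to_numpy(dtype=float)}
    levels = sorted(col.astype(str).unique())
    # the reference level need not appear in the data (e.g. prediction rows)
    ref = reference if reference is not None else levels[0]
    out = {}
    for lev in levels:
        if lev == ref:
            continue
        out[f"{var}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
    return out


def build_design(
    df: pd.DataFrame,
    terms: list[tuple[str, ...]],
    references: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for main effects and interactions.

    ``terms`` is a list of tuples: ``("age",)`` is a main effect,
    ``("age", "sex")`` a two-way interaction (product of the coded columns).
    An intercept column is always included first.
    """
    references = references or {}
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for term in terms:
        if len(term) == 1:
            cols.update(_term_columns(df, term[0], references.get(term[0])))
        elif len(term) == 2:
            c1 = _term_columns(df, term[0], references.get(term[0]))
            c2 = _term_columns(df, term[1], references.get(term[1]))
            for n1, v1 in c1.items():
                for n2, v2 in c2.items():
                    cols[f"{n1}:{n2}"] = v1 * v2
        else:
            raise ValueError(f"only main effects and two-way interactions supported, got {term}")
    names = list(cols)
    return np.column_stack([cols[n] for n in names]), names


# ---------------------------------------------------------------------------
# the GLM
# ---------------------------------------------------------------------------


@dataclass
class GammaGLMResult:
    coef: np.ndarray
    names: list[str]
    cov: np.ndarray  # dispersion * (X'X)^-1
    dispersion: float  # Pearson estimate
    shape_ml: float  # ML gamma shape used for the AIC
    loglik: float
    aic: float
    deviance: float
    n_iter: int
    terms: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.exp(X @ self.coef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "estimate": self.coef, "se": self.se})


def _gamma_shape_ml(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape given the fitted means.

    Solves ``log(alpha) - digamma(alpha) = mean(y/mu - log(y/mu) - 1)``.
    """
    r = y / mu
    c = float(np.mean(r - np.log(r)) - 1.0)
    if c <= 0:
        return 1e8  # essentially no dispersion
    f = lambda a: np.log(a) - digamma(a) - c
    lo, hi = 1e-6, 1e8
    # log(a)-digamma(a) is decreasing from +inf to 0, so a root is bracketed
    return float(brentq(f, lo, hi, maxiter=200))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    return float(
        np.sum(alpha * np.log(alpha * y / mu) - alpha * y / mu - np.log(y) - gammaln(alpha))
    )


def fit_gamma_glm(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GammaGLMResult:
    """Gamma GLM, log link, by IRLS.

    Raises ``RuntimeError`` with the iteration trace if IRLS fails to
    converge within ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    eta = np.log(np.clip(y, np.min(y[y > 0]), None))  # start at the saturated predictor
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    trace = []
    converged = False
    for it in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta_new = np.linalg.lstsq(X, z, rcond=None)[0]
        delta = float(np.max(np.abs(beta_new - beta)))
        trace.append(delta)
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations; trace={trace[-10:]}")
    mu = np.exp(X @ beta)
    resid_p = (y - mu) / mu
    dispersion = float(resid_p @ resid_p / (n - p))
    deviance = float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = dispersion * xtx_inv
    alpha = _gamma_shape_ml(y, mu)
    ll = _gamma_loglik(y, mu, alpha)
    aic = -2.0 * ll + 2.0 * (p + 1)  # +1 for the estimated shape
    return GammaGLMResult(beta, names, cov, dispersion, alpha, ll, aic, deviance, it + 1)


# ---------------------------------------------------------------------------
# multicollinearity screening and AIC model search
# ---------------------------------------------------------------------------


def variance_inflation(X: np.ndarray, names: list[str]) -> dict[str, float]:
    """VIF per non-intercept column: 1/(1 - R^2) against the other columns."""
    out = {}
    idx_all = list(range(X.shape[1]))
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        others = [k for k in idx_all if k != j]
        xj = X[:, j]
        fit = np.linalg.lstsq(X[:, others], xj, rcond=None)[0]
        resid = xj - X[:, others] @ fit
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        out[name] = np.inf if ss_res <= 1e-12 * max(ss_tot, 1.0) else ss_tot / ss_res
    return out


@dataclass
class ModelSearchResult:
    best: GammaGLMResult
    candidates: pd.DataFrame  # one row per candidate (terms, aic)
    vif: dict[str, float]
    vif_flags: list[str]


def search_interactions(
    df: pd.DataFrame,
    y: np.ndarray,
    main_effects: list[str],
    candidate_interactions: list[tuple[str, str]] | None = None,
    references: dict[str, str] | None = None,
    vif_threshold: float = 4.0,
    drop_flagged: bool = False,
) -> ModelSearchResult:
    """Exhaustive AIC search over subsets of two-way interactions.

    Main effects are always retained.  VIF is computed on the main-effects
    design; columns exceeding ``vif_threshold`` are flagged (and excluded
    from the interaction candidates only when ``drop_flagged``).
    """
    if candidate_interactions is None:
        candidate_interactions = list(combinations(main_effects, 2))
    X_main, main_names = build_design(df, [(m,) for m in main_effects], references)
    vif = variance_inflation(X_main, main_names)
    flags = [n for n, v in vif.items() if v > vif_threshold]
    if drop_flagged and flags:
        flagged_vars = {n.split("[")[0] for n in flags}
        candidate_interactions = [
            (a, b) for a, b in candidate_interactions
            if a not in flagged_vars and b not in flagged_vars
        ]

    rows = []
    best_fit, best_terms = None, None
    for r in range(len(candidate_interactions) + 1):
        for combo in combinations(candidate_interactions, r):
            terms = [(m,) for m in main_effects] + [tuple(c) for c in combo]
            X, names = build_design(df, terms, references)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # aliased interaction (e.g. empty cell)
            fit = fit_gamma_glm(X, y, names)
            fit.terms = terms
            rows.append({"interactions": "+".join(":".join(c) for c in combo) or "(none)",
                         "aic": fit.aic, "n_params": X.shape[1]})
            if best_fit is None or fit.aic < best_fit.aic:
                best_fit, best_terms = fit, terms
    if best_fit is None:
        raise RuntimeError("no candidate model had full column rank")
    return ModelSearchResult(best_fit, pd.DataFrame(rows), vif, flags)
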