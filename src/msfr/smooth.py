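"""Penalized B-spline regression with REML smoothness selection.

Supports the additive Gaussian model used for survey biomass surfaces:

    log(BPUE + delta) = intercept + f(depth) + g(lon, lat, year) + noise

``f`` is a univariate P-spline (cubic B-spline basis, second-difference
penalty); ``g`` is a tensor-product of marginal B-spline bases with one
difference penalty per margin, each carrying its own smoothing parameter.
Each smooth is sum-to-zero constrained so the intercept stays identifiable.
Smoothing parameters are chosen by minimising the Gaussian restricted
likelihood (REML) over log-lambdas; GCV is available as a fallback.

The fitted object exposes the coefficient vector and its Bayesian posterior
covariance ``sigma^2 (X'X + S)^-1``, which downstream code resamples to
propagate smoothing uncertainty into buffer-integrated availability indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize


def bspline_basis(x: np.ndarray, knots_interior: int, degree: int = 3,
                  domain: tuple[float, float] | None = None) -> tuple[np.ndarray, dict]:
    """Cubic B-spline design matrix with evenly spaced knots over ``domain``."""
    x = np.asarray(x, dtype=float)
    lo, hi = domain if domain is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, knots_interior + 2)
    t = np.concatenate([[lo] * degree, inner, [hi] * degree])
    spec = {"t": t, "degree": degree, "domain": (lo, hi)}
    return _eval_basis(x, spec), spec


def _eval_basis(x: np.ndarray, spec: dict) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), spec["domain"][0], spec["domain"][1])
    return BSpline.design_matrix(x, spec["t"], spec["degree"]).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _constrain(B: np.ndarray, S_list: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Absorb the sum-to-zero constraint 1'B beta = 0 into the basis.

    Returns the reduced basis, penalties, and the (p, p-1) transform Z with
    B_reduced = B Z, so new-coefficient objects map back via Z.
    """
    c = B.sum(axis=0)[:, None]
    # orthonormal null space of c'
    q, _ = np.linalg.qr(c, mode="complete")
    Z = q[:, 1:]
    return B @ Z, [Z.T @ S @ Z for S in S_list], Z


@dataclass
class SmoothTerm:
    """One constrained smooth: basis evaluator + penalty blocks."""

    kind: str  # "spline" or "tensor"
    variables: list[str]
    specs: list[dict]
    Z: np.ndarray
    penalties: list[np.ndarray]  # in constrained coordinates
    n_coef: int

    def design(self, data: dict[str, np.ndarray]) -> np.ndarray:
        mats = [_eval_basis(data[v], spec) for v, spec in zip(self.variables, self.specs)]
        B = mats[0]
        for M in mats[1:]:
            B = _row_kron(B, M)
        return B @ self.Z


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product."""
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def make_spline_term(x: np.ndarray, var: str, k: int = 8) -> tuple[SmoothTerm, np.ndarray]:
    B, spec = bspline_basis(x, knots_interior=max(k - 4, 1))
    S = difference_penalty(B.shape[1])
    Bc, Sc, Z = _constrain(B, [S])
    term = SmoothTerm("spline", [var], [spec], Z, Sc, Bc.shape[1])
    return term, Bc


def make_tensor_term(
    data: dict[str, np.ndarray], variables: list[str], k: tuple[int, ...]
) -> tuple[SmoothTerm, np.ndarray]:
    mats, specs, margins = [], [], []
    for v, kv in zip(variables, k):
        B, spec = bspline_basis(data[v], knots_interior=max(kv - 4, 1))
        mats.append(B)
        specs.append(spec)
        margins.append(B.shape[1])
    B = mats[0]
    for M in mats[1:]:
        B = _row_kron(B, M)
    # one penalty per margin: I x ... x D'D x ... x I
    S_list = []
    for j in range(len(margins)):
        blocks = [difference_penalty(m) if i == j else np.eye(m) for i, m in enumerate(margins)]
        S = blocks[0]
        for b in blocks[1:]:
            S = np.kron(S, b)
        S_list.append(S)
    Bc, Sc, Z = _constrain(B, S_list)
    term = SmoothTerm("tensor", list(variables), specs, Z, Sc, Bc.shape[1])
    return term, Bc


@dataclass
class PenalizedFit:
    terms: list[SmoothTerm]
    coef: np.ndarray
    cov: np.ndarray
    sigma2: float
    lambdas: np.ndarray
    edf: float
    deviance_explained: float
    method: str
    term_slices: list[slice]

    def design(self, data: dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(data.values())))
        blocks = [np.ones((n, 1))]
        blocks += [t.design(data) for t in self.terms]
        return np.hstack(blocks)

    def predict(self, data: dict[str, np.ndarray], coef: np.ndarray | None = None) -> np.ndarray:
        return self.design(data) @ (self.coef if coef is None else coef)

    def sample_coefficients(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Parametric draws beta ~ N(coef, cov), shape (n, p).

        Uses an eigendecomposition with negative eigenvalues clipped at zero
        (they arise only from round-off in the penalized solve).
        """
        w, V = np.linalg.eigh((self.cov + self.cov.T) / 2.0)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        return self.coef[None, :] + rng.standard_normal((n, len(self.coef))) @ L.T


def fit_penalized_gaussian(
    data: dict[str, np.ndarray],
    y: np.ndarray,
    spline_vars: list[tuple[str, int]],
    tensor_vars: tuple[list[str], tuple[int, ...]] | None = None,
    method: str = "REML",
) -> PenalizedFit:
    """Fit the additive penalized model by REML (or GCV) smoothness selection."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    terms: list[SmoothTerm] = []
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    penalty_blocks: list[tuple[int, np.ndarray]] = []  # (term offset, S)

    offset = 1
    for var, k in spline_vars:
        term, B = make_spline_term(data[var], var, k)
        terms.append(term)
        blocks.append(B)
        for S in term.penalties:
            penalty_blocks.append((offset, S))
        offset += term.n_coef
    if tensor_vars is not None:
        variables, k = tensor_vars
        term, B = make_tensor_term(data, variables, k)
        terms.append(term)
        blocks.append(B)
        for S in term.penalties:
            penalty_blocks.append((offset, S))
        offset += term.n_coef

    X = np.hstack(blocks)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    if np.linalg.matrix_rank(XtX) < min(p, n):
        pass  # penalization regularizes; rank issues surface in the solve below

    def full_penalty(log_lam: np.ndarray) -> np.ndarray:
        S = np.zeros((p, p))
        for lam, (off, Sk) in zip(np.exp(log_lam), penalty_blocks):
            d = Sk.shape[0]
            S[off:off + d, off:off + d] += lam * Sk
        return S

    # null-space dimension of the summed penalty (lambda-independent structure)
    S1 = full_penalty(np.zeros(len(penalty_blocks)))
    eig1 = np.linalg.eigvalsh(S1)
    rank_S = int(np.sum(eig1 > eig1.max() * 1e-10)) if eig1.max() > 0 else 0
    M_null = p - rank_S

    def solve(log_lam):
        S = full_penalty(log_lam)
        A = XtX + S + 1e-10 * np.eye(p)
        beta = np.linalg.solve(A, Xty)
        resid = y - X @ beta
        rss = float(resid @ resid)
        return S, A, beta, rss

    def reml_score(log_lam):
        log_lam = np.clip(log_lam, -20, 20)
        S, A, beta, rss = solve(log_lam)
        bSb = float(beta @ S @ beta)
        sigma2 = (rss + bSb) / max(n - M_null, 1)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        eig = np.linalg.eigvalsh(S)
        pos = eig[eig > max(eig.max(), 1e-300) * 1e-10]
        logdet_S = float(np.sum(np.log(pos))) if pos.size else 0.0
        return 0.5 * (
            (n - M_null) * np.log(2 * np.pi * sigma2)
            + (rss + bSb) / sigma2
            + logdet_A
            - logdet_S
        )

    def gcv_score(log_lam):
        log_lam = np.clip(log_lam, -20, 20)
        S, A, beta, rss = solve(log_lam)
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        return n * rss / max(n - edf, 1e-6) ** 2

    score = reml_score if method.upper() == "REML" else gcv_score
    n_lam = len(penalty_blocks)
    best = None
    for start in (np.zeros(n_lam), np.full(n_lam, 4.0)):
        res = minimize(score, start, method="Nelder-Mead",
                       options={"xatol": 1e-2, "fatol": 1e-3, "maxiter": 200 * n_lam})
        if best is None or res.fun < best.fun:
            best = res
    log_lam = np.clip(best.x, -20, 20)

    S, A, beta, rss = solve(log_lam)
    bSb = float(beta @ S @ beta)
    sigma2 = (rss + bSb) / max(n - M_null, 1)
    cov = sigma2 * np.linalg.inv(A)
    edf = float(np.trace(np.linalg.solve(A, XtX)))
    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 0.0

    slices, off = [], 1
    for t in terms:
        slices.append(slice(off, off + t.n_coef))
        off += t.n_coef
    return PenalizedFit(terms, beta, cov, sigma2, np.exp(log_lam), edf, dev_expl,
                        method.upper(), slices)
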