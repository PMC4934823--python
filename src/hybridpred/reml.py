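"""Restricted maximum likelihood for linear mixed models with dense covariance.

Fits y = X beta + sum_k u_k + e where each random term u_k has covariance
sigma2_k * G_k for a known PSD matrix G_k (an equality indicator Z Z' for a
grouping factor, or an arbitrary relationship matrix), and e ~ N(0, sigma2_e I).

The optimiser takes average-information (AI) steps with step halving and
falls back to expectation-maximisation updates whenever an AI step fails to
improve the restricted likelihood; variance components are clamped at a
small positive floor, which is how boundary (zero-variance) solutions are
represented.  This is the numeric contract all phenotypic analyses rely on:
the returned solution maximises the restricted likelihood to the stated
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["RandomTerm", "REMLResult", "factor_covariance", "reml_fit"]


@dataclass(frozen=True)
class RandomTerm:
    """A named random term with covariance structure G and level count q."""

    name: str
    G: np.ndarray
    q: int


def factor_covariance(codes: np.ndarray, name: str) -> RandomTerm:
    """Equality-indicator covariance Z Z' of a grouping factor.

    ``codes`` are integer level codes per observation; a negative code means
    the observation does not carry this term (its row/column is zero).
    """
    codes = np.asarray(codes)
    valid = codes >= 0
    G = (codes[:, None] == codes[None, :]) & valid[:, None] & valid[None, :]
    q = len(np.unique(codes[valid])) if valid.any() else 0
    return RandomTerm(name, G.astype(float), max(q, 1))


@dataclass
class REMLResult:
    variances: dict[str, float]
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return self.variances[name]


def _loglik_and_derivs(y, X, terms, theta, floor, want_derivs=True):
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, th in zip(terms, theta[:-1]):
        if th > 0:
            V += th * t.G
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_X = linalg.cho_solve((c, low), X, check_finite=False)
    Vinv_y = linalg.cho_solve((c, low), y, check_finite=False)
    XtVinvX = X.T @ Vinv_X
    try:
        cx = linalg.cho_factor(XtVinvX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = linalg.cho_solve(cx, X.T @ Vinv_y, check_finite=False)
    Py = Vinv_y - Vinv_X @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + yPy)
    out = {"loglik": ll, "beta": beta, "XtVinvX": XtVinvX, "Py": Py, "chol": (c, low)}
    if not want_derivs:
        return out

    # P = Vinv - Vinv X (X'Vinv X)^-1 X' Vinv, assembled densely once
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    B = linalg.cho_solve(cx, Vinv_X.T, check_finite=False)
    P = Vinv - Vinv_X @ B
    P = (P + P.T) / 2.0

    k = len(terms) + 1
    score = np.empty(k)
    w = np.empty((n, k))
    for i, t in enumerate(terms):
        GPy = t.G @ Py
        score[i] = -0.5 * (float(np.sum(P * t.G)) - float(Py @ GPy))
        w[:, i] = GPy
    score[-1] = -0.5 * (float(np.trace(P)) - float(Py @ Py))
    w[:, -1] = Py
    Pw = P @ w
    AI = 0.5 * (w.T @ Pw)
    out.update(score=score, AI=AI, P=P)
    return out


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    tol: float = 1e-8,
    max_iter: int = 200,
    start: dict[str, float] | None = None,
) -> REMLResult:
    """Fit the variance-components model by AI-REML with EM fallback."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    n = len(y)
    vy = float(np.var(y)) or 1.0
    floor = 1e-10 * vy
    k = len(terms) + 1

    theta = np.full(k, vy / k)
    if start:
        for i, t in enumerate(terms):
            if t.name in start:
                theta[i] = max(start[t.name], floor)
        theta[-1] = max(start.get("error", theta[-1]), floor)

    state = _loglik_and_derivs(y, X, terms, theta, floor)
    if state is None:
        raise RuntimeError("REML: singular covariance at starting values")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, AI = state["score"], state["AI"]
        # parameters stuck at the zero boundary with downhill gradient are
        # held fixed, otherwise they corrupt the AI direction
        active = ~((theta <= 2 * floor) & (score < 0))
        if not active.any():
            converged = True
            break
        # AI step with ridge + step halving; EM fallback
        new_state = None
        delta = None
        try:
            ka = int(active.sum())
            AIa = AI[np.ix_(active, active)]
            da = np.linalg.solve(AIa + 1e-8 * np.eye(ka) * np.trace(AIa) / ka, score[active])
            delta = np.zeros(k)
            delta[active] = da
        except np.linalg.LinAlgError:
            pass
        if delta is not None:
            step = 1.0
            for _ in range(10):
                cand = np.maximum(theta + step * delta, floor)
                trial = _loglik_and_derivs(y, X, terms, cand, floor)
                if trial is not None and trial["loglik"] >= state["loglik"] - 1e-12:
                    new_state, theta_new = trial, cand
                    break
                step /= 2.0
        if new_state is None:
            # EM update: sigma^2 <- sigma^2 + sigma^4/q * (y'PGPy - tr(PG))
            P, Py = state["P"], state["Py"]
            cand = theta.copy()
            for i, t in enumerate(terms):
                grad = float(Py @ (t.G @ Py)) - float(np.sum(P * t.G))
                cand[i] = max(theta[i] + theta[i] ** 2 / t.q * grad, floor)
            grad_e = float(Py @ Py) - float(np.trace(P))
            cand[-1] = max(theta[-1] + theta[-1] ** 2 / n * grad_e, floor)
            trial = _loglik_and_derivs(y, X, terms, cand, floor)
            if trial is None:
                break
            new_state, theta_new = trial, cand

        rel = abs(new_state["loglik"] - state["loglik"]) / (abs(state["loglik"]) + 1.0)
        theta, state = theta_new, new_state
        if rel < tol:
            converged = True
            break

    XtVinvX = state["XtVinvX"]
    cov_beta = np.linalg.inv(XtVinvX)
    variances = {t.name: (0.0 if theta[i] <= 2 * floor else float(theta[i]))
                 for i, t in enumerate(terms)}
    variances["error"] = float(theta[-1])
    return REMLResult(
        variances=variances,
        beta=state["beta"],
        cov_beta=cov_beta,
        loglik=float(state["loglik"]),
        converged=converged,
        n_iter=it,
    )
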