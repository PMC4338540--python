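"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is deliberately naive (literal loops, generic solvers,
dense eigendecompositions) and never calls into the package's own
implementations.
"""

import numpy as np
from numpy.linalg import cholesky, inv
from scipy import linalg
from scipy.optimize import minimize


def brute_force_c(time, status, risk) -> float:
    """Literal pair loop over the concordance definition."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and status[i] == 1:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp


def naive_newton_cox(X, time, status, tol=1e-12):
    """Independent unpenalized Breslow MLE via explicit risk-set loops."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(100):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        w = np.exp(X @ beta)
        for i in range(n):
            if status[i] != 1:
                continue
            rs = time >= time[i]
            s0 = w[rs].sum()
            s1 = (w[rs, None] * X[rs]).sum(axis=0)
            s2 = np.einsum("i,ij,ik->jk", w[rs], X[rs], X[rs])
            grad += X[i] - s1 / s0
            hess -= s2 / s0 - np.outer(s1 / s0, s1 / s0)
        beta = beta + linalg.solve(-hess, grad)
        if np.abs(grad).max() < tol:
            break
    return beta


def direct_bh(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = 1.0
    for rank in range(m, 0, -1):
        best = min(best, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = best
    return q


def orthonormal_design(n: int, p: int, seed: int = 0) -> np.ndarray:
    """Centred columns with X'X/n exactly the identity."""
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(n, p))
    Gc = G - G.mean(axis=0)
    return Gc @ inv(cholesky((Gc.T @ Gc) / n)).T


def lasso_qp_solution(X, y, lam):
    """Generic bound-constrained solver for the lasso at one penalty."""
    n, p = X.shape

    def obj(v):
        b = v[:p] - v[p:]
        r = y - X @ b
        return 0.5 * np.sum(r * r) / n + lam * np.sum(v)

    res = minimize(obj, np.zeros(2 * p), bounds=[(0, None)] * (2 * p),
                   method="L-BFGS-B",
                   options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 10000})
    return res.x[:p] - res.x[p:]


def dense_pca_scores(values, k: int):
    """Sample scores from an explicit eigendecomposition of the Gram matrix."""
    data = values.T - values.T.mean(axis=0)  # samples x genes, gene-centred
    w, v = np.linalg.eigh(data @ data.T)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0, None), v[:, order]
    scores = v[:, :k] * np.sqrt(w[:k])
    for j in range(k):  # same sign convention: largest |gene loading| positive
        load = data.T @ v[:, j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores
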