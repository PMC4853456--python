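"""Independent oracles used by the tests.

These deliberately avoid the package's own solution paths: generic
constrained optimization for the penalized logistic objectives,
exhaustive pair counting for AUC, and direct discrete sums for TFCE.
"""

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def enet_logistic_objective_oracle(X, y, lambda1, alpha):
    """Optimal value of mean logistic loss + lambda1*(alpha L1 +
    (1-alpha)/2 L2) via smooth split-variable L-BFGS-B."""
    n, p = X.shape

    def f(th):
        u, v, b = th[:p], th[p:2 * p], th[2 * p]
        beta = u - v
        m = y * (X @ beta + b)
        return (np.mean(np.logaddexp(0, -m)) + lambda1 * (
            alpha * (u + v).sum() + 0.5 * (1 - alpha) * (beta ** 2).sum()))

    def g(th):
        u, v, b = th[:p], th[p:2 * p], th[2 * p]
        beta = u - v
        m = y * (X @ beta + b)
        pr = 1.0 / (1.0 + np.exp(m))
        gl = -(X.T @ (y * pr)) / n
        gb = -(y * pr).mean()
        gu = gl + lambda1 * alpha + lambda1 * (1 - alpha) * beta
        gv = -gl + lambda1 * alpha - lambda1 * (1 - alpha) * beta
        return np.r_[gu, gv, gb]

    res = minimize(f, np.zeros(2 * p + 1), jac=g, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p) + [(None, None)],
                   options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-12})
    return res.fun


def tv_logistic_objective_oracle(X, y, lambda1, lambda_tv, D):
    """Optimal value of mean logistic loss + lambda1 ||b||_1 +
    lambda_tv ||D b||_1 via an epigraph formulation (trust-constr)."""
    n, p = X.shape
    ne = D.shape[0]

    def f(th):
        beta, b = th[:p], th[p]
        u, t = th[p + 1:2 * p + 1], th[2 * p + 1:]
        m = y * (X @ beta + b)
        return np.mean(np.logaddexp(0, -m)) + lambda1 * u.sum() + lambda_tv * t.sum()

    nv = 2 * p + 1 + ne
    A1 = np.zeros((p, nv)); A1[:, :p] = np.eye(p); A1[:, p + 1:2 * p + 1] = -np.eye(p)
    A2 = np.zeros((p, nv)); A2[:, :p] = np.eye(p); A2[:, p + 1:2 * p + 1] = np.eye(p)
    B1 = np.zeros((ne, nv)); B1[:, :p] = D; B1[:, 2 * p + 1:] = -np.eye(ne)
    B2 = np.zeros((ne, nv)); B2[:, :p] = D; B2[:, 2 * p + 1:] = np.eye(ne)
    cons = [LinearConstraint(A1, -np.inf, 0), LinearConstraint(A2, 0, np.inf),
            LinearConstraint(B1, -np.inf, 0), LinearConstraint(B2, 0, np.inf)]
    res = minimize(f, np.zeros(nv), method="trust-constr", constraints=cons,
                   options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14})
    return res.fun


def auc_pair_counting(scores, y):
    """Mann-Whitney AUC: concordant pairs count 1, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = scores[y > 0]
    neg = scores[y <= 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def tfce_chain_oracle(values, E, H, dh):
    """Discrete TFCE sum on a chain graph by direct enumeration."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.zeros(n)
    vmax = values.max(initial=0.0)
    if vmax <= 0:
        return out
    h = dh
    while h <= vmax + 1e-12:
        above = values >= h
        # connected runs along the chain
        start = 0
        while start < n:
            if not above[start]:
                start += 1
                continue
            end = start
            while end + 1 < n and above[end + 1]:
                end += 1
            extent = end - start + 1
            for v in range(start, end + 1):
                out[v] += extent ** E * h ** H * dh
            start = end + 1
        h += dh
    return out
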