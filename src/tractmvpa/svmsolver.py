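"""Compact SMO solver for soft-margin C-SVC on small problems.

This is the kernel-SVM engine used throughout the package.  It solves the
standard dual

    min_a  1/2 a' Q a - e' a    s.t.  0 <= a_i <= C,  y' a = 0,

with Q_ij = y_i y_j K(x_i, x_j), by sequential minimal optimization with
maximal-violating-pair working-set selection (the libsvm strategy).  The
hot loops are numba-jitted so that leave-one-out cross-validation wrapped
in a permutation test (millions of fits on cohorts of a few dozen
subjects) stays tractable on one CPU.  Correctness is cross-checked
against libsvm (via scikit-learn) in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KERNEL_LINEAR = 0
KERNEL_POLY = 1
KERNEL_RBF = 2

_KERNEL_CODES = {"linear": KERNEL_LINEAR, "polynomial": KERNEL_POLY, "rbf": KERNEL_RBF}


def kernel_code(name: str) -> int:
    try:
        return _KERNEL_CODES[name]
    except KeyError:
        raise ValueError(f"unknown kernel {name!r}; expected one of {sorted(_KERNEL_CODES)}")


@njit(cache=True)
def kernel_matrix(A, B, code, gamma, degree, coef0):
    """Gram matrix between rows of A and rows of B."""
    n, m = A.shape[0], B.shape[0]
    K = np.empty((n, m))
    if code == KERNEL_RBF:
        for i in range(n):
            for j in range(m):
                s = 0.0
                for k in range(A.shape[1]):
                    d = A[i, k] - B[j, k]
                    s += d * d
                K[i, j] = np.exp(-gamma * s)
    else:
        for i in range(n):
            for j in range(m):
                s = 0.0
                for k in range(A.shape[1]):
                    s += A[i, k] * B[j, k]
                if code == KERNEL_POLY:
                    K[i, j] = (gamma * s + coef0) ** degree
                else:
                    K[i, j] = s
    return K


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):
    """SMO on a precomputed kernel matrix.

    Returns (alpha, rho, n_iter, converged); the decision function is
    f(x) = sum_i alpha_i y_i K(x_i, x) - rho.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    # gradient of the dual objective: G_i = sum_j Q_ij alpha_j - 1
    G = -np.ones(n)
    it = 0
    converged = False
    m_up = 0.0
    m_low = 0.0
    # alphas within eps_b of a bound are treated as at the bound when
    # building the working set, so rounding noise cannot stall a pair
    eps_b = 1e-12 * C
    while it < max_iter:
        # second-order working-set selection (libsvm WSS2):
        # i maximizes -y G over I_up; j minimizes -b^2/a over violating I_low
        i_up = -1
        m_up = -1e300
        m_low = 1e300
        for t in range(n):
            v = -y[t] * G[t]
            at_lo = alpha[t] <= eps_b
            at_hi = alpha[t] >= C - eps_b
            if (y[t] > 0 and not at_hi) or (y[t] < 0 and not at_lo):
                if v > m_up:
                    m_up = v
                    i_up = t
            if (y[t] > 0 and not at_lo) or (y[t] < 0 and not at_hi):
                if v < m_low:
                    m_low = v
        if i_up < 0 or m_up - m_low < tol:
            converged = True
            break
        i = i_up
        i_low = -1
        best = 1e300
        for t in range(n):
            v = -y[t] * G[t]
            at_lo = alpha[t] <= eps_b
            at_hi = alpha[t] >= C - eps_b
            if (y[t] > 0 and not at_lo) or (y[t] < 0 and not at_hi):
                b_it = m_up - v
                if b_it > 0.0:
                    a_it = K[i, i] + K[t, t] - 2.0 * K[i, t]
                    if a_it <= 1e-12:
                        a_it = 1e-12
                    gain = -(b_it * b_it) / a_it
                    if gain < best:
                        best = gain
                        i_low = t
        if i_low < 0:
            converged = True
            break
        j = i_low
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 1e-12:
            eta = 1e-12
        # two-variable analytic step on alpha_j (note y_t*G_t = E_t = f_t - y_t)
        a_j_old = alpha[j]
        a_i_old = alpha[i]
        delta = y[j] * ((G[i] * y[i]) - (G[j] * y[j])) / eta
        a_j_new = a_j_old + delta
        if y[i] != y[j]:
            L = max(0.0, a_j_old - a_i_old)
            H = min(C, C + a_j_old - a_i_old)
        else:
            L = max(0.0, a_i_old + a_j_old - C)
            H = min(C, a_i_old + a_j_old)
        if a_j_new < L:
            a_j_new = L
        elif a_j_new > H:
            a_j_new = H
        s = y[i] * y[j]
        a_i_new = a_i_old + s * (a_j_old - a_j_new)
        # snap to the box to keep bound bookkeeping exact
        if a_j_new <= eps_b:
            a_j_new = 0.0
        elif a_j_new >= C - eps_b:
            a_j_new = C
        if a_i_new <= eps_b:
            a_i_new = 0.0
        elif a_i_new >= C - eps_b:
            a_i_new = C
        d_i = a_i_new - a_i_old
        d_j = a_j_new - a_j_old
        if abs(d_i) < 1e-15 and abs(d_j) < 1e-15:
            # numerically stuck on this pair; treat as converged
            converged = True
            break
        alpha[i] = a_i_new
        alpha[j] = a_j_new
        for t in range(n):
            G[t] += y[t] * y[i] * K[t, i] * d_i + y[t] * y[j] * K[t, j] * d_j
        it += 1
    # intercept: average KKT condition over free SVs, else midpoint bound
    n_free = 0
    s_free = 0.0
    for t in range(n):
        if eps_b < alpha[t] < C - eps_b:
            n_free += 1
            s_free += y[t] * G[t]
    if n_free > 0:
        rho = s_free / n_free
    else:
        rho = -(m_up + m_low) / 2.0
    return alpha, rho, it, converged


@njit(cache=True)
def decision_from_alpha(K_test_train, alpha, y, rho):
    """f(x) = sum_i alpha_i y_i K(x_i, x) - rho for each test row."""
    m = K_test_train.shape[0]
    out = np.empty(m)
    for t in range(m):
        s = 0.0
        for i in range(K_test_train.shape[1]):
            s += alpha[i] * y[i] * K_test_train[t, i]
        out[t] = s - rho
    return out


def svc_fit(X, y, C=1.0, kernel="rbf", gamma=None, degree=3, coef0=1.0,
            tol=1e-3, max_iter=100_000):
    """Fit a C-SVC; returns a dict of fitted state.

    gamma=None uses the 'scale' convention 1/(n_features * var(X)).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    code = kernel_code(kernel)
    if gamma is None or gamma == "scale":
        v = X.var()
        gamma = 1.0 / (X.shape[1] * v) if v > 0 else 1.0
    K = kernel_matrix(X, X, code, gamma, degree, coef0)
    alpha, rho, n_iter, converged = smo_solve(K, y, C, tol, max_iter)
    return {
        "X": X, "y": y, "alpha": alpha, "rho": rho,
        "kernel": kernel, "code": code, "gamma": float(gamma),
        "degree": int(degree), "coef0": float(coef0), "C": float(C),
        "n_iter": int(n_iter), "converged": bool(converged),
    }


def svc_decision(state, X_new):
    X_new = np.ascontiguousarray(X_new, dtype=np.float64)
    K = kernel_matrix(X_new, state["X"], state["code"], state["gamma"],
                      state["degree"], state["coef0"])
    return decision_from_alpha(K, state["alpha"], state["y"], state["rho"])


def dual_objective(state):
    """Value of the dual objective 1/2 a'Qa - e'a at the solution."""
    K = kernel_matrix(state["X"], state["X"], state["code"], state["gamma"],
                      state["degree"], state["coef0"])
    ay = state["alpha"] * state["y"]
    return 0.5 * ay @ K @ ay - state["alpha"].sum()
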