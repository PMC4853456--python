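"""Classifier families for two-group voxelwise prediction.

Three families are provided, mirroring the analysis the package
implements:

``svm``
    Soft-margin kernel SVM (linear / polynomial / RBF) solved by the
    package's SMO engine (:mod:`tractmvpa.svmsolver`).
``enet_lrc``
    Logistic regression with an ElasticNet penalty,

        min  (1/n) sum log(1 + exp(-y_i (x_i' b + b0)))
             + lambda1 * (alpha ||b||_1 + (1 - alpha)/2 ||b||_2^2),

    solved by FISTA proximal gradient (the penalty's proximal operator is
    soft-thresholding followed by ridge shrinkage).
``tv_lrc``
    Structured sparse total-variation logistic regression,

        min  (1/n) sum log(1 + exp(-y_i (x_i' b + b0)))
             + lambda1 ||b||_1 + lambda_tv ||D b||_1,

    where D is the edge-difference operator of the skeleton adjacency
    graph (anisotropic TV), solved by ADMM with residual balancing.

Features are z-scored per voxel with training statistics by default;
the standardization parameters are stored on the model and re-applied
to test subjects.  Decision scores are oriented so that larger means
more "+1-like"; ties at exactly zero predict +1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from . import svmsolver
from .skeletons import TractSkeleton

__all__ = ["ClassifierSpec", "TrainedModel", "train_svm", "train_enet_lrc",
           "train_tv_lrc", "build_tract_gradient", "decision_scores",
           "save_model", "load_model", "ConvergenceWarning"]

FAMILIES = ("svm", "enet_lrc", "tv_lrc")


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "svm"
    kernel: str = "rbf"                 # svm only
    C: float = 1.0
    gamma: float | str | None = "scale"
    degree: int = 3
    coef0: float = 1.0
    lambda1: float = 0.1                # linear families
    alpha: float = 0.5                  # enet mixing; 1 = pure lasso
    lambda_tv: float = 0.1              # tv_lrc only
    standardize: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (isinstance(self.degree, int) and self.degree >= 1):
            raise ValueError("degree must be a positive integer")
        if self.lambda1 < 0 or self.lambda_tv < 0:
            raise ValueError("penalty weights must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    mean_: np.ndarray               # standardization parameters (zeros/ones if off)
    scale_: np.ndarray
    coef_: np.ndarray | None = None     # linear families, standardized space
    intercept_: float = 0.0
    svm_state: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_linear(self) -> bool:
        return self.spec.family in ("enet_lrc", "tv_lrc") or (
            self.spec.family == "svm" and self.spec.kernel == "linear")

    def coefficient_map(self) -> np.ndarray:
        """Per-voxel coefficients on the original feature scale."""
        if self.coef_ is None:
            raise ValueError("model has no explicit coefficients")
        return self.coef_ / self.scale_


def _standardizer(X: np.ndarray, on: bool):
    if not on:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be coded -1/+1")
    if (y > 0).sum() < 1 or (y < 0).sum() < 1:
        raise ValueError("need at least one subject per class")
    return X, y


def train_svm(X, y, spec: ClassifierSpec) -> TrainedModel:
    """Soft-margin C-SVC at the spec's kernel and hyperparameters."""
    if spec.family != "svm":
        raise ValueError("spec.family must be 'svm'")
    X, y = _check_Xy(X, y)
    mean, scale = _standardizer(X, spec.standardize)
    Z = (X - mean) / scale
    gamma = None if spec.gamma in (None, "scale") else float(spec.gamma)
    state = svmsolver.svc_fit(Z, y, C=spec.C, kernel=spec.kernel, gamma=gamma,
                              degree=spec.degree, coef0=spec.coef0)
    model = TrainedModel(spec=spec, mean_=mean, scale_=scale, svm_state=state,
                         diagnostics={"n_iter": state["n_iter"],
                                      "converged": state["converged"]})
    if spec.kernel == "linear":
        ay = state["alpha"] * y
        model.coef_ = ay @ Z
        model.intercept_ = -state["rho"]
    return model


def _logistic_loss_grad(Z1, y, w):
    """Mean logistic loss and gradient; Z1 has an appended ones column."""
    m = y * (Z1 @ w)
    # stable log(1+exp(-m))
    loss = np.mean(np.logaddexp(0.0, -m))
    p = 1.0 / (1.0 + np.exp(m))        # = sigma(-m)
    g = -(Z1.T @ (y * p)) / len(y)
    return loss, g


def enet_objective(Z, y, coef, intercept, lambda1, alpha):
    m = y * (Z @ coef + intercept)
    loss = np.mean(np.logaddexp(0.0, -m))
    return loss + lambda1 * (alpha * np.abs(coef).sum()
                             + 0.5 * (1 - alpha) * (coef ** 2).sum())


def train_enet_lrc(X, y, spec: ClassifierSpec, max_iter: int = 50_000,
                   tol: float = 1e-12, grad_tol: float = 1e-8) -> TrainedModel:
    """ElasticNet logistic regression via FISTA with backtracking-free
    constant step (1 / Lipschitz bound).  The intercept is unpenalized.

    Convergence requires both a flat objective (relative change below
    ``tol`` over 10 iterations) and a small proximal-gradient mapping
    (below ``grad_tol * (1 + ||w||)``); the latter guards against early
    stops on flat objectives where the iterates are still moving.
    """
    if spec.family != "enet_lrc":
        raise ValueError("spec.family must be 'enet_lrc'")
    X, y = _check_Xy(X, y)
    mean, scale = _standardizer(X, spec.standardize)
    Z = (X - mean) / scale
    n, p = Z.shape
    Z1 = np.c_[Z, np.ones(n)]
    # the ridge part of the penalty lives in the prox, so the smooth term
    # is the logistic loss alone
    L = np.linalg.norm(Z1, 2) ** 2 / (4.0 * n)
    step = 1.0 / max(L, 1e-12)
    lam_l1 = spec.lambda1 * spec.alpha
    lam_l2 = spec.lambda1 * (1 - spec.alpha)

    w = np.zeros(p + 1)
    v = w.copy()
    t_acc = 1.0
    obj_prev = np.inf
    trace = []
    converged = False
    for it in range(max_iter):
        _, g = _logistic_loss_grad(Z1, y, v)
        u = v - step * g
        w_new = u.copy()
        w_new[:p] = np.sign(u[:p]) * np.maximum(np.abs(u[:p]) - step * lam_l1, 0.0)
        w_new[:p] /= (1.0 + step * lam_l2)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2))
        v = w_new + ((t_acc - 1.0) / t_new) * (w_new - w)
        w, t_acc = w_new, t_new
        if it % 10 == 0 or it == max_iter - 1:
            obj = enet_objective(Z, y, w[:p], w[p], spec.lambda1, spec.alpha)
            trace.append(obj)
            if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
                # stationarity: proximal-gradient step from w itself
                _, gw = _logistic_loss_grad(Z1, y, w)
                uw = w - step * gw
                w_chk = uw.copy()
                w_chk[:p] = np.sign(uw[:p]) * np.maximum(
                    np.abs(uw[:p]) - step * lam_l1, 0.0)
                w_chk[:p] /= (1.0 + step * lam_l2)
                gm = np.linalg.norm(w_chk - w) / step
                if gm <= grad_tol * (1.0 + np.linalg.norm(w)):
                    converged = True
                    break
            obj_prev = obj
    if not converged:
        warnings.warn("ElasticNet LRC did not converge within the iteration "
                      "cap; returning the last iterate", ConvergenceWarning,
                      stacklevel=2)
    obj = enet_objective(Z, y, w[:p], w[p], spec.lambda1, spec.alpha)
    return TrainedModel(spec=spec, mean_=mean, scale_=scale, coef_=w[:p],
                        intercept_=float(w[p]),
                        diagnostics={"objective": float(obj),
                                     "objective_trace": trace,
                                     "n_iter": it + 1, "converged": converged})


def build_tract_gradient(skeleton: TractSkeleton) -> sparse.csr_matrix:
    """Edge-difference operator: one row per adjacency edge with +1/-1 on
    the endpoints.  Constant maps are in its nullspace; on a connected
    skeleton its rank is V - 1."""
    e = skeleton.adjacency
    n_e = len(e)
    rows = np.repeat(np.arange(n_e), 2)
    cols = e.ravel()
    data = np.tile([1.0, -1.0], n_e)
    return sparse.csr_matrix((data, (rows, cols)),
                             shape=(n_e, skeleton.n_voxels))


def tv_objective(Z, y, coef, intercept, lambda1, lambda_tv, D):
    m = y * (Z @ coef + intercept)
    loss = np.mean(np.logaddexp(0.0, -m))
    return (loss + lambda1 * np.abs(coef).sum()
            + lambda_tv * np.abs(D @ coef).sum())


def _newton_logistic_quad(Z1, y, rho, A, b_lin, w0, n_iter=50, tol=1e-10):
    """Minimize mean logistic loss + rho/2 ||A w - b_lin||^2 by Newton.

    A is dense (stacked identity and edge-difference rows acting on the
    coefficient block only, extended with a zero column for the
    intercept).
    """
    w = w0.copy()
    n = len(y)
    AtA = A.T @ A
    Atb = A.T @ b_lin
    for _ in range(n_iter):
        m = y * (Z1 @ w)
        p = 1.0 / (1.0 + np.exp(m))
        g = -(Z1.T @ (y * p)) / n + rho * (AtA @ w - Atb)
        s = p * (1.0 - p)
        H = (Z1.T * s) @ Z1 / n + rho * AtA
        H[np.diag_indices_from(H)] += 1e-12
        try:
            dw = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            dw = np.linalg.lstsq(H, g, rcond=None)[0]
        w = w - dw
        if np.abs(dw).max() < tol:
            break
    return w


def train_tv_lrc(X, y, skeleton: TractSkeleton, spec: ClassifierSpec,
                 rho: float = 1.0, max_iter: int = 5000,
                 abs_tol: float = 1e-8, rel_tol: float = 1e-6) -> TrainedModel:
    """Total-variation logistic regression by ADMM.

    Splitting: z1 = b (L1 block) and z2 = D b (TV block); both proximal
    updates are soft-thresholds.  The penalty parameter follows the
    standard residual-balancing rule (factor 2 when one residual exceeds
    10x the other).  ADMM is not a descent method, so the objective trace
    is monitored and the best iterate encountered is returned.
    """
    if spec.family != "tv_lrc":
        raise ValueError("spec.family must be 'tv_lrc'")
    X, y = _check_Xy(X, y)
    if X.shape[1] != skeleton.n_voxels:
        raise ValueError("feature columns must match skeleton voxels")
    mean, scale = _standardizer(X, spec.standardize)
    Z = (X - mean) / scale
    n, p = Z.shape
    Z1 = np.c_[Z, np.ones(n)]
    D = build_tract_gradient(skeleton).toarray()
    n_e = D.shape[0]
    # stacked constraint A w = [b; D b] on the coefficient block
    A = np.zeros((p + n_e, p + 1))
    A[:p, :p] = np.eye(p)
    A[p:, :p] = D

    w = np.zeros(p + 1)
    z = np.zeros(p + n_e)
    u = np.zeros(p + n_e)
    best_obj = np.inf
    best_w = w.copy()
    trace = []
    converged = False
    pri = dua = np.inf
    for it in range(max_iter):
        w = _newton_logistic_quad(Z1, y, rho, A, z - u, w)
        Aw = A @ w
        z_old = z.copy()
        v = Aw + u
        z[:p] = np.sign(v[:p]) * np.maximum(np.abs(v[:p]) - spec.lambda1 / rho, 0.0)
        z[p:] = np.sign(v[p:]) * np.maximum(np.abs(v[p:]) - spec.lambda_tv / rho, 0.0)
        u += Aw - z
        obj = tv_objective(Z, y, w[:p], w[p], spec.lambda1, spec.lambda_tv, D)
        trace.append(obj)
        if obj < best_obj:
            best_obj = obj
            best_w = w.copy()
        pri = np.linalg.norm(Aw - z)
        dua = rho * np.linalg.norm(A.T @ (z - z_old))
        eps_pri = np.sqrt(A.shape[0]) * abs_tol + rel_tol * max(
            np.linalg.norm(Aw), np.linalg.norm(z))
        eps_dua = np.sqrt(A.shape[1]) * abs_tol + rel_tol * rho * np.linalg.norm(A.T @ u)
        if pri < eps_pri and dua < eps_dua:
            converged = True
            break
        if pri > 10 * dua:
            rho *= 2.0
            u /= 2.0
        elif dua > 10 * pri:
            rho /= 2.0
            u *= 2.0
    if not converged:
        warnings.warn(
            f"TV LRC ADMM stopped at the iteration cap (primal residual "
            f"{pri:.2e}, dual {dua:.2e})", ConvergenceWarning, stacklevel=2)
    # report the sparsified consensus coefficients (z carries exact zeros)
    coef = z[:p].copy()
    intercept = float(best_w[p])
    obj = tv_objective(Z, y, coef, intercept, spec.lambda1, spec.lambda_tv, D)
    if best_obj < obj:
        coef, intercept = best_w[:p], float(best_w[p])
        obj = best_obj
    return TrainedModel(spec=spec, mean_=mean, scale_=scale, coef_=np.asarray(coef),
                        intercept_=intercept,
                        diagnostics={"objective": float(obj),
                                     "objective_trace": trace,
                                     "n_iter": it + 1, "converged": converged,
                                     "primal_residual": float(pri),
                                     "dual_residual": float(dua)})


def decision_scores(model: TrainedModel, X) -> np.ndarray:
    """Per-subject real decision scores; sign predicts the label
    (ties at exactly 0 go to +1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.mean_):
        raise ValueError(f"feature count {X.shape[1]} does not match the "
                         f"trained model ({len(model.mean_)})")
    Z = (X - model.mean_) / model.scale_
    if model.spec.family == "svm" and model.svm_state is not None:
        return svmsolver.svc_decision(model.svm_state, Z)
    return Z @ model.coef_ + model.intercept_


def predict_labels(model: TrainedModel, X) -> np.ndarray:
    s = decision_scores(model, X)
    return np.where(s >= 0, 1.0, -1.0)


def save_model(model: TrainedModel, path) -> None:
    """Serialize spec + coefficients + standardization to versioned JSON."""
    payload = {
        "format": "tractmvpa-model", "version": 1,
        "spec": asdict(model.spec),
        "mean": model.mean_.tolist(), "scale": model.scale_.tolist(),
        "intercept": model.intercept_,
        "coef": None if model.coef_ is None else model.coef_.tolist(),
        "diagnostics": {k: v for k, v in model.diagnostics.items()
                        if not isinstance(v, (np.ndarray, list))},
    }
    if model.svm_state is not None:
        s = model.svm_state
        payload["svm_state"] = {
            "X": s["X"].tolist(), "y": s["y"].tolist(),
            "alpha": s["alpha"].tolist(), "rho": s["rho"],
            "kernel": s["kernel"], "gamma": s["gamma"], "degree": s["degree"],
            "coef0": s["coef0"], "C": s["C"],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "tractmvpa-model":
        raise ValueError("not a tractmvpa model file")
    spec = ClassifierSpec(**payload["spec"])
    model = TrainedModel(spec=spec,
                         mean_=np.asarray(payload["mean"]),
                         scale_=np.asarray(payload["scale"]),
                         coef_=None if payload["coef"] is None
                         else np.asarray(payload["coef"]),
                         intercept_=payload["intercept"],
                         diagnostics=payload.get("diagnostics", {}))
    if "svm_state" in payload:
        s = payload["svm_state"]
        model.svm_state = {
            "X": np.asarray(s["X"]), "y": np.asarray(s["y"]),
            "alpha": np.asarray(s["alpha"]), "rho": s["rho"],
            "kernel": s["kernel"], "code": svmsolver.kernel_code(s["kernel"]),
            "gamma": s["gamma"], "degree": s["degree"], "coef0": s["coef0"],
            "C": s["C"],
        }
    return model
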