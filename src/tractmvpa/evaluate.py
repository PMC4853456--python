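"""Leave-one-out cross-validation, grid search, ROC and permutation tests.

The protocol mirrors the tract-restricted MVPA design: in every fold the
per-voxel F-scores, the top-fraction voxel selection and the per-voxel
standardization are computed from the training subjects only, a
classifier is trained at each hyperparameter combination, and the single
held-out subject is scored.  Hyperparameters are chosen by maximizing
LOOCV accuracy over the grid — the optimistic placement the study design
implies; because the permutation null repeats the identical procedure
(grid search included) for every relabelling, the permutation p-value
remains valid.  A fully nested inner/outer mode is also available.

The permutation p is the raw fraction of null statistics greater than or
equal to the observed one ("equal or superior" counts ties); the
positively biased but never-zero estimator (b + 1) / (m + 1) is reported
alongside.

For the kernel-SVM family the whole fold loop (F-scores, selection,
standardization, Gram matrix, SMO) is jitted with numba so that a full
permutation test with grid search runs in seconds on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from numba import njit
from sklearn import metrics as _skmetrics

from . import svmsolver
from .classify import (ClassifierSpec, TrainedModel, decision_scores,
                       train_enet_lrc, train_svm, train_tv_lrc)
from .featselect import fscore, select_top_fraction
from .skeletons import TractSkeleton

__all__ = ["GridSearchSpec", "CVResult", "ROCCurve", "PermutationResult",
           "loocv", "roc_curve", "permutation_test", "null_roc_contours",
           "FPR_GRID"]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class GridSearchSpec:
    """Hyperparameter grids; combinations are enumerated fraction-major,
    then C (or lambda1), then gamma (or alpha / lambda_tv), and ties in
    cross-validated accuracy resolve to the earliest combination."""
    fractions: tuple = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)
    C: tuple = tuple(float(2.0 ** k) for k in range(-5, 16, 2))
    gamma: tuple = tuple(float(2.0 ** k) for k in range(-15, 4, 2))
    lambda1: tuple = (0.001, 0.01, 0.1, 1.0)
    alpha: tuple = (0.5,)
    lambda_tv: tuple = (0.01, 0.1)

    def __post_init__(self):
        for name in ("fractions", "C", "gamma", "lambda1", "alpha", "lambda_tv"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid {name} must be non-empty")

    @classmethod
    def desk_scale(cls) -> "GridSearchSpec":
        """Small grid used for desk-scale runs and calibration studies."""
        return cls(fractions=(0.2, 1.0), C=(1.0, 100.0), gamma=("scale",),
                   lambda1=(0.01, 0.1), alpha=(0.5,), lambda_tv=(0.01,))

    def combos(self, spec: ClassifierSpec):
        """Deterministic enumeration of grid points for a family."""
        out = []
        if spec.family == "svm":
            gammas = self.gamma if spec.kernel == "rbf" else (spec.gamma,)
            for f in self.fractions:
                for C in self.C:
                    for g in gammas:
                        out.append({"fraction": f, "C": C, "gamma": g})
        elif spec.family == "enet_lrc":
            for f in self.fractions:
                for lam in self.lambda1:
                    for a in self.alpha:
                        out.append({"fraction": f, "lambda1": lam, "alpha": a})
        else:
            for f in self.fractions:
                for lam in self.lambda1:
                    for lt in self.lambda_tv:
                        out.append({"fraction": f, "lambda1": lam,
                                    "lambda_tv": lt})
        return out


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def interpolate(self, fpr_grid: np.ndarray = FPR_GRID) -> np.ndarray:
        return np.interp(fpr_grid, self.fpr, self.tpr)


@dataclass
class CVResult:
    y_true: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    accuracy: float
    roc: ROCCurve
    auc: float
    chosen: dict
    grid_accuracies: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    p: float                        # raw fraction, can be 0
    p_plus_one: float               # (b+1)/(m+1) estimator
    statistic: str
    n_perm: int
    seed: int
    null_roc_tpr: np.ndarray        # (n_perm, len(FPR_GRID))
    observed_roc: ROCCurve


def roc_curve(scores, y) -> ROCCurve:
    """ROC from sweeping the decision threshold from +inf to -inf;
    AUC is the trapezoidal area (= Mann-Whitney statistic, ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.r_[0.0, fpr]
        tpr = np.r_[0.0, tpr]
    auc = float(_skmetrics.auc(fpr, tpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# fast SVM LOOCV core


@njit(cache=True)
def _loocv_svm_core(X, y, fractions, Cs, gammas, code, degree, coef0, tol):
    """All-fold, all-combination LOOCV decision scores for kernel SVM.

    gammas < 0 encode the 'scale' convention (1 / (k * var)).  Returns an
    (n_combos, n) array of held-out decision scores with combinations
    enumerated fraction-major, then C, then gamma.
    """
    n, V = X.shape
    nf, nc, ng = len(fractions), len(Cs), len(gammas)
    scores_out = np.zeros((nf * nc * ng, n))
    m = n - 1
    Xtr = np.empty((m, V))
    ytr = np.empty(m)
    for i in range(n):
        # training split
        r = 0
        for t in range(n):
            if t != i:
                Xtr[r] = X[t]
                ytr[r] = y[t]
                r += 1
        # per-voxel F-scores on the training fold
        fs = np.empty(V)
        npos = 0
        for t in range(m):
            if ytr[t] > 0:
                npos += 1
        nneg = m - npos
        for v in range(V):
            sp = 0.0
            sp2 = 0.0
            sn = 0.0
            sn2 = 0.0
            for t in range(m):
                x = Xtr[t, v]
                if ytr[t] > 0:
                    sp += x
                    sp2 += x * x
                else:
                    sn += x
                    sn2 += x * x
            mp = sp / npos
            mn = sn / nneg
            ma = (sp + sn) / m
            vp = (sp2 - npos * mp * mp) / (npos - 1)
            vn = (sn2 - nneg * mn * mn) / (nneg - 1)
            num = (mp - ma) ** 2 + (mn - ma) ** 2
            den = vp + vn
            if den <= 0.0:
                fs[v] = 0.0 if num == 0.0 else np.inf
            else:
                fs[v] = num / den
        order = np.argsort(-fs, kind="mergesort")
        for fi in range(nf):
            k = int(np.ceil(fractions[fi] * V))
            sel = order[:k]
            # standardization from the training fold
            Z = np.empty((m, k))
            zt = np.empty(k)
            var_sum = 0.0
            for c in range(k):
                v = sel[c]
                mu = 0.0
                for t in range(m):
                    mu += Xtr[t, v]
                mu /= m
                s2 = 0.0
                for t in range(m):
                    d = Xtr[t, v] - mu
                    s2 += d * d
                s2 /= m
                sd = np.sqrt(s2) if s2 > 0 else 1.0
                for t in range(m):
                    Z[t, c] = (Xtr[t, v] - mu) / sd
                zt[c] = (X[i, v] - mu) / sd
                zv = 0.0
                for t in range(m):
                    zv += Z[t, c] * Z[t, c]
                var_sum += zv / m
            zbar = 0.0
            for c in range(k):
                s = 0.0
                for t in range(m):
                    s += Z[t, c]
                zbar += (s / m) ** 2
            z_var = var_sum / k - zbar / k
            # pairwise squared distances / inner products
            G = np.empty((m, m))
            gtest = np.empty(m)
            if code == svmsolver.KERNEL_RBF:
                for a in range(m):
                    for b in range(a, m):
                        s = 0.0
                        for c in range(k):
                            d = Z[a, c] - Z[b, c]
                            s += d * d
                        G[a, b] = s
                        G[b, a] = s
                    s = 0.0
                    for c in range(k):
                        d = Z[a, c] - zt[c]
                        s += d * d
                    gtest[a] = s
            else:
                for a in range(m):
                    for b in range(a, m):
                        s = 0.0
                        for c in range(k):
                            s += Z[a, c] * Z[b, c]
                        G[a, b] = s
                        G[b, a] = s
                    s = 0.0
                    for c in range(k):
                        s += Z[a, c] * zt[c]
                    gtest[a] = s
            K = np.empty((m, m))
            Ktest = np.empty((1, m))
            for gi in range(ng):
                g = gammas[gi]
                if g < 0:
                    g = 1.0 / (k * z_var) if z_var > 0 else 1.0
                if code == svmsolver.KERNEL_RBF:
                    for a in range(m):
                        for b in range(m):
                            K[a, b] = np.exp(-g * G[a, b])
                        Ktest[0, a] = np.exp(-g * gtest[a])
                elif code == svmsolver.KERNEL_POLY:
                    for a in range(m):
                        for b in range(m):
                            K[a, b] = (g * G[a, b] + coef0) ** degree
                        Ktest[0, a] = (g * gtest[a] + coef0) ** degree
                else:
                    for a in range(m):
                        for b in range(m):
                            K[a, b] = G[a, b]
                        Ktest[0, a] = gtest[a]
                for ci in range(nc):
                    alpha, rho_, _, _ = svmsolver.smo_solve(K, ytr, Cs[ci],
                                                           tol, 100_000)
                    dec = svmsolver.decision_from_alpha(Ktest, alpha, ytr, rho_)
                    combo = (fi * nc + ci) * ng + gi
                    scores_out[combo, i] = dec[0]
    return scores_out


def _encode_gammas(gammas):
    out = []
    for g in gammas:
        out.append(-1.0 if g in (None, "scale") else float(g))
    return np.asarray(out, dtype=float)


def _svm_grid_scores(X, y, spec: ClassifierSpec, grid: GridSearchSpec):
    """(combos, per-combo held-out scores) via the jitted core."""
    gammas = grid.gamma if spec.kernel == "rbf" else (spec.gamma,)
    scores = _loocv_svm_core(
        np.ascontiguousarray(X, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
        np.asarray(grid.fractions, dtype=np.float64),
        np.asarray(grid.C, dtype=np.float64),
        _encode_gammas(gammas),
        svmsolver.kernel_code(spec.kernel), spec.degree, spec.coef0, 1e-3)
    return grid.combos(spec), scores


def _induced_subskeleton(skeleton: TractSkeleton, voxels) -> TractSkeleton:
    voxels = np.asarray(voxels)
    remap = -np.ones(skeleton.n_voxels, dtype=np.int64)
    remap[voxels] = np.arange(len(voxels))
    e = skeleton.adjacency
    keep = (remap[e[:, 0]] >= 0) & (remap[e[:, 1]] >= 0)
    edges = np.sort(remap[e[keep]], axis=1)
    return TractSkeleton(skeleton.voxel_coords[voxels], edges,
                         skeleton.end_labels[voxels],
                         skeleton.arc_position[voxels],
                         hemisphere=skeleton.hemisphere)


def _fit_linear(X, y, spec: ClassifierSpec, combo: dict,
                skeleton: TractSkeleton | None) -> TrainedModel:
    if spec.family == "enet_lrc":
        s = ClassifierSpec(family="enet_lrc", lambda1=combo["lambda1"],
                           alpha=combo.get("alpha", spec.alpha),
                           standardize=spec.standardize)
        return train_enet_lrc(X, y, s)
    s = ClassifierSpec(family="tv_lrc", lambda1=combo["lambda1"],
                       lambda_tv=combo.get("lambda_tv", spec.lambda_tv),
                       standardize=spec.standardize)
    return train_tv_lrc(X, y, skeleton, s)


def _generic_grid_scores(X, y, spec, grid, skeleton):
    """Per-combination held-out scores for the linear families."""
    n, V = X.shape
    combos = grid.combos(spec)
    scores = np.zeros((len(combos), n))
    for i in range(n):
        tr = np.arange(n) != i
        fs = fscore(X[tr], y[tr])
        order = select_top_fraction(fs, 1.0).retained
        for ci, combo in enumerate(combos):
            k = ceil(combo["fraction"] * V)
            sel = order[:k]
            sub = _induced_subskeleton(skeleton, sel) if spec.family == "tv_lrc" else None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if spec.family == "svm":
                    s = ClassifierSpec(family="svm", kernel=spec.kernel,
                                       C=combo["C"], gamma=combo["gamma"],
                                       degree=spec.degree, coef0=spec.coef0,
                                       standardize=spec.standardize)
                    model = train_svm(X[tr][:, sel], y[tr], s)
                else:
                    model = _fit_linear(X[tr][:, sel], y[tr], spec, combo, sub)
            scores[ci, i] = decision_scores(model, X[i:i + 1, sel])[0]
    return combos, scores


def _accuracy(scores, y):
    pred = np.where(scores >= 0, 1.0, -1.0)
    return float(np.mean(pred == y))


def _pick_best(combos, score_mat, y, statistic="accuracy"):
    stats = np.empty(len(combos))
    for i, row in enumerate(score_mat):
        stats[i] = (_accuracy(row, y) if statistic == "accuracy"
                    else roc_curve(row, y).auc)
    best = int(np.argmax(stats))    # first maximizer wins ties
    return best, stats


def loocv(X, y, spec: ClassifierSpec, grid: GridSearchSpec | None = None,
          skeleton: TractSkeleton | None = None, nested: bool = False,
          statistic: str = "accuracy", seed: int | None = None) -> CVResult:
    """Leave-one-out cross-validation with in-fold selection and grid search.

    Default (non-nested) mode selects the grid point maximizing the
    LOOCV ``statistic`` and reports that point's held-out predictions.
    Nested mode re-runs the whole grid search inside each outer fold on
    the n-1 training subjects and is free of selection optimism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if (y > 0).sum() < 2 or (y < 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")
    grid = grid or GridSearchSpec.desk_scale()
    if spec.family == "tv_lrc" and skeleton is None:
        raise ValueError("tv_lrc needs the skeleton for the TV graph")

    runner = _svm_grid_scores if spec.family == "svm" else \
        (lambda X_, y_, s_, g_: _generic_grid_scores(X_, y_, s_, g_, skeleton))

    if not nested:
        combos, score_mat = runner(X, y, spec, grid)
        best, stats = _pick_best(combos, score_mat, y, statistic)
        scores = score_mat[best]
        chosen = combos[best]
        grid_acc = {tuple(c.items()): float(s) for c, s in zip(combos, stats)}
    else:
        scores = np.empty(n)
        chosen_per_fold = []
        for i in range(n):
            tr = np.arange(n) != i
            combos, inner = runner(X[tr], y[tr], spec, grid)
            best, _ = _pick_best(combos, inner, y[tr], statistic)
            combo = combos[best]
            fs = fscore(X[tr], y[tr])
            sel = select_top_fraction(fs, combo["fraction"]).retained
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if spec.family == "svm":
                    s = ClassifierSpec(family="svm", kernel=spec.kernel,
                                       C=combo["C"], gamma=combo["gamma"],
                                       degree=spec.degree, coef0=spec.coef0,
                                       standardize=spec.standardize)
                    model = train_svm(X[tr][:, sel], y[tr], s)
                else:
                    sub = (_induced_subskeleton(skeleton, sel)
                           if spec.family == "tv_lrc" else None)
                    model = _fit_linear(X[tr][:, sel], y[tr], spec, combo, sub)
            scores[i] = decision_scores(model, X[i:i + 1, sel])[0]
            chosen_per_fold.append(combo)
        chosen = {"per_fold": chosen_per_fold}
        grid_acc = {}

    pred = np.where(scores >= 0, 1.0, -1.0)
    roc = roc_curve(scores, y)
    return CVResult(y_true=y, predictions=pred, scores=scores,
                    accuracy=float(np.mean(pred == y)), roc=roc, auc=roc.auc,
                    chosen=chosen, grid_accuracies=grid_acc, seed=seed)


def permutation_test(X, y, spec: ClassifierSpec, grid: GridSearchSpec | None = None,
                     skeleton: TractSkeleton | None = None, n_perm: int = 500,
                     statistic: str = "accuracy", nested: bool = False,
                     seed: int = 0) -> PermutationResult:
    """Full-pipeline permutation significance.

    Every permutation re-runs the complete LOOCV including feature
    selection and grid search on a uniformly permuted label vector
    (class sizes preserved by construction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("accuracy", "auc"):
        raise ValueError("statistic must be 'accuracy' or 'auc'")
    y = np.asarray(y, dtype=float)
    obs = loocv(X, y, spec, grid, skeleton, nested=nested,
                statistic=statistic, seed=seed)
    obs_stat = obs.accuracy if statistic == "accuracy" else obs.auc
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_perm)
    null_tpr = np.empty((n_perm, len(FPR_GRID)))
    for b in range(n_perm):
        yp = rng.permutation(y)
        res = loocv(X, yp, spec, grid, skeleton, nested=nested,
                    statistic=statistic)
        null_stats[b] = res.accuracy if statistic == "accuracy" else res.auc
        null_tpr[b] = res.roc.interpolate(FPR_GRID)
    p = float(np.mean(null_stats >= obs_stat))
    p1 = float((1 + np.sum(null_stats >= obs_stat)) / (n_perm + 1))
    return PermutationResult(observed=obs_stat, null_stats=null_stats, p=p,
                             p_plus_one=p1, statistic=statistic, n_perm=n_perm,
                             seed=seed, null_roc_tpr=null_tpr,
                             observed_roc=obs.roc)


def null_roc_contours(null_tpr: np.ndarray, levels=(0.01, 0.05, 0.1),
                      fpr_grid: np.ndarray = FPR_GRID) -> dict:
    """Pointwise null-distribution contours of an ROC ensemble.

    The contour at level p is, at each false-positive rate, the (1 - p)
    quantile of the interpolated null true-positive rates, so contours
    are nested: smaller p lies above.
    """
    null_tpr = np.asarray(null_tpr, dtype=float)
    if null_tpr.ndim != 2 or len(null_tpr) == 0:
        raise ValueError("need a non-empty (n_curves, n_fpr) ensemble")
    out = {}
    for lev in levels:
        if not 0 < lev < 1:
            raise ValueError("levels must lie in (0, 1)")
        if len(null_tpr) < 1.0 / lev:
            warnings.warn(f"only {len(null_tpr)} curves for level {lev}; "
                          "quantile unstable", stacklevel=2)
        # order-statistic quantile: the contour is an actual ensemble
        # member's TPR, matching the counting definition of the level
        out[lev] = np.quantile(null_tpr, 1.0 - lev, axis=0,
                               method="inverted_cdf")
    return out
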