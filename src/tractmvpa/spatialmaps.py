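"""Voxelwise interpretation maps and their permutation inference.

For a two-group design the covariance between each voxel's feature and
the +/-1 group coding is the interpretable "activation pattern"
counterpart of classifier weights: its sign says which group has the
larger mean at that voxel.  Statistical maps are assessed with
threshold-free cluster enhancement (TFCE), which integrates cluster
extent and height over all thresholds,

    TFCE(v) = sum_h extent(v, h)^E * h^H * dh,

with family-wise error controlled by the permutation distribution of the
maximum |TFCE| statistic.  Linear-classifier coefficient maps are
stabilized by averaging over bootstrap resamples, and diagnostics
compare the two kinds of map (sign agreement and correlation over the
non-zero support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .classify import ClassifierSpec, TrainedModel, train_enet_lrc, train_tv_lrc
from .skeletons import TractSkeleton

__all__ = ["VoxelMap", "TFCEParams", "group_covariance_map", "tfce",
           "tfce_permutation_fwe", "bootstrap_coefficient_map",
           "coef_covariance_diagnostics"]


@dataclass
class VoxelMap:
    """Per-voxel scalar field aligned to a skeleton."""
    values: np.ndarray
    skeleton: TractSkeleton
    semantics: str = "covariance"   # covariance | tfce | coefficient | p_value

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.skeleton.n_voxels:
            raise ValueError("map length must equal skeleton voxel count")
        if self.semantics == "p_value" and (
                (self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("p-value maps must lie in [0, 1]")


@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings; the E=0.5, H=2 defaults are the established
    convention for skeletonized data, with dh set to max/100 at call
    time when left as None."""
    E: float = 0.5
    H: float = 2.0
    dh: float | None = None

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


def group_covariance_map(X, y, skeleton: TractSkeleton) -> VoxelMap:
    """Sample covariance (n-1 denominator) between each voxel and the
    +/-1 group coding; positive where the +1 group mean is larger."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    yc = y - y.mean()
    cov = yc @ (X - X.mean(axis=0)) / (len(y) - 1)
    return VoxelMap(values=cov, skeleton=skeleton, semantics="covariance")


def _tfce_one_sided(values: np.ndarray, skeleton: TractSkeleton,
                    params: TFCEParams) -> np.ndarray:
    """Discrete TFCE sum for a non-negative map."""
    vmax = values.max(initial=0.0)
    out = np.zeros_like(values)
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / 100.0
    if dh > vmax:
        warnings.warn("dh exceeds the map maximum; using a single step at "
                      "the maximum", stacklevel=3)
        heights = np.array([vmax])
        dh_eff = vmax
    else:
        heights = np.arange(dh, vmax + 0.5 * dh, dh)
        dh_eff = dh
    edges = skeleton.adjacency
    n = skeleton.n_voxels
    for h in heights:
        above = values >= h
        if not above.any():
            continue
        keep = above[edges[:, 0]] & above[edges[:, 1]]
        e = edges[keep]
        graph = csr_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        # component sizes among suprathreshold voxels only
        lab = labels[above]
        sizes = np.bincount(lab, minlength=labels.max() + 1)
        extent = np.zeros(n)
        extent[above] = sizes[labels[above]]
        out[above] += extent[above] ** params.E * h ** params.H * dh_eff
    return out


def tfce(vmap: VoxelMap, params: TFCEParams | None = None) -> VoxelMap:
    """Two-sided TFCE: positive values enhanced as-is, negative values
    enhanced on the negated map and re-signed."""
    params = params or TFCEParams()
    values = np.asarray(vmap.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("map must be finite")
    pos = _tfce_one_sided(np.maximum(values, 0.0), vmap.skeleton, params)
    neg = _tfce_one_sided(np.maximum(-values, 0.0), vmap.skeleton, params)
    return VoxelMap(values=pos - neg, skeleton=vmap.skeleton, semantics="tfce")


def tfce_permutation_fwe(X, y, skeleton: TractSkeleton,
                         params: TFCEParams | None = None, n_perm: int = 500,
                         seed: int = 0) -> dict:
    """Voxelwise FWE p-values for the TFCE-enhanced covariance map.

    The null is the distribution of the maximum |TFCE| over voxels under
    label permutation; following common practice the unpermuted
    labelling is included as one member of the ensemble, so p-values lie
    in [1/n_perm, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = params or TFCEParams()
    y = np.asarray(y, dtype=float)
    obs_cov = group_covariance_map(X, y, skeleton)
    obs_tfce = tfce(obs_cov, params)
    obs_abs = np.abs(obs_tfce.values)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    null_max[0] = obs_abs.max()
    for b in range(1, n_perm):
        yp = rng.permutation(y)
        t = tfce(group_covariance_map(X, yp, skeleton), params)
        null_max[b] = np.abs(t.values).max()
    p = (null_max[None, :] >= obs_abs[:, None]).mean(axis=1)
    return {
        "covariance": obs_cov,
        "tfce": obs_tfce,
        "p_fwe": VoxelMap(values=p, skeleton=skeleton, semantics="p_value"),
        "null_max": null_max,
    }


def bootstrap_coefficient_map(X, y, skeleton: TractSkeleton,
                              spec: ClassifierSpec, n_boot: int = 500,
                              seed: int = 0,
                              _resample_hook=None) -> dict:
    """Mean linear-classifier coefficient map over bootstrap resamples.

    Subjects are resampled with replacement from the whole sample at the
    spec's fixed hyperparameters; resamples missing a class are redrawn
    (counted in the output).  ``_resample_hook`` replaces the resampling
    (e.g. the identity) for testing.
    """
    if spec.family not in ("enet_lrc", "tv_lrc"):
        raise ValueError("bootstrap maps require a linear family")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    total = np.zeros(X.shape[1])
    redraws = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            if _resample_hook is not None:
                idx = np.asarray(_resample_hook(b))
            else:
                idx = rng.integers(0, n, size=n)
                while len(np.unique(y[idx])) < 2:
                    redraws += 1
                    idx = rng.integers(0, n, size=n)
            if spec.family == "enet_lrc":
                model = train_enet_lrc(X[idx], y[idx], spec)
            else:
                model = train_tv_lrc(X[idx], y[idx], skeleton, spec)
            total += model.coefficient_map()
    return {
        "coef": VoxelMap(values=total / n_boot, skeleton=skeleton,
                         semantics="coefficient"),
        "n_boot": n_boot,
        "redraws": redraws,
    }


@dataclass
class MapDiagnostics:
    sign_agreement: float | None
    pearson_r: float | None
    n_nonzero: int


def coef_covariance_diagnostics(coefs: VoxelMap, covs: VoxelMap) -> MapDiagnostics:
    """Sign agreement and Pearson correlation of coefficient and
    covariance maps over the non-zero coefficient support."""
    if coefs.skeleton is not covs.skeleton and \
            not np.array_equal(coefs.skeleton.voxel_coords, covs.skeleton.voxel_coords):
        raise ValueError("maps must share a skeleton")
    c = coefs.values
    v = covs.values
    support = c != 0
    n_nz = int(support.sum())
    if n_nz == 0:
        return MapDiagnostics(sign_agreement=None, pearson_r=None, n_nonzero=0)
    agree = float(np.mean(np.sign(c[support]) == np.sign(v[support])))
    if n_nz >= 2 and np.std(c[support]) > 0 and np.std(v[support]) > 0:
        r = float(np.corrcoef(c[support], v[support])[0, 1])
    else:
        r = None
    return MapDiagnostics(sign_agreement=agree, pearson_r=r, n_nonzero=n_nz)
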