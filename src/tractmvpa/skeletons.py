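"""Synthetic tract-restricted skeleton geometry.

A :class:`TractSkeleton` is the voxel scaffold every map and feature in
the package lives on: an ordered list of unique integer voxel coordinates
on a 1-mm grid, the 26-neighbour adjacency among them, and labels marking
the two end regions of the tract (the orbitofrontal and anterior-temporal
ends in the uncinate-fasciculus setting the generator emulates).

The generator grows a connected tube of voxels along a smooth random 3-D
curve, so the result is a single connected component by construction and
every voxel carries a normalized arc-length position ``t`` in [0, 1] used
for end-region labelling and for placing spatially tapered group effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["TractSkeleton", "make_skeleton"]


@dataclass
class TractSkeleton:
    """Voxel grid support for tract-restricted analyses.

    Attributes
    ----------
    voxel_coords : (V, 3) int array
        Unique 0-based voxel indices on a 1-mm isotropic grid.
    adjacency : (E, 2) int array
        Symmetric edge list (each undirected edge stored once, i < j)
        under 26-neighbour connectivity.
    end_labels : (V,) array of str
        One of ``frontal`` / ``temporal`` / ``mid`` per voxel.
    arc_position : (V,) float array
        Normalized position along the tract curve in [0, 1]; 0 is the
        frontal end.
    hemisphere : str
        ``"left"`` or ``"right"``; a bookkeeping tag.
    """

    voxel_coords: np.ndarray
    adjacency: np.ndarray
    end_labels: np.ndarray
    arc_position: np.ndarray
    hemisphere: str = "right"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.int64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.int64).reshape(-1, 2)
        if len(np.unique(self.voxel_coords, axis=0)) != len(self.voxel_coords):
            raise ValueError("voxel coordinates must be unique")
        self._index = {tuple(c): i for i, c in enumerate(self.voxel_coords)}

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)

    @property
    def n_edges(self) -> int:
        return len(self.adjacency)

    def region_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.end_labels == label)

    def adjacency_matrix(self):
        """Sparse symmetric boolean adjacency matrix."""
        i, j = self.adjacency.T
        n = self.n_voxels
        data = np.ones(2 * len(i), dtype=bool)
        return coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()

    def n_components(self) -> int:
        return connected_components(self.adjacency_matrix(), directed=False)[0]

    def shape(self) -> tuple:
        """Minimal grid shape containing all voxels."""
        return tuple(int(m) + 1 for m in self.voxel_coords.max(axis=0))

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape(), dtype=bool)
        mask[tuple(self.voxel_coords.T)] = True
        return mask

    def lookup(self, coords) -> np.ndarray:
        """Map (k, 3) coordinates to voxel indices; -1 where absent."""
        return np.array([self._index.get(tuple(c), -1) for c in np.asarray(coords)],
                        dtype=np.int64)


def _edges_from_coords(coords: np.ndarray) -> np.ndarray:
    """26-connectivity edge list (i < j) among unique integer coords."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    edges = []
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None and j > i:
                edges.append((i, j))
    return np.asarray(edges, dtype=np.int64).reshape(-1, 2)


def make_skeleton(n_voxels: int = 940, curvature: float = 0.25,
                  tube_radius: float = 1.3, end_fraction: float = 0.1,
                  hemisphere: str = "right", seed: int = 0) -> TractSkeleton:
    """Grow a connected voxel tube along a smooth random curve.

    Parameters
    ----------
    n_voxels : int
        Exact number of skeleton voxels (default 940, the size of the
        right-hemisphere tract the generator emulates; 832 for the left).
    curvature : float
        Relative amplitude of smooth lateral excursions of the curve
        (0 gives a straight tube).
    tube_radius : float
        Radius (in voxels) within which grid voxels are collected around
        the curve.
    end_fraction : float
        Fraction of voxels labelled as each end region (``frontal`` at
        t=0, ``temporal`` at t=1); must lie in (0, 0.5).
    seed : int
        Seeds the curve geometry; the result is deterministic given all
        arguments.
    """
    if n_voxels < 10:
        raise ValueError("n_voxels must be >= 10 to form two disjoint end regions")
    if not 0 < end_fraction < 0.5:
        raise ValueError("end_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)

    # length sized so a tube of this radius holds ~n_voxels; the walk
    # below keeps collecting until the count is reached regardless
    approx_area = max(1.0, np.pi * tube_radius ** 2 / 2.0)
    length = max(12.0, 1.6 * n_voxels / approx_area)

    n_ctrl = 7
    s_ctrl = np.linspace(0.0, 1.0, n_ctrl)
    base = np.c_[s_ctrl * length, np.zeros(n_ctrl), np.zeros(n_ctrl)]
    wiggle = rng.normal(scale=curvature * length / 6.0, size=(n_ctrl, 2))
    wiggle[0] = wiggle[-1] = 0.0
    base[:, 1:] += wiggle
    curve = CubicSpline(s_ctrl, base, axis=0)

    # oversample the curve far beyond the nominal length so the walk can
    # extend if the tube is thinner than expected near the ends
    s_fine = np.linspace(0.0, 1.0, max(4000, 30 * n_voxels))
    pts = curve(s_fine)
    pts -= pts.min(axis=0)
    pts += 2.0 * tube_radius + 1.0

    r_int = int(np.ceil(tube_radius))
    ball = [(dx, dy, dz)
            for dx in range(-r_int, r_int + 1)
            for dy in range(-r_int, r_int + 1)
            for dz in range(-r_int, r_int + 1)
            if dx * dx + dy * dy + dz * dz <= tube_radius ** 2]
    ball.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))

    taken: dict[tuple, float] = {}
    order: list[tuple] = []
    for s, p in zip(s_fine, pts):
        c0 = np.floor(p).astype(int)
        for off in ball:
            c = (int(c0[0] + off[0]), int(c0[1] + off[1]), int(c0[2] + off[2]))
            if c not in taken:
                if order:
                    prev = order[-1]
                    # only accept voxels 26-adjacent to the existing tube;
                    # check against a recent window for speed
                    ok = False
                    for q in order[-min(len(order), 200):]:
                        if max(abs(c[0] - q[0]), abs(c[1] - q[1]), abs(c[2] - q[2])) == 1:
                            ok = True
                            break
                    if not ok:
                        continue
                taken[c] = s
                order.append(c)
                if len(order) >= n_voxels:
                    break
        if len(order) >= n_voxels:
            break
    if len(order) < n_voxels:
        raise ValueError(
            f"could not grow {n_voxels} voxels; increase curve length or tube_radius")

    coords = np.asarray(order, dtype=np.int64)
    coords -= coords.min(axis=0)
    t = np.array([taken[c] for c in order])
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)

    edges = _edges_from_coords(coords)
    n_end = int(np.ceil(end_fraction * n_voxels))
    ranks = np.argsort(np.argsort(t, kind="stable"), kind="stable")
    labels = np.full(n_voxels, "mid", dtype=object)
    labels[ranks < n_end] = "frontal"
    labels[ranks >= n_voxels - n_end] = "temporal"
    return TractSkeleton(coords, edges, np.asarray(labels), t, hemisphere=hemisphere)
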