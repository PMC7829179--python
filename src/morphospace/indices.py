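"""Functional diversity indices on an assemblage's morphospace points.

Five indices: convex-hull volume (FRic), a 2-D kernel-density
hypervolume (Hyp), minimum-spanning-tree evenness (FEve), and the mean
and standard deviation of nearest-neighbor distances (mNND, sdNND).
All operate on presence/absence point sets — species carry equal
weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

INDEX_NAMES = ("FRic", "Hyp", "FEve", "mNND", "sdNND")


class HullVolume(NamedTuple):
    volume: float
    k_used: int
    degenerate: bool


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex hull volume; degenerate (affinely dependent) sets give 0."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] <= pts.shape[1]:
        return 0.0, True
    if pts.shape[1] == 1:  # qhull needs >= 2 dimensions; 1-D volume is the range
        r = float(np.ptp(pts[:, 0]))
        return r, r == 0.0
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def fric(points: np.ndarray, k: int | None = None) -> HullVolume:
    """Functional richness: minimum convex polytope volume.

    When the assemblage is too small for the requested dimensionality
    (S <= k), the axes are truncated to ``min(k, S - 1)`` and the
    reduction is recorded via ``k_used``.
    """
    pts = np.asarray(points, dtype=float)
    s = pts.shape[0]
    if s < 2:
        raise ValueError("FRic needs at least 2 species")
    k_req = pts.shape[1] if k is None else min(k, pts.shape[1])
    k_used = min(k_req, s - 1)
    vol, degen = hull_volume(pts[:, :k_used])
    return HullVolume(vol, k_used, degen)


def hypervolume2d(
    points: np.ndarray, mass: float = 0.95, grid_size: int = 200
) -> float:
    """Kernel-density hypervolume on the first two axes.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a regular
    ``grid_size`` x ``grid_size`` grid spanning the data range padded by
    three bandwidths per axis; the returned area is that of the
    highest-density region enclosing the requested probability mass.
    """
    pts = np.asarray(points, dtype=float)[:, :2]
    if pts.shape[0] < 3:
        raise ValueError("hypervolume needs at least 3 species")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    kde = gaussian_kde(pts.T, bw_method="silverman")
    bw = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - 3 * bw
    hi = pts.max(axis=0) + 3 * bw
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    gx, gy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()]))
    dens = np.sort(dens)[::-1]
    cum = np.cumsum(dens) * cell
    n_cells = int(np.searchsorted(cum, mass * cum[-1])) + 1
    return float(n_cells * cell)


def _mst_branch_lengths(points: np.ndarray) -> np.ndarray:
    d = squareform(pdist(points))
    # dense zeros mean "no edge" to csgraph; shift off-diagonal entries so
    # coincident points (distance 0) still yield spanning branches
    scale = d.max() if d.max() > 0 else 1.0
    eps = scale * 1e-9
    mst = minimum_spanning_tree(d + eps * (1 - np.eye(d.shape[0]))).toarray()
    bl = mst[mst > 0] - eps
    return np.clip(bl, 0.0, None)


def feve(points: np.ndarray) -> float:
    """Functional evenness over the minimum spanning tree (equal weights).

    With presence/absence data every branch carries weight equal to its
    length; partial evenness PEW_l = len_l / sum(len), and

        FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))

    which is 1 when all branches are equal and approaches 0 as the tree
    becomes dominated by one long branch.
    """
    pts = np.asarray(points, dtype=float)
    s = pts.shape[0]
    if s < 3:
        raise ValueError("FEve needs at least 3 species")
    bl = _mst_branch_lengths(pts)
    total = bl.sum()
    if total == 0:
        raise ValueError("all points identical; FEve undefined")
    # duplicate points yield zero-length branches the sparse MST drops;
    # they contribute min(0, thr) = 0, so pad explicitly to S-1 branches
    if len(bl) < s - 1:
        bl = np.concatenate([bl, np.zeros(s - 1 - len(bl))])
    pew = bl / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def nnd(points: np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation of nearest-neighbor distances."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("nearest-neighbor distances need at least 2 species")
    d = squareform(pdist(pts))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    return float(nn.mean()), float(nn.std(ddof=1))


def nnd_from_dist(d: np.ndarray) -> tuple[float, float]:
    """Same as :func:`nnd` but from a precomputed distance submatrix."""
    d = d.copy()
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    return float(nn.mean()), float(nn.std(ddof=1))


@dataclass
class FDResult:
    """All five indices for one assemblage; undefined indices are NaN."""

    assemblage: str
    richness: int
    fric: float
    hyp: float
    feve: float
    mnnd: float
    sdnnd: float
    k_fric: int
    degenerate: bool


def compute_indices(
    points: np.ndarray, assemblage: str = "", k: int = 5,
    hyp_mass: float = 0.95, hyp_grid: int = 200,
) -> FDResult:
    """Compute all five indices, leaving NaN where S is too small."""
    pts = np.asarray(points, dtype=float)
    s = pts.shape[0]
    hv = fric(pts, k=k) if s >= 2 else HullVolume(np.nan, 0, True)
    hyp = hypervolume2d(pts, hyp_mass, hyp_grid) if s >= 3 else np.nan
    ev = feve(pts) if s >= 3 else np.nan
    mn, sd = nnd(pts) if s >= 2 else (np.nan, np.nan)
    return FDResult(assemblage, s, hv.volume, hyp, ev, mn, sd, hv.k_used, hv.degenerate)
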