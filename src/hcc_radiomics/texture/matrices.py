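"""Texture matrix builders: GLCM, GLRLM, GLSZM, NGTDM.

Conventions
-----------
* GLCM and GLRLM are computed per axial slice along the four in-plane
  unit-distance directions (0, 90, 45, 135 degrees) and pooled over
  slices and directions; voxel pairs and runs never cross an unmasked
  voxel or a slice boundary.
* GLSZM zones are maximal 26-connected 3D components of equal gray level
  within the mask; they partition the masked voxels.
* The NGTDM uses the 3D 26-neighborhood (3x3x3 minus the center); only
  masked neighbors enter the neighborhood mean, and voxels without any
  masked neighbor are excluded.

All builders operate on a :class:`~hcc_radiomics.discretization.QuantizedVolume`
whose grid is 0 outside the mask and 1..Ng inside, and assert their
conservation identities (probability normalization, voxel tiling,
partition of the mask) on every call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..discretization import QuantizedVolume
from ..errors import DegenerateMatrixError

__all__ = ["GLCMatrix", "RunLengthMatrix", "SizeZoneMatrix", "NGTDMTable",
           "glcm_matrix", "glrlm_matrix", "glszm_matrix", "ngtdm_table",
           "IN_PLANE_DIRECTIONS"]

#: unit-distance in-plane offsets (dx, dy) for GLCM/GLRLM: 0, 90, 45, 135 deg
IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, direction-aggregated co-occurrence probabilities p(i, j)."""

    p: np.ndarray          # (ng, ng), sums to 1
    ng: int

    def __post_init__(self):
        total = self.p.sum()
        assert abs(total - 1.0) < 1e-12, f"GLCM not normalized: sum={total}"
        assert np.allclose(self.p, self.p.T, atol=1e-15), "GLCM not symmetric"


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts R(i, j) of runs of gray level i and length j, pooled over
    directions; satisfies sum_ij j*R(i,j) = n_directions * n_voxels."""

    R: np.ndarray          # (ng, max_run_length) integer counts
    n_voxels: int
    n_directions: int

    def __post_init__(self):
        lengths = np.arange(1, self.R.shape[1] + 1)
        tiled = int((self.R * lengths).sum())
        expected = self.n_directions * self.n_voxels
        assert tiled == expected, (
            f"GLRLM tiling identity violated: {tiled} != {expected}")


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Counts Z(i, s) of 26-connected zones of gray level i and size s;
    zones partition the mask: sum_is s*Z(i,s) = n_voxels."""

    Z: np.ndarray          # (ng, max_zone_size) integer counts
    n_voxels: int

    def __post_init__(self):
        sizes = np.arange(1, self.Z.shape[1] + 1)
        covered = int((self.Z * sizes).sum())
        assert covered == self.n_voxels, (
            f"GLSZM partition identity violated: {covered} != {self.n_voxels}")


@dataclass(frozen=True)
class NGTDMTable:
    """Per-gray-level neighborhood gray-tone differences.

    ``s[i-1]`` is the summed absolute deviation of level-i voxels from
    their masked 26-neighborhood mean; ``p[i-1]`` the occurrence fraction
    among the ``n_valid`` voxels that have at least one masked neighbor.
    """

    s: np.ndarray          # (ng,)
    p: np.ndarray          # (ng,), sums to 1 over occurring levels
    n_valid: int
    ng: int

    def __post_init__(self):
        assert abs(self.p.sum() - 1.0) < 1e-12, "NGTDM p_i not normalized"
        assert (self.s >= 0).all(), "NGTDM s_i must be nonnegative"


def _bbox(grid: np.ndarray) -> np.ndarray:
    """Crop to the foreground bounding box (labels > 0)."""
    fg = np.argwhere(grid > 0)
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    return grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _pair_slices(shape, offset):
    """Index slices (sa, sb) such that b = a shifted by +offset."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        sa.append(slice(max(0, -d), n - max(0, d)))
        sb.append(slice(max(0, d), n - max(0, -d)))
    return tuple(sa), tuple(sb)


def glcm_matrix(q: QuantizedVolume,
                directions=IN_PLANE_DIRECTIONS) -> GLCMatrix:
    """Pooled symmetric gray-level co-occurrence matrix.

    Distance-1 co-occurrences between masked voxel pairs are accumulated
    along the in-plane directions within each axial slice, pooled over
    slices and directions, symmetrized, and normalized to sum to 1.
    """
    grid = _bbox(q.grid)
    ng = q.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for dx, dy in directions:
        sa, sb = _pair_slices(grid.shape, (dx, dy, 0))
        a = grid[sa].ravel()
        b = grid[sb].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        flat = (a[ok].astype(np.int64) - 1) * ng + (b[ok] - 1)
        counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T          # symmetrize: count both orderings
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError(
            "no masked voxel pair is adjacent along any direction")
    return GLCMatrix(p=counts / total, ng=ng)


def _runs_1d(line: np.ndarray):
    """Labels and lengths of the maximal nonzero constant runs of a 1D array."""
    if line.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    padded = np.concatenate(([0], line, [0]))
    # boundary k: padded[k] != padded[k+1]  <=>  a segment starts at line[k]
    change = np.flatnonzero(padded[1:] != padded[:-1])
    starts = change[:-1]
    lengths = np.diff(change)
    keep = line[starts] > 0
    return line[starts[keep]].astype(np.int64), lengths[keep].astype(np.int64)


def _slice_lines(sl: np.ndarray, direction):
    """Enumerate the 1D traversal lines of a 2D slice along a direction."""
    dx, dy = direction
    if (dx, dy) == (1, 0):
        return [sl[:, j] for j in range(sl.shape[1])]
    if (dx, dy) == (0, 1):
        return [sl[i, :] for i in range(sl.shape[0])]
    if (dx, dy) == (1, 1):
        return [np.diagonal(sl, offset=k)
                for k in range(-(sl.shape[0] - 1), sl.shape[1])]
    if (dx, dy) == (1, -1):
        flipped = sl[:, ::-1]
        return [np.diagonal(flipped, offset=k)
                for k in range(-(sl.shape[0] - 1), sl.shape[1])]
    raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(q: QuantizedVolume,
                 directions=IN_PLANE_DIRECTIONS) -> RunLengthMatrix:
    """Pooled gray-level run-length matrix.

    A run is a maximal segment of consecutive masked voxels sharing one
    gray level along an in-plane direction of an axial slice; an unmasked
    voxel breaks the run.  Counts are pooled over slices and directions.
    """
    grid = _bbox(q.grid)
    ng = q.ng
    max_len = max(grid.shape[0] + grid.shape[1], 2)
    R = np.zeros((ng, max_len), dtype=np.int64)
    for z in range(grid.shape[2]):
        sl = grid[:, :, z]
        if not sl.any():
            continue
        for direction in directions:
            for line in _slice_lines(sl, direction):
                labels, lengths = _runs_1d(np.ascontiguousarray(line))
                if labels.size:
                    np.add.at(R, (labels - 1, lengths - 1), 1)
    n_voxels = int((grid > 0).sum())
    last = int(np.max(np.nonzero(R.any(axis=0))[0])) + 1 if R.any() else 1
    return RunLengthMatrix(R=R[:, :last], n_voxels=n_voxels,
                           n_directions=len(directions))


def glszm_matrix(q: QuantizedVolume) -> SizeZoneMatrix:
    """Gray-level size-zone matrix over 26-connected equal-label 3D zones."""
    grid = _bbox(q.grid)
    n_voxels = int((grid > 0).sum())
    ng = q.ng
    zone_levels: list[np.ndarray] = []
    zone_sizes: list[np.ndarray] = []
    for level in np.unique(grid[grid > 0]):
        labeled, n_comp = ndimage.label(grid == level, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zone_levels.append(np.full(n_comp, level, dtype=np.int64))
        zone_sizes.append(sizes.astype(np.int64))
    levels = np.concatenate(zone_levels)
    sizes = np.concatenate(zone_sizes)
    Z = np.zeros((ng, int(sizes.max())), dtype=np.int64)
    np.add.at(Z, (levels - 1, sizes - 1), 1)
    return SizeZoneMatrix(Z=Z, n_voxels=n_voxels)


def ngtdm_table(q: QuantizedVolume) -> NGTDMTable:
    """Neighborhood gray-tone difference table over the 26-neighborhood."""
    grid = _bbox(q.grid)
    mask = grid > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_n = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    neigh_sum = ndimage.convolve(grid.astype(float) * mask, kernel, mode="constant")
    valid = mask & (neigh_n > 0.5)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateMatrixError("no masked voxel has a masked neighbor")
    labels = grid[valid]
    mean_neigh = neigh_sum[valid] / neigh_n[valid]
    dev = np.abs(labels - mean_neigh)

    ng = q.ng
    s = np.zeros(ng)
    np.add.at(s, labels - 1, dev)
    counts = np.bincount(labels - 1, minlength=ng).astype(float)
    p = counts / n_valid
    return NGTDMTable(s=s, p=p, n_valid=n_valid, ng=ng)
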