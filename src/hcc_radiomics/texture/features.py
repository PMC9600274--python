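"""Feature formulas for each texture family, plus the global features.

Gray levels i and run lengths / zone sizes j are 1-based throughout.
Histogram moments are computed on quantized labels (the toolbox
convention at a stated Ng); kurtosis is non-excess (a Gaussian scores 3),
and skewness/kurtosis of a zero-variance region are defined as 0.
GLCM entropy uses log base 2.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import QhullError
from skimage.morphology import convex_hull_image

from ..discretization import QuantizedVolume
from ..errors import DegenerateMatrixError, ValidationError
from .matrices import GLCMatrix, NGTDMTable, RunLengthMatrix, SizeZoneMatrix

__all__ = ["global_features", "histogram_features", "glcm_features",
           "glrlm_features", "glszm_features", "ngtdm_features",
           "NGTDM_EPSILON"]

#: caps the coarseness singularity of a perfectly uniform region
NGTDM_EPSILON = 1e-6


# ---------------------------------------------------------------- global

def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of mask faces exposed to background (or the grid edge),
    weighted by the per-axis face areas (spacing-aware)."""
    sx, sy, sz = spacing
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    padded = np.pad(mask.astype(np.int8), 1)
    total = 0.0
    for axis in range(3):
        diff = np.abs(np.diff(padded, axis=axis))
        total += float(diff.sum()) * face_area[axis]
    return total


def _solidity(mask: np.ndarray) -> float:
    """Foreground volume over convex-hull volume, on the voxel grid.

    The hull is rasterized on the same lattice so the ratio is a count
    ratio (spacing cancels) and lies in (0, 1].  Degenerate foregrounds
    (fewer than 4 voxels, or coplanar) are convex by convention.
    """
    n_fg = int(mask.sum())
    if n_fg < 4:
        return 1.0
    # the hull lives inside the foreground bounding box; crop for speed
    fg = np.argwhere(mask)
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    cropped = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    try:
        # hull of voxel centers (no half-voxel dilation): a convex digital
        # shape then scores ~1 within discretization error
        hull = convex_hull_image(cropped, offset_coordinates=False)
    except (QhullError, ValueError):
        return 1.0
    n_hull = int(hull.sum())
    if n_hull <= 0:
        return 1.0
    return min(1.0, n_fg / n_hull)


def global_features(adc, ve, mask) -> dict[str, float]:
    """The nine global features: masked mean/max/min of each map, plus
    mask solidity, surface area (mm^2) and volume (mm^3)."""
    if adc.shape != mask.shape or ve.shape != mask.shape:
        raise ValidationError("maps and mask must share the same grid shape")
    fg = mask.grid
    if not fg.any():
        raise ValidationError("empty mask")
    a = adc.grid[fg]
    v = ve.grid[fg]
    sx, sy, sz = mask.spacing
    return {
        "adc_global_mean": float(a.mean()),
        "adc_global_max": float(a.max()),
        "adc_global_min": float(a.min()),
        "ve_global_mean": float(v.mean()),
        "ve_global_max": float(v.max()),
        "ve_global_min": float(v.min()),
        "global_solidity": _solidity(fg),
        "global_surface_area": _surface_area(fg, mask.spacing),
        "global_volume": float(fg.sum()) * sx * sy * sz,
    }


# ------------------------------------------------------------- histogram

def histogram_features(q: QuantizedVolume) -> dict[str, float]:
    """Variance, skewness and (non-excess) kurtosis of the masked labels.

    Spatially invariant: any permutation of the masked voxels yields the
    same three values.
    """
    labels = q.masked_labels().astype(float)
    m = labels.mean()
    d = labels - m
    m2 = float((d ** 2).mean())
    if m2 == 0.0:
        return {"histogram_variance": 0.0, "histogram_skewness": 0.0,
                "histogram_kurtosis": 0.0}
    m3 = float((d ** 3).mean())
    m4 = float((d ** 4).mean())
    return {
        "histogram_variance": m2,
        "histogram_skewness": m3 / m2 ** 1.5,
        "histogram_kurtosis": m4 / m2 ** 2,
    }


# ------------------------------------------------------------------ GLCM

def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The nine co-occurrence features.

    With marginal mean mu_x = sum_i i p_x(i) and standard deviation
    sigma_x (the matrix is symmetric, so mu_x = mu_y), and the diagonal
    sum distribution p_{x+y}(k) = sum_{i+j=k} p(i, j).
    """
    p = m.p
    ng = m.ng
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]

    px = p.sum(axis=1)
    mu = float((np.arange(1, ng + 1) * px).sum())
    sigma2 = float(((np.arange(1, ng + 1) - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    contrast = float(((i - j) ** 2 * p).sum())
    if sigma == 0.0:
        correlation = 0.0
    else:
        correlation = float(((i - mu) * (j - mu) * p).sum()) / sigma2
    energy = float((p ** 2).sum())
    variance = float(((i - mu) ** 2 * p).sum())
    # p_{x+y}: k = i + j runs 2..2*ng
    ksum = np.zeros(2 * ng + 1)
    np.add.at(ksum, (i + j).ravel(), p.ravel())
    sum_average = float((np.arange(2 * ng + 1) * ksum).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    autocorrelation = float((i * j * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_variance": variance,
        "glcm_sum_average": sum_average,
        "glcm_dissimilarity": dissimilarity,
        "glcm_autocorrelation": autocorrelation,
        "glcm_entropy": entropy,
        "glcm_homogeneity": homogeneity,
    }


# ----------------------------------------------------------------- GLRLM

def _emphasis_features(M: np.ndarray, axis_total: int, prefix: str,
                       names: tuple[str, ...]) -> dict[str, float]:
    """The 13 emphasis/non-uniformity/variance features shared (up to
    naming) by the run-length and size-zone families.

    M(i, j) are counts over gray level i (rows) and run length / zone
    size j (columns); ``axis_total`` is the denominator of the
    percentage feature (direction-count x voxels for runs, voxels for
    zones).
    """
    N = float(M.sum())
    if N == 0:
        raise DegenerateMatrixError(f"{prefix}: empty matrix")
    i = np.arange(1, M.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, M.shape[1] + 1)[None, :].astype(float)
    rho = M / N

    mu_i = float((rho * i).sum())
    mu_j = float((rho * j).sum())
    vals = [
        float((rho / j ** 2).sum()),            # short emphasis
        float((rho * j ** 2).sum()),            # long emphasis
        float((M.sum(axis=1) ** 2).sum() / N),  # gray-level non-uniformity
        float((M.sum(axis=0) ** 2).sum() / N),  # length non-uniformity
        N / float(axis_total),                  # percentage
        float((rho / i ** 2).sum()),            # low gray-level emphasis
        float((rho * i ** 2).sum()),            # high gray-level emphasis
        float((rho / (i ** 2 * j ** 2)).sum()),  # short + low
        float((rho * i ** 2 / j ** 2).sum()),    # short + high
        float((rho * j ** 2 / i ** 2).sum()),    # long + low
        float((rho * i ** 2 * j ** 2).sum()),    # long + high
        float((rho * (i - mu_i) ** 2).sum()),    # gray-level variance
        float((rho * (j - mu_j) ** 2).sum()),    # length variance
    ]
    return {f"{prefix}_{n}": v for n, v in zip(names, vals)}


_GLRLM_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
                "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv")
_GLSZM_NAMES = ("sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
                "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv")


def glrlm_features(r: RunLengthMatrix) -> dict[str, float]:
    """The 13 run-length features (SRE, LRE, GLN, RLN, RP, LGRE, HGRE,
    SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV)."""
    return _emphasis_features(r.R.astype(float),
                              r.n_directions * r.n_voxels,
                              "glrlm", _GLRLM_NAMES)


def glszm_features(z: SizeZoneMatrix) -> dict[str, float]:
    """The 13 size-zone analogues (SZE, LZE, GLN, ZSN, ZP, LGZE, HGZE,
    SZLGE, SZHGE, LZLGE, LZHGE, GLV, ZSV)."""
    return _emphasis_features(z.Z.astype(float), z.n_voxels,
                              "glszm", _GLSZM_NAMES)


# ----------------------------------------------------------------- NGTDM

def ngtdm_features(t: NGTDMTable) -> dict[str, float]:
    """The classical five neighborhood gray-tone difference features:
    coarseness, contrast, busyness, complexity and strength."""
    p = t.p
    s = t.s
    n = float(t.n_valid)
    levels = np.arange(1, t.ng + 1).astype(float)
    occ = p > 0
    ngp = int(occ.sum())

    coarseness = 1.0 / (NGTDM_EPSILON + float((p * s).sum()))

    pi = p[occ][:, None]
    pj = p[occ][None, :]
    ii = levels[occ][:, None]
    jj = levels[occ][None, :]
    si = s[occ][:, None]
    sj = s[occ][None, :]

    if ngp > 1:
        contrast = (float((pi * pj * (ii - jj) ** 2).sum())
                    / (ngp * (ngp - 1))) * (float(s.sum()) / n)
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = (float((p * s).sum()) / denom_busy) if denom_busy > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj)
                            / (n * (pi + pj))).sum())
        strength = (float(((pi + pj) * (ii - jj) ** 2).sum())
                    / (NGTDM_EPSILON + float(s.sum())))
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
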