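"""Independent brute-force oracles for the texture operators.

Everything here is written as naive per-voxel Python loops, deliberately
sharing no code with the package implementation, so agreement between the
two routes is evidence of correctness rather than of shared bugs.
Label grids follow the package convention: 0 outside the mask, 1..ng
inside.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRECTIONS_2D = ((1, 0), (0, 1), (1, 1), (1, -1))


def oracle_glcm(labels: np.ndarray, directions=DIRECTIONS_2D,
                ng: int | None = None) -> np.ndarray:
    """Symmetric pooled co-occurrence probabilities by pair enumeration."""
    nx, ny, nz = labels.shape
    ng = int(labels.max()) if ng is None else ng
    counts = np.zeros((ng, ng))
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                a = labels[x, y, z]
                if a == 0:
                    continue
                for dx, dy in directions:
                    u, v = x + dx, y + dy
                    if 0 <= u < nx and 0 <= v < ny:
                        b = labels[u, v, z]
                        if b > 0:
                            counts[a - 1, b - 1] += 1
                            counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total


def oracle_glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum(((i + 1) - mu) ** 2 * px[i] for i in range(ng))
    out = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            if v == 0 and i != j:
                pass
            gi, gj = i + 1, j + 1
            out["contrast"] += (gi - gj) ** 2 * v
            out["energy"] += v * v
            out["variance"] += (gi - mu) ** 2 * v
            out["sum_average"] += (gi + gj) * v
            out["dissimilarity"] += abs(gi - gj) * v
            out["autocorrelation"] += gi * gj * v
            if v > 0:
                out["entropy"] -= v * math.log2(v)
            out["homogeneity"] += v / (1 + abs(gi - gj))
            if sigma2 > 0:
                out["correlation"] += (gi - mu) * (gj - mu) * v / sigma2
    out.setdefault("correlation", 0.0)
    return dict(out)


def oracle_glrlm(labels: np.ndarray, directions=DIRECTIONS_2D) -> dict:
    """Run counts {(level, length): count} by explicit line walking."""
    nx, ny, nz = labels.shape
    runs: dict = defaultdict(int)
    for z in range(nz):
        for dx, dy in directions:
            starts = []
            for x in range(nx):
                for y in range(ny):
                    # a line start has no in-grid predecessor
                    px, py = x - dx, y - dy
                    if not (0 <= px < nx and 0 <= py < ny):
                        starts.append((x, y))
            for x0, y0 in starts:
                x, y = x0, y0
                cur, length = 0, 0
                while 0 <= x < nx and 0 <= y < ny:
                    lab = labels[x, y, z]
                    if lab == cur and lab > 0:
                        length += 1
                    else:
                        if cur > 0:
                            runs[(cur, length)] += 1
                        cur, length = lab, (1 if lab > 0 else 0)
                    x, y = x + dx, y + dy
                if cur > 0:
                    runs[(cur, length)] += 1
    return dict(runs)


def _emphasis_oracle(counts: dict, axis_total: int) -> dict:
    """The 13 shared emphasis features from {(level, j): count}."""
    N = sum(counts.values())
    rho = {k: c / N for k, c in counts.items()}
    mu_i = sum(i * r for (i, _), r in rho.items())
    mu_j = sum(j * r for (_, j), r in rho.items())
    by_i = defaultdict(float)
    by_j = defaultdict(float)
    for (i, j), c in counts.items():
        by_i[i] += c
        by_j[j] += c
    return {
        "short": sum(r / j ** 2 for (_, j), r in rho.items()),
        "long": sum(r * j ** 2 for (_, j), r in rho.items()),
        "gln": sum(v ** 2 for v in by_i.values()) / N,
        "ln": sum(v ** 2 for v in by_j.values()) / N,
        "pct": N / axis_total,
        "low": sum(r / i ** 2 for (i, _), r in rho.items()),
        "high": sum(r * i ** 2 for (i, _), r in rho.items()),
        "short_low": sum(r / (i ** 2 * j ** 2) for (i, j), r in rho.items()),
        "short_high": sum(r * i ** 2 / j ** 2 for (i, j), r in rho.items()),
        "long_low": sum(r * j ** 2 / i ** 2 for (i, j), r in rho.items()),
        "long_high": sum(r * i ** 2 * j ** 2 for (i, j), r in rho.items()),
        "glv": sum(r * (i - mu_i) ** 2 for (i, _), r in rho.items()),
        "jv": sum(r * (j - mu_j) ** 2 for (_, j), r in rho.items()),
    }


def oracle_glrlm_features(labels: np.ndarray, directions=DIRECTIONS_2D) -> dict:
    runs = oracle_glrlm(labels, directions)
    n_vox = int((labels > 0).sum())
    return _emphasis_oracle(runs, len(directions) * n_vox)


def oracle_glszm(labels: np.ndarray) -> dict:
    """Zone counts {(level, size): count} by flood fill (26-connected)."""
    nx, ny, nz = labels.shape
    seen = np.zeros(labels.shape, dtype=bool)
    zones: dict = defaultdict(int)
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                level = labels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in offs:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                and not seen[u, v, w]
                                and labels[u, v, w] == level):
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                zones[(int(level), size)] += 1
    return dict(zones)


def oracle_glszm_features(labels: np.ndarray) -> dict:
    zones = oracle_glszm(labels)
    n_vox = int((labels > 0).sum())
    return _emphasis_oracle(zones, n_vox)


def oracle_ngtdm(labels: np.ndarray, ng: int, eps: float = 1e-6) -> dict:
    """The five neighborhood gray-tone difference features per voxel loop."""
    nx, ny, nz = labels.shape
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lab = labels[x, y, z]
                if lab == 0:
                    continue
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                    and labels[u, v, w] > 0):
                                neigh.append(labels[u, v, w])
                if not neigh:
                    continue
                n_valid += 1
                n_i[lab - 1] += 1
                s[lab - 1] += abs(lab - sum(neigh) / len(neigh))
    p = n_i / n_valid
    occ = [i for i in range(ng) if p[i] > 0]
    ngp = len(occ)
    coarse = 1.0 / (eps + sum(p[i] * s[i] for i in range(ng)))
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
                    / (ngp * (ngp - 1))) * (s.sum() / n_valid)
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ)
        busy = sum(p[i] * s[i] for i in range(ng)) / denom if denom > 0 else 0.0
        cmplx = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j])
                    / (n_valid * (p[i] + p[j])) for i in occ for j in occ)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ)
                    / (eps + s.sum()))
    else:
        contrast = busy = cmplx = strength = 0.0
    return {"coarseness": coarse, "contrast": contrast, "busyness": busy,
            "complexity": cmplx, "strength": strength}


def oracle_surface_area(mask: np.ndarray, spacing) -> float:
    """Exposed-face counting by explicit 6-neighbor loop."""
    sx, sy, sz = spacing
    areas = {(1, 0, 0): sy * sz, (-1, 0, 0): sy * sz,
             (0, 1, 0): sx * sz, (0, -1, 0): sx * sz,
             (0, 0, 1): sx * sy, (0, 0, -1): sx * sy}
    nx, ny, nz = mask.shape
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for (dx, dy, dz), a in areas.items():
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz) \
                            or not mask[u, v, w]:
                        total += a
    return total
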