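"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately naive (pure-python loops, direct formula
transcription) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Even-odd ray-casting test; points on an edge count as inside."""
    verts = [(float(a), float(b)) for a, b in vertices]
    n = len(verts)
    # boundary check: point on any closed-ring segment
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
    inside = False
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def rasterize_contour(vertices, dims):
    M, N = dims
    mask = np.zeros((M, N), dtype=bool)
    for r in range(M):
        for c in range(N):
            mask[r, c] = point_in_polygon(c + 0.5, r + 0.5, vertices)
    return mask


def moments(values) -> tuple[float, float, float, float, float]:
    """(mean, population variance, skewness, kurtosis, histogram entropy)."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    if var > 0:
        skew = (sum((v - mean) ** 3 for v in vals) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in vals) / n) / var**2
    else:
        skew = kurt = math.nan
    counts: dict[int, int] = {}
    for v in vals:
        counts[int(v)] = counts.get(int(v), 0) + 1
    ent = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return mean, var, skew, kurt, ent


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts(image, mask, d: int, angle: int, symmetric: bool = True) -> dict[tuple[int, int], int]:
    """Ordered-pair counts by full enumeration of every pixel."""
    M = len(image)
    N = len(image[0])
    ur, uc = _OFFSETS[angle]
    dr, dc = ur * d, uc * d
    counts: dict[tuple[int, int], int] = {}
    for r in range(M):
        for c in range(N):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < M and 0 <= c2 < N and mask[r][c] and mask[r2][c2]:
                pair = (int(image[r][c]), int(image[r2][c2]))
                counts[pair] = counts.get(pair, 0) + 1
                if symmetric:
                    rev = (pair[1], pair[0])
                    counts[rev] = counts.get(rev, 0) + 1
    return counts


def glcm_features(counts: dict[tuple[int, int], int]) -> dict[str, float]:
    total = sum(counts.values())
    contrast = energy = homogeneity = entropy = 0.0
    for (i, j), c in counts.items():
        p = c / total
        contrast += abs(i - j) ** 2 * p
        energy += p * p
        homogeneity += p / (1 + (i - j) ** 2)
        entropy -= p * math.log2(p)
    return {"contrast": contrast, "energy": energy, "homogeneity": homogeneity, "entropy": entropy}


def texture_by_enumeration(image, mask, d: int) -> dict[str, float]:
    """Four-angle-averaged texture features via exhaustive pair enumeration."""
    feats = []
    for angle in (0, 45, 90, 135):
        counts = glcm_counts(image, mask, d, angle)
        if not counts:
            raise ValueError("no pairs")
        feats.append(glcm_features(counts))
    return {k: sum(f[k] for f in feats) / len(feats) for k in feats[0]}


# D-study oracle: explicit per-effect divisors, written out by hand
_EFFECT_DIVISORS = {
    "E": ("e",), "V": ("v",), "I": ("i",),
    "SE": ("e",), "SV": ("v",), "SI": ("i",),
    "EV": ("e", "v"), "EI": ("e", "i"), "VI": ("v", "i"),
    "SEV": ("e", "v"), "SEI": ("e", "i"), "SVI": ("v", "i"),
    "EVI": ("e", "v", "i"), "SEVI": ("e", "v", "i"),
}


def dstudy_by_hand(components: dict[str, float], n_e: int, n_v: int, n_i: int) -> tuple[float, float]:
    """(phi, sem) by term-by-term summation."""
    sizes = {"e": n_e, "v": n_v, "i": n_i}
    err = 0.0
    for eff, facets in _EFFECT_DIVISORS.items():
        denom = 1
        for f in facets:
            denom *= sizes[f]
        err += max(0.0, components.get(eff, 0.0)) / denom
    s2 = max(0.0, components.get("S", 0.0))
    return s2 / (s2 + err), math.sqrt(err)
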