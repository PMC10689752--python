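"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: the dilated
hull volume is estimated by rejection sampling with an exact point-to-
triangle distance, and the ideal-lattice bond-order values are evaluated
directly from the Steinhardt sum over explicit neighbor shells.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y


def point_triangle_distance(P: np.ndarray, A, B, C) -> np.ndarray:
    """Exact distance from each point in P to triangle ABC (Ericson's
    region-based algorithm, vectorized over P)."""
    ab, ac = B - A, C - A
    ap = P - A
    d1, d2 = ap @ ab, ap @ ac
    bp = P - B
    d3, d4 = bp @ ab, bp @ ac
    cp = P - C
    d5, d6 = cp @ ab, cp @ ac
    Q = np.empty_like(P)
    done = np.zeros(len(P), bool)

    m = (d1 <= 0) & (d2 <= 0)
    Q[m] = A
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    Q[m] = B
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = d1 / (d1 - d3 + 1e-300)
    Q[m] = A + v[m, None] * ab
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    Q[m] = C
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = d2 / (d2 - d6 + 1e-300)
    Q[m] = A + w[m, None] * ac
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    w = (d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300)
    Q[m] = B + w[m, None] * (C - B)
    done |= m
    m = ~done
    denom = va + vb + vc
    v = vb / (denom + 1e-300)
    w = vc / (denom + 1e-300)
    Q[m] = A + v[m, None] * ab + w[m, None] * ac
    return np.linalg.norm(P - Q, axis=1)


def mc_dilated_volume(points: np.ndarray, r: float, n_samples: int, seed: int):
    """Monte-Carlo estimate (value, standard error) of the volume within
    distance r of the convex hull of ``points`` (rejection sampling in the
    bounding box)."""
    points = np.asarray(points, float)
    rng = np.random.default_rng(seed)
    lo, hi = points.min(0) - r, points.max(0) + r
    box = float(np.prod(hi - lo))
    samples = rng.uniform(lo, hi, (n_samples, 3))
    if len(points) >= 4:
        try:
            hull = ConvexHull(points)
        except Exception:
            hull = None
    else:
        hull = None
    if hull is not None and hull.volume > 0:
        excess = samples @ hull.equations[:, :3].T + hull.equations[:, 3]
        inside = (excess <= 0).all(axis=1)
        candidates = np.where(~inside & (excess.max(axis=1) <= r))[0]
        dmin = np.full(len(candidates), np.inf)
        P = samples[candidates]
        for simplex in hull.simplices:
            a, b, c = points[simplex]
            dmin = np.minimum(dmin, point_triangle_distance(P, a, b, c))
        count = int(inside.sum()) + int((dmin <= r).sum())
    else:
        # degenerate hull: distance to the point set's convex hull equals
        # distance to all simplices of any triangulation; fall back to
        # distance-to-segments/points
        import itertools

        dmin = np.full(n_samples, np.inf)
        for i in range(len(points)):
            dmin = np.minimum(dmin, np.linalg.norm(samples - points[i], axis=1))
        for i, j in itertools.combinations(range(len(points)), 2):
            a, b = points[i], points[j]
            denom = (b - a) @ (b - a)
            if denom == 0:
                continue
            t = np.clip((samples - a) @ (b - a) / denom, 0.0, 1.0)
            proj = a + t[:, None] * (b - a)
            dmin = np.minimum(dmin, np.linalg.norm(samples - proj, axis=1))
        for i, j, k in itertools.combinations(range(len(points)), 3):
            a, b, c = points[i], points[j], points[k]
            if np.linalg.norm(np.cross(b - a, c - a)) < 1e-12:
                continue
            dmin = np.minimum(dmin, point_triangle_distance(samples, a, b, c))
        count = int((dmin <= r).sum())
    p = count / n_samples
    value = box * p
    se = box * np.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return value, se


def steinhardt_on_shell(bonds: np.ndarray, l: int = 6) -> float:
    """Steinhardt q_l evaluated directly on an explicit bond set."""
    bonds = np.asarray(bonds, float)
    rn = np.linalg.norm(bonds, axis=1)
    theta = np.arccos(np.clip(bonds[:, 2] / rn, -1, 1))
    phi = np.arctan2(bonds[:, 1], bonds[:, 0])
    total = 0.0
    for m in range(-l, l + 1):
        ylm = sph_harm_y(l, m, theta, phi)
        total += abs(ylm.mean()) ** 2
    return float(np.sqrt(4 * np.pi / (2 * l + 1) * total))


def fcc_shell() -> np.ndarray:
    """The 12 nearest-neighbor bond vectors of an FCC site."""
    out = []
    for a, b in [(0, 1), (0, 2), (1, 2)]:
        for sa in (1, -1):
            for sb in (1, -1):
                v = np.zeros(3)
                v[a], v[b] = sa, sb
                out.append(v / np.sqrt(2))
    return np.array(out)


def hcp_shell() -> np.ndarray:
    """The 12 nearest-neighbor bond vectors of an HCP site."""
    out = []
    for k in range(6):
        ang = np.pi / 3 * k
        out.append([np.cos(ang), np.sin(ang), 0.0])
    for dz in (1, -1):
        for k in range(3):
            ang = 2 * np.pi / 3 * k + np.pi / 6
            out.append(
                [
                    np.cos(ang) / np.sqrt(3),
                    np.sin(ang) / np.sqrt(3),
                    dz * np.sqrt(2.0 / 3.0),
                ]
            )
    return np.array(out)


def spheroid_area(a: float, c: float) -> float:
    """Closed-form spheroid surface area (independent re-derivation)."""
    if np.isclose(a, c):
        return 4 * np.pi * a * a
    if c > a:
        e = np.sqrt(1 - (a / c) ** 2)
        return 2 * np.pi * a * a + 2 * np.pi * a * c * np.arcsin(e) / e
    e = np.sqrt(1 - (c / a) ** 2)
    return 2 * np.pi * a * a + np.pi * c * c / e * np.log((1 + e) / (1 - e))
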