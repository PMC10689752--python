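"""Exact packing-fraction machinery for finite sphere clusters.

The central quantity is the packing fraction of a cluster inside the tightest
convex container that holds it, ``eta_ch = N * V0 / V_ch``, where ``V_ch`` is
the volume of the convex hull of the *balls* (not of the centers).  The hull
of the balls equals the hull of the centers dilated (Minkowski sum) by the
sphere radius ``r``, so for a full-dimensional hull the Steiner formula gives
it exactly::

    V_ch = V_hull + A_hull * r + (sum_e l_e * gamma_e / 2) * r^2 + (4*pi/3) * r^3

with ``l_e`` the edge lengths and ``gamma_e`` the exterior dihedral angles of
the center hull.  Degenerate clusters (coplanar, collinear, a single point)
are routed to the corresponding lower-dimensional closed forms: a dilated
polygon, a spherocylinder, and a single ball.

The reference against which clusters are scored is the "sausage": N collinear
spheres at contact, whose hull of balls is a spherocylinder, giving the closed
form ``eta_lin(N) = 2N / (3N - 1)``.
"""

from __future__ import annotations

import itertools
import json
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "SphereCluster",
    "HullSummary",
    "SausageReference",
    "center_hull",
    "dilated_volume",
    "hull_summary",
    "packing_fraction_ch",
    "eta_lin",
    "nu_lin",
    "sausage_reference",
    "reduced_volume",
    "sphere_volume",
]

#: relative singular-value threshold used to detect degenerate hull dimensions
DIM_TOL = 1e-8

#: relative tolerance on the hard-sphere overlap constraint
OVERLAP_TOL = 1e-9


def sphere_volume(diameter: float = 1.0) -> float:
    """Volume of a single sphere, ``V0 = (pi/6) d^3``."""
    return np.pi / 6.0 * diameter**3


@dataclass
class SphereCluster:
    """N labelled sphere centers sharing a common diameter.

    Coordinates are in the same length unit as ``diameter`` (by convention the
    colloid diameter sigma_c, so ``diameter=1`` for most constructions).
    """

    centers: np.ndarray
    diameter: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be an (N, 3) array")
        if not np.isfinite(self.centers).all():
            raise ValueError("non-finite coordinates in cluster")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def n(self) -> int:
        return len(self.centers)

    def min_distance(self) -> float:
        """Smallest pairwise center distance (inf for N = 1)."""
        if self.n < 2:
            return np.inf
        from scipy.spatial.distance import pdist

        return float(pdist(self.centers).min())

    def validate_overlaps(self, tol: float = OVERLAP_TOL) -> None:
        """Raise ``ValueError`` naming the closest pair if any two spheres
        overlap beyond ``diameter * (1 - tol)``."""
        if self.n < 2:
            return
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(self.centers))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] < self.diameter * (1.0 - tol):
            raise ValueError(
                f"spheres {i} and {j} overlap: distance {d[i, j]:.12g} "
                f"< diameter {self.diameter:.12g}"
            )


@dataclass
class HullSummary:
    """Convex hull of the centers plus its Steiner decomposition.

    ``dim`` is the intrinsic dimension of the center hull.  For ``dim < 3``
    the 3-D measures are zero and the lower-dimensional ones are stored in
    ``length`` (dim 1) or ``area2``/``perimeter2`` (dim 2).  ``V_ch`` and
    ``eta_ch`` are filled once a dilation radius is known.
    """

    n: int
    dim: int
    V_hull: float = 0.0
    A_hull: float = 0.0
    edge_term: float = 0.0
    length: float = 0.0
    area2: float = 0.0
    perimeter2: float = 0.0
    V_ch: float | None = None
    eta_ch: float | None = None

    def to_record(self, eta_lin_value: float | None = None) -> dict:
        rec = {
            "N": self.n,
            "dim": self.dim,
            "V_hull": self.V_hull,
            "A_hull": self.A_hull,
            "edge_term": self.edge_term,
            "V_ch": self.V_ch,
            "eta_ch": self.eta_ch,
        }
        if eta_lin_value is not None:
            rec["eta_lin"] = eta_lin_value
            rec["beats_sausage"] = bool(
                self.eta_ch is not None and self.eta_ch > eta_lin_value
            )
        return rec

    def to_json(self, eta_lin_value: float | None = None) -> str:
        return json.dumps(self.to_record(eta_lin_value))


@dataclass
class SausageReference:
    """Closed-form packing fraction and reduced volume of the ideal linear
    arrangement of N spheres at contact."""

    N: int
    eta_lin: float
    nu_lin: float


def _intrinsic_dimension(centered: np.ndarray) -> tuple[int, np.ndarray]:
    """Number of singular values above ``DIM_TOL`` times the largest, plus the
    right singular vectors for projecting onto the affine hull."""
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0:
        return 0, np.eye(3)
    dim = int((sv > DIM_TOL * sv[0]).sum())
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    return dim, vt


def center_hull(cluster: SphereCluster) -> HullSummary:
    """Convex hull of the sphere centers with degenerate-dimension handling.

    Returns the undilated measures: volume, surface area and the edge term
    ``sum_e l_e * gamma_e / 2`` (exterior dihedral angles) for dim 3; polygon
    area/perimeter for dim 2; segment length for dim 1.
    """
    pts = cluster.centers
    n = len(pts)
    if n == 1:
        return HullSummary(n=1, dim=0)
    c = pts - pts.mean(axis=0)
    dim, vt = _intrinsic_dimension(c)
    if dim == 0:
        return HullSummary(n=n, dim=0)
    if dim == 1:
        t = c @ vt[0]
        return HullSummary(n=n, dim=1, length=float(t.max() - t.min()))
    if dim == 2:
        p2 = c @ vt[:2].T
        hull2 = ConvexHull(p2)
        # in 2-D scipy reports area as 'volume' and perimeter as 'area'
        return HullSummary(
            n=n, dim=2, area2=float(hull2.volume), perimeter2=float(hull2.area)
        )
    hull = ConvexHull(pts)
    edge_normals: dict[tuple[int, int], list[np.ndarray]] = defaultdict(list)
    for simplex, eq in zip(hull.simplices, hull.equations):
        nrm = eq[:3]
        for a, b in itertools.combinations(sorted(simplex), 2):
            edge_normals[(a, b)].append(nrm)
    edge_term = 0.0
    for (a, b), normals in edge_normals.items():
        if len(normals) != 2:  # pragma: no cover - qhull guarantees 2
            raise RuntimeError(f"hull edge ({a}, {b}) not shared by 2 facets")
        cos_g = float(np.clip(np.dot(normals[0], normals[1]), -1.0, 1.0))
        gamma = float(np.arccos(cos_g))  # exterior dihedral angle
        edge_term += float(np.linalg.norm(pts[a] - pts[b])) * gamma / 2.0
    return HullSummary(
        n=n,
        dim=3,
        V_hull=float(hull.volume),
        A_hull=float(hull.area),
        edge_term=edge_term,
    )


def dilated_volume(hull: HullSummary, r: float) -> float:
    """Volume of the center hull dilated by radius ``r`` (hull of the balls).

    Steiner formula in dim 3; closed forms for the degenerate dimensions:
    slab + half-cylinders + ball for a polygon, spherocylinder for a segment,
    a single ball for a point.
    """
    if r <= 0:
        raise ValueError("dilation radius must be positive")
    ball = 4.0 / 3.0 * np.pi * r**3
    if hull.dim == 0:
        return ball
    if hull.dim == 1:
        return np.pi * r**2 * hull.length + ball
    if hull.dim == 2:
        return 2.0 * r * hull.area2 + (np.pi / 2.0) * r**2 * hull.perimeter2 + ball
    return hull.V_hull + hull.A_hull * r + hull.edge_term * r**2 + ball


def hull_summary(cluster: SphereCluster, validate: bool = True) -> HullSummary:
    """Full hull summary of a cluster: center hull, dilated volume at the
    sphere radius, and the convex-hull packing fraction ``eta_ch``."""
    if validate:
        cluster.validate_overlaps()
    hull = center_hull(cluster)
    r = cluster.diameter / 2.0
    hull.V_ch = float(dilated_volume(hull, r))
    hull.eta_ch = cluster.n * sphere_volume(cluster.diameter) / hull.V_ch
    return hull


def packing_fraction_ch(cluster: SphereCluster, validate: bool = True) -> float:
    """Convex-hull-of-balls packing fraction ``eta_ch = N V0 / V_ch``."""
    return float(hull_summary(cluster, validate=validate).eta_ch)


def eta_lin(N: int) -> float:
    """Packing fraction of N spheres on a line at contact.

    The hull of the balls is a spherocylinder of length ``(N-1) d`` and radius
    ``d/2``; the ratio reduces to ``2N / (3N - 1)`` independent of ``d``.
    Decreases monotonically from 1 (N = 1) to 2/3 as N grows.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return 2.0 * N / (3.0 * N - 1.0)


def nu_lin(N: int) -> float:
    """Reduced volume of the tightest linear arrangement of N spheres:
    ``(4/3 + 2(N-1)) / ((4/3) N^{3/2})``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return (4.0 / 3.0 + 2.0 * (N - 1)) / (4.0 / 3.0 * N**1.5)


def sausage_reference(N: int) -> SausageReference:
    return SausageReference(N=N, eta_lin=eta_lin(N), nu_lin=nu_lin(N))


def reduced_volume(V_v: float, A_v: float) -> float:
    """Reduced volume ``nu = 3 sqrt(4 pi) V / A^{3/2}``.

    Ratio of the vesicle volume to the volume of the sphere with the same
    surface area; 1 for a sphere by the isoperimetric equality, smaller for
    any deflated shape.  A value above ``1 + 1e-6`` signals an inconsistent
    (non-realizable) volume/area pair and raises.
    """
    if V_v <= 0 or A_v <= 0:
        raise ValueError("volume and area must be positive")
    nu = 3.0 * np.sqrt(4.0 * np.pi) * V_v / A_v**1.5
    if nu > 1.0 + 1e-6:
        raise ValueError(
            f"reduced volume {nu:.8g} > 1: inconsistent volume/area pair"
        )
    return float(min(nu, 1.0))
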