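"""Shape and order diagnostics for colloid clusters and vesicle bead clouds.

* ``kappa2`` — relative shape anisotropy from the gyration tensor:
  ``kappa^2 = 3 (a_x^2 + a_y^2 + a_z^2) / (2 (a_x + a_y + a_z)^2) - 1/2``
  with a_x >= a_y >= a_z the eigenvalues.  0 for isotropic clusters, 1/4 for
  symmetric planar ones, 1 for collinear ones.
* ``q6`` — Steinhardt l = 6 bond-orientational order, sensitive to FCC-like
  local order in compact clusters.
* ``vesicle_geometry`` — watertight surface reconstruction of a membrane
  bead cloud giving the enclosed volume, area, reduced volume nu and colloid
  packing fraction eta.
* ``classify`` / ``detect_bistability`` — conformation labels from kappa^2
  and two-state switching detection on kappa^2(t) time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from scipy.special import sph_harm_y

from .geometry import SphereCluster, reduced_volume, sphere_volume

__all__ = [
    "GyrationResult",
    "VesicleFrame",
    "StateLabel",
    "BistabilitySegment",
    "kappa2",
    "q6",
    "vesicle_geometry",
    "classify",
    "detect_bistability",
]

#: classifier band edges on kappa^2: cluster < 0.15 <= plate < 0.35 <=
#: intermediate < 0.5 <= linear
BAND_EDGES = (0.15, 0.35, 0.5)
LABELS = ("cluster", "plate", "intermediate", "linear")


@dataclass
class GyrationResult:
    eigenvalues: np.ndarray  # descending, units length^2
    kappa2: float


@dataclass
class VesicleFrame:
    """Membrane bead positions (+ optional orientations) and colloid positions
    at one instant.  Lengths in sigma; time in tau = sqrt(m sigma^2 / eps)."""

    beads: np.ndarray
    orientations: np.ndarray | None = None
    colloids: np.ndarray | None = None
    colloid_diameter: float = 12.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.beads = np.atleast_2d(np.asarray(self.beads, dtype=float))
        if len(self.beads) < 4:
            raise ValueError("need at least 4 membrane beads")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("orientations must be unit vectors")
        if self.colloids is not None:
            self.colloids = np.atleast_2d(np.asarray(self.colloids, dtype=float))


@dataclass
class StateLabel:
    label: str
    kappa2: float
    nu: float | None = None


@dataclass
class BistabilitySegment:
    state: str
    start: float
    end: float


def kappa2(points: np.ndarray) -> GyrationResult:
    """Relative shape anisotropy of a point configuration.

    Unweighted gyration tensor of the centered coordinates; invariant under
    rigid motions and uniform scaling.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("kappa2 needs at least 2 points")
    c = pts - pts.mean(axis=0)
    gyr = c.T @ c / len(c)
    ev = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    tr = ev.sum()
    if tr <= 0.0:
        raise ValueError("degenerate input: all points coincide")
    k2 = 1.5 * float((ev**2).sum()) / float(tr**2) - 0.5
    return GyrationResult(eigenvalues=ev, kappa2=float(np.clip(k2, 0.0, 1.0)))


def q6(
    cluster: SphereCluster | np.ndarray,
    neighbor_cutoff: float | None = None,
    l: int = 6,
    per_particle: bool = False,
):
    """Cluster-averaged Steinhardt bond-order parameter q_l (default l = 6).

    Per particle, ``q_l = sqrt(4 pi / (2l+1) * sum_m |<Y_lm(r_hat)>|^2)``
    with the average over neighbors within ``neighbor_cutoff`` (default 1.33
    diameters, the midpoint of the first and second FCC shells).  Particles
    with no neighbors contribute 0 with a warning.  The ideal FCC shell gives
    ~0.575, ideal HCP ~0.485, a single bond exactly 1.
    """
    if isinstance(cluster, SphereCluster):
        pts = cluster.centers
        d = cluster.diameter
    else:
        pts = np.atleast_2d(np.asarray(cluster, dtype=float))
        d = 1.0
    if len(pts) < 2:
        raise ValueError("q6 needs at least 2 particles")
    cutoff = 1.33 * d if neighbor_cutoff is None else neighbor_cutoff
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    neigh: list[list[int]] = [[] for _ in range(len(pts))]
    for a, b in pairs:
        neigh[a].append(b)
        neigh[b].append(a)
    ms = np.arange(-l, l + 1)
    qi = np.zeros(len(pts))
    isolated = 0
    for i, nb in enumerate(neigh):
        if not nb:
            isolated += 1
            continue
        bonds = pts[nb] - pts[i]
        rn = np.linalg.norm(bonds, axis=1)
        theta = np.arccos(np.clip(bonds[:, 2] / rn, -1.0, 1.0))
        phi = np.arctan2(bonds[:, 1], bonds[:, 0])
        # sph_harm_y(l, m, polar, azimuth)
        ylm = sph_harm_y(
            np.full((len(ms), len(nb)), l),
            ms[:, None],
            theta[None, :],
            phi[None, :],
        )
        qlm = ylm.mean(axis=1)
        qi[i] = np.sqrt(4.0 * np.pi / (2 * l + 1) * float((np.abs(qlm) ** 2).sum()))
    if isolated:
        warnings.warn(
            f"{isolated} particle(s) without neighbors contribute q{l} = 0",
            stacklevel=2,
        )
    if per_particle:
        return qi
    return float(qi.mean())


def _alpha_shape_surface(points: np.ndarray, alpha: float):
    """Boundary triangles (outward-oriented) of the alpha complex of a point
    cloud: Delaunay tetrahedra with circumradius < alpha, faces kept if they
    belong to exactly one kept tetrahedron."""
    tri = Delaunay(points)
    tets = tri.simplices
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    # circumradius per tetrahedron
    ba, ca, da = b - a, c - a, d - a
    det = np.einsum("ij,ij->i", ba, np.cross(ca, da))
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (
            np.einsum("ij,ij->i", ba, ba)[:, None] * np.cross(ca, da)
            + np.einsum("ij,ij->i", ca, ca)[:, None] * np.cross(da, ba)
            + np.einsum("ij,ij->i", da, da)[:, None] * np.cross(ba, ca)
        ) / (2.0 * det[:, None])
    circ = np.linalg.norm(u, axis=1)
    keep = np.where((np.abs(det) > 1e-12) & (circ < alpha))[0]
    face_count: dict[tuple[int, int, int], list] = {}
    for ti in keep:
        t = tets[ti]
        for omit in range(4):
            face = tuple(sorted(np.delete(t, omit)))
            rec = face_count.setdefault(face, [0, None, None])
            rec[0] += 1
            rec[1] = t[omit]  # opposite vertex (interior side)
    faces = []
    for face, (count, opp, _) in face_count.items():
        if count == 1:
            faces.append((face, opp))
    # orient each boundary face outward (away from the opposite vertex)
    oriented = []
    for (i, j, k), opp in faces:
        n = np.cross(points[j] - points[i], points[k] - points[i])
        if np.dot(n, points[opp] - points[i]) > 0:
            i, j = j, i
        oriented.append((i, j, k))
    return np.array(oriented, dtype=int)


def _mesh_measures(points: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    """Volume (divergence theorem) and area of an oriented triangle mesh."""
    p0, p1, p2 = points[faces[:, 0]], points[faces[:, 1]], points[faces[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    vol = float(np.einsum("ij,ij->i", p0, cross).sum() / 6.0)
    area = float(np.linalg.norm(cross, axis=1).sum() / 2.0)
    return abs(vol), area


def _is_watertight(faces: np.ndarray) -> tuple[bool, str]:
    edges: dict[tuple[int, int], int] = {}
    for i, j, k in faces:
        for e in ((i, j), (j, k), (k, i)):
            key = tuple(sorted(e))
            edges[key] = edges.get(key, 0) + 1
    bad = [e for e, c in edges.items() if c != 2]
    if bad:
        return False, f"{len(bad)} boundary/non-manifold edges (e.g. {bad[0]})"
    return True, ""


def vesicle_geometry(
    frame: VesicleFrame, alpha: float | None = None
) -> tuple[float, float, float, float | None]:
    """Volume, area, reduced volume and colloid packing fraction of a vesicle.

    Reconstructs a watertight triangulated surface through the membrane bead
    cloud (alpha shape with alpha = 2x the median bead spacing by default,
    falling back to the convex hull when the alpha complex is not closed),
    then applies the divergence theorem for the volume.  Returns
    ``(V_v, A_v, nu, eta)`` with ``eta = N V0 / V_v`` when colloids are
    present, else ``eta = None``.
    """
    pts = frame.beads
    if alpha is None:
        tree = cKDTree(pts)
        dd, _ = tree.query(pts, k=2)
        alpha = 2.0 * float(np.median(dd[:, 1]))
    try:
        faces = _alpha_shape_surface(pts, alpha)
        ok, defect = (False, "empty alpha complex") if len(faces) == 0 else _is_watertight(faces)
    except Exception as exc:  # qhull failures on degenerate clouds
        faces, ok, defect = np.empty((0, 3), int), False, str(exc)
    if not ok:
        hull = ConvexHull(pts)
        faces = _orient_hull_faces(pts, hull)
        ok2, defect2 = _is_watertight(faces)
        if not ok2:
            raise ValueError(
                f"surface reconstruction failed: alpha shape ({defect}); "
                f"convex hull ({defect2})"
            )
    V, A = _mesh_measures(pts, faces)
    nu = reduced_volume(V, A)
    eta = None
    if frame.colloids is not None and len(frame.colloids):
        eta = len(frame.colloids) * sphere_volume(frame.colloid_diameter) / V
    return V, A, nu, eta


def _orient_hull_faces(points: np.ndarray, hull: ConvexHull) -> np.ndarray:
    centroid = points[hull.vertices].mean(axis=0)
    faces = []
    for simplex in hull.simplices:
        i, j, k = simplex
        n = np.cross(points[j] - points[i], points[k] - points[i])
        if np.dot(n, points[i] - centroid) < 0:
            i, j = j, i
        faces.append((i, j, k))
    return np.array(faces, dtype=int)


def classify(kappa2_value: float, nu: float | None = None) -> StateLabel:
    """Conformation label from kappa^2: cluster (< 0.15), plate ([0.15,
    0.35)), intermediate ([0.35, 0.5)), linear (>= 0.5)."""
    k2 = float(kappa2_value)
    idx = int(np.searchsorted(BAND_EDGES, k2, side="right"))
    return StateLabel(label=LABELS[idx], kappa2=k2, nu=nu)


def detect_bistability(
    kappa2_series: np.ndarray,
    dt: float = 1.0,
    smooth_window: int = 20,
    min_dwell: int = 50,
) -> tuple[list[BistabilitySegment], int, bool]:
    """Segment a kappa^2(t) series into classifier states and detect
    two-state switching.

    The series is smoothed with a centered moving average (``smooth_window``
    samples), classified sample-by-sample, and segments shorter than
    ``min_dwell`` samples are merged into their neighbors (suppressing
    single-frame flicker and the transient band crossings during switches).
    A series is bistable when it alternates at least twice between two
    distinct states, each visit dwelling at least ``min_dwell`` samples.

    Returns ``(segments, alternation_count, bistable)`` with segment times in
    units of ``dt``.
    """
    x = np.asarray(kappa2_series, dtype=float)
    if len(x) < 100:
        raise ValueError("series too short (need >= 100 samples)")
    w = min(smooth_window, len(x))
    kernel = np.ones(w) / w
    sm = np.convolve(x, kernel, mode="same")
    # label per sample
    labels = np.searchsorted(BAND_EDGES, sm, side="right")
    # run-length encode
    runs: list[list] = []  # [label, length]
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    # iteratively dissolve the shortest run below min_dwell
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_dwell:
            break
        if i == 0:
            runs[1][1] += runs[0][1]
            runs.pop(0)
        elif i == len(runs) - 1:
            runs[-2][1] += runs[-1][1]
            runs.pop()
        else:
            left, right = runs[i - 1], runs[i + 1]
            if left[0] == right[0]:
                left[1] += runs[i][1] + right[1]
                runs.pop(i + 1)
                runs.pop(i)
            else:
                half = runs[i][1] // 2
                left[1] += half
                right[1] += runs[i][1] - half
                runs.pop(i)
        # merge equal neighbors
        j = 0
        while j < len(runs) - 1:
            if runs[j][0] == runs[j + 1][0]:
                runs[j][1] += runs[j + 1][1]
                runs.pop(j + 1)
            else:
                j += 1
    segments = []
    t = 0
    for lab, length in runs:
        segments.append(
            BistabilitySegment(state=LABELS[lab], start=t * dt, end=(t + length) * dt)
        )
        t += length
    alternations = sum(
        1 for a, b in zip(runs, runs[1:]) if a[0] != b[0]
    )
    states = {r[0] for r in runs}
    bistable = (
        len(states) == 2
        and alternations >= 2
        and all(r[1] >= min_dwell for r in runs)
    )
    return segments, alternations, bistable
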