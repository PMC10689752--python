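"""Deterministic generators for the cluster families scored against the sausage.

All constructions place sphere centers on close-packed (Barlow) lattices with
nearest-neighbor distance exactly one diameter:

* linear chains (the sausage itself),
* planar patches of the triangular / centered-hexagonal / square lattices,
* FCC tetrahedra, octahedra and triangular bipyramids with regular and
  irregular vertex truncations,
* Mackay icosahedra (twenty slightly strained FCC grains),
* arbitrary Barlow stacks of triangular layers (FCC = "ABC", HCP = "AB").

Truncations are described by :class:`TruncationSpec`: per-vertex cap sizes
drawn from the figurate cap-number series of the vertex type (tetrahedral
numbers 1, 4, 10, 20, ... for tetrahedron/bipyramid vertices, square-pyramidal
numbers 1, 5, 14, 30, ... for octahedron vertices, which sit on fourfold
axes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import SphereCluster

__all__ = [
    "TruncationSpec",
    "LatticeSlice",
    "make_lattice_slice",
    "make_linear",
    "make_planar",
    "make_fcc_tetrahedron",
    "make_fcc_octahedron",
    "make_fcc_bipyramid",
    "make_bipyramid",
    "make_mackay_icosahedron",
    "make_barlow_stack",
    "truncate",
    "enumerate_truncations",
    "tetrahedral_number",
    "octahedral_number",
    "square_pyramidal_number",
    "triangular_number",
]

# lattice basis for the FCC tetrahedron: two in-plane triangular-lattice
# vectors and the close-packed interlayer vector (all length 1)
_A1 = np.array([1.0, 0.0, 0.0])
_A2 = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])
_A3 = np.array([0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)])

#: interlayer spacing of close-packed triangular layers
LAYER_DZ = np.sqrt(2.0 / 3.0)

# lateral offsets of the three close-packed layer registries
_OFFSETS = {
    "A": np.array([0.0, 0.0]),
    "B": np.array([0.5, np.sqrt(3.0) / 6.0]),
    "C": np.array([1.0, np.sqrt(3.0) / 3.0]),
}


def triangular_number(m: int) -> int:
    return m * (m + 1) // 2


def tetrahedral_number(m: int) -> int:
    return m * (m + 1) * (m + 2) // 6


def octahedral_number(m: int) -> int:
    return m * (2 * m * m + 1) // 3


def square_pyramidal_number(m: int) -> int:
    return m * (m + 1) * (2 * m + 1) // 6


def _cap_depth(n: int, series) -> int:
    """Invert a figurate cap-number series; raise if ``n`` is not a member."""
    d = 0
    while series(d) < n:
        d += 1
    if series(d) != n:
        raise ValueError(
            f"{n} is not a valid cap number for this vertex type "
            f"(expected one of the series {[series(i) for i in range(1, 6)]})"
        )
    return d


@dataclass(frozen=True)
class TruncationSpec:
    """Base polyhedron plus per-vertex cap sizes.

    ``family`` is one of ``"T"`` (FCC tetrahedron, 4 vertices), ``"O"`` (FCC
    octahedron, 6 vertices as three opposite pairs) or ``"B"`` (triangular
    bipyramid, 2 apex vertices).  ``cuts`` holds the number of spheres removed
    at each vertex; entries must be cap numbers of the vertex type.
    """

    family: str
    base_size: int
    cuts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.family not in ("T", "O", "B"):
            raise ValueError(f"unknown family {self.family!r}")
        nvert = {"T": 4, "O": 6, "B": 2}[self.family]
        if len(self.cuts) != nvert:
            raise ValueError(
                f"family {self.family} needs {nvert} cut entries, "
                f"got {len(self.cuts)}"
            )

    @property
    def k(self) -> int:
        """Number of vertices with a nonzero cut."""
        return sum(1 for c in self.cuts if c > 0)

    @property
    def depths(self) -> tuple[int, ...]:
        series = (
            square_pyramidal_number if self.family == "O" else tetrahedral_number
        )
        return tuple(_cap_depth(c, series) for c in self.cuts)

    def canonical(self) -> tuple:
        """Deduplication key: cap multiset per symmetry-equivalent vertex orbit.

        Tetrahedron and bipyramid-apex vertices form a single orbit (sorted
        multiset); octahedron vertices are canonicalized as the sorted multiset
        of sorted opposite-axis pairs.
        """
        if self.family == "O":
            pairs = tuple(
                sorted(
                    tuple(sorted((self.cuts[2 * a], self.cuts[2 * a + 1])))
                    for a in range(3)
                )
            )
            return ("O", self.base_size, pairs)
        return (self.family, self.base_size, tuple(sorted(self.cuts)))

    @property
    def n_removed(self) -> int:
        return sum(self.cuts)


@dataclass
class LatticeSlice:
    """A close-packed slab keyed by its Barlow stacking sequence.

    ``stacking`` is the layer-registry string actually used (e.g. "ABCAB"
    for an FCC slab of five layers, "ABAB..." for HCP); ``layer_rows`` the
    triangle edge of each layer; ``cluster`` the generated sphere packing.
    """

    stacking: str
    layer_rows: tuple[int, ...]
    cluster: SphereCluster


def make_lattice_slice(layer_rows, stacking: str = "ABC") -> LatticeSlice:
    """Build a :class:`LatticeSlice` from a layer profile and stacking."""
    rows = tuple(int(r) for r in layer_rows)
    cluster = make_barlow_stack(rows, stacking)
    seq = (stacking * (len(rows) // len(stacking) + 1))[: len(rows)]
    return LatticeSlice(stacking=seq, layer_rows=rows, cluster=cluster)


def make_linear(N: int, diameter: float = 1.0) -> SphereCluster:
    """N equispaced collinear spheres at contact (the sausage)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    pts = np.zeros((N, 3))
    pts[:, 0] = np.arange(N) * diameter
    return SphereCluster(pts, diameter=diameter, label=f"linear N={N}")


def make_planar(kind: str, size_index: int, diameter: float = 1.0) -> SphereCluster:
    """Planar lattice patch at contact.

    ``triangular``: triangle-shaped patch of the triangular lattice with
    ``m (m+1) / 2`` spheres; ``hexagonal``: centered hexagon with
    ``3 m (m-1) + 1``; ``square``: an ``m x m`` square lattice.
    """
    m = size_index
    if m < 1:
        raise ValueError("size_index must be >= 1")
    if kind == "triangular":
        pts = [
            i * _A1 + j * _A2 for i in range(m) for j in range(m - i)
        ]
    elif kind == "square":
        pts = [
            np.array([i, j, 0.0]) for i in range(m) for j in range(m)
        ]
    elif kind == "hexagonal":
        pts = []
        for i in range(-(m - 1), m):
            for j in range(-(m - 1), m):
                if abs(i + j) <= m - 1:
                    pts.append(i * _A1 + j * _A2)
    else:
        raise ValueError(f"unknown planar kind {kind!r}")
    pts = np.array(pts) * diameter
    return SphereCluster(pts, diameter=diameter, label=f"{kind} m={m}")


def _tetra_sites(m: int):
    """Barycentric lattice indices (i, j, k, l) of the FCC tetrahedron with m
    spheres per edge; i + j + k + l = m - 1."""
    return [
        (i, j, k, m - 1 - i - j - k)
        for i in range(m)
        for j in range(m - i)
        for k in range(m - i - j)
    ]


def _tetra_points(sites) -> np.ndarray:
    return np.array([i * _A1 + j * _A2 + k * _A3 for i, j, k, _ in sites])


def make_fcc_tetrahedron(m: int, diameter: float = 1.0) -> SphereCluster:
    """Regular FCC tetrahedron with m spheres per edge, N = m(m+1)(m+2)/6."""
    if m < 1:
        raise ValueError("m must be >= 1")
    pts = _tetra_points(_tetra_sites(m)) * diameter
    return SphereCluster(pts, diameter=diameter, label=f"T base m={m}")


def _tetra_truncated_points(m: int, depths: tuple[int, int, int, int]) -> np.ndarray:
    """Remove a cap of ``depths[v]`` complete layers at each of the four
    vertices (vertex v is where barycentric coordinate v is maximal)."""
    keep = []
    for site in _tetra_sites(m):
        if any(d > 0 and c >= m - d for c, d in zip(site, depths)):
            continue
        keep.append(site)
    if not keep:
        raise ValueError("truncation removed every sphere")
    return _tetra_points(keep)


def _octa_sites(m: int):
    """Integer FCC sites of the octahedron with m spheres per edge: L1 norm
    <= m - 1 with coordinate-sum parity matching m - 1 (sublattice of the
    checkerboard lattice; nearest-neighbor distance sqrt(2))."""
    par = (m - 1) % 2
    sites = []
    for i in range(-(m - 1), m):
        for j in range(-(m - 1) + abs(i), m - abs(i)):
            kmax = m - 1 - abs(i) - abs(j)
            for k in range(-kmax, kmax + 1):
                if (i + j + k) % 2 == par:
                    sites.append((i, j, k))
    return sites


def make_fcc_octahedron(m: int, diameter: float = 1.0) -> SphereCluster:
    """Regular FCC octahedron, N = m(2m^2+1)/3, square layer profile
    1^2, 2^2, ..., m^2, ..., 2^2, 1^2 along a fourfold axis."""
    if m < 1:
        raise ValueError("m must be >= 1")
    pts = np.array(_octa_sites(m), dtype=float) / np.sqrt(2.0) * diameter
    return SphereCluster(pts, diameter=diameter, label=f"O base m={m}")


def _octa_truncated_points(m: int, depths: tuple[int, ...]) -> np.ndarray:
    """Remove square-pyramidal caps of the given depths at the six vertices
    ordered (+x, -x, +y, -y, +z, -z)."""
    keep = []
    for (i, j, k) in _octa_sites(m):
        coords = (i, -i, j, -j, k, -k)
        if any(d > 0 and c >= m - d for c, d in zip(coords, depths)):
            continue
        keep.append((i, j, k))
    if not keep:
        raise ValueError("truncation removed every sphere")
    return np.array(keep, dtype=float) / np.sqrt(2.0)


def _bipyramid_points(m: int, top_cut: int = 0, bot_cut: int = 0) -> np.ndarray:
    """Triangular bipyramid: two FCC tetrahedra of base edge m sharing the
    base layer (the lower half is the mirror twin of the upper, a valid
    Barlow contact packing).  ``top_cut``/``bot_cut`` remove that many apex
    layers (tetrahedral caps)."""
    top = _tetra_points(_tetra_sites(m))
    layer = np.round(top[:, 2] / LAYER_DZ).astype(int)
    if top_cut >= m or bot_cut >= m:
        raise ValueError("apex cut removes the shared base layer")
    upper = top[layer <= m - 1 - top_cut]
    lower = top[(layer >= 1) & (layer <= m - 1 - bot_cut)] * np.array([1.0, 1.0, -1.0])
    return np.vstack([upper, lower])


def make_bipyramid(
    m: int, top_cut: int = 0, bot_cut: int = 0, diameter: float = 1.0
) -> SphereCluster:
    """Triangular bipyramid over a base of edge m with optional apex cuts."""
    pts = _bipyramid_points(m, top_cut, bot_cut) * diameter
    return SphereCluster(
        pts, diameter=diameter, label=f"B base m={m} cuts=({top_cut},{bot_cut})"
    )


def make_fcc_bipyramid(layer_profile, diameter: float = 1.0) -> SphereCluster:
    """Bipyramid from a unimodal profile of triangular-layer sizes.

    The profile lists the sphere count of each close-packed triangular layer,
    e.g. ``(1, 3, 6, 3, 1)``; it must rise to a unique maximal layer in unit
    row steps and fall the same way (a contiguous slab of the full bipyramid).
    """
    profile = tuple(int(x) for x in layer_profile)
    if not profile:
        raise ValueError("empty layer profile")
    rows = []
    for size in profile:
        s = int(round((np.sqrt(8 * size + 1) - 1) / 2))
        if triangular_number(s) != size:
            raise ValueError(f"layer size {size} is not a triangular number")
        rows.append(s)
    m = max(rows)
    peak = rows.index(m)
    expect_up = list(range(m - peak, m + 1))
    expect_down = list(range(m - 1, m - 1 - (len(rows) - peak - 1), -1))
    if rows != expect_up + expect_down:
        raise ValueError(
            f"layer profile {profile} is not a unimodal unit-step bipyramid slab"
        )
    top_cut = m - 1 - (len(rows) - peak - 1)
    bot_cut = m - 1 - peak
    return make_bipyramid(m, top_cut=top_cut, bot_cut=bot_cut, diameter=diameter)


def make_barlow_stack(
    layer_rows, stacking: str = "ABC", diameter: float = 1.0
) -> SphereCluster:
    """Stack of close-packed triangular layers with an explicit registry
    sequence; FCC is the repeating "ABC", HCP "AB".

    ``layer_rows`` gives the triangle edge (rows) of each layer; adjacent
    layers must sit in different registries for contact stacking.
    """
    rows = list(layer_rows)
    seq = (stacking * (len(rows) // len(stacking) + 1))[: len(rows)]
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError(f"invalid stacking {stacking!r}: repeated layer {a}")
    pts = []
    for t, (s, reg) in enumerate(zip(rows, seq)):
        off = _OFFSETS[reg]
        for i in range(s):
            for j in range(s - i):
                pts.append(
                    [i + 0.5 * j + off[0], j * np.sqrt(3.0) / 2.0 + off[1], t * LAYER_DZ]
                )
    pts = np.array(pts) * diameter
    return SphereCluster(
        pts, diameter=diameter, label=f"barlow {stacking} rows={tuple(rows)}"
    )


def make_mackay_icosahedron(shells: int, diameter: float = 1.0) -> SphereCluster:
    """Mackay icosahedron with the given number of shells (N = 13, 55, 147,
    ...): a center plus icosahedral shells built from twenty slightly strained
    FCC tetrahedral grains.  The minimum center distance is normalized to one
    diameter; intra-shell and radial spacings differ by the ~5% Mackay strain.
    """
    if shells < 1:
        raise ValueError("shells must be >= 1")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in itertools.product((-1.0, 1.0), (-phi, phi)):
        verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.array(verts) / np.linalg.norm((0.0, 1.0, phi))
    # faces: triples of mutually nearest vertices
    from scipy.spatial import ConvexHull

    faces = ConvexHull(verts).simplices
    pts = {(0.0, 0.0, 0.0)}
    for s in range(1, shells + 1):
        for face in faces:
            v0, v1, v2 = (verts[i] * s for i in face)
            for a in range(s + 1):
                for b in range(s + 1 - a):
                    c = s - a - b
                    p = (v0 * a + v1 * b + v2 * c) / s
                    pts.add(tuple(np.round(p, 9)))
    pts = np.array(sorted(pts))
    from scipy.spatial.distance import pdist

    pts = pts / pdist(pts).min() * diameter
    return SphereCluster(pts, diameter=diameter, label=f"mackay shells={shells}")


def _base_cluster(family: str, m: int) -> SphereCluster:
    if family == "T":
        return make_fcc_tetrahedron(m)
    if family == "O":
        return make_fcc_octahedron(m)
    if family == "B":
        return make_bipyramid(m)
    raise ValueError(f"unknown family {family!r}")


def _base_count(family: str, m: int) -> int:
    if family == "T":
        return tetrahedral_number(m)
    if family == "O":
        return octahedral_number(m)
    return 2 * tetrahedral_number(m) - triangular_number(m)


def truncate(cluster: SphereCluster, spec: TruncationSpec) -> SphereCluster:
    """Remove the cap sets given by ``spec`` from an untruncated base cluster.

    The cluster must be the matching family base (same sphere count as the
    regular polyhedron of ``spec.base_size``).  Caps must be pairwise
    disjoint; overlapping caps raise a validation error.
    """
    m = spec.base_size
    if cluster.n != _base_count(spec.family, m):
        raise ValueError(
            f"cluster has N={cluster.n}, expected the {spec.family} base of "
            f"size m={m} with N={_base_count(spec.family, m)}"
        )
    depths = spec.depths
    if any(d >= m for d in depths):
        raise ValueError("cap depth exceeds the base polyhedron")
    if spec.family == "T":
        pts = _tetra_truncated_points(m, depths)
    elif spec.family == "O":
        pts = _octa_truncated_points(m, depths)
    else:
        pts = _bipyramid_points(m, depths[0], depths[1])
    expected = _base_count(spec.family, m) - spec.n_removed
    if len(pts) != expected:
        raise ValueError(
            f"caps overlap: removing {spec.cuts} from {spec.family}(m={m}) "
            f"left {len(pts)} spheres, expected {expected}"
        )
    pts = pts * cluster.diameter
    label = f"{spec.family}(m={m}) cuts={spec.cuts}"
    return SphereCluster(pts, diameter=cluster.diameter, label=label)


def _spec_iter(family: str, m: int, asymmetric: bool):
    """All canonical truncation specs of a base (complete caps only)."""
    if family == "T":
        caps = [tetrahedral_number(d) for d in range(m)]
        if asymmetric:
            for combo in itertools.combinations_with_replacement(caps, 4):
                yield TruncationSpec("T", m, combo)
        else:
            for c in caps:
                yield TruncationSpec("T", m, (c,) * 4)
    elif family == "O":
        caps = [square_pyramidal_number(d) for d in range(m)]
        if asymmetric:
            seen = set()
            for combo in itertools.product(caps, repeat=6):
                spec = TruncationSpec("O", m, combo)
                key = spec.canonical()
                if key not in seen:
                    seen.add(key)
                    yield spec
        else:
            for c in caps:
                yield TruncationSpec("O", m, (c,) * 6)
    else:
        caps = [tetrahedral_number(d) for d in range(m)]
        if asymmetric:
            for combo in itertools.combinations_with_replacement(caps, 2):
                yield TruncationSpec("B", m, combo)
        else:
            for c in caps:
                yield TruncationSpec("B", m, (c, c))


def enumerate_truncations(
    family: str,
    base_sizes,
    N_range: tuple[int, int],
    asymmetric: bool = False,
):
    """All non-equivalent complete-cap truncations of a family with N in
    ``N_range`` (inclusive), deduplicated under the base symmetry group.

    Returns a list of ``(TruncationSpec, SphereCluster)`` in deterministic
    order (base size, then canonical cut key).  Invalid specs (overlapping
    caps, empty results) are skipped silently.
    """
    lo, hi = N_range
    out = []
    for m in base_sizes:
        base = _base_cluster(family, m)
        for spec in sorted(_spec_iter(family, m, asymmetric), key=lambda s: s.canonical()):
            n_out = _base_count(family, m) - spec.n_removed
            if not (lo <= n_out <= hi) or n_out < 1:
                continue
            try:
                cluster = truncate(base, spec)
            except ValueError:
                continue
            out.append((spec, cluster))
    return out
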