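"""Seeded synthetic fixtures for the analysis pipeline.

Everything the order-parameter and state-analysis stages consume can be
generated here with known ground truth: bead-sampled closed surfaces whose
volume and area follow from closed forms, noisy colloid archetypes with known
conformation labels, and telegraph-like kappa^2(t) series with planted dwell
segments.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import make_linear, make_planar, _A1, _A2
from .geometry import SphereCluster
from .order import VesicleFrame
from .projection import rescale_to_contact

__all__ = [
    "ShapeFixture",
    "sphere_fixture",
    "prolate_fixture",
    "oblate_fixture",
    "spherocylinder_fixture",
    "sample_surface",
    "noisy_archetype",
    "telegraph_kappa2",
]


def _spheroid_area(a: float, c: float) -> float:
    """Surface area of a spheroid with equatorial semi-axis a (twice) and
    polar semi-axis c; closed forms for prolate (c > a) and oblate (c < a)."""
    if np.isclose(a, c):
        return 4.0 * np.pi * a * a
    if c > a:  # prolate
        e = np.sqrt(1.0 - (a / c) ** 2)
        return 2.0 * np.pi * a * a * (1.0 + c / (a * e) * np.arcsin(e))
    e = np.sqrt(1.0 - (c / a) ** 2)  # oblate
    return 2.0 * np.pi * a * a + np.pi * c * c / e * np.log((1.0 + e) / (1.0 - e))


@dataclass
class ShapeFixture:
    """Closed surface with known volume/area; shapes: sphere, prolate,
    discoid (oblate spheroid), spherocylinder.  Parameters in sigma units."""

    shape: str
    params: dict = field(default_factory=dict)

    @property
    def volume(self) -> float:
        p = self.params
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * p["R"] ** 3
        if self.shape in ("prolate", "discoid"):
            return 4.0 / 3.0 * np.pi * p["a"] ** 2 * p["c"]
        if self.shape == "spherocylinder":
            return np.pi * p["R"] ** 2 * p["L"] + 4.0 / 3.0 * np.pi * p["R"] ** 3
        raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def area(self) -> float:
        p = self.params
        if self.shape == "sphere":
            return 4.0 * np.pi * p["R"] ** 2
        if self.shape in ("prolate", "discoid"):
            return _spheroid_area(p["a"], p["c"])
        if self.shape == "spherocylinder":
            return 2.0 * np.pi * p["R"] * p["L"] + 4.0 * np.pi * p["R"] ** 2
        raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def nu(self) -> float:
        from .geometry import reduced_volume

        return reduced_volume(self.volume, self.area)


def sphere_fixture(R: float = 20.0) -> ShapeFixture:
    return ShapeFixture("sphere", {"R": R})


def prolate_fixture(a: float = 10.0, c: float = 20.0) -> ShapeFixture:
    if c <= a:
        raise ValueError("prolate needs polar semi-axis c > equatorial a")
    return ShapeFixture("prolate", {"a": a, "c": c})


def oblate_fixture(a: float = 20.0, c: float = 8.0) -> ShapeFixture:
    if c >= a:
        raise ValueError("discoid needs polar semi-axis c < equatorial a")
    return ShapeFixture("discoid", {"a": a, "c": c})


def spherocylinder_fixture(R: float, L: float) -> ShapeFixture:
    """Capsule of cylinder length L and radius R; with ``R = d/2`` and
    ``L = (N-1) d`` this matches the N-sphere sausage envelope."""
    return ShapeFixture("spherocylinder", {"R": R, "L": L})


def sample_surface(
    fixture: ShapeFixture, n_beads: int = 3000, seed: int = 0
) -> VesicleFrame:
    """Near-uniform (area-weighted) random sampling of the fixture surface."""
    if n_beads < 100:
        raise ValueError("need at least 100 beads")
    rng = np.random.default_rng(seed)
    p = fixture.params
    if fixture.shape == "sphere":
        pts = _sample_sphere_dirs(rng, n_beads) * p["R"]
    elif fixture.shape in ("prolate", "discoid"):
        pts = _sample_spheroid(rng, n_beads, p["a"], p["c"])
    elif fixture.shape == "spherocylinder":
        pts = _sample_spherocylinder(rng, n_beads, p["R"], p["L"])
    else:
        raise ValueError(f"unknown shape {fixture.shape!r}")
    return VesicleFrame(beads=pts)


def _sample_sphere_dirs(rng, n) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_spheroid(rng, n, a, c) -> np.ndarray:
    """Rejection sampling proportional to the spheroid area element."""
    out = np.empty((0, 3))
    gmax = a * max(a, c)  # sup of the area stretch factor over the sphere
    while len(out) < n:
        u = _sample_sphere_dirs(rng, 2 * n)
        # map unit sphere -> spheroid; area element scales with the norm of
        # the cofactor-transformed normal
        x = u * np.array([a, a, c])
        g = np.linalg.norm(u * np.array([a * c, a * c, a * a]), axis=1)
        accept = rng.uniform(0.0, gmax, size=len(g)) < g
        out = np.vstack([out, x[accept]])
    return out[:n]


def _sample_spherocylinder(rng, n, R, L) -> np.ndarray:
    area_cyl = 2.0 * np.pi * R * L
    area_caps = 4.0 * np.pi * R**2
    n_cyl = int(round(n * area_cyl / (area_cyl + area_caps)))
    phi = rng.uniform(0.0, 2.0 * np.pi, n_cyl)
    z = rng.uniform(-L / 2.0, L / 2.0, n_cyl)
    cyl = np.c_[R * np.cos(phi), R * np.sin(phi), z]
    caps = _sample_sphere_dirs(rng, n - n_cyl) * R
    caps[:, 2] += np.sign(caps[:, 2]) * L / 2.0
    return np.vstack([cyl, caps])


def noisy_archetype(
    kind: str, N: int, noise_sd: float = 0.0, seed: int = 0, diameter: float = 1.0
) -> SphereCluster:
    """Colloid archetype (line / triangular plate / compact FCC cluster) with
    isotropic Gaussian positional noise, re-projected to contact so the
    hard-sphere constraint holds.

    ``noise_sd`` is in diameters and must stay below 0.2 (beyond that the
    archetype identity is not meaningful).
    """
    if noise_sd >= 0.2:
        raise ValueError("noise_sd must be < 0.2 diameters")
    rng = np.random.default_rng(seed)
    if kind == "linear":
        base = make_linear(N).centers
    elif kind == "plate":
        # smallest triangular patch holding N sites, truncated to N
        m = 1
        while m * (m + 1) // 2 < N:
            m += 1
        base = make_planar("triangular", m).centers[:N]
    elif kind == "cluster":
        # N FCC sites nearest the lattice centroid of a compact block
        block = [
            i * _A1 + j * _A2 + k * np.array([0.5, np.sqrt(3) / 6, np.sqrt(2 / 3)])
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
        ]
        block = np.array(block)
        block = block[np.argsort(np.linalg.norm(block, axis=1), kind="stable")]
        base = block[:N]
    else:
        raise ValueError(f"unknown archetype {kind!r}")
    pts = base + rng.normal(scale=noise_sd, size=base.shape)
    if noise_sd == 0.0:
        return SphereCluster(
            base * diameter, diameter=diameter, label=f"{kind} archetype N={N}"
        )
    cluster, _ = rescale_to_contact(pts * diameter, diameter=diameter)
    cluster.label = f"{kind} archetype N={N} noise={noise_sd}"
    return cluster


def telegraph_kappa2(
    states,
    dwell_mean: float = 500.0,
    noise_sd: float = 0.03,
    length: int = 5000,
    seed: int = 0,
    dwell_min: int = 60,
) -> tuple[np.ndarray, list[tuple[int, int, float]], int]:
    """Telegraph-like kappa^2(t) series with exponential dwell times.

    ``states`` are the band-center levels visited cyclically; dwell times are
    a shifted exponential with mean ``dwell_mean`` and floor ``dwell_min``
    samples (memoryless switching, the simplest model of fluctuation-driven
    alternation; the floor keeps every planted segment resolvable by a
    finite-window detector).  Gaussian observation noise of sd ``noise_sd``
    is added and the result clipped to [0, 1].

    Returns ``(series, planted_segments, planted_alternations)`` where each
    planted segment is ``(start, end, level)``.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one state level")
    if dwell_mean <= dwell_min:
        raise ValueError("dwell_mean must exceed dwell_min")
    rng = np.random.default_rng(seed)
    series = np.empty(length)
    segments: list[tuple[int, int, float]] = []
    t = 0
    idx = 0
    while t < length:
        dwell = dwell_min + int(round(rng.exponential(dwell_mean - dwell_min)))
        end = min(length, t + dwell)
        if length - end < dwell_min:  # avoid an unresolvable final sliver
            end = length
        series[t:end] = states[idx % len(states)]
        segments.append((t, end, states[idx % len(states)]))
        t = end
        idx += 1
    series = np.clip(series + rng.normal(scale=noise_sd, size=length), 0.0, 1.0)
    alternations = sum(
        1 for a, b in zip(segments, segments[1:]) if a[2] != b[2]
    )
    return series, segments, alternations
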