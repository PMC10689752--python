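"""Projection of arbitrary cluster coordinates to the hard-sphere limit.

Externally produced clusters (energy-minimized soft-sphere configurations,
simulation snapshots of WCA colloids) generally have a minimum center
distance different from the nominal diameter.  Before a packing fraction can
be compared against the sausage reference they are mapped to a valid
hard-sphere configuration:

* :func:`rescale_to_contact` — uniform scaling about the centroid so the
  minimum pairwise distance equals the diameter exactly.  This is the default
  projection; it preserves the cluster geometry (and therefore eta_ch of
  any already-at-contact construction).
* :func:`tighten` — optional local hull-volume descent subject to the
  non-overlap constraint, for clusters whose contact network leaves slack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import SphereCluster, packing_fraction_ch, dilated_volume, center_hull

__all__ = ["ProjectionReport", "rescale_to_contact", "tighten"]


@dataclass
class ProjectionReport:
    scale_factor: float
    min_distance_before: float
    min_distance_after: float
    relaxation_steps: int
    eta_ch_before: float
    eta_ch_after: float


def _eta_unsafe(points: np.ndarray, diameter: float) -> float:
    """eta_ch without the overlap validation (used for before/after reports
    where the input may not yet satisfy the hard-sphere constraint)."""
    return packing_fraction_ch(
        SphereCluster(points, diameter=diameter), validate=False
    )


def rescale_to_contact(
    points: np.ndarray, diameter: float = 1.0, label: str = ""
) -> tuple[SphereCluster, ProjectionReport]:
    """Uniformly scale a point set about its centroid so the minimum pairwise
    distance equals ``diameter`` exactly."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least 2 points to set a contact scale")
    dmin = float(pdist(pts).min())
    if dmin <= 0.0:
        raise ValueError("coincident points cannot be rescaled to contact")
    scale = diameter / dmin
    centroid = pts.mean(axis=0)
    out = centroid + (pts - centroid) * scale
    cluster = SphereCluster(out, diameter=diameter, label=label or "rescaled")
    report = ProjectionReport(
        scale_factor=scale,
        min_distance_before=dmin,
        min_distance_after=cluster.min_distance(),
        relaxation_steps=0,
        eta_ch_before=_eta_unsafe(pts, diameter),
        eta_ch_after=packing_fraction_ch(cluster),
    )
    return cluster, report


def _vch(points: np.ndarray, r: float) -> float:
    return dilated_volume(center_hull(SphereCluster(points, diameter=2 * r)), r)


def tighten(
    cluster: SphereCluster,
    max_iters: int = 100,
    step: float = 1e-3,
    rel_tol: float = 1e-10,
) -> tuple[SphereCluster, ProjectionReport]:
    """Local dilated-hull-volume descent under the non-overlap constraint.

    Sweeps the spheres in index order; each sphere is moved against the
    numerical gradient of the dilated hull volume (step ``step * diameter``),
    with moves that would violate the hard-sphere constraint projected back
    along the offending pair axes.  Moves are only accepted if they do not
    increase the volume, so ``eta_ch`` never decreases.  Terminates when a
    full sweep improves the volume by less than ``rel_tol`` relative or after
    ``max_iters`` sweeps.
    """
    cluster.validate_overlaps()
    d = cluster.diameter
    r = d / 2.0
    pts = cluster.centers.copy()
    eta_before = packing_fraction_ch(cluster)
    h = 1e-6 * d
    sweeps = 0
    for sweeps in range(1, max_iters + 1):
        v_start = _vch(pts, r)
        for i in range(len(pts)):
            grad = np.zeros(3)
            for ax in range(3):
                for sgn, w in ((1.0, 1.0), (-1.0, -1.0)):
                    q = pts.copy()
                    q[i, ax] += sgn * h
                    grad[ax] += w * _vch(q, r)
            grad /= 2.0 * h
            gn = np.linalg.norm(grad)
            if gn == 0.0:
                continue
            trial = pts.copy()
            trial[i] -= step * d * grad / gn
            # push back out of any overlaps created by the move
            for _ in range(8):
                dist = np.linalg.norm(trial - trial[i], axis=1)
                dist[i] = np.inf
                j = int(np.argmin(dist))
                if dist[j] >= d * (1.0 - 1e-12):
                    break
                axis = trial[i] - trial[j]
                axis /= np.linalg.norm(axis)
                trial[i] = trial[j] + axis * d
            dist = np.linalg.norm(trial - trial[i], axis=1)
            dist[i] = np.inf
            if dist.min() < d * (1.0 - 1e-12):
                continue  # could not resolve overlaps; reject move
            if _vch(trial, r) <= _vch(pts, r):
                pts = trial
        v_end = _vch(pts, r)
        if v_start - v_end < rel_tol * v_start:
            break
    out = SphereCluster(pts, diameter=d, label=cluster.label or "tightened")
    report = ProjectionReport(
        scale_factor=1.0,
        min_distance_before=cluster.min_distance(),
        min_distance_after=out.min_distance(),
        relaxation_steps=sweeps,
        eta_ch_before=eta_before,
        eta_ch_after=packing_fraction_ch(out),
    )
    return out, report
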