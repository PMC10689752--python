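"""File formats: XYZ / extended XYZ, trajectory dumps, catalogue CSV, JSON.

Plain XYZ carries one sphere per record (element tag ignored on input); the
comment line stores a small JSON header with the declared units and diameter
so coordinates in sigma and sigma_c are never silently mixed.  Extended XYZ
adds per-particle orientation columns (nx ny nz) for membrane beads, and a
whitespace dump reader (id, type, x, y, z[, nx, ny, nz]) is provided for
externally produced trajectories.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import SphereCluster

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_extxyz_frames",
    "write_extxyz_frame",
    "read_dump_frames",
    "format_csv_value",
]


def write_xyz(path, cluster: SphereCluster, element: str = "S") -> None:
    header = json.dumps(
        {"diameter": cluster.diameter, "units": "sigma_c", "label": cluster.label}
    )
    lines = [str(cluster.n), header]
    for x, y, z in cluster.centers:
        lines.append(f"{element} {x:.12g} {y:.12g} {z:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path, diameter: float | None = None) -> SphereCluster:
    """Read a plain XYZ file; the element tag is ignored.  The diameter comes
    from the JSON comment line when present, else from the argument
    (default 1)."""
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0].split()[0])
    meta = {}
    try:
        meta = json.loads(lines[1])
    except (json.JSONDecodeError, IndexError):
        pass
    d = diameter if diameter is not None else float(meta.get("diameter", 1.0))
    pts = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        pts.append([float(v) for v in parts[1:4]])
    return SphereCluster(
        np.array(pts), diameter=d, label=str(meta.get("label", Path(path).stem))
    )


def write_extxyz_frame(fh, beads, orientations=None, colloids=None, time=0.0) -> None:
    """Append one frame in a simple extended-XYZ layout: membrane beads as
    'M x y z nx ny nz', colloids as 'C x y z 0 0 0'."""
    n = len(beads) + (0 if colloids is None else len(colloids))
    fh.write(f"{n}\n")
    fh.write(json.dumps({"time": time, "columns": "type x y z nx ny nz"}) + "\n")
    if orientations is None:
        orientations = np.zeros_like(beads)
    for (x, y, z), (nx, ny, nz) in zip(beads, orientations):
        fh.write(f"M {x:.9g} {y:.9g} {z:.9g} {nx:.6g} {ny:.6g} {nz:.6g}\n")
    if colloids is not None:
        for x, y, z in colloids:
            fh.write(f"C {x:.9g} {y:.9g} {z:.9g} 0 0 0\n")


def read_extxyz_frames(path):
    """Yield ``(time, beads, orientations, colloids)`` per frame."""
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        try:
            meta = json.loads(lines[i + 1])
        except json.JSONDecodeError:
            meta = {}
        beads, orients, colloids = [], [], []
        for line in lines[i + 2 : i + 2 + n]:
            parts = line.split()
            xyz = [float(v) for v in parts[1:4]]
            extra = [float(v) for v in parts[4:7]] if len(parts) >= 7 else [0.0] * 3
            if parts[0] == "C":
                colloids.append(xyz)
            else:
                beads.append(xyz)
                orients.append(extra)
        yield (
            float(meta.get("time", 0.0)),
            np.array(beads),
            np.array(orients),
            np.array(colloids) if colloids else None,
        )
        i += 2 + n


def read_dump_frames(path):
    """Read a whitespace trajectory dump with per-line records
    ``id type x y z [nx ny nz]``; frames separated by blank lines or a
    leading ``#t <time>`` comment.  Type 0/``M`` = membrane, 1/``C`` =
    colloid."""
    text = Path(path).read_text()
    frames = []
    current: list[list[str]] = []
    time = 0.0
    times: list[float] = []
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("#t"):
            if current:
                frames.append(current)
                times.append(time)
                current = []
            time = float(s.split()[1])
            continue
        if not s:
            if current:
                frames.append(current)
                times.append(time)
                current = []
            continue
        current.append(s.split())
    if current:
        frames.append(current)
        times.append(time)
    for t, rows in zip(times, frames):
        beads, orients, colloids = [], [], []
        for parts in rows:
            typ = parts[1]
            xyz = [float(v) for v in parts[2:5]]
            if typ in ("1", "C"):
                colloids.append(xyz)
            else:
                beads.append(xyz)
                orients.append(
                    [float(v) for v in parts[5:8]] if len(parts) >= 8 else [0.0] * 3
                )
        yield (
            t,
            np.array(beads),
            np.array(orients),
            np.array(colloids) if colloids else None,
        )


def format_csv_value(v) -> str:
    """Fixed 12-significant-digit formatting for deterministic catalogues."""
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{v:.12g}"
    return str(v)
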