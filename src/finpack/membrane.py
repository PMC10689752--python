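"""Coarse-grained vesicle + colloid simulator (desk scale).

A solvent-free meshless membrane: beads of diameter sigma carrying a unit
orientation vector interact through an orientation-dependent pair potential

    U(r_ij, n_i, n_j) = U_R(r) + [1 - phi]          r < r_min
                        U_A(r) * phi                r_min <= r < r_c

    U_R(r) = eps [ (r_min/r)^4 - 2 (r_min/r)^2 ]
    U_A(r) = -eps cos^{2 xi}( (pi/2) (r - r_min) / (r_c - r_min) )
    phi    = 1 + mu (a - 1)
    a      = (n_i x r_hat) . (n_j x r_hat)
             + sin(theta0) (n_i - n_j) . r_hat - sin^2(theta0)

which self-assembles into fluid bilayer-like sheets with bending rigidity set
by mu.  Colloids (diameter sigma_c) and solvent beads are soft repulsive WCA
spheres; solvent lives only outside the vesicle (between the membrane and a
spherical confining wall) so its density sets an external osmotic pressure,
which is how the deflation protocol drives the reduced volume down.

Dynamics: Langevin (BAOAB splitting) on positions, overdamped rotational
Langevin on orientations with the torque obtained by projecting dU/dn_i
orthogonally to n_i; an NVE mode (orientations frozen) is provided for
energy-conservation checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .order import VesicleFrame, kappa2, vesicle_geometry

logger = logging.getLogger("finpack")

__all__ = [
    "MembraneParams",
    "SimState",
    "pair_energy",
    "pair_gradients",
    "wca_energy",
    "build_vesicle_state",
    "compute_forces",
    "total_energy",
    "integrate",
    "measure_state",
    "deflate",
]

MEMBRANE, COLLOID, SOLVENT = 0, 1, 2


@dataclass
class MembraneParams:
    """Model parameters; defaults are the standard fluid-membrane set
    (kappa_c ~ 20 kT, near-zero surface tension at kT/eps = 0.23)."""

    epsilon: float = 1.0
    sigma: float = 1.0
    r_min: float = 2.0 ** (1.0 / 6.0)
    r_c: float = 2.6
    xi: float = 4.0
    mu: float = 3.0
    sin_theta0: float = 0.0
    kT_over_eps: float = 0.23
    colloid_diameter: float = 12.0
    colloid_epsilon: float = 1.0
    solvent_diameter: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_c):
            raise ValueError("need 0 < r_min < r_c")
        if self.xi <= 0:
            raise ValueError("xi must be positive")


# ---------------------------------------------------------------------------
# pair interactions (njit kernels shared by tests and the integrator)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _membrane_pair(dx, dy, dz, nix, niy, niz, njx, njy, njz,
                   eps, r_min, r_c, xi, mu, s0):
    """Energy, force on i, and dU/dn for one membrane pair.

    The displacement (dx, dy, dz) points from i to j.  Returns a flat tuple
    (U, fix, fiy, fiz, gix, giy, giz, gjx, gjy, gjz); the force on j is -f_i.
    """
    r2 = dx * dx + dy * dy + dz * dz
    r = np.sqrt(r2)
    if r >= r_c or r <= 0.0:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    ux, uy, uz = dx / r, dy / r, dz / r
    nidotu = nix * ux + niy * uy + niz * uz
    njdotu = njx * ux + njy * uy + njz * uz
    ninj = nix * njx + niy * njy + niz * njz
    a = ninj - nidotu * njdotu + s0 * ((nix - njx) * ux + (niy - njy) * uy
                                       + (niz - njz) * uz) - s0 * s0
    phi = 1.0 + mu * (a - 1.0)
    if r < r_min:
        q = r_min / r
        q2 = q * q
        U = eps * (q2 * q2 - 2.0 * q2) + (1.0 - phi)
        dUdr = 4.0 * eps * (q2 - q2 * q2) / r
        dUda = -mu
    else:
        u = (np.pi / 2.0) * (r - r_min) / (r_c - r_min)
        cu = np.cos(u)
        if xi == 4.0:  # fast path for the default exponent
            c2 = cu * cu
            c4 = c2 * c2
            cpow = c4 * c4
            cpow1 = c4 * c2 * cu
        else:
            cpow = cu ** (2.0 * xi)
            cpow1 = cu ** (2.0 * xi - 1.0)
        UA = -eps * cpow
        U = UA * phi
        dUAdr = (eps * 2.0 * xi * cpow1 * np.sin(u)
                 * (np.pi / 2.0) / (r_c - r_min))
        dUdr = dUAdr * phi
        dUda = UA * mu
    # da/du_hat
    dax = -njdotu * nix - nidotu * njx + s0 * (nix - njx)
    day = -njdotu * niy - nidotu * njy + s0 * (niy - njy)
    daz = -njdotu * niz - nidotu * njz + s0 * (niz - njz)
    # project out the radial component and divide by r
    proj = dax * ux + day * uy + daz * uz
    tx = (dax - proj * ux) / r
    ty = (day - proj * uy) / r
    tz = (daz - proj * uz) / r
    # F_i = dU/dr * u_hat + dU/da * (I - uu)/r da/du
    fix = dUdr * ux + dUda * tx
    fiy = dUdr * uy + dUda * ty
    fiz = dUdr * uz + dUda * tz
    # dU/dn_i = dUda * (n_j - (n_j.u) u + s0 u), dU/dn_j symmetric
    gix = dUda * (njx - njdotu * ux + s0 * ux)
    giy = dUda * (njy - njdotu * uy + s0 * uy)
    giz = dUda * (njz - njdotu * uz + s0 * uz)
    gjx = dUda * (nix - nidotu * ux - s0 * ux)
    gjy = dUda * (niy - nidotu * uy - s0 * uy)
    gjz = dUda * (niz - nidotu * uz - s0 * uz)
    return U, fix, fiy, fiz, gix, giy, giz, gjx, gjy, gjz


@njit(cache=False)
def _wca(r, sig, eps):
    """WCA energy and dU/dr at separation r for contact scale sig."""
    rcut = sig * 2.0 ** (1.0 / 6.0)
    if r >= rcut or r <= 0.0:
        return 0.0, 0.0
    sr2 = (sig / r) * (sig / r)
    sr6 = sr2 * sr2 * sr2
    U = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    dUdr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return U, dUdr


@njit(cache=False)
def _forces_kernel(pos, orient, types, pi, pj, F, G,
                   eps, r_min, r_c, xi, mu, s0,
                   sig_mix, eps_wca):
    """Accumulate pair forces/orientation gradients; returns potential energy.

    sig_mix is the 3x3 contact-scale table for WCA pairs (entry 0,0 unused:
    membrane-membrane goes through the orientation potential).
    """
    U = 0.0
    for p in range(len(pi)):
        i, j = pi[p], pj[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        ti, tj = types[i], types[j]
        if ti == MEMBRANE and tj == MEMBRANE:
            (u, fix, fiy, fiz, gix, giy, giz, gjx, gjy, gjz) = _membrane_pair(
                dx, dy, dz,
                orient[i, 0], orient[i, 1], orient[i, 2],
                orient[j, 0], orient[j, 1], orient[j, 2],
                eps, r_min, r_c, xi, mu, s0)
            U += u
            F[i, 0] += fix
            F[i, 1] += fiy
            F[i, 2] += fiz
            F[j, 0] -= fix
            F[j, 1] -= fiy
            F[j, 2] -= fiz
            G[i, 0] += gix
            G[i, 1] += giy
            G[i, 2] += giz
            G[j, 0] += gjx
            G[j, 1] += gjy
            G[j, 2] += gjz
        else:
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            u, dUdr = _wca(r, sig_mix[ti, tj], eps_wca)
            if u != 0.0 or dUdr != 0.0:
                U += u
                # r = |r_j - r_i| so dr/dr_i = -u_hat and F_i = dUdr * u_hat
                fx = dUdr * dx / r
                fy = dUdr * dy / r
                fz = dUdr * dz / r
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
    return U


@njit(cache=False)
def _wall_kernel(pos, types, F, R_wall, radii, eps_wca):
    """Repulsive spherical container: WCA on the gap to the wall."""
    U = 0.0
    for i in range(len(pos)):
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        gap = R_wall - r
        sig = radii[types[i]]
        u, dUdgap = _wca(gap, sig, eps_wca)
        if u != 0.0 and r > 0.0:
            U += u
            # dgap/dr_i = -r_hat ; F_i = -dU/dgap * dgap/dr_i = dUdgap * r_hat
            F[i, 0] += dUdgap * pos[i, 0] / r
            F[i, 1] += dUdgap * pos[i, 1] / r
            F[i, 2] += dUdgap * pos[i, 2] / r
    return U


# ---------------------------------------------------------------------------
# plain-array wrappers used by the tests
# ---------------------------------------------------------------------------


def pair_energy(r_vec, n_i, n_j, params: MembraneParams) -> float:
    """Membrane pair energy for displacement ``r_vec`` from i to j."""
    r_vec = np.asarray(r_vec, float)
    if np.linalg.norm(r_vec) == 0.0:
        raise ValueError("zero separation")
    out = _membrane_pair(
        r_vec[0], r_vec[1], r_vec[2], *np.asarray(n_i, float), *np.asarray(n_j, float),
        params.epsilon, params.r_min, params.r_c, params.xi, params.mu,
        params.sin_theta0)
    return float(out[0])


def pair_gradients(r_vec, n_i, n_j, params: MembraneParams):
    """(force on i, dU/dn_i, dU/dn_j) for one membrane pair."""
    r_vec = np.asarray(r_vec, float)
    out = _membrane_pair(
        r_vec[0], r_vec[1], r_vec[2], *np.asarray(n_i, float), *np.asarray(n_j, float),
        params.epsilon, params.r_min, params.r_c, params.xi, params.mu,
        params.sin_theta0)
    f_i = np.array(out[1:4])
    g_i = np.array(out[4:7])
    g_j = np.array(out[7:10])
    return f_i, g_i, g_j


def wca_energy(r: float, diameter: float, epsilon: float = 1.0) -> float:
    """Weeks-Chandler-Andersen energy at separation r (contact scale =
    ``diameter``): ``4 eps [(d/r)^12 - (d/r)^6] + eps`` below the cutoff
    ``2^{1/6} d``, zero above."""
    if r <= 0:
        raise ValueError("separation must be positive")
    return float(_wca(r, diameter, epsilon)[0])


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    pos: np.ndarray
    vel: np.ndarray
    orient: np.ndarray  # one row per particle; meaningful for membrane rows
    types: np.ndarray
    masses: np.ndarray
    params: MembraneParams
    R_wall: float
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    _pairs: tuple | None = None
    _steps_since_rebuild: int = 0

    @property
    def membrane_idx(self) -> np.ndarray:
        return np.where(self.types == MEMBRANE)[0]

    @property
    def colloid_idx(self) -> np.ndarray:
        return np.where(self.types == COLLOID)[0]

    @property
    def solvent_idx(self) -> np.ndarray:
        return np.where(self.types == SOLVENT)[0]

    def frame(self) -> VesicleFrame:
        m = self.membrane_idx
        c = self.colloid_idx
        return VesicleFrame(
            beads=self.pos[m],
            orientations=None,
            colloids=self.pos[c] if len(c) else None,
            colloid_diameter=self.params.colloid_diameter,
            time=self.time,
        )


def _sig_mix(params: MembraneParams) -> np.ndarray:
    s, sc, sv = params.sigma, params.colloid_diameter, params.solvent_diameter
    table = np.zeros((3, 3))
    table[MEMBRANE, COLLOID] = table[COLLOID, MEMBRANE] = 0.5 * (s + sc)
    table[COLLOID, COLLOID] = sc
    table[COLLOID, SOLVENT] = table[SOLVENT, COLLOID] = 0.5 * (sc + sv)
    table[MEMBRANE, SOLVENT] = table[SOLVENT, MEMBRANE] = 0.5 * (s + sv)
    table[SOLVENT, SOLVENT] = sv
    return table


def _wall_radii(params: MembraneParams) -> np.ndarray:
    return np.array(
        [params.sigma, params.colloid_diameter / 2.0, params.solvent_diameter]
    )


_SKIN = 0.6


def _build_pairs(state: SimState):
    """Verlet pair list: membrane pairs at the membrane cutoff, solvent-
    involving pairs at the (much shorter) WCA cutoff, and direct colloid
    pairs."""
    pos = state.pos
    types = state.types
    p = state.params
    memb = np.where(types == MEMBRANE)[0]
    tree_m = cKDTree(pos[memb])
    mm = tree_m.query_pairs(p.r_c + _SKIN, output_type="ndarray")
    pi = memb[mm[:, 0]]
    pj = memb[mm[:, 1]]
    small = np.where(types != COLLOID)[0]
    if len(small) > len(memb):
        wca_cut = 2.0 ** (1.0 / 6.0) * max(p.solvent_diameter, p.sigma) + _SKIN
        ss = cKDTree(pos[small]).query_pairs(wca_cut, output_type="ndarray")
        a, b = small[ss[:, 0]], small[ss[:, 1]]
        keep = (types[a] == SOLVENT) | (types[b] == SOLVENT)
        pi = np.concatenate([pi, a[keep]])
        pj = np.concatenate([pj, b[keep]])
    cols = state.colloid_idx
    if len(cols):
        sig = _sig_mix(state.params)
        ci, cj = [], []
        for c in cols:
            d = np.linalg.norm(pos - pos[c], axis=1)
            cut = sig[types[c], types] * 2.0 ** (1.0 / 6.0) + _SKIN
            mask = (d < cut) & (np.arange(len(pos)) > c)
            for j in np.where(mask)[0]:
                ci.append(c)
                cj.append(j)
            mask2 = (d < cut) & (np.arange(len(pos)) < c) & (types != COLLOID)
            for j in np.where(mask2)[0]:
                ci.append(j)
                cj.append(c)
        if ci:
            pi = np.concatenate([pi, np.array(ci)])
            pj = np.concatenate([pj, np.array(cj)])
    return pi.astype(np.int64), pj.astype(np.int64)


def compute_forces(state: SimState, rebuild: bool = False):
    """Forces, orientation gradients and potential energy for the state."""
    if state._pairs is None or rebuild:
        state._pairs = _build_pairs(state)
        state._steps_since_rebuild = 0
    pi, pj = state._pairs
    F = np.zeros_like(state.pos)
    G = np.zeros_like(state.pos)
    p = state.params
    U = _forces_kernel(
        state.pos, state.orient, state.types, pi, pj, F, G,
        p.epsilon, p.r_min, p.r_c, p.xi, p.mu, p.sin_theta0,
        _sig_mix(p), p.colloid_epsilon)
    U += _wall_kernel(state.pos, state.types, F, state.R_wall,
                      _wall_radii(p), p.colloid_epsilon)
    return F, G, U


def total_energy(state: SimState) -> float:
    """Potential + translational kinetic energy."""
    _, _, U = compute_forces(state, rebuild=True)
    K = 0.5 * float((state.masses * (state.vel**2).sum(axis=1)).sum())
    return U + K


def integrate(
    state: SimState,
    n_steps: int,
    dt: float = 0.005,
    thermostat: str = "langevin",
    gamma: float = 1.0,
    rotate: bool = True,
    rot_mobility: float = 1.0,
    rebuild_every: int = 10,
) -> SimState:
    """Advance the state in place (BAOAB Langevin or velocity-Verlet NVE).

    Orientations follow overdamped rotational Langevin dynamics: the update
    direction is -dU/dn projected orthogonally to n, plus tangential noise,
    renormalized each step.  Raises if any displacement in one step exceeds
    r_c / 2 (unstable time step).
    """
    if dt > 0.005 + 1e-12:
        raise ValueError("dt must be <= 0.005 tau")
    if thermostat not in ("langevin", "nve"):
        raise ValueError("thermostat must be 'langevin' or 'nve'")
    p = state.params
    kT = p.kT_over_eps * p.epsilon
    m = state.masses[:, None]
    memb = state.membrane_idx
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    F, G, _ = compute_forces(state, rebuild=True)
    max_step = p.r_c / 2.0
    for _ in range(n_steps):
        state.vel += 0.5 * dt * F / m
        dr = 0.5 * dt * state.vel
        state.pos += dr
        if thermostat == "langevin":
            noise = state.rng.standard_normal(state.vel.shape)
            state.vel = c1 * state.vel + c2 / np.sqrt(state.masses)[:, None] * noise
        dr2 = 0.5 * dt * state.vel
        state.pos += dr2
        disp = np.abs(dr + dr2).max()
        if disp > max_step:
            raise RuntimeError(
                f"displacement {disp:.3g} > r_c/2 in one step: unstable dt"
            )
        state._steps_since_rebuild += 1
        rebuild = state._steps_since_rebuild >= rebuild_every
        F, G, _ = compute_forces(state, rebuild=rebuild)
        state.vel += 0.5 * dt * F / m
        if rotate and len(memb):
            n = state.orient[memb]
            g = G[memb]
            g_perp = g - (np.einsum("ij,ij->i", g, n))[:, None] * n
            step_det = -rot_mobility * dt * g_perp
            if thermostat == "langevin":
                xi = state.rng.standard_normal(n.shape)
                xi -= (np.einsum("ij,ij->i", xi, n))[:, None] * n
                step_det += np.sqrt(2.0 * rot_mobility * kT * dt) * xi
            n = n + step_det
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            state.orient[memb] = n
        state.time += dt
    return state


def kinetic_temperature(state: SimState) -> float:
    """Instantaneous kinetic temperature from the translational DOF."""
    K = 0.5 * float((state.masses * (state.vel**2).sum(axis=1)).sum())
    return 2.0 * K / (3.0 * len(state.pos))


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.c_[
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ]


def build_vesicle_state(
    radius: float,
    n_colloids: int = 0,
    params: MembraneParams | None = None,
    wall_radius: float | None = None,
    bead_area: float = 1.25,
    seed: int = 0,
) -> SimState:
    """Spherical vesicle of membrane beads (Fibonacci-lattice coverage, one
    bead per ``bead_area`` sigma^2, outward orientations) with ``n_colloids``
    WCA colloids placed inside, ready for Langevin dynamics."""
    params = params or MembraneParams()
    rng = np.random.default_rng(seed)
    n_beads = int(round(4.0 * np.pi * radius**2 / bead_area))
    beads = _fibonacci_sphere(n_beads) * radius
    orient = _fibonacci_sphere(n_beads)
    pos = [beads]
    types = [np.full(n_beads, MEMBRANE)]
    sc = params.colloid_diameter
    if n_colloids:
        # compact FCC-site arrangement recentered on its centroid
        pitch = sc * 1.05
        a1 = np.array([1.0, 0.0, 0.0])
        a2 = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])
        a3 = np.array([0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)])
        sites = np.array(
            [
                i * a1 + j * a2 + k * a3
                for i in range(-3, 4)
                for j in range(-3, 4)
                for k in range(-3, 4)
            ]
        )
        # greedy compact growth: next site minimizes the spread of the set
        chosen = [int(np.argmin(np.linalg.norm(sites, axis=1)))]
        while len(chosen) < n_colloids:
            sel = sites[chosen]
            best, best_cost = None, np.inf
            for idx in range(len(sites)):
                if idx in chosen:
                    continue
                trial = np.vstack([sel, sites[idx]])
                cost = ((trial - trial.mean(axis=0)) ** 2).sum()
                if cost < best_cost - 1e-12:
                    best, best_cost = idx, cost
            chosen.append(best)
        spots = sites[chosen] * pitch
        spots = spots - spots.mean(axis=0)
        reach = 0.5 * (sc + params.sigma) + 0.2  # colloid-bead WCA contact
        if np.linalg.norm(spots, axis=1).max() + reach > radius:
            raise ValueError(
                f"vesicle radius {radius} too small for {n_colloids} colloids"
            )
        pos.append(spots)
        types.append(np.full(n_colloids, COLLOID))
    pos = np.vstack(pos)
    types = np.concatenate(types)
    orient_full = np.zeros_like(pos)
    orient_full[: n_beads] = orient
    masses = np.ones(len(pos))
    masses[types == COLLOID] = (sc / params.sigma) ** 3
    kT = params.kT_over_eps * params.epsilon
    vel = rng.standard_normal(pos.shape) * np.sqrt(kT / masses)[:, None]
    vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()
    return SimState(
        pos=pos,
        vel=vel,
        orient=orient_full,
        types=types,
        masses=masses,
        params=params,
        R_wall=wall_radius if wall_radius is not None else radius * 1.8,
        rng=rng,
    )


def _membrane_radius(state: SimState) -> float:
    m = state.membrane_idx
    return float(np.linalg.norm(state.pos[m], axis=1).max())


def add_solvent(state: SimState, n_add: int, max_tries: int = 200) -> int:
    """Insert WCA solvent beads in the region between the membrane and the
    wall (rejection sampling, non-overlapping).  Returns the number actually
    inserted."""
    p = state.params
    r_in = _membrane_radius(state) + p.sigma
    r_out = state.R_wall - p.solvent_diameter
    if r_out <= r_in:
        return 0
    added = []
    tree = cKDTree(state.pos)
    for _ in range(n_add):
        for _ in range(max_tries):
            u = state.rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rad = (state.rng.uniform(r_in**3, r_out**3)) ** (1.0 / 3.0)
            cand = u * rad
            d, j = tree.query(cand)
            ok = d >= 0.95 * _sig_mix(p)[SOLVENT, state.types[j]]
            if ok and all(
                np.linalg.norm(cand - q) >= 0.95 * p.solvent_diameter for q in added
            ):
                added.append(cand)
                break
    if not added:
        return 0
    n_new = len(added)
    kT = p.kT_over_eps * p.epsilon
    state.pos = np.vstack([state.pos, np.array(added)])
    state.types = np.concatenate([state.types, np.full(n_new, SOLVENT)])
    state.masses = np.concatenate([state.masses, np.ones(n_new)])
    state.vel = np.vstack(
        [state.vel, state.rng.standard_normal((n_new, 3)) * np.sqrt(kT)]
    )
    state.orient = np.vstack([state.orient, np.zeros((n_new, 3))])
    state._pairs = None
    return n_new


def remove_solvent(state: SimState, n_remove: int) -> int:
    """Remove the given number of solvent beads (outermost first)."""
    sol = state.solvent_idx
    if len(sol) == 0:
        return 0
    n_remove = min(n_remove, len(sol))
    order = np.argsort(-np.linalg.norm(state.pos[sol], axis=1), kind="stable")
    drop = set(sol[order[:n_remove]].tolist())
    keep = np.array([i for i in range(len(state.pos)) if i not in drop])
    state.pos = state.pos[keep]
    state.vel = state.vel[keep]
    state.orient = state.orient[keep]
    state.types = state.types[keep]
    state.masses = state.masses[keep]
    state._pairs = None
    return n_remove


def membrane_intact(state: SimState, cutoff: float | None = None) -> bool:
    """True when the membrane bead neighbor graph is a single component."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import coo_matrix

    m = state.membrane_idx
    pts = state.pos[m]
    cutoff = cutoff or 1.6 * state.params.sigma
    pairs = cKDTree(pts).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return len(pts) <= 1
    n = len(pts)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def measure_state(state: SimState) -> dict:
    """Reduced volume, colloid anisotropy and related observables."""
    V, A, nu, eta = vesicle_geometry(state.frame())
    out = {"t": state.time, "V": V, "A": A, "nu": nu, "eta": eta}
    cols = state.colloid_idx
    if len(cols) >= 2:
        out["kappa2"] = kappa2(state.pos[cols]).kappa2
    return out


def deflate(
    state: SimState,
    target_nu: float,
    solvent_increment: int = 50,
    equil_steps: int = 4000,
    dt: float = 0.004,
    max_increments: int = 60,
    tol: float = 0.02,
    record=None,
    stop=None,
) -> list[dict]:
    """Drive the vesicle reduced volume toward ``target_nu`` by adding
    (deflation) or removing (re-inflation) outer solvent in increments, with
    Langevin equilibration between increments.

    Records ``(t, nu, kappa2, n_solvent)`` after every increment; aborts with
    a diagnostic if the membrane bead graph disconnects (rupture).  An
    optional ``stop`` predicate on the per-increment record ends the protocol
    early (useful for conformation-triggered stopping).
    """
    records = [] if record is None else record
    for _ in range(max_increments):
        obs = measure_state(state)
        obs["n_solvent"] = int(len(state.solvent_idx))
        records.append(obs)
        if abs(obs["nu"] - target_nu) <= tol:
            break
        if stop is not None and stop(obs):
            break
        if not membrane_intact(state):
            raise RuntimeError(
                "membrane ruptured during solvent exchange (bead graph "
                "disconnected); reduce the solvent increment"
            )
        if obs["nu"] > target_nu:
            n = add_solvent(state, solvent_increment)
            if n == 0:
                logger.warning("no room to insert solvent; stopping early")
                break
        else:
            n = remove_solvent(state, solvent_increment)
            if n == 0:
                logger.warning("no solvent left to remove; stopping early")
                break
        integrate(state, equil_steps, dt=dt, thermostat="langevin")
    return records
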