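"""Membrane model: pair potential, forces, integrator, stability."""

import numpy as np
import pytest

from finpack.membrane import (
    MembraneParams,
    SimState,
    build_vesicle_state,
    integrate,
    kinetic_temperature,
    membrane_intact,
    pair_energy,
    pair_gradients,
    total_energy,
    wca_energy,
)


@pytest.fixture(scope="module")
def params():
    return MembraneParams()


def random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestPairEnergy:
    def test_minimum_at_rmin_aligned(self, params):
        # both orientations perpendicular to the bond: a = 1, phi = 1, U = -eps
        u = pair_energy([params.r_min, 0, 0], [0, 0, 1], [0, 0, 1], params)
        assert u == pytest.approx(-1.0, rel=1e-12)

    def test_zero_at_cutoff(self, params, rng):
        for _ in range(5):
            ni, nj = random_unit(rng), random_unit(rng)
            u = pair_energy([params.r_c, 0, 0], ni, nj, params)
            assert u == pytest.approx(0.0, abs=1e-12)

    def test_branch_continuity_at_rmin(self, params, rng):
        """Left branch U_R + (1 - phi) meets right branch U_A * phi at r_min
        for every orientation pair (identity -1 + 1 - phi = -phi at eps=1)."""
        d = params.r_min
        for _ in range(10):
            ni, nj = random_unit(rng), random_unit(rng)
            u_hat = random_unit(rng)
            lo = pair_energy(u_hat * (d - 1e-10), ni, nj, params)
            hi = pair_energy(u_hat * (d + 1e-10), ni, nj, params)
            assert lo == pytest.approx(hi, abs=1e-7)

    def test_zero_separation_rejected(self, params):
        with pytest.raises(ValueError):
            pair_energy([0.0, 0.0, 0.0], [0, 0, 1], [0, 0, 1], params)

    def test_misaligned_contact_is_repulsive_branch(self, params):
        # orientation along the bond: a = 0, phi = 1 - mu < 0, so the
        # attractive branch switches sign (suppresses stacking)
        u = pair_energy([1.5, 0, 0], [1, 0, 0], [1, 0, 0], params)
        assert u > 0


class TestWCA:
    def test_cutoff_and_contact_values(self):
        sc = 12.0
        assert wca_energy(2 ** (1 / 6) * sc, sc) == pytest.approx(0.0, abs=1e-12)
        assert wca_energy(sc, sc) == pytest.approx(1.0, rel=1e-12)
        assert wca_energy(0.95 * sc, sc) == pytest.approx(2.9610, abs=1e-4)

    def test_zero_above_cutoff(self):
        assert wca_energy(1.2 * 12.0, 12.0) == 0.0


class TestForces:
    def test_force_matches_numerical_gradient(self, params, rng):
        """Analytic forces and orientation gradients agree with central
        differences to 1e-6 relative across both branches."""
        h = 1e-6
        for _ in range(20):
            ni, nj = random_unit(rng), random_unit(rng)
            rv = random_unit(rng) * rng.uniform(0.85, 2.55)
            f_i, g_i, g_j = pair_gradients(rv, ni, nj, params)
            scale = max(np.linalg.norm(f_i), 1.0)
            for ax in range(3):
                dp, dm = rv.copy(), rv.copy()
                dp[ax] += h
                dm[ax] -= h
                # r_vec points i -> j, so dU/dr_vec = -dU/dr_i = F_i
                num = (
                    pair_energy(dp, ni, nj, params) - pair_energy(dm, ni, nj, params)
                ) / (2 * h)
                assert f_i[ax] == pytest.approx(num, abs=1e-5 * scale)
            for ax in range(3):
                dp, dm = ni.copy(), ni.copy()
                dp[ax] += h
                dm[ax] -= h
                num = (
                    pair_energy(rv, dp, nj, params) - pair_energy(rv, dm, nj, params)
                ) / (2 * h)
                assert g_i[ax] == pytest.approx(num, abs=1e-5 * max(abs(num), 1.0))
            for ax in range(3):
                dp, dm = nj.copy(), nj.copy()
                dp[ax] += h
                dm[ax] -= h
                num = (
                    pair_energy(rv, ni, dp, params) - pair_energy(rv, ni, dm, params)
                ) / (2 * h)
                assert g_j[ax] == pytest.approx(num, abs=1e-5 * max(abs(num), 1.0))


def flat_patch_state(params, n_side=5, speed=0.05, seed=1):
    pts = []
    for i in range(-n_side, n_side + 1):
        for j in range(-n_side, n_side + 1):
            if abs(i + j) <= n_side:
                pts.append(
                    [(i + 0.5 * j) * params.r_min, j * np.sqrt(3) / 2 * params.r_min, 0.0]
                )
    pts = np.array(pts)
    rng = np.random.default_rng(seed)
    n = len(pts)
    return SimState(
        pos=pts,
        vel=rng.normal(scale=speed, size=(n, 3)),
        orient=np.tile([0.0, 0.0, 1.0], (n, 1)),
        types=np.zeros(n, dtype=np.int64),
        masses=np.ones(n),
        params=params,
        R_wall=1e6,
        rng=rng,
    )


class TestIntegrator:
    def test_nve_energy_drift_below_1e3(self, params):
        state = flat_patch_state(params)
        e0 = total_energy(state)
        integrate(state, 10_000, dt=0.002, thermostat="nve", rotate=False)
        e1 = total_energy(state)
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_two_bead_relaxation_toward_pair_minimum(self, params):
        rng = np.random.default_rng(0)
        state = SimState(
            pos=np.array([[0.0, 0.0, 0.0], [1.3, 0.0, 0.0]]),
            vel=np.zeros((2, 3)),
            orient=np.tile([0.0, 0.0, 1.0], (2, 1)),
            types=np.zeros(2, dtype=np.int64),
            masses=np.ones(2),
            params=params,
            R_wall=1e6,
            rng=rng,
        )
        # heavily damped, zero-temperature dynamics
        zero_T = MembraneParams(kT_over_eps=0.0)
        state.params = zero_T
        integrate(state, 4000, dt=0.002, thermostat="langevin", gamma=5.0, rotate=False)
        sep = np.linalg.norm(state.pos[1] - state.pos[0])
        assert sep == pytest.approx(zero_T.r_min, abs=0.02)

    def test_thermostat_temperature_within_5_percent(self):
        state = build_vesicle_state(radius=4.0, seed=5)
        integrate(state, 3000, dt=0.004)  # transient
        temps = []
        for _ in range(25):
            integrate(state, 400, dt=0.004)
            temps.append(kinetic_temperature(state))
        assert np.mean(temps) == pytest.approx(0.23, rel=0.05)

    def test_orientations_stay_normalized(self):
        state = build_vesicle_state(radius=4.0, seed=6)
        integrate(state, 2000, dt=0.004)
        norms = np.linalg.norm(state.orient[state.membrane_idx], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_unstable_dt_detected(self, params):
        state = flat_patch_state(params, speed=0.0)
        state.vel[0] = [500.0, 0.0, 0.0]
        with pytest.raises(RuntimeError, match="unstable"):
            integrate(state, 5, dt=0.005, thermostat="nve", rotate=False)

    def test_dt_cap_enforced(self, params):
        state = flat_patch_state(params)
        with pytest.raises(ValueError, match="dt"):
            integrate(state, 1, dt=0.01)


class TestVesicleStability:
    def test_closed_shell_stays_closed(self):
        """A prebuilt spherical shell (>= 500 beads) with a colloid inside
        remains a single connected membrane over 10^4 Langevin steps."""
        p = MembraneParams(colloid_diameter=4.0)
        state = build_vesicle_state(radius=7.2, n_colloids=1, params=p, seed=7)
        assert len(state.membrane_idx) >= 500
        r0 = np.linalg.norm(state.pos[state.membrane_idx], axis=1).max()
        integrate(state, 10_000, dt=0.004)
        assert membrane_intact(state)
        r1 = np.linalg.norm(state.pos[state.membrane_idx], axis=1).max()
        assert r1 < 1.5 * r0
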