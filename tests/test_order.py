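"""Shape anisotropy, bond order, surface reconstruction, classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import finpack as fp
from finpack.order import BAND_EDGES, detect_bistability
from finpack.synth import (
    oblate_fixture,
    prolate_fixture,
    sample_surface,
    sphere_fixture,
    spherocylinder_fixture,
)

from oracles import fcc_shell, hcp_shell, steinhardt_on_shell


class TestKappa2:
    def test_collinear_is_one(self):
        pts = np.zeros((7, 3))
        pts[:, 2] = np.arange(7)
        assert fp.kappa2(pts).kappa2 == pytest.approx(1.0)

    def test_symmetric_planar_is_quarter(self):
        # hexagon: a_x = a_y, a_z = 0
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.c_[np.cos(ang), np.sin(ang), np.zeros(6)]
        assert fp.kappa2(pts).kappa2 == pytest.approx(0.25, abs=1e-12)

    def test_isotropic_is_zero(self):
        # octahedron vertices: all three eigenvalues equal
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            float,
        )
        assert fp.kappa2(pts).kappa2 == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_and_scale_invariance(self, rng):
        pts = rng.normal(size=(20, 3))
        base = fp.kappa2(pts).kappa2
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            moved = 3.7 * (pts @ R.T) + rng.normal(size=3)
            assert fp.kappa2(moved).kappa2 == pytest.approx(base, abs=1e-10)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fp.kappa2(np.zeros((5, 3)))


class TestQ6:
    def test_single_bond_is_unity(self):
        assert fp.q6(fp.make_linear(2)) == pytest.approx(1.0, abs=1e-10)

    def test_ideal_fcc_shell_value(self):
        """Central particle of a 13-sphere FCC motif: the oracle value
        evaluates to ~0.5745."""
        ideal = steinhardt_on_shell(fcc_shell())
        assert ideal == pytest.approx(0.5745, abs=2e-4)
        motif = np.vstack([np.zeros(3), fcc_shell()])
        per = fp.q6(motif, per_particle=True)
        assert per[0] == pytest.approx(ideal, abs=1e-10)

    def test_ideal_hcp_shell_value(self):
        ideal = steinhardt_on_shell(hcp_shell())
        assert ideal == pytest.approx(0.4848, abs=2e-4)
        motif = np.vstack([np.zeros(3), hcp_shell()])
        per = fp.q6(motif, per_particle=True)
        assert per[0] == pytest.approx(ideal, abs=1e-10)

    def test_rotation_invariance(self, rng):
        cluster = fp.make_fcc_tetrahedron(4)
        base = fp.q6(cluster)
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            rotated = fp.SphereCluster(cluster.centers @ R.T)
            assert fp.q6(rotated) == pytest.approx(base, abs=1e-10)

    def test_isolated_particle_warns(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [50, 0, 0]], float)
        with pytest.warns(UserWarning, match="without neighbors"):
            val = fp.q6(pts)
        assert 0 < val < 1


class TestVesicleGeometry:
    @pytest.mark.parametrize(
        "fixture,label",
        [
            (sphere_fixture(20.0), "sphere"),
            (prolate_fixture(10.0, 20.0), "prolate"),
            (oblate_fixture(15.0, 6.0), "discoid"),
            (spherocylinder_fixture(6.0, 24.0), "capsule"),
        ],
    )
    def test_nu_recovery_within_3_percent(self, fixture, label):
        frame = sample_surface(fixture, n_beads=3000, seed=7)
        V, A, nu, eta = fp.vesicle_geometry(frame)
        assert nu == pytest.approx(fixture.nu, rel=0.03), label

    def test_sphere_nu_is_one(self):
        frame = sample_surface(sphere_fixture(20.0), n_beads=3000, seed=1)
        _, _, nu, _ = fp.vesicle_geometry(frame)
        assert nu == pytest.approx(1.0, abs=0.02)

    def test_spherocylinder_matches_sausage_reference(self):
        # capsule matching the N = 5 sausage envelope (d = 12 sigma)
        d = 12.0
        fixture = spherocylinder_fixture(d / 2, 4 * d)
        frame = sample_surface(fixture, n_beads=4000, seed=3)
        _, _, nu, _ = fp.vesicle_geometry(frame)
        assert nu == pytest.approx(fp.nu_lin(5), rel=0.03)

    def test_eta_reported_with_colloids(self):
        frame = sample_surface(sphere_fixture(20.0), n_beads=2000, seed=2)
        frame.colloids = np.zeros((3, 3))
        frame.colloids[:, 0] = [-13, 0, 13]
        frame.colloid_diameter = 12.0
        V, A, nu, eta = fp.vesicle_geometry(frame)
        assert eta == pytest.approx(3 * np.pi / 6 * 12**3 / V, rel=1e-12)


class TestClassifier:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.02, "cluster"),
            (0.14, "cluster"),
            (0.25, "plate"),
            (0.4, "intermediate"),
            (0.5, "linear"),
            (0.7, "linear"),
        ],
    )
    def test_bands(self, value, label):
        assert fp.classify(value).label == label

    def test_band_edges_cover_unit_interval(self):
        assert BAND_EDGES == (0.15, 0.35, 0.5)

    def test_noiseless_archetypes_classify_exactly(self):
        line = fp.make_linear(9).centers
        plate = fp.make_planar("triangular", 3).centers
        compact = fp.make_mackay_icosahedron(1).centers
        assert fp.classify(fp.kappa2(line).kappa2).label == "linear"
        assert fp.classify(fp.kappa2(plate).kappa2).label == "plate"
        assert fp.classify(fp.kappa2(compact).kappa2).label == "cluster"


class TestBistability:
    def test_constant_series_single_segment(self):
        series = np.full(500, 0.25)
        segments, alternations, bistable = detect_bistability(series)
        assert len(segments) == 1
        assert segments[0].state == "plate"
        assert alternations == 0
        assert not bistable

    def test_clean_telegraph_recovers_alternations(self):
        # deterministic square wave, dwell 50 samples, plate <-> linear
        series = np.tile(np.r_[np.full(50, 0.25), np.full(50, 0.7)], 5)
        segments, alternations, bistable = detect_bistability(
            series, smooth_window=20, min_dwell=30
        )
        states = {s.state for s in segments}
        assert states == {"plate", "linear"}
        assert alternations == 9
        assert bistable

    def test_noise_only_cluster_not_bistable(self, rng):
        series = np.clip(rng.normal(0.02, 0.02, 2000), 0, 1)
        segments, alternations, bistable = detect_bistability(series)
        assert len(segments) == 1
        assert segments[0].state == "cluster"
        assert not bistable

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_bistability(np.full(50, 0.2))
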