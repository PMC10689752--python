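"""Hull machinery, Steiner dilation, and the sausage reference forms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import finpack as fp
from finpack.geometry import center_hull, dilated_volume

from conftest import random_contact_cluster
from oracles import mc_dilated_volume

TETRA = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3) / 2, 0.0],
        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
    ]
)


class TestCenterHull:
    def test_single_point_dim0(self):
        h = center_hull(fp.SphereCluster([[1.0, 2.0, 3.0]]))
        assert h.dim == 0 and h.V_hull == 0.0

    def test_collinear_dim1_length(self):
        pts = np.zeros((5, 3))
        pts[:, 0] = np.arange(5)
        h = center_hull(fp.SphereCluster(pts))
        assert h.dim == 1
        assert h.length == pytest.approx(4.0)

    def test_regular_tetrahedron_volume(self):
        h = center_hull(fp.SphereCluster(TETRA))
        assert h.dim == 3
        assert h.V_hull == pytest.approx(1.0 / (6.0 * np.sqrt(2.0)), rel=1e-12)
        assert h.A_hull == pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_planar_dim2_measures(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        h = center_hull(fp.SphereCluster(square))
        assert h.dim == 2
        assert h.area2 == pytest.approx(1.0)
        assert h.perimeter2 == pytest.approx(4.0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fp.SphereCluster([[0.0, 0.0, np.nan]])


class TestDilatedVolume:
    def test_single_ball(self):
        h = center_hull(fp.SphereCluster([[0.0, 0.0, 0.0]]))
        assert dilated_volume(h, 0.5) == pytest.approx(np.pi / 6.0)

    def test_two_sphere_spherocylinder(self):
        h = center_hull(fp.SphereCluster([[0, 0, 0], [1, 0, 0]]))
        assert dilated_volume(h, 0.5) == pytest.approx(np.pi / 4 + np.pi / 6)

    def test_tetrahedron_steiner_terms(self):
        # edge 1, r = 1/2: interior + face + edge + vertex closed forms
        h = center_hull(fp.SphereCluster(TETRA))
        v = dilated_volume(h, 0.5)
        interior = 1.0 / (6 * np.sqrt(2))
        faces = np.sqrt(3.0) * 0.5
        gamma = np.pi - np.arccos(1.0 / 3.0)  # exterior dihedral of tetrahedron
        edges = 6 * gamma / 2.0 * 0.25
        ball = np.pi / 6.0
        assert v == pytest.approx(interior + faces + edges + ball, rel=1e-10)
        assert v == pytest.approx(2.9404, abs=2e-4)

    def test_monotone_in_points(self, rng):
        cluster = random_contact_cluster(rng, 8)
        v1 = dilated_volume(center_hull(cluster), 0.5)
        grown = np.vstack([cluster.centers, cluster.centers.max(0) + 1.0])
        v2 = dilated_volume(center_hull(fp.SphereCluster(grown)), 0.5)
        assert v2 >= v1

    @pytest.mark.parametrize("n", [2, 3, 5, 8, 12, 20])
    def test_monte_carlo_oracle(self, n, rng):
        """Exact Steiner dilation agrees with rejection sampling within 3 SE."""
        for rep in range(4):
            cluster = random_contact_cluster(rng, n)
            exact = dilated_volume(center_hull(cluster), 0.5)
            est, se = mc_dilated_volume(
                cluster.centers, 0.5, n_samples=120_000, seed=1000 * n + rep
            )
            assert abs(exact - est) <= 3.0 * se

    def test_flattened_prism_converges_to_planar_formula(self):
        """A thin triangular prism's dilated volume approaches the dim-2
        closed form of its base triangle as the thickness goes to zero."""
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        flat = np.c_[tri, np.zeros(3)]
        target = dilated_volume(center_hull(fp.SphereCluster(flat)), 0.5)
        for h in (1e-3, 1e-5):
            prism = np.vstack([np.c_[tri, np.full(3, -h / 2)], np.c_[tri, np.full(3, h / 2)]])
            v = dilated_volume(center_hull(fp.SphereCluster(prism)), 0.5)
            assert v == pytest.approx(target, rel=5 * h)


class TestPackingFraction:
    def test_single_sphere_is_unity(self):
        assert fp.packing_fraction_ch(fp.SphereCluster([[0, 0, 0]])) == pytest.approx(1.0)

    def test_pair_matches_sausage(self):
        pair = fp.make_linear(2)
        assert fp.packing_fraction_ch(pair) == pytest.approx(0.8, rel=1e-12)

    def test_contact_tetrahedron(self):
        eta = fp.packing_fraction_ch(fp.SphereCluster(TETRA))
        assert eta == pytest.approx(0.7123, abs=2e-4)
        # slightly below the four-sphere sausage value 8/11
        assert eta < fp.eta_lin(4)

    def test_overlap_error_names_pair(self):
        pts = np.array([[0, 0, 0], [0.5, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="0 and 1"):
            fp.packing_fraction_ch(fp.SphereCluster(pts))

    def test_scale_invariance_with_diameter(self):
        c1 = fp.make_fcc_tetrahedron(3, diameter=1.0)
        c2 = fp.make_fcc_tetrahedron(3, diameter=2.5)
        assert fp.packing_fraction_ch(c1) == pytest.approx(
            fp.packing_fraction_ch(c2), rel=1e-12
        )


class TestSausageReference:
    @pytest.mark.parametrize(
        "N,expected", [(1, 1.0), (2, 0.8), (4, 8.0 / 11.0), (100, 200.0 / 299.0)]
    )
    def test_eta_lin_closed_form(self, N, expected):
        assert fp.eta_lin(N) == pytest.approx(expected, rel=1e-14)

    def test_eta_lin_equals_explicit_spherocylinder_ratio(self):
        for N in (2, 5, 17):
            v_sc = np.pi / 4 * (N - 1) + np.pi / 6
            assert fp.eta_lin(N) == pytest.approx(N * np.pi / 6 / v_sc, rel=1e-14)

    def test_nu_lin_values(self):
        assert fp.nu_lin(1) == pytest.approx(1.0)
        assert fp.nu_lin(3) == pytest.approx(0.7698, abs=1e-4)
        assert fp.nu_lin(9) == pytest.approx(0.4815, abs=1e-4)

    def test_monotone_decreasing_and_limit(self):
        ns = np.arange(1, 400)
        etas = np.array([fp.eta_lin(n) for n in ns])
        nus = np.array([fp.nu_lin(n) for n in ns])
        assert (np.diff(etas) < 0).all()
        assert (np.diff(nus) < 0).all()
        assert fp.eta_lin(10**6) == pytest.approx(2.0 / 3.0, abs=1e-5)

    def test_invalid_N(self):
        with pytest.raises(ValueError):
            fp.eta_lin(0)
        with pytest.raises(ValueError):
            fp.nu_lin(0)


class TestReducedVolume:
    def test_sphere_is_unity(self):
        assert fp.reduced_volume(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0)

    def test_spherocylinder_consistent_with_nu_lin(self):
        N, d = 5, 1.0
        L, r = (N - 1) * d, d / 2
        V = np.pi * r**2 * L + 4 * np.pi / 3 * r**3
        A = 2 * np.pi * r * L + 4 * np.pi * r**2
        assert fp.reduced_volume(V, A) == pytest.approx(fp.nu_lin(5), rel=1e-12)

    def test_prolate_two_to_one(self):
        from oracles import spheroid_area

        a, c = 1.0, 2.0
        V = 4 * np.pi / 3 * a * a * c
        nu = fp.reduced_volume(V, spheroid_area(a, c))
        assert nu == pytest.approx(0.8950, abs=1e-4)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fp.reduced_volume(10.0, 4 * np.pi)
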