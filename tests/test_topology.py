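"""Persistent homology against the brute-force oracle; sliced-Wasserstein."""

import numpy as np
import pytest

import brainstates as bs
from brainstates import topology as tp
from oracle import brute_force_sliced_wasserstein, brute_force_vr


def random_distance_matrix(rng, n, low=0.1, high=1.0):
    D = rng.uniform(low, high, size=(n, n))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def random_diagram(rng, dim=0, max_pts=6):
    m = rng.integers(0, max_pts + 1)
    b = np.zeros(m) if dim == 0 else rng.uniform(0, 1, m)
    d = b + rng.uniform(0.05, 1.0, m)
    return tp.PersistenceDiagram(dimension=dim,
                                 pairs=np.column_stack([b, d]) if m else
                                 np.empty((0, 2)))


class TestVRPersistence:
    def test_two_points(self):
        dg = bs.vr_persistence(tp.Filtration(np.array([[0.0, 0.7],
                                                       [0.7, 0.0]]), max_dim=1))
        assert dg[0].pairs.tolist() == [[0.0, 0.7]]
        assert dg[0].essential_count == 1
        assert dg[1].n_pairs == 0

    def test_unit_square_h1(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dg = bs.vr_persistence(tp.Filtration(D, max_dim=2))
        assert dg[1].n_pairs == 1
        assert np.allclose(dg[1].pairs[0], [1.0, np.sqrt(2)])
        assert dg[2].n_pairs == 0

    def test_equidistant_points(self):
        n, d = 6, 0.5
        D = np.full((n, n), d)
        np.fill_diagonal(D, 0.0)
        dg = bs.vr_persistence(tp.Filtration(D, max_dim=2))
        assert dg[0].n_pairs == n - 1
        assert np.allclose(dg[0].pairs[:, 1], d)
        assert dg[1].n_pairs == 0  # clique fill-in at d kills all loops at d

    def test_h0_birth_zero_count_n_minus_1(self, rng):
        for n in (2, 5, 9):
            D = random_distance_matrix(rng, n)
            dg = bs.vr_persistence(tp.Filtration(D, max_dim=0))
            assert dg[0].n_pairs == n - 1
            assert np.all(dg[0].pairs[:, 0] == 0.0)
            assert dg[0].essential_count == 1

    def test_matches_brute_force_oracle(self, rng):
        """Exact agreement with global boundary-matrix reduction, dims 0-2."""
        for trial in range(40):
            n = int(rng.integers(3, 9))
            D = random_distance_matrix(rng, n)
            got = bs.vr_persistence(tp.Filtration(D, max_dim=2))
            exp = brute_force_vr(D, max_dim=2)
            for k in range(3):
                pairs, ess = exp[k]
                assert got[k].essential_count == ess, f"dim {k} essential"
                assert got[k].n_pairs == len(pairs), f"dim {k} count"
                if pairs:
                    assert np.allclose(got[k].pairs, np.array(pairs),
                                       atol=1e-12)

    def test_h0_stability_under_perturbation(self, rng):
        """Perturbing every entry by <= eps moves every H0 death by <= eps."""
        D = random_distance_matrix(rng, 12)
        base = np.sort(bs.vr_persistence(tp.Filtration(D, max_dim=0))[0].pairs[:, 1])
        for _ in range(20):
            eps = 0.01
            P = rng.uniform(-eps, eps, size=D.shape)
            P = 0.5 * (P + P.T)
            np.fill_diagonal(P, 0.0)
            D2 = np.clip(D + P, 0.0, None)
            np.fill_diagonal(D2, 0.0)
            pert = np.sort(
                bs.vr_persistence(tp.Filtration(D2, max_dim=0))[0].pairs[:, 1])
            assert np.abs(base - pert).max() <= eps + 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError, match="NaN|finite"):
            tp.Filtration(np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError, match="negative"):
            tp.Filtration(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            tp.Filtration(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_node_guard(self):
        D = np.zeros((401, 401))
        with pytest.raises(ValueError, match="force"):
            bs.vr_persistence(tp.Filtration(D, max_dim=2))


class TestSingleLinkage:
    def test_chain(self):
        D = np.array([[0.0, 0.2, 0.9],
                      [0.2, 0.0, 0.3],
                      [0.9, 0.3, 0.0]])
        assert np.allclose(bs.h0_single_linkage(D), [0.2, 0.3])

    def test_equidistant_triple(self):
        D = np.full((3, 3), 0.5)
        np.fill_diagonal(D, 0.0)
        assert np.allclose(bs.h0_single_linkage(D), [0.5, 0.5])

    def test_equals_vr_h0_deaths(self, rng):
        for _ in range(25):
            D = random_distance_matrix(rng, 20)
            merge = bs.h0_single_linkage(D)
            deaths = np.sort(
                bs.vr_persistence(tp.Filtration(D, max_dim=0))[0].pairs[:, 1])
            assert np.abs(merge - deaths).max() < 1e-9


class TestSlicedWasserstein:
    def test_identity_and_symmetry(self, rng):
        for _ in range(10):
            a = random_diagram(rng, dim=1)
            b = random_diagram(rng, dim=1)
            assert bs.sliced_wasserstein(a, a) == 0.0
            assert np.isclose(bs.sliced_wasserstein(a, b),
                              bs.sliced_wasserstein(b, a))

    def test_single_point_vs_empty_matches_brute_force(self):
        d1 = tp.PersistenceDiagram(dimension=1, pairs=np.array([[0.0, 1.0]]))
        d2 = tp.PersistenceDiagram(dimension=1, pairs=np.empty((0, 2)))
        got = bs.sliced_wasserstein(d1, d2)
        exp = brute_force_sliced_wasserstein(d1.pairs, d2.pairs)
        assert np.isclose(got, exp)

    def test_matches_brute_force_on_random_diagrams(self, rng):
        for _ in range(30):
            a = random_diagram(rng, dim=1)
            b = random_diagram(rng, dim=1)
            assert np.isclose(bs.sliced_wasserstein(a, b),
                              brute_force_sliced_wasserstein(a.pairs, b.pairs))

    def test_pseudo_metric_axioms(self, rng):
        for _ in range(60):
            a, b, c = (random_diagram(rng, dim=0) for _ in range(3))
            dab = bs.sliced_wasserstein(a, b)
            dac = bs.sliced_wasserstein(a, c)
            dcb = bs.sliced_wasserstein(c, b)
            assert dab >= 0.0
            assert dab <= dac + dcb + 1e-9

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            bs.sliced_wasserstein(random_diagram(rng, 0), random_diagram(rng, 1))


class TestDiagramMatrix:
    def test_identical_diagrams_zero_matrix(self, rng):
        d = random_diagram(rng, dim=0, max_pts=5)
        sdm = bs.diagram_distance_matrix([d, d, d])
        assert np.allclose(sdm.D, 0.0)
        assert sdm.metric_name == "H0"

    def test_matches_scalar_calls(self, rng):
        dgs = [random_diagram(rng, dim=1) for _ in range(4)]
        sdm = bs.diagram_distance_matrix(dgs)
        for i in range(4):
            for j in range(4):
                assert np.isclose(sdm.D[i, j],
                                  bs.sliced_wasserstein(dgs[i], dgs[j]),
                                  atol=1e-10)

    def test_permutation_equivariance(self, rng):
        dgs = [random_diagram(rng, dim=0) for _ in range(5)]
        perm = [3, 1, 4, 0, 2]
        D1 = bs.diagram_distance_matrix(dgs).D
        D2 = bs.diagram_distance_matrix([dgs[i] for i in perm]).D
        assert np.allclose(D2, D1[np.ix_(perm, perm)])

    def test_cross_matrix_matches_scalar(self, rng):
        a = [random_diagram(rng, dim=1) for _ in range(3)]
        b = [random_diagram(rng, dim=1) for _ in range(4)]
        R = tp.diagram_cross_matrix(a, b)
        for i in range(3):
            for j in range(4):
                assert np.isclose(R[i, j], bs.sliced_wasserstein(a[i], b[j]),
                                  atol=1e-10)

    def test_mixed_dimensions_error(self, rng):
        with pytest.raises(ValueError, match="mixed"):
            bs.diagram_distance_matrix([random_diagram(rng, 0),
                                        random_diagram(rng, 1)])


def test_diagram_csv_roundtrip(tmp_path, rng):
    dgs = [random_diagram(rng, dim=k, max_pts=5) for k in (0, 1, 2)]
    for d in dgs:
        d.essential_count = int(rng.integers(0, 3))
    path = tmp_path / "dgm.csv"
    tp.write_diagrams_csv(dgs, path)
    back = tp.read_diagrams_csv(path)
    for a, b in zip(dgs, back):
        assert a.dimension == b.dimension
        assert a.essential_count == b.essential_count
        assert a.pairs.shape == b.pairs.shape
        if a.pairs.size:
            assert np.abs(a.pairs - b.pairs).max() < 1e-12
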