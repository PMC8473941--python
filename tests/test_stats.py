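"""Bray-Curtis, NMDS and Mantel, cross-checked against independent references."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from sklearn.isotonic import IsotonicRegression

from gdgtbudget.errors import DataError, UndefinedResultError
from gdgtbudget.stats import NMDS, bray_curtis, bray_curtis_matrix, kruskal_stress, mantel, nmds


def reference_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Independent Kruskal stress-1: isotonic fit via sklearn, direct formula."""
    iu = np.triu_indices(len(D), 1)
    delta = D[iu]
    d = pdist(coords)
    dhat = IsotonicRegression().fit_transform(delta, d)
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum()))


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_vectors(self):
        assert bray_curtis([2, 0], [0, 2]) == 1.0

    def test_hand_arithmetic(self):
        assert bray_curtis([1, 1], [1, 3]) == pytest.approx(1 / 3)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(6), rng.random(6)
            assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))
            assert 0.0 <= bray_curtis(x, y) <= 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y), rel=1e-12)

    def test_not_scale_invariant(self):
        assert bray_curtis([2, 2], [1, 3]) != pytest.approx(bray_curtis([1, 1], [1, 3]))

    def test_both_zero_signalled(self):
        with pytest.raises(UndefinedResultError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_normalizes_rows(self):
        table = pd.DataFrame([[2, 2], [1, 1]], index=["a", "b"])
        dm = bray_curtis_matrix(table, relative=True)
        assert dm["a", "b"] == pytest.approx(0.0)  # same composition, different scale

    def test_matrix_zero_row_rejected(self):
        with pytest.raises(DataError, match="all-zero"):
            bray_curtis_matrix(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"]))


class TestNMDS:
    def test_collinear_points_embed_exactly(self):
        coords = np.array([[0.0], [1.0], [2.5], [4.0]])
        D = squareform(pdist(coords))
        res = nmds(D, ndim=2, n_restarts=10, seed=0)
        assert res.stress < 1e-3

    def test_planar_points_embed_exactly(self):
        rng = np.random.default_rng(3)
        coords = rng.random((5, 2))
        D = squareform(pdist(coords))
        res = nmds(D, ndim=2, n_restarts=10, seed=0)
        assert res.stress < 1e-3

    def test_stress_matches_independent_evaluation(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            D = squareform(pdist(rng.random((6, 4))))
            res = nmds(D, ndim=2, n_restarts=10, seed=trial)
            assert res.stress == pytest.approx(reference_stress(D, res.coordinates), abs=1e-8)
            assert res.stress == pytest.approx(kruskal_stress(D, res.coordinates), abs=1e-12)

    def test_stress_never_increases(self):
        rng = np.random.default_rng(7)
        D = squareform(pdist(rng.random((8, 3))))
        res = nmds(D, ndim=2, n_restarts=5, seed=0)
        assert (np.diff(res.stress_history) <= 1e-9).all()

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(9)
        D = squareform(pdist(rng.random((7, 3))))
        a = nmds(D, seed=4)
        b = nmds(D, seed=4)
        assert a.stress == b.stress
        assert (a.coordinates == b.coordinates).all()

    def test_coordinates_centered(self):
        rng = np.random.default_rng(11)
        D = squareform(pdist(rng.random((6, 3))))
        res = nmds(D, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_stress_invariant_under_rotation(self):
        rng = np.random.default_rng(13)
        D = squareform(pdist(rng.random((6, 3))))
        res = nmds(D, seed=0)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = res.coordinates @ R.T + np.array([3.0, -1.0])
        assert kruskal_stress(D, rotated) == pytest.approx(res.stress, abs=1e-10)

    def test_degenerate_all_equal_warns(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning, match="arbitrary"):
            model = NMDS(seed=0).fit(D)
        assert not model.converged_

    def test_too_few_objects_rejected(self):
        with pytest.raises(DataError):
            nmds(np.zeros((2, 2)))

    def test_fit_exposes_sklearn_style_attributes(self):
        rng = np.random.default_rng(15)
        D = squareform(pdist(rng.random((5, 3))))
        model = NMDS(n_components=2, n_restarts=4, seed=1).fit(DistanceMatrix(D, list("abcde")))
        assert model.embedding_.shape == (5, 2)
        assert model.n_restarts_used_ == 4
        assert model.ids_ == list("abcde")


class TestMantel:
    def rand_dm(self, rng, n=8):
        return squareform(pdist(rng.random((n, 3))))

    def test_self_correlation(self):
        D = self.rand_dm(np.random.default_rng(0))
        res = mantel(D, D, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_constant_matrix_signalled(self):
        D = self.rand_dm(np.random.default_rng(1))
        C = np.ones((8, 8)) - np.eye(8)
        with pytest.raises(UndefinedResultError):
            mantel(D, C, seed=0)

    def test_label_mismatch_rejected(self):
        D = self.rand_dm(np.random.default_rng(2), n=4)
        with pytest.raises(DataError, match="labels"):
            mantel(DistanceMatrix(D, list("abcd")), DistanceMatrix(D, list("abce")), seed=0)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            D1, D2 = self.rand_dm(rng), self.rand_dm(rng)
            ours = mantel(D1, D2, n_perm=99, seed=trial)
            ref_r, _, _ = skbio_mantel(DistanceMatrix(D1), DistanceMatrix(D2),
                                       permutations=0, alternative="greater")
            assert ours.r == pytest.approx(float(ref_r), rel=1e-9)

    def test_invariant_to_common_relabeling(self):
        rng = np.random.default_rng(4)
        D1, D2 = self.rand_dm(rng), self.rand_dm(rng)
        perm = rng.permutation(8)
        a = mantel(D1, D2, n_perm=99, seed=0)
        b = mantel(D1[np.ix_(perm, perm)], D2[np.ix_(perm, perm)], n_perm=99, seed=0)
        assert a.r == pytest.approx(b.r, rel=1e-9)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(5)
        D1, D2 = self.rand_dm(rng), self.rand_dm(rng)
        assert mantel(D1, D2, seed=8) == mantel(D1, D2, seed=8)
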