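import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnspf.exceptions import ConvergenceError
from lnspf.functional import FunctionalFeatures
from lnspf.fusion import (FeatureMatrix, ScoreVector, build_feature_matrix,
                          build_h, cscore, entropy_weights, propagate)
from lnspf.topology import TopologyFeatures


def _fm(z):
    """FeatureMatrix from a raw array, normalizing like the builder."""
    z = np.asarray(z, dtype=float)
    sums = z.sum(axis=0)
    zero = sums <= 0
    znorm = np.divide(z, np.where(zero, 1.0, sums), where=~zero,
                      out=np.zeros_like(z))
    return FeatureMatrix(proteins=[f"p{i}" for i in range(z.shape[0])],
                         Z=z, Znorm=znorm, zero_columns=zero)


class TestBuildFeatureMatrix:
    def test_column_normalization_and_order(self):
        topo = TopologyFeatures(tp1={"a": 1.0, "b": 3.0},
                                tp2={"a": 0.0, "b": 0.0})
        func = FunctionalFeatures(fp1={"a": 2.0, "b": 2.0},
                                  fp2={"a": 1.0, "b": 0.5})
        fm = build_feature_matrix(topo, func, ["a", "b"])
        np.testing.assert_allclose(fm.Znorm[:, 0], [0.25, 0.75])
        assert fm.feature_names == ("TP1", "TP2", "FP1", "FP2")
        assert fm.Z.shape == (2, 4)
        # the all-zero TP2 column stays zero and is flagged
        assert fm.zero_columns.tolist() == [False, True, False, False]
        np.testing.assert_allclose(fm.Znorm[:, 1], [0.0, 0.0])

    def test_nonzero_columns_sum_to_one(self):
        rng = np.random.default_rng(2)
        fm = _fm(rng.random((7, 4)))
        np.testing.assert_allclose(fm.Znorm.sum(axis=0), np.ones(4))


class TestEntropyWeights:
    def test_uniform_column_gets_zero_weight(self):
        fm = _fm(np.column_stack([np.ones(5), [1, 0, 0, 0, 0]]))
        ew = entropy_weights(fm)
        assert ew.e[0] == pytest.approx(1.0)
        assert ew.e[1] == pytest.approx(0.0)
        np.testing.assert_allclose(ew.w, [0.0, 1.0])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        ew = entropy_weights(_fm(rng.random((9, 4))))
        assert ew.w.sum() == pytest.approx(1.0)
        assert (ew.w >= 0).all()
        assert ((0 <= ew.e) & (ew.e <= 1)).all()

    def test_all_uniform_falls_back_to_equal_weights(self):
        fm = _fm(np.ones((6, 3)))
        ew = entropy_weights(fm)
        assert ew.uniform_fallback
        np.testing.assert_allclose(ew.w, np.full(3, 1 / 3))

    def test_zero_column_treated_as_uninformative(self):
        fm = _fm(np.column_stack([[0, 0, 0, 0], [1.0, 0, 0, 0]]))
        ew = entropy_weights(fm)
        assert ew.w[0] == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    def test_invariants_on_random_matrices(self, n, seed):
        """Entropies stay in [0,1] and weights form a distribution for any
        non-negative feature matrix."""
        rng = np.random.default_rng(seed)
        ew = entropy_weights(_fm(rng.random((n, 4)) ** 2))
        assert ((0 <= ew.e) & (ew.e <= 1)).all()
        assert ew.w.sum() == pytest.approx(1.0)
        assert (ew.w >= 0).all()

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError):
            entropy_weights(_fm([[1.0, 2.0]]))

    def test_constant_column_leaves_other_ratios_unchanged(self):
        rng = np.random.default_rng(8)
        z = rng.random((10, 3))
        w_without = entropy_weights(_fm(z)).w
        w_with = entropy_weights(_fm(np.column_stack([z, np.ones(10)]))).w
        np.testing.assert_allclose(w_with[:3] / w_with[:3].sum(),
                                   w_without / w_without.sum(), atol=1e-12)
        assert w_with[3] == pytest.approx(0.0)


class TestCScore:
    def test_weighted_row_sum(self):
        fm = _fm([[0.2, 0.4], [0.8, 0.6]])
        fm.Znorm = np.array([[0.2, 0.4], [0.8, 0.6]])  # use rows directly
        from lnspf.fusion import EntropyWeights
        ew = EntropyWeights(e=np.zeros(2), w=np.array([0.5, 0.5]))
        assert cscore(fm, ew).values[0] == pytest.approx(0.3)

    def test_degenerate_weight_selects_column(self):
        rng = np.random.default_rng(3)
        fm = _fm(rng.random((6, 4)))
        from lnspf.fusion import EntropyWeights
        ew = EntropyWeights(e=np.zeros(4), w=np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(cscore(fm, ew).values, fm.Znorm[:, 0])


class TestBuildH:
    def test_min_rule_hand_example(self):
        cs = ScoreVector(values=np.array([1.0, 2.0, 3.0]), stage="CScore")
        h = build_h(cs).H
        expected = np.array([[1, 1, 1], [1, 2, 2], [1, 2, 3]]) / 6.0
        np.testing.assert_allclose(h, expected)

    def test_equal_scores_give_uniform_matrix(self):
        cs = ScoreVector(values=np.full(4, 2.5), stage="CScore")
        np.testing.assert_allclose(build_h(cs).H, np.full((4, 4), 0.25))

    def test_single_protein(self):
        cs = ScoreVector(values=np.array([5.0]), stage="CScore")
        np.testing.assert_allclose(build_h(cs).H, [[1.0]])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            build_h(ScoreVector(values=np.zeros(3), stage="CScore"))

    def test_symmetry_and_min_dominance(self):
        rng = np.random.default_rng(5)
        cs = ScoreVector(values=rng.random(12), stage="CScore")
        h = build_h(cs).H
        assert (h >= 0).all()
        np.testing.assert_allclose(h, h.T)
        for i in range(12):
            for j in range(12):
                if i != j:
                    assert h[i, j] <= min(h[i, i], h[j, j]) + 1e-15

    def test_edge_restricted_variant(self, triangle_tail_net):
        cs = ScoreVector(values=np.array([1.0, 2.0, 3.0, 4.0]),
                         stage="CScore")
        h = build_h(cs, adjacency=triangle_tail_net.adjacency()).H
        a, d = triangle_tail_net.index["a"], triangle_tail_net.index["d"]
        assert h[a, d] == 0.0 and h[a, a] > 0


class TestPropagate:
    def test_zero_matrix_fixed_point(self):
        from lnspf.fusion import FusionMatrix
        y0 = ScoreVector(values=np.array([1.0, 2.0]), stage="Y0")
        out = propagate(FusionMatrix(H=np.zeros((2, 2))), y0, alpha=0.6)
        np.testing.assert_allclose(out.values, 0.4 * y0.values)

    def test_zero_start_stays_zero(self):
        cs = ScoreVector(values=np.array([1.0, 2.0, 3.0]), stage="CScore")
        out = propagate(build_h(cs),
                        ScoreVector(values=np.zeros(3), stage="Y0"),
                        alpha=0.6)
        np.testing.assert_allclose(out.values, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_solve(self, seed):
        rng = np.random.default_rng(seed)
        cs = ScoreVector(values=rng.random(15) + 0.05, stage="CScore")
        h = build_h(cs)
        y0 = ScoreVector(values=rng.random(15), stage="Y0")
        alpha, delta = 0.6, 1e-9
        out = propagate(h, y0, alpha, delta=delta, max_iter=5000)
        closed = 0.4 * np.linalg.solve(np.eye(15) - alpha * h.H, y0.values)
        assert np.linalg.norm(out.values - closed) < 10 * delta

    def test_divergent_iteration_raises(self):
        from lnspf.fusion import FusionMatrix
        bad = FusionMatrix(H=np.full((3, 3), 2.0))  # rho = 6, alpha·rho > 1
        y0 = ScoreVector(values=np.ones(3), stage="Y0")
        with pytest.raises(ConvergenceError):
            propagate(bad, y0, alpha=0.9, max_iter=200)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        c = rng.random(10) + 0.1
        y = rng.random(10)
        perm = rng.permutation(10)
        out = propagate(build_h(ScoreVector(values=c, stage="CScore")),
                        ScoreVector(values=y, stage="Y0"), 0.6, delta=1e-12)
        out_p = propagate(
            build_h(ScoreVector(values=c[perm], stage="CScore")),
            ScoreVector(values=y[perm], stage="Y0"), 0.6, delta=1e-12)
        np.testing.assert_allclose(out_p.values, out.values[perm],
                                   atol=1e-9)
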