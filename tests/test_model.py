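"""Mode-1 HOSVD: oracle equivalence, orthonormality, reconstruction,
orientation, segments and mean-frequency diagnostics."""

import math

import numpy as np
import pytest

import alntensor as at
from alntensor.model import mode1_hosvd, mode1_unfold

from conftest import random_alignment


def oracle_unfolding(values):
    """Independently materialized K x LM unfolding: slices side by side."""
    K, L, M = values.shape
    out = np.zeros((K, L * M))
    for i in range(K):
        for s in range(L):
            for m in range(M):
                out[i, s * M + m] = values[i, s, m]
    return out


def random_tensor(seed, K=None, M=None):
    rng = np.random.default_rng(seed)
    K = K or int(rng.integers(2, 9))
    M = M or int(rng.integers(1, 11))
    return at.encode_tensor(random_alignment(rng, K, M))


class TestDecomposition:
    def test_rank_one_tensor(self):
        # u (x) B with unit u and unit-norm 6 x M pattern B
        rng = np.random.default_rng(0)
        u = np.zeros(5)
        u[2] = 1.0
        B = rng.normal(size=(6, 4))
        B /= np.linalg.norm(B)
        values = u[:, None, None] * B[None, :, :]
        t = at.NucleotideTensor.__new__(at.NucleotideTensor)  # bypass one-hot
        t.values, t.organism_ids = values, [f"o{i}" for i in range(5)]
        t.position_labels, t.slice_order = [1, 2, 3, 4], at.SYMBOLS
        res = mode1_hosvd(t)
        assert res.singular_values[0] == pytest.approx(1.0)
        assert res.singular_values[1:] == pytest.approx(0.0, abs=1e-12)
        assert abs(np.dot(res.eigenpositions[:, 0], u)) == pytest.approx(1.0)
        assert abs(np.sum(res.eigenorganisms[0] * B)) == pytest.approx(1.0)
        # segment of the rank-1 component is proportional to a row of B
        seg = res.segment(1, "A").to_numpy()
        assert np.allclose(np.abs(seg), np.abs(B[0]), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_singular_values_match_dense_svd_of_unfolding(self, seed):
        t = random_tensor(seed)
        res = mode1_hosvd(t)
        ref = np.linalg.svd(oracle_unfolding(t.values.astype(float)),
                            compute_uv=False)
        R = res.n_components
        np.testing.assert_allclose(res.singular_values, ref[:R], atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_reconstruction(self, seed):
        t = random_tensor(seed)
        np.testing.assert_allclose(mode1_hosvd(t).reconstruct(),
                                   t.values.astype(float), atol=1e-10)

    def test_truncation_is_best_rank_r(self):
        t = random_tensor(99, K=6, M=8)
        res = mode1_hosvd(t)
        X = mode1_unfold(t.values.astype(float))
        for r in (1, 2, 4):
            err = np.linalg.norm(X - mode1_unfold(res.reconstruct(r)))
            expected = math.sqrt(float((res.singular_values[r:] ** 2).sum()))
            assert err == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_orthonormal_factors(self, seed):
        res = mode1_hosvd(random_tensor(seed))
        R = res.n_components
        np.testing.assert_allclose(
            res.eigenpositions.T @ res.eigenpositions, np.eye(R), atol=1e-10)
        V = mode1_unfold(res.eigenorganisms)
        np.testing.assert_allclose(V @ V.T, np.eye(R), atol=1e-10)

    def test_permutation_equivariance(self):
        t = random_tensor(5, K=6, M=7)
        res = mode1_hosvd(t)
        rng = np.random.default_rng(1)
        perm = rng.permutation(6)
        t2 = at.NucleotideTensor(t.values[perm],
                                 [t.organism_ids[i] for i in perm],
                                 t.position_labels)
        res2 = mode1_hosvd(t2)
        np.testing.assert_allclose(res2.singular_values, res.singular_values,
                                   atol=1e-10)
        for r in range(res.n_components):
            # matched up to the joint sign of the component pair
            a, b = res.eigenpositions[perm, r], res2.eigenpositions[:, r]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_all_zero_tensor_rejected(self):
        t = at.NucleotideTensor.__new__(at.NucleotideTensor)
        t.values = np.zeros((3, 6, 4))
        t.organism_ids = ["a", "b", "c"]
        t.position_labels = [1, 2, 3, 4]
        t.slice_order = at.SYMBOLS
        with pytest.raises(ValueError, match="all-zero"):
            mode1_hosvd(t)


class TestFractions:
    def test_single_nonzero_value(self):
        assert at.significance_fractions([2, 0, 0]).tolist() == [1, 0, 0]

    @pytest.mark.parametrize("convention", ["squared", "linear"])
    def test_equal_values_give_uniform_fractions(self, convention):
        f = at.significance_fractions([3.0] * 7, convention)
        np.testing.assert_allclose(f, np.full(7, 1 / 7))

    def test_linear_vs_squared(self):
        f_sq = at.significance_fractions([2.0, 1.0], "squared")
        f_lin = at.significance_fractions([2.0, 1.0], "linear")
        np.testing.assert_allclose(f_sq, [0.8, 0.2])
        np.testing.assert_allclose(f_lin, [2 / 3, 1 / 3])

    def test_fractions_sum_to_one(self, fitted):
        _, res = fitted
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(res.singular_values) <= 1e-12).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            at.significance_fractions([0.0, 0.0])


class TestOrientation:
    def test_flip_is_involution_and_preserves_reconstruction(self, fitted):
        _, res = fitted
        twice = res.flip(2).flip(2)
        np.testing.assert_array_equal(twice.eigenpositions,
                                      res.eigenpositions)
        np.testing.assert_allclose(res.flip(3).reconstruct(5),
                                   res.reconstruct(5), atol=1e-12)

    def test_orient_toward_group_puts_group_on_top(self, fitted,
                                                   default_dataset):
        _, res = fitted
        groupA = default_dataset.truth.groups["CladeA"]
        oriented = res.orient(2, rule="group", group=groupA)
        top, _ = oriented.extreme_organisms(2, 12)
        assert set(top) <= set(groupA)

    def test_default_rule_max_abs_positive(self, fitted):
        _, res = fitted
        for r in (1, 2, 3):
            u = res.eigenposition(r)
            assert u[int(np.argmax(np.abs(u)))] > 0


class TestSegmentsAndDiagnostics:
    def test_segment_norms_sum_to_one(self, fitted):
        _, res = fitted
        for r in (1, 2, 5):
            total = sum(np.sum(res.segment(r, s).to_numpy() ** 2)
                        for s in at.SYMBOLS)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_identical_organisms_make_component1_exact_average(self):
        rng = np.random.default_rng(4)
        row = rng.choice(list("ACGU-"), size=20)
        chars = np.tile(row, (5, 1))
        aln = at.SequenceAlignment([f"o{i}" for i in range(5)], chars)
        res = mode1_hosvd(at.encode_tensor(aln))
        diag = res.mean_frequency_correlation(1, at.encode_tensor(aln))
        assert diag.eigenposition_cv == pytest.approx(0.0, abs=1e-12)
        for sym, c in diag.correlations.items():
            freq = (chars == sym).mean(axis=0)
            if freq.std() > 0:
                assert c == pytest.approx(1.0, abs=1e-10)
            else:
                assert math.isnan(c)

    def test_correlation_matches_independent_pearson(self):
        t = random_tensor(11, K=8, M=9)
        res = mode1_hosvd(t)
        diag = res.mean_frequency_correlation(2, t)
        for s, sym in enumerate(at.SYMBOLS):
            x = res.eigenorganisms[1, s, :]
            y = t.values[:, s, :].mean(axis=0).astype(float)
            if x.std() == 0 or y.std() == 0:
                assert math.isnan(diag.correlations[sym])
                continue
            xc, yc = x - x.mean(), y - y.mean()
            expected = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
            assert diag.correlations[sym] == pytest.approx(expected, abs=1e-12)

    def test_component1_mean_like_later_components_not(self, fitted):
        _, res = fitted
        assert res.mean_frequency_correlation(1).is_mean_like
        for r in (2, 3, 4):
            assert not res.mean_frequency_correlation(r).is_mean_like


class TestRobustnessAndSerialization:
    def test_components_stable_under_organism_subsampling(self,
                                                          default_dataset):
        """Dropping a random 10% of organisms leaves components 2-3
        essentially unchanged on the shared organisms."""
        ds = default_dataset
        model = at.AlignmentTensorModel(ds.alignment, ds.taxonomy, ds.pairing)
        res = model.fit()
        rng = np.random.default_rng(42)
        keep = np.sort(rng.choice(60, size=54, replace=False))
        sub = at.SequenceAlignment(
            [ds.alignment.organism_ids[i] for i in keep],
            ds.alignment.characters[keep])
        res_sub = at.AlignmentTensorModel(sub).fit()
        for r in (2, 3):
            full = res.eigenpositions[keep, r - 1]
            best = max(abs(np.corrcoef(full,
                                       res_sub.eigenpositions[:, q])[0, 1])
                       for q in (1, 2, 3))
            assert best > 0.9

    def test_save_load_round_trip(self, fitted, tmp_path):
        _, res = fitted
        res.save(tmp_path / "bundle")
        back = at.AlignmentTensorResults.load(tmp_path / "bundle")
        np.testing.assert_array_equal(back.eigenpositions, res.eigenpositions)
        np.testing.assert_array_equal(back.eigenorganisms, res.eigenorganisms)
        assert back.organism_ids == res.organism_ids
        assert back.position_labels == res.position_labels

    def test_summary_mentions_shape_and_fractions(self, fitted):
        _, res = fitted
        text = res.summary(5)
        assert "Organisms (K):     60" in text
        assert "squared" in text
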