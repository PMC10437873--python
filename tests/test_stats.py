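"""Spearman clustering, PCA, and Kruskal-Wallis against hand-worked oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermenz import AbundanceMatrix
from thermenz.abundance import viz_transform
from thermenz.stats import (
    CorrelationResult,
    UndefinedCorrelationError,
    cluster,
    kruskal_wallis,
    pca,
    spearman_matrix,
)


def matrix_from(arr, samples=None, families=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    families = families or [f"GH{i + 1}" for i in range(arr.shape[0])]
    return AbundanceMatrix("CAZY", pd.DataFrame(arr, index=families, columns=samples))


class TestSpearman:
    def test_self_correlation_is_one(self):
        m = matrix_from([[1, 1], [2, 2], [5, 5]])
        res = spearman_matrix(m)
        assert res.rho == pytest.approx(np.ones((2, 2)))

    def test_hand_worked_rho(self):
        """x=[1,2,3], y=[3,1,2]: 1 - 6*6/(3*8) = -0.5."""
        m = matrix_from(np.array([[1, 3], [2, 1], [3, 2]]))
        res = spearman_matrix(m)
        assert res.rho[0, 1] == pytest.approx(-0.5)

    def test_rank_invariance_under_display_transform(self, rng):
        raw = matrix_from(rng.uniform(0, 50, (6, 4)))
        trans = AbundanceMatrix("CAZY", viz_transform(raw))
        r1 = spearman_matrix(raw).rho
        r2 = spearman_matrix(trans).rho
        assert np.allclose(r1, r2)

    def test_constant_vector_flagged_undefined(self):
        m = matrix_from([[1, 2, 3], [1, 5, 4], [1, 9, 8]])  # S0 constant
        res = spearman_matrix(m)
        assert np.isnan(res.rho[0, 1]) and np.isnan(res.rho[0, 2])
        assert res.rho[0, 0] == 1.0
        assert not np.isnan(res.rho[1, 2])

    def test_families_axis(self):
        m = matrix_from([[1, 2, 3], [3, 2, 1]])
        res = spearman_matrix(m, axis="families")
        assert res.labels == ["GH1", "GH2"]
        assert res.rho[0, 1] == pytest.approx(-1.0)


class TestCluster:
    def test_identical_samples_merge_at_zero(self):
        m = matrix_from([[1, 1, 5], [2, 2, 1], [3, 3, 9]])
        res = cluster(spearman_matrix(m))
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_four_point_complete_linkage_hand_worked(self):
        """Manual agglomeration: d(A,B)=0.1 merges first, d(C,D)=0.2 second,
        then complete linkage joins the two pairs at max cross-distance 1.0."""
        labels = ["A", "B", "C", "D"]
        rho = np.array([
            [1.0, 0.9, 0.3, 0.2],
            [0.9, 1.0, 0.1, 0.0],
            [0.3, 0.1, 1.0, 0.8],
            [0.2, 0.0, 0.8, 1.0],
        ])
        res = cluster(CorrelationResult(labels, rho), linkage="complete")
        assert res.linkage[:, 2] == pytest.approx([0.1, 0.2, 1.0])
        # first merge is {A,B} (ids 0,1), second {C,D} (ids 2,3)
        assert set(res.linkage[0, :2]) == {0, 1}
        assert set(res.linkage[1, :2]) == {2, 3}

    def test_permutation_of_input_gives_same_tree(self, rng):
        data = rng.uniform(0, 10, (8, 5))
        m = matrix_from(data)
        res1 = cluster(spearman_matrix(m))
        perm = [3, 0, 4, 1, 2]
        m2 = AbundanceMatrix("CAZY", m.data.iloc[:, perm])
        res2 = cluster(spearman_matrix(m2))
        assert res1.leaf_order == res2.leaf_order
        assert np.allclose(res1.linkage, res2.linkage)

    def test_undefined_correlations_are_rejected_with_advice(self):
        m = matrix_from([[1, 2, 3], [1, 5, 4]])  # constant first sample
        with pytest.raises(UndefinedCorrelationError, match="prevalence"):
            cluster(spearman_matrix(m))

    def test_newick_has_all_leaves(self):
        m = matrix_from(np.arange(12).reshape(4, 3) ** 2 % 7)
        res = cluster(spearman_matrix(m))
        nwk = res.to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in res.labels)


class TestPca:
    def test_two_points_pc1_explains_everything(self):
        df = pd.DataFrame([[-1.0, 1.0], [0.0, 0.0]],
                          index=["f1", "f2"], columns=["S0", "S1"])
        res = pca(df, transform=None)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Independent oracle: eigendecomposition of the covariance of the
        centered, transformed sample vectors, on a 5-sample fixture."""
        data = rng.uniform(0, 30, (3, 5))
        m = matrix_from(data)
        res = pca(m)  # log10(x+0.5), centered
        X = np.log10(data.T + 0.5)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = res.loadings.shape[1]
        for i in range(k):
            v = evecs[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.loadings.iloc[:, i], v, atol=1e-10)
            assert np.allclose(res.scores.iloc[:, i], Xc @ v, atol=1e-10)
        assert np.allclose(res.explained_variance_fraction,
                           (evals / evals.sum())[:k], atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        data = rng.uniform(0, 5, (4, 6))
        m = matrix_from(data)
        res = pca(m, transform=None)
        X = data.T
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-10)

    def test_explained_fractions_monotone_and_bounded(self, rng):
        res = pca(matrix_from(rng.uniform(0, 9, (5, 7))))
        ev = res.explained_variance_fraction
        assert np.all(ev >= -1e-12) and np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-9

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            pca(matrix_from([[1.0], [2.0]]))


class TestKruskalWallis:
    def test_hand_worked_h(self):
        """A=[1,2], B=[3,4]: H = 12/20 * (9/2 + 49/2) - 15 = 2.4."""
        res = kruskal_wallis([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_degenerate_all_equal(self):
        res = kruskal_wallis([5, 5, 5, 5], ["A", "A", "B", "B"])
        assert res.H == 0.0 and res.pvalue == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([1, 2, 3], ["A", "A", "A"])

    def test_matches_exhaustive_permutation_statistic(self):
        """On tie-free data the H statistic is a deterministic function of
        the rank assignment; check it against direct computation from ranks
        for every permutation of a small arrangement."""
        values = [10.0, 3.0, 7.0, 1.0, 8.0, 5.0]
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        n = len(values)
        ranks = pd.Series(values).rank().to_numpy()
        for perm in itertools.permutations(range(n)):
            v = [values[i] for i in perm]
            r = ranks[list(perm)]
            expected = 12 / (n * (n + 1)) * sum(
                r[groups == g].sum() ** 2 / (groups == g).sum()
                for g in ("A", "B", "C")
            ) - 3 * (n + 1)
            assert kruskal_wallis(v, groups).H == pytest.approx(expected)
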