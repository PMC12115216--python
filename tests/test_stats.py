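"""Mann-Whitney, letter codes, PCA and confidence ellipses."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from seedmorph.stats import (
    compare_groups,
    letter_codes,
    mann_whitney,
    mean_confidence_ellipse,
    pca_fourier,
)


def brute_force_mw(a, b):
    """Oracle: exact two-sided Mann-Whitney p by enumerating all rank splits."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n, m = len(a), len(b)

    # U = number of pairs (x in a, y in b) with x > y; no ties assumed
    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(n + m), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    # two-sided p over the symmetric null distribution of U
    mu = n * m / 2.0
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, float(p)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)=2/20 by enumeration

    def test_identical_multisets(self):
        u, p = mann_whitney([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_all_identical_warns_p_one(self):
        u, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(1.0, size=7)
        ua, pa = mann_whitney(a, b)
        ub, pb = mann_whitney(b, a)
        assert pa == pytest.approx(pb, rel=1e-12)
        assert ua + ub == pytest.approx(len(a) * len(b))

    @pytest.mark.parametrize("na,nb", [(n, m) for n in range(1, 8) for m in range(n, 8)])
    def test_matches_exhaustive_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = list(rng.permutation(np.arange(1.0, na + nb + 1))[:na])
        b = [v for v in np.arange(1.0, na + nb + 1) if v not in a]
        u_oracle, p_oracle = brute_force_mw(a, b)
        u, p = mann_whitney(a, b)
        # scipy reports U for the first sample (pairs where a > b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestLetterCodes:
    def test_no_difference_shares_letter(self):
        out = letter_codes(np.array([[1.0, 0.3], [0.3, 1.0]]), ["g1", "g2"])
        assert out["g1"] == out["g2"] == "a"

    def test_difference_distinct_letters(self):
        out = letter_codes(np.array([[1.0, 0.01], [0.01, 1.0]]), ["g1", "g2"])
        assert set(out["g1"]) & set(out["g2"]) == set()

    def test_three_groups_one_significant_pair(self):
        p = np.ones((3, 3))
        p[0, 2] = p[2, 0] = 0.001  # only groups 1 and 3 differ
        out = letter_codes(p, ["g1", "g2", "g3"])
        assert set(out["g1"]) & set(out["g3"]) == set()
        assert set(out["g1"]) & set(out["g2"])
        assert set(out["g2"]) & set(out["g3"])


class TestPCA:
    def _coeff_frame(self, X):
        cols = [f"{c}{k}" for c in "ABCD" for k in range(1, 9)]
        return pd.DataFrame(X, columns=cols)

    def test_collinear_data_pc1_is_everything(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        direction = rng.normal(size=32)
        X = np.outer(t, direction) + 5.0
        res = pca_fourier(self._coeff_frame(X))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_flat_spectrum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 32))
        res = pca_fourier(self._coeff_frame(X))
        assert np.all(np.abs(res.variance_fractions - 1.0 / 32.0) < 0.02)

    def test_variance_fractions_sorted_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 32)) * np.linspace(3, 0.1, 32)
        res = pca_fourier(self._coeff_frame(X))
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() == pytest.approx(1.0, abs=1e-6)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 32))
        df = self._coeff_frame(X)
        res = pca_fourier(df)
        recon = res.scores[res.loadings.columns].to_numpy() @ res.loadings.to_numpy().T + res.column_means.to_numpy()
        assert np.abs(recon - X).max() < 1e-8

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 32))
        X[:, 0] = 7.0
        with pytest.warns(UserWarning, match="A1"):
            res = pca_fourier(self._coeff_frame(X))
        assert res.dropped_columns == ["A1"]

    def test_group_centroids_and_ellipses(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (20, 32)), rng.normal(3, 1, (20, 32))])
        labels = ["a"] * 20 + ["b"] * 20
        res = pca_fourier(self._coeff_frame(X), group_labels=labels)
        assert set(res.centroids) == {"a", "b"}
        assert set(res.ellipses) == {"a", "b"}


class TestEllipseCoverage:
    def test_mean_ellipse_covers_true_mean_95_percent(self):
        """Across 500 simulated Gaussian groups the 95% mean-ellipse contains
        the true mean 95% +/- 3% of the time."""
        rng = np.random.default_rng(11)
        mean = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.7], [0.7, 1.2]])
        hits = sum(
            mean_confidence_ellipse(rng.multivariate_normal(mean, cov, size=50)).contains(mean)
            for _ in range(500)
        )
        assert 0.92 <= hits / 500 <= 0.98


class TestCompareGroups:
    def test_identical_groups_share_letters(self):
        vals = list(np.linspace(0, 1, 12))
        groups = {"a": {"S": vals}, "b": {"S": vals}}
        res = compare_groups(groups)
        assert res["S"].letters["a"] == res["S"].letters["b"]

    def test_clear_separation_significant(self):
        groups = {"a": {"S": list(range(10))}, "b": {"S": list(range(100, 110))}}
        res = compare_groups(groups)
        assert res["S"].p_values[("a", "b")] < 0.01
        assert res["S"].letters["a"] != res["S"].letters["b"]

    def test_small_group_excluded(self):
        groups = {"a": {"S": [1.0]}, "b": {"S": [1.0, 2.0, 3.0]}, "c": {"S": [4.0, 5.0, 6.0]}}
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_groups(groups)
        assert res["S"].groups == ["b", "c"]

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"only": {"S": [1.0, 2.0]}})
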