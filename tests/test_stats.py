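"""Ordination, distances, Mantel and diversity statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as skbio_mantel

from trflpsim.stats import (
    bray_curtis_matrix,
    covariance_pca,
    euclidean_pc_distances,
    linear_regression,
    mantel_test,
    margalef_index,
    simpson_index,
)


def random_abundance(rng, n, k):
    x = rng.random((n, k))
    return pd.DataFrame(x / x.sum(axis=1, keepdims=True),
                        index=[f"s{i}" for i in range(n)])


# --------------------------------------------------------------------- PCA
def test_pca_constant_matrix_reports_zero_variance():
    mat = pd.DataFrame(np.ones((4, 3)))
    res = covariance_pca(mat)
    assert np.allclose(res.scores, 0)
    assert np.allclose(res.explained, 0)


def test_pca_single_varying_column_loads_pc1_fully():
    mat = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4], "b": [0.5] * 4})
    res = covariance_pca(mat)
    assert res.explained[0] == pytest.approx(1.0)


def test_pca_isometry_all_components():
    """Euclidean distances over all PCs equal centred-row distances."""
    rng = np.random.default_rng(3)
    mat = random_abundance(rng, 6, 4)
    res = covariance_pca(mat)
    d_pca = euclidean_pc_distances(res.scores, n_components=None)
    centred = mat - mat.mean(axis=0)
    d_direct = squareform(pdist(centred.to_numpy()))
    assert np.allclose(d_pca.to_numpy(), d_direct, atol=1e-12)


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(4)
    mat = random_abundance(rng, 8, 5)
    a = covariance_pca(mat)
    b = covariance_pca(mat.copy())
    pd.testing.assert_frame_equal(a.scores, b.scores)
    # largest-magnitude loading of each component is positive
    for _, row in a.loadings.iterrows():
        assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0


def test_pc_distance_examples():
    scores = pd.DataFrame({"PC1": [0.0, 3.0], "PC2": [0.0, 4.0]}, index=["a", "b"])
    d = euclidean_pc_distances(scores, 2)
    assert d.loc["a", "b"] == pytest.approx(5.0)
    assert d.loc["a", "a"] == 0.0
    with pytest.raises(ValueError):
        euclidean_pc_distances(scores, 3)


# ------------------------------------------------------------- Bray-Curtis
def test_bray_curtis_closed_forms():
    mat = pd.DataFrame(
        [[0.7, 0.3, 0.0, 0.0], [0.3, 0.7, 0.0, 0.0],
         [0.0, 0.0, 0.5, 0.5], [0.7, 0.3, 0.0, 0.0]],
        index=list("abcd"),
    )
    d = bray_curtis_matrix(mat)
    assert d.loc["a", "b"] == pytest.approx(0.4)  # 1 - 2*(0.3+0.3)/2
    assert d.loc["a", "c"] == pytest.approx(1.0)  # disjoint supports
    assert d.loc["a", "d"] == pytest.approx(0.0)  # identical rows
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def test_bray_curtis_matches_hand_formula_on_random_data():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.random((5, 7)))
    d = bray_curtis_matrix(mat).to_numpy()
    X = mat.to_numpy()
    for i, j in itertools.combinations(range(5), 2):
        bc = 1 - 2 * np.minimum(X[i], X[j]).sum() / (X[i].sum() + X[j].sum())
        assert d[i, j] == pytest.approx(bc)


def test_bray_curtis_zero_rows_warn_and_define_zero():
    mat = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    with pytest.warns(RuntimeWarning):
        d = bray_curtis_matrix(mat)
    assert d.iloc[0, 1] == 0.0


# ------------------------------------------------------------------ Mantel
def example_distance(labels, rng):
    pts = rng.random((len(labels), 3))
    return pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)


def test_mantel_self_and_scale_invariance():
    rng = np.random.default_rng(6)
    d = example_distance(list("abcde"), rng)
    assert mantel_test(d, d, n_perm=99, seed=0).r == pytest.approx(1.0)
    assert mantel_test(d, 2 * d, n_perm=99, seed=0).r == pytest.approx(1.0)


def test_mantel_symmetry_and_p_bound():
    rng = np.random.default_rng(7)
    d1 = example_distance(list("abcdef"), rng)
    d2 = example_distance(list("abcdef"), rng)
    r12 = mantel_test(d1, d2, n_perm=199, seed=1)
    r21 = mantel_test(d2, d1, n_perm=199, seed=1)
    assert r12.r == pytest.approx(r21.r)
    assert r12.p >= 1 / 200


def exhaustive_mantel_p(d1: np.ndarray, d2: np.ndarray) -> float:
    """Exact permutation p over all n! joint relabellings of d2."""
    n = d1.shape[0]
    iu = np.tril_indices(n, k=-1)
    x = d1[iu]
    xz = (x - x.mean()) / x.std()
    def corr(mat):
        y = mat[iu]
        return np.mean(xz * (y - y.mean()) / y.std())
    r_obs = corr(d2)
    perms = list(itertools.permutations(range(n)))
    count = sum(
        corr(d2[np.ix_(p, p)]) >= r_obs - 1e-12 for p in perms
    )
    return count / len(perms)


def test_mantel_p_within_monte_carlo_error_of_exhaustive():
    rng = np.random.default_rng(8)
    labels = list("abcd")
    d1 = example_distance(labels, rng)
    d2 = example_distance(labels, rng)
    exact = exhaustive_mantel_p(d1.to_numpy(), d2.to_numpy())
    res = mantel_test(d1, d2, n_perm=10000, seed=2)
    mc_sd = math.sqrt(exact * (1 - exact) / 10000)
    assert abs(res.p - exact) < max(4 * mc_sd, 0.01)


def test_mantel_agrees_with_skbio():
    rng = np.random.default_rng(9)
    labels = [f"s{i}" for i in range(7)]
    d1 = example_distance(labels, rng)
    d2 = example_distance(labels, rng)
    ours = mantel_test(d1, d2, n_perm=999, seed=3)
    r_ref, p_ref, _ = skbio_mantel(
        SkbioDM(d1.to_numpy(), ids=labels),
        SkbioDM(d2.to_numpy(), ids=labels),
        permutations=999,
        alternative="greater",
    )
    assert ours.r == pytest.approx(r_ref, abs=1e-12)
    assert ours.p == pytest.approx(p_ref, abs=0.05)


def test_mantel_errors():
    d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError, match="zero-variance"):
        mantel_test(d, d, n_perm=10)
    rng = np.random.default_rng(10)
    d1 = example_distance(list("abc"), rng)
    d2 = example_distance(list("abd"), rng)
    with pytest.raises(ValueError, match="labels"):
        mantel_test(d1, d2)


# --------------------------------------------------------------- diversity
def test_margalef_closed_forms():
    assert margalef_index([5.0], total=1000) == 0.0
    assert margalef_index([1, 1, 1, 1, 1], total=1000) == pytest.approx(
        4 / math.log(1000)
    )
    assert margalef_index([1, 1, 1], total=math.e**2) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        margalef_index([1.0], total=1)


def test_simpson_closed_forms():
    assert simpson_index([1.0]) == 0.0
    assert simpson_index([0.25] * 4) == pytest.approx(0.75)
    assert simpson_index([0.5, 0.3, 0.2]) == pytest.approx(0.62)
    assert simpson_index([0.25] * 4, variant="inverse") == pytest.approx(4.0)
    with pytest.raises(ValueError):
        simpson_index([0.5, -0.5, 1.0])


def test_gini_simpson_of_equal_taxa_identity():
    for n in range(2, 8):
        assert simpson_index([1 / n] * n) == pytest.approx(1 - 1 / n)


# -------------------------------------------------------------- regression
def test_regression_exact_line():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = linear_regression(x, 2 * x)
    assert res.slope == pytest.approx(2.0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.df == (1, 2)


def test_regression_matches_normal_equations():
    x = np.array([0.5, 1.1, 1.9, 3.2, 4.1, 5.0])
    y = np.array([1.2, 1.9, 3.1, 4.0, 5.4, 5.9])
    res = linear_regression(x, y)
    A = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert res.intercept == pytest.approx(beta[0])
    assert res.slope == pytest.approx(beta[1])
    resid = y - A @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert res.r_squared == pytest.approx(1 - ss_res / ss_tot)
    assert res.f_statistic == pytest.approx(
        res.r_squared * (len(x) - 2) / (1 - res.r_squared)
    )


def test_regression_null_behaviour():
    rng = np.random.default_rng(11)
    x = rng.random(400)
    y = rng.random(400)
    res = linear_regression(x, y)
    assert res.r_squared < 0.05
    with pytest.raises(ValueError, match="zero variance"):
        linear_regression(np.ones(5), np.arange(5.0))
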