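"""Ordination, distance, permutation and diversity statistics.

Covariance PCA (mean-centred, unscaled), Euclidean distances between PC
scores, Bray-Curtis dissimilarities, the Mantel permutation test, Margalef
and Gini-Simpson diversity, and ordinary least-squares regression of
observed on predicted indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PCAResult",
    "covariance_pca",
    "euclidean_pc_distances",
    "bray_curtis_matrix",
    "MantelResult",
    "mantel_test",
    "margalef_index",
    "simpson_index",
    "RegressionResult",
    "linear_regression",
]


@dataclass
class PCAResult:
    """Scores (samples × components), loadings (components × variables) and
    the fraction of total variance each component explains."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray

    def variance_explained(self, n_components: int = 2) -> float:
        """Summed variance fraction of the first `n_components` components."""
        return float(self.explained[:n_components].sum())


def covariance_pca(matrix: pd.DataFrame) -> PCAResult:
    """Principal component analysis on the covariance matrix.

    Columns are mean-centred but not scaled, so abundant TRFs dominate — the
    standard choice for relative-abundance community data. Components are
    ordered by decreasing eigenvalue with a deterministic sign convention:
    the largest-magnitude loading of each component is made positive. A
    constant matrix yields zero scores and zero explained variance.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt, index=comp_names, columns=matrix.columns),
        explained=explained,
    )


def euclidean_pc_distances(
    scores: pd.DataFrame, n_components: int | None = 2
) -> pd.DataFrame:
    """Pairwise Euclidean distances on the first `n_components` PC scores
    (all components when None). Over all components the distances equal
    those between the mean-centred rows of the original matrix."""
    if n_components is not None:
        if n_components > scores.shape[1]:
            raise ValueError(
                f"requested {n_components} components; only {scores.shape[1]} available"
            )
        scores = scores.iloc[:, :n_components]
    d = squareform(pdist(scores.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between abundance rows.

    BC(a, b) = 1 − 2·Σ min(a, b) / (Σa + Σb), in [0, 1]. A pair of all-zero
    rows is defined as distance 0, with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn(
            "all-zero abundance rows: Bray-Curtis undefined, set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class MantelResult:
    """Mantel correlation between two distance matrices and its one-sided
    permutation p-value (None when run with zero permutations)."""

    r: float
    p: float | None
    n_perm: int


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(d, k=-1)
    return d[i, j]


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test of association between distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the p-value
    counts joint row/column permutations of `d2` whose correlation reaches
    the observed one: p = (#{r_perm >= r_obs} + 1) / (n_perm + 1), so p is
    bounded below by 1/(n_perm+1). With ``n_perm=0`` only r is computed.
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices must share labels and order")
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and congruent")
    x = _lower_triangle(a)
    y = _lower_triangle(b)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance triangle: Mantel r undefined")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xz * yz))
    if n_perm <= 0:
        return MantelResult(r=r_obs, p=None, n_perm=0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _lower_triangle(b[np.ix_(perm, perm)])
        r_perm = np.mean((yp - yp.mean()) / yp.std() * xz)
        if r_perm >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm)


def margalef_index(abundances, total: float | None = None) -> float:
    """Margalef richness index (S − 1) / ln N.

    S is the number of taxa with positive abundance; N the total count of
    individuals (for fluorescence data, pass total peak area rounded to the
    nearest integer). Zero for a single taxon; undefined (error) for N ≤ 1.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    s = int((a > 0).sum())
    if s < 1:
        raise ValueError("at least one taxon must be present")
    n = float(a.sum() if total is None else total)
    if n <= 1:
        raise ValueError("Margalef's index requires N > 1")
    return (s - 1) / np.log(n)


def simpson_index(proportions, variant: str = "gini") -> float:
    """Simpson's diversity from relative abundances.

    ``gini`` (default): 1 − Σ p², the probability two random individuals
    differ — 0 for a monoculture, larger for more even communities.
    ``inverse``: 1 / Σ p².
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("proportions must sum to a positive value")
    if abs(total - 1.0) > 1e-6:
        p = p / total
    d = float(np.sum(p**2))
    if variant == "gini":
        return 1.0 - d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


@dataclass
class RegressionResult:
    """OLS fit of observed on predicted indices, with the F test on
    (1, n−2) degrees of freedom."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R², F(1, n−2) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs matched x/y with n >= 3")
    if np.std(x) == 0:
        raise ValueError("zero variance in predictor")
    fit = sps.linregress(x, y)
    n = x.size
    r2 = fit.rvalue**2
    df = (1, n - 2)
    if 1.0 - r2 < 1e-15:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = r2 * df[1] / (1.0 - r2)
        p = float(sps.f.sf(f_stat, *df))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        df=df,
        p=p,
        n=n,
    )
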