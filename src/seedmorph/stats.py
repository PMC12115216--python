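"""Population statistics: Mann-Whitney comparisons with compact letter
display, and PCA over the 32 Fourier coefficients with group centroids and
95% confidence ellipses for the group means.

Tests are two-sided at alpha = 0.05 with no multiple-testing correction.
PCA is on centered, unscaled coefficients (they share a unit after shape
normalization); correlation-mode PCA is available via ``scale=True``.
The confidence ellipse is for the location of the group MEAN (chi-square
quantile on the covariance of the mean), not a data ellipse, so it may
contain few or no observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["ComparisonResult", "PCAResult", "mann_whitney", "letter_codes", "pca_fourier",
           "compare_groups", "mean_confidence_ellipse", "ALPHA"]

ALPHA = 0.05

FOURIER_COLUMNS = tuple(f"{c}{k}" for c in "ABCD" for k in range(1, 9))


@dataclass
class ComparisonResult:
    metric: str
    groups: list[str]
    means: dict[str, float]
    cvs: dict[str, float]
    u_stats: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    letters: dict[str, str]


@dataclass
class Ellipse:
    center: np.ndarray  # (2,)
    cov: np.ndarray     # (2, 2) covariance of the mean
    level: float = 0.95

    def contains(self, point: np.ndarray) -> bool:
        d = np.asarray(point) - self.center
        q = float(d @ np.linalg.solve(self.cov, d))
        return q <= sps.chi2.ppf(self.level, df=2)

    def boundary(self, n: int = 200) -> np.ndarray:
        r = np.sqrt(sps.chi2.ppf(self.level, df=2))
        t = np.linspace(0, 2 * np.pi, n)
        L = np.linalg.cholesky(self.cov)
        return self.center + (r * L @ np.stack([np.cos(t), np.sin(t)])).T


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # coefficients x components
    scores: pd.DataFrame            # observations x components (+ group column)
    variance_fractions: np.ndarray
    centroids: dict[str, np.ndarray]
    ellipses: dict[str, Ellipse]
    column_means: pd.Series = field(default=None)
    dropped_columns: list[str] = field(default_factory=list)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U for sample_a), tie-corrected.

    Exact null distribution when min(n) <= 8 and there are no ties,
    normal approximation otherwise. Identical pooled values give p = 1
    with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical across both samples; p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def letter_codes(pairwise_p: np.ndarray, labels: list[str], alpha: float = ALPHA) -> dict[str, str]:
    """Greedy compact letter display from a symmetric p-value matrix.

    Groups that are not significantly different (p >= alpha) share at least
    one letter; significantly different groups share none.
    """
    p = np.asarray(pairwise_p, dtype=float)
    n = len(labels)
    if p.shape != (n, n):
        raise ValueError("pairwise_p must be square and match labels")
    # insert-absorb: maintain letter classes (sets of mutually non-different groups)
    classes: list[set[int]] = []
    for i in range(n):
        placed = False
        for cls in classes:
            if all(p[i, j] >= alpha for j in cls):
                cls.add(i)
                placed = True
        if not placed:
            new = {i}
            # pull in every earlier group compatible with the whole new class
            for j in range(n):
                if j != i and all(p[j, k] >= alpha for k in new):
                    new.add(j)
            classes.append(new)
    # absorb duplicate/subset classes
    classes = [c for k, c in enumerate(classes) if not any(c < d or (c == d and k2 < k) for k2, d in enumerate(classes) if k2 != k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, cls in zip(alphabet, classes):
        for i in sorted(cls):
            out[labels[i]] += letter
    return out


def mean_confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse for the mean of 2-D points (normal approximation)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 two-dimensional points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False) / len(pts)
    return Ellipse(center=center, cov=cov, level=level)


def pca_fourier(coeff_table: pd.DataFrame, group_labels=None, n_components: int | None = None, *, scale: bool = False) -> PCAResult:
    """Covariance PCA over the 32 Fourier coefficient columns.

    Expects columns A1..A8, B1..B8, C1..C8, D1..D8 (extra columns ignored).
    Constant columns are dropped with a warning. Per-group centroids and 95%
    mean-confidence ellipses are computed in the (PC1, PC2) plane.
    """
    cols = [c for c in FOURIER_COLUMNS if c in coeff_table.columns]
    if not cols:
        cols = list(coeff_table.columns)
    X = coeff_table[cols].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 observations")
    const = [c for c, v in zip(cols, X.std(axis=0)) if v == 0.0]
    if const:
        warnings.warn(f"dropping constant column(s): {const}", stacklevel=2)
        cols = [c for c in cols if c not in const]
        X = coeff_table[cols].to_numpy(dtype=float)
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n_comp = min(n_components or min(X.shape), min(len(X) - 1, X.shape[1]))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=coeff_table.index, columns=comp_names)
    centroids: dict[str, np.ndarray] = {}
    ellipses: dict[str, Ellipse] = {}
    if group_labels is not None:
        groups = pd.Series(np.asarray(group_labels), index=coeff_table.index, name="group")
        scores_df["group"] = groups
        for g, sub in scores_df.groupby("group", sort=True):
            xy = sub[["PC1", "PC2"]].to_numpy()
            centroids[str(g)] = xy.mean(axis=0)
            if len(xy) >= 3:
                ellipses[str(g)] = mean_confidence_ellipse(xy)
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=comp_names),
        scores=scores_df,
        variance_fractions=pca.explained_variance_ratio_,
        centroids=centroids,
        ellipses=ellipses,
        column_means=pd.Series(pca.mean_, index=cols),
        dropped_columns=const,
    )


def compare_groups(measurements_by_group: dict[str, dict[str, "np.ndarray | list[float]"]],
                   metrics: list[str] | None = None, alpha: float = ALPHA) -> dict[str, ComparisonResult]:
    """Per-metric group means, CVs, pairwise Mann-Whitney tests and letters.

    ``measurements_by_group`` maps group -> {metric -> values}. Groups with
    fewer than 2 values on a metric are excluded from that metric with a
    warning.
    """
    if len(measurements_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if metrics is None:
        metrics = sorted({m for d in measurements_by_group.values() for m in d})
    out: dict[str, ComparisonResult] = {}
    for metric in metrics:
        data = {}
        for g, d in measurements_by_group.items():
            vals = np.asarray(d.get(metric, []), dtype=float)
            if len(vals) < 2:
                warnings.warn(f"group {g!r} excluded from {metric!r} (n < 2)", stacklevel=2)
                continue
            data[g] = vals
        if len(data) < 2:
            continue
        labels = sorted(data)
        u_stats, p_values = {}, {}
        pmat = np.ones((len(labels), len(labels)))
        for i, gi in enumerate(labels):
            for j, gj in enumerate(labels):
                if j <= i:
                    continue
                u, p = mann_whitney(data[gi], data[gj])
                u_stats[(gi, gj)] = u
                p_values[(gi, gj)] = p
                pmat[i, j] = pmat[j, i] = p
        out[metric] = ComparisonResult(
            metric=metric,
            groups=labels,
            means={g: float(v.mean()) for g, v in data.items()},
            cvs={g: float(100.0 * v.std(ddof=1) / v.mean()) if v.mean() != 0 else float("nan") for g, v in data.items()},
            u_stats=u_stats,
            p_values=p_values,
            letters=letter_codes(pmat, labels, alpha),
        )
    return out
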