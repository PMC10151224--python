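"""Multivariate analysis of tangent shape variables.

Principal components of the tangent shape variables are the working shape
space; canonical variate (discriminant) axes, pairwise Mahalanobis distances
with permutation tests, and the allometric regression of the first shape PC
on centroid size are all computed on retained PC scores.

PC retention keeps every component whose eigenvalue exceeds 1e-12 times the
largest, further capped at n - n_groups - 1 so the pooled within-group
covariance stays invertible.  With k = 10 landmarks the nondegenerate shape
space has 2k - 4 = 16 dimensions, all of which are retained when n allows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .superimposition import AlignedDataset

logger = logging.getLogger(__name__)

EIGENVALUE_REL_TOL = 1e-12
RIDGE_REL = 1e-8


@dataclass
class PCAResult:
    """Eigendecomposition of the shape-variable covariance.

    ``axes`` has one orthonormal loading vector (length 2k) per column;
    ``scores`` are centered; components are ordered by decreasing eigenvalue
    and each axis is oriented so its largest-magnitude loading is positive.
    """

    axes: np.ndarray              # (2k, p)
    scores: np.ndarray            # (n, p)
    eigenvalues: np.ndarray       # (p,)
    variance_fractions: np.ndarray
    mean: np.ndarray              # (2k,) mean shape variable vector

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Shape variables back from scores: mean + scores @ axes.T."""
        return self.mean + self.scores @ self.axes.T


def shape_pca(aligned: AlignedDataset) -> PCAResult:
    """PCA of tangent shape variables via SVD of the centered data matrix."""
    X = aligned.shape_variables
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    centered = X - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    axes = vt.T
    scores = u * s
    # deterministic sign: largest-|loading| entry positive on each axis
    for j in range(axes.shape[1]):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] *= -1
            scores[:, j] *= -1
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(axes, scores, eigenvalues, fractions, mean)


def retained_components(pca: PCAResult, n_groups: int) -> int:
    """Number of PCs used for discriminant/Mahalanobis work (see module docs)."""
    if pca.eigenvalues.size == 0 or pca.eigenvalues[0] <= 0:
        raise ValueError("no shape variation to analyze")
    above = int(np.sum(pca.eigenvalues > EIGENVALUE_REL_TOL * pca.eigenvalues[0]))
    cap = pca.n - n_groups - 1
    if cap < 1:
        raise ValueError("too few specimens for the number of groups")
    return min(above, cap)


def _group_codes(labels: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], np.ndarray]:
    groups = sorted(set(labels))
    code_of = {g: i for i, g in enumerate(groups)}
    return groups, np.array([code_of[g] for g in labels])


def pooled_within_covariance(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pooled within-group covariance with n - g denominator."""
    n, p = X.shape
    ss = np.zeros((p, p))
    for g in range(n_groups):
        sub = X[codes == g]
        d = sub - sub.mean(axis=0)
        ss += d.T @ d
    return ss / (n - n_groups)


def _safe_inverse(S: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(S)
    except np.linalg.LinAlgError:
        lam = RIDGE_REL * np.trace(S) / S.shape[0]
        logger.warning("singular pooled covariance; ridge-regularized with lambda=%.3e", lam)
        return np.linalg.inv(S + lam * np.eye(S.shape[0]))


@dataclass
class DFAResult:
    """Canonical variate (discriminant) analysis on retained PC scores."""

    axes: np.ndarray               # (p_retained, n_axes), normalized a' W a = 1
    scores: np.ndarray             # (n, n_axes)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    group_means: dict[tuple[str, str], np.ndarray]


def discriminant_analysis(pca: PCAResult, labels: list[tuple[str, str]]) -> DFAResult:
    """Canonical variate axes: eigenvectors of W^-1 B on retained PC scores.

    Axes are normalized so the pooled within-group covariance is the identity
    in discriminant space (a' W a = 1); for two groups the squared separation
    of the group means along DF1 therefore equals the Mahalanobis D^2.
    """
    groups, codes = _group_codes(labels)
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    p = retained_components(pca, g)
    X = pca.scores[:, :p]
    W = pooled_within_covariance(X, codes, g)
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for gi in range(g):
        sub = X[codes == gi]
        d = sub.mean(axis=0) - grand
        B += len(sub) * np.outer(d, d)
    B /= g - 1
    try:
        eigvals, eigvecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; retain fewer PCs (reduce dataset dimensionality)"
        ) from exc
    order = np.argsort(eigvals)[::-1][: g - 1]
    axes = eigvecs[:, order]
    eigvals = np.clip(eigvals[order], 0.0, None)
    scores = X @ axes
    fractions = eigvals / eigvals.sum() if eigvals.sum() > 0 else np.zeros_like(eigvals)
    means = {grp: scores[codes == gi].mean(axis=0) for gi, grp in enumerate(groups)}
    return DFAResult(axes, scores, eigvals, fractions, means)


@dataclass
class PairwiseDistanceResult:
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    distance: float
    raw_p: float
    adjusted_p: float


def _pairwise_d(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """All pairwise Mahalanobis distances under the pooled covariance."""
    S_inv = _safe_inverse(pooled_within_covariance(X, codes, n_groups))
    means = np.stack([X[codes == g].mean(axis=0) for g in range(n_groups)])
    out = np.zeros((n_groups, n_groups))
    for a, b in itertools.combinations(range(n_groups), 2):
        d = means[a] - means[b]
        out[a, b] = out[b, a] = np.sqrt(float(d @ S_inv @ d))
    return out


def mahalanobis_pairwise_test(
    pca: PCAResult,
    labels: list[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PairwiseDistanceResult]:
    """Pairwise Mahalanobis distances between group means with permutation p.

    D(a, b) uses the pooled within-group covariance over all groups on
    retained PC scores.  For each pair, specimens of the two groups are
    shuffled between them ``n_perm`` times; group means and the pooled
    covariance are recomputed per shuffle (the PC basis is group-blind and is
    not recomputed).  p = (b + 1)/(B + 1), Bonferroni-adjusted across pairs.
    """
    groups, codes = _group_codes(labels)
    g = len(groups)
    for gi, grp in enumerate(groups):
        if np.sum(codes == gi) < 3:
            raise ValueError(f"group {grp} has fewer than 3 specimens")
    p = retained_components(pca, g)
    X = pca.scores[:, :p]
    obs = _pairwise_d(X, codes, g)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(g), 2))
    results = []
    n_pairs = len(pairs)
    for a, b in pairs:
        idx = np.where((codes == a) | (codes == b))[0]
        sub_codes = codes.copy()
        exceed = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(codes[idx])
            sub_codes[idx] = shuffled
            d_perm = _pairwise_d(X, sub_codes, g)[a, b]
            if d_perm >= obs[a, b]:
                exceed += 1
        raw = (exceed + 1) / (n_perm + 1)
        results.append(
            PairwiseDistanceResult(
                groups[a], groups[b], float(obs[a, b]), raw, min(1.0, raw * n_pairs)
            )
        )
    return results


def distance_table(results: list[PairwiseDistanceResult]) -> pd.DataFrame:
    """Square table with D below the diagonal and adjusted p above."""
    groups = sorted({r.group_a for r in results} | {r.group_b for r in results})
    names = [f"{s} ({x})" for s, x in groups]
    tab = pd.DataFrame("-", index=names, columns=names, dtype=object)
    idx = {g: i for i, g in enumerate(groups)}
    for r in results:
        a, b = sorted((idx[r.group_a], idx[r.group_b]))
        tab.iat[b, a] = f"{r.distance:.2f}"
        tab.iat[a, b] = f"{r.adjusted_p:.4g}"
    return tab


@dataclass
class AllometryResult:
    species: str
    slope: float
    intercept: float
    r_squared_percent: float
    p: float
    n: int


def allometry_regression(
    aligned: AlignedDataset, pca: PCAResult, per_group: bool = False
) -> list[AllometryResult]:
    """OLS of the first shape PC on centroid size, one fit per species.

    Sexes are pooled within species (set ``per_group`` to fit each
    (species, sex) cell instead).  r^2 is reported in percent; p is the
    slope's t-test (identical to the regression F-test with one predictor).
    """
    cs = aligned.centroid_sizes
    pc1 = pca.scores[:, 0]
    labels = aligned.group_labels
    keys = sorted(set(labels)) if per_group else sorted({s for s, _ in labels})
    results = []
    for key in keys:
        if per_group:
            mask = np.array([lab == key for lab in labels])
            name = f"{key[0]} ({key[1]})"
        else:
            mask = np.array([s == key for s, _ in labels])
            name = key
        if mask.sum() < 3:
            raise ValueError(f"need >= 3 specimens to fit allometry for {name}")
        x, y = cs[mask], pc1[mask]
        if np.var(x) == 0:
            raise ValueError(f"zero centroid-size variance in {name}")
        fit = stats.linregress(x, y)
        results.append(
            AllometryResult(
                species=name,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared_percent=float(fit.rvalue**2 * 100),
                p=float(fit.pvalue),
                n=int(mask.sum()),
            )
        )
    return results
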