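"""End-to-end benchmark experiments used for validation and reporting.

Each function runs one self-contained experiment on synthetic data — the
printed-table aggregation check, similarity-invariance audit, oracle
comparisons, permutation-test calibration, the study-design classification
contrast, repeatability closed forms, and allometry recovery — and returns
plain numbers.  Problem sizes are chosen so the whole battery runs in a few
minutes on one CPU.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from . import (
    classification,
    clustering,
    repeatability,
    shape_analysis,
    size_analysis,
    synthetic_data,
)
from .landmark_io import LandmarkDataset
from .superimposition import generalized_procrustes, optimal_rotation

#: Published per-group (correct, observed) cross-validated counts of the
#: reference study: size-based and shape-based classification.
REFERENCE_SIZE_COUNTS = {
    ("H. sanguinolenta", "male"): (2, 50),
    ("H. sanguinolenta", "female"): (41, 50),
    ("H. aberrans", "male"): (11, 20),
    ("H. aberrans", "female"): (12, 20),
}
REFERENCE_SHAPE_COUNTS = {
    ("H. sanguinolenta", "male"): (50, 50),
    ("H. sanguinolenta", "female"): (50, 50),
    ("H. aberrans", "male"): (19, 20),
    ("H. aberrans", "female"): (20, 20),
}


def table_aggregation() -> dict[str, float]:
    """Overall and pooled-by-sex accuracies from the published per-group counts."""
    size = classification.confusion_from_counts(REFERENCE_SIZE_COUNTS)
    shape = classification.confusion_from_counts(REFERENCE_SHAPE_COUNTS)
    return {
        "size_overall_pct": round(size.overall_accuracy, 1),
        "size_male_pct": round(size.pooled_by_sex_accuracy["male"], 1),
        "size_female_pct": round(size.pooled_by_sex_accuracy["female"], 1),
        "shape_overall_pct": round(shape.overall_accuracy, 1),
        "shape_male_pct": round(shape.pooled_by_sex_accuracy["male"], 1),
        "shape_female_pct": round(shape.pooled_by_sex_accuracy["female"], 1),
    }


def _random_similarity(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.3, 4.0)
    c, s = np.cos(theta), np.sin(theta)
    return (coords @ np.array([[c, s], [-s, c]])) * scale + rng.uniform(-30, 30, size=2)


def similarity_invariance_audit(seed: int = 0, n_scale: float = 0.3) -> dict[str, float]:
    """Largest change in any downstream statistic under random similarity
    transforms of every input specimen.

    Covers tangent shape variables, pairwise Mahalanobis distances, LOO shape
    accuracy, and the repeatability index.
    """
    rng = np.random.default_rng(seed)
    ds = synthetic_data.simulate_reference_dataset(
        synthetic_data.study_design_spec(seed=seed + 1, n_scale=n_scale)
    )
    moved = LandmarkDataset(
        [replace(c, coords=_random_similarity(rng, c.coords)) for c in ds]
    )
    a1, a2 = generalized_procrustes(ds), generalized_procrustes(moved)
    delta_shape = float(np.abs(a1.shape_variables - a2.shape_variables).max())

    p1, p2 = shape_analysis.shape_pca(a1), shape_analysis.shape_pca(a2)
    d1 = shape_analysis.mahalanobis_pairwise_test(p1, a1.group_labels, n_perm=1, seed=0)
    d2 = shape_analysis.mahalanobis_pairwise_test(p2, a2.group_labels, n_perm=1, seed=0)
    delta_d = float(max(abs(x.distance - y.distance) for x, y in zip(d1, d2)))

    acc1 = classification.loo_classify_shape(a1, p1).overall_accuracy
    acc2 = classification.loo_classify_shape(a2, p2).overall_accuracy
    delta_acc = float(abs(acc1 - acc2))

    rep_ds = synthetic_data.simulate_replicated_digitization(ds, 0.004, m=2, seed=seed + 2)
    rep_moved = LandmarkDataset(
        [replace(c, coords=_random_similarity(rng, c.coords)) for c in rep_ds]
    )
    r1 = repeatability.procrustes_anova_repeatability(rep_ds).repeatability_percent
    r2 = repeatability.procrustes_anova_repeatability(rep_moved).repeatability_percent
    delta_rep = float(abs(r1 - r2))
    return {
        "shape_variables": delta_shape,
        "mahalanobis": delta_d,
        "accuracy": delta_acc,
        "repeatability": delta_rep,
        "max": max(delta_shape, delta_d, delta_acc, delta_rep),
    }


def upgma_oracle_comparison(n_matrices: int = 50, n_taxa: int = 6, seed: int = 0) -> dict:
    """Count agreement between the UPGMA implementation and a from-scratch
    brute-force agglomerator on random distance matrices."""
    rng = np.random.default_rng(seed)
    matches = 0
    max_height_err = 0.0
    for _ in range(n_matrices):
        pts = rng.normal(size=(n_taxa, 4))
        D = clustering.shape_distance_matrix(pts)
        labels = [f"t{i}" for i in range(n_taxa)]
        la, ma = clustering.upgma_tree(D, labels).cophenetic()
        lb, mb = _brute_force_upgma(D, labels).cophenetic()
        ia = {l: i for i, l in enumerate(la)}
        ib = {l: i for i, l in enumerate(lb)}
        errs = [
            abs(ma[ia[x], ia[y]] - mb[ib[x], ib[y]])
            for x, y in itertools.combinations(labels, 2)
        ]
        max_height_err = max(max_height_err, max(errs))
        if max(errs) < 1e-9:
            matches += 1
    return {"matches": matches, "n": n_matrices, "max_height_error": max_height_err}


def _brute_force_upgma(dist: np.ndarray, labels: list[str]) -> clustering.DendrogramNode:
    D = np.asarray(dist, float)
    clusters = [
        (frozenset([i]), clustering.DendrogramNode(0.0, name=labels[i]))
        for i in range(len(labels))
    ]
    while len(clusters) > 1:
        best = None
        for (ia, a), (ib, b) in itertools.combinations(enumerate(clusters), 2):
            d = float(np.mean([D[i, j] for i in a[0] for j in b[0]]))
            key = (d, min(labels[i] for i in a[0] | b[0]))
            if best is None or key < best[0]:
                best = (key, ia, ib, d)
        _, ia, ib, d = best
        a, b = clusters[ia], clusters[ib]
        merged = (a[0] | b[0], clustering.DendrogramNode(d / 2, children=(a[1], b[1])))
        clusters = [c for i, c in enumerate(clusters) if i not in (ia, ib)] + [merged]
    return clusters[0][1]


def opa_grid_search_comparison(n_pairs: int = 5, seed: int = 0) -> dict[str, float]:
    """Max |angle| gap between the fitted rotation and a 1e-4 rad grid minimizer."""
    rng = np.random.default_rng(seed)
    thetas = np.arange(-np.pi, np.pi, 1e-4)
    cos, sin = np.cos(thetas), np.sin(thetas)
    worst = 0.0
    for _ in range(n_pairs):
        a = rng.normal(size=(6, 2))
        b = rng.normal(size=(6, 2))
        a -= a.mean(0)
        a /= np.linalg.norm(a)
        b -= b.mean(0)
        b /= np.linalg.norm(b)
        xr = np.einsum("ki,ti->tk", a, np.stack([cos, -sin], 1))
        yr = np.einsum("ki,ti->tk", a, np.stack([sin, cos], 1))
        cost = ((xr - b[:, 0]) ** 2 + (yr - b[:, 1]) ** 2).sum(axis=1)
        theta_star = thetas[int(np.argmin(cost))]
        r = optimal_rotation(a, b)
        theta_fit = float(np.arctan2(r[0, 1], r[0, 0]))
        worst = max(worst, abs(float(np.angle(np.exp(1j * (theta_fit - theta_star))))))
    return {"max_angle_error_rad": worst, "n": n_pairs}


def dfa_mahalanobis_consistency(seed: int = 0) -> float:
    """|DF-space separation^2 - D^2| for a two-group dataset."""
    k = 10
    off = synthetic_data.margin_offset(k, 3.0, -3.0, axis=1, noise_sd=0.01)
    spec = synthetic_data.SimulationSpec(
        template=synthetic_data.template_wing_shape(k),
        groups=[
            synthetic_data.GroupSpec("A", "male", 25, 3.5, 0.2, np.zeros((k, 2))),
            synthetic_data.GroupSpec("B", "male", 25, 3.5, 0.2, off),
        ],
        landmark_noise_sd=0.01,
        seed=seed,
    )
    aligned = generalized_procrustes(synthetic_data.simulate_reference_dataset(spec))
    pca = shape_analysis.shape_pca(aligned)
    dfa = shape_analysis.discriminant_analysis(pca, aligned.group_labels)
    res = shape_analysis.mahalanobis_pairwise_test(pca, aligned.group_labels, n_perm=1, seed=0)
    means = list(dfa.group_means.values())
    sep2 = float(np.sum((means[0] - means[1]) ** 2))
    return abs(sep2 - res[0].distance ** 2)


def permutation_calibration(
    n_datasets: int = 200,
    n_per_group: int = 20,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error of the CS and Mahalanobis permutation tests on null data.

    Each replicate draws two identically distributed groups, runs both
    pairwise permutation tests, and records whether raw p < alpha.
    """
    k = 10
    rejections_cs = 0
    rejections_shape = 0
    for rep in range(n_datasets):
        spec = synthetic_data.SimulationSpec(
            template=synthetic_data.template_wing_shape(k),
            groups=[
                synthetic_data.GroupSpec("A", "male", n_per_group, 3.5, 0.2, np.zeros((k, 2))),
                synthetic_data.GroupSpec("B", "male", n_per_group, 3.5, 0.2, np.zeros((k, 2))),
            ],
            landmark_noise_sd=0.01,
            seed=seed * 1_000_003 + rep,
        )
        # permutation streams seeded independently of the data stream
        perm_seed = seed * 1_299_827 + 7_919 * rep + 1
        aligned = generalized_procrustes(synthetic_data.simulate_reference_dataset(spec))
        size_res = size_analysis.cs_anova_permutation(
            aligned, n_perm=n_perm, alpha=alpha, seed=perm_seed
        )
        if size_res.pairwise[0].raw_p < alpha:
            rejections_cs += 1
        pca = shape_analysis.shape_pca(aligned)
        maha = shape_analysis.mahalanobis_pairwise_test(
            pca, aligned.group_labels, n_perm=n_perm, seed=perm_seed + 1
        )
        if maha[0].raw_p < alpha:
            rejections_shape += 1
    return {
        "cs_rejection_rate": rejections_cs / n_datasets,
        "shape_rejection_rate": rejections_shape / n_datasets,
        "n": n_datasets,
    }


def study_design_classification(seed: int = 0) -> dict[str, float]:
    """LOO size and shape accuracy on the full synthetic study design."""
    ds = synthetic_data.simulate_reference_dataset(synthetic_data.study_design_spec(seed=seed))
    aligned = generalized_procrustes(ds)
    pca = shape_analysis.shape_pca(aligned)
    shape_conf = classification.loo_classify_shape(aligned, pca)
    size_conf = classification.loo_classify_size(aligned)
    return {
        "shape_overall_pct": shape_conf.overall_accuracy,
        "size_overall_pct": size_conf.overall_accuracy,
        "n": aligned.n,
    }


def repeatability_benchmarks(seed: int = 0, n_specimens: int = 100) -> dict[str, float]:
    """Closed-form repeatability checks: equal variances, zero error, MS arithmetic."""
    noise = 0.01
    spec = synthetic_data.SimulationSpec(
        template=synthetic_data.template_wing_shape(),
        groups=[
            synthetic_data.GroupSpec("A", "male", n_specimens, 1.0, 0.0, np.zeros((10, 2)))
        ],
        landmark_noise_sd=noise,
        seed=seed,
    )
    ds = synthetic_data.simulate_reference_dataset(spec)
    equal = repeatability.procrustes_anova_repeatability(
        synthetic_data.simulate_replicated_digitization(ds, error_sd=noise, m=2, seed=seed + 1)
    ).repeatability_percent
    zero = repeatability.procrustes_anova_repeatability(
        synthetic_data.simulate_replicated_digitization(ds, error_sd=0.0, m=2, seed=seed + 2)
    ).repeatability_percent
    arithmetic = repeatability.repeatability_from_mean_squares(10.0, 1.0, 2).repeatability_percent
    return {
        "equal_variance_pct": equal,
        "zero_error_pct": zero,
        "ms_example_pct": arithmetic,
        "n": n_specimens,
    }


def allometry_recovery(
    n_seeds: int = 50, n_specimens: int = 100, target_fraction: float = 0.30, seed: int = 0
) -> dict[str, float]:
    """Recover a known allometric variance share and audit the null.

    The generator puts a dominant major shape axis at 10x the isotropic
    per-dimension noise variance (mirroring the strong anisotropy of real
    wing covariances) and sets the allometric coefficient b from the
    variance-ratio oracle r^2 = b^2 var(CS) / var(PC1), with
    var(PC1) = b^2 var(CS) + major_axis^2 + noise^2.  Null runs (b = 0, same
    major axis) should keep r^2 below 5 %.
    """
    noise, cs_sd = 0.01, 0.28
    axis_total = 10 * noise**2                       # var(PC1) target
    b = np.sqrt(target_fraction * axis_total) / cs_sd
    major_effect = np.sqrt(axis_total - target_fraction * axis_total - noise**2)
    major_null = np.sqrt(axis_total - noise**2)
    recovered = []
    null_below = 0
    for i in range(n_seeds):
        for coef, major, bucket in ((b, major_effect, "effect"), (0.0, major_null, "null")):
            spec = synthetic_data.SimulationSpec(
                template=synthetic_data.template_wing_shape(),
                groups=[
                    synthetic_data.GroupSpec(
                        "A", "male", n_specimens, 3.94, cs_sd, np.zeros((10, 2))
                    )
                ],
                landmark_noise_sd=noise,
                allometric_coef=coef,
                major_axis_sd=major,
                seed=seed * 500_009 + 2 * i + (0 if bucket == "effect" else 1),
            )
            aligned = generalized_procrustes(synthetic_data.simulate_reference_dataset(spec))
            pca = shape_analysis.shape_pca(aligned)
            r2 = shape_analysis.allometry_regression(aligned, pca)[0].r_squared_percent
            if bucket == "effect":
                recovered.append(r2)
            elif r2 < 5.0:
                null_below += 1
    return {
        "mean_r2_pct": float(np.mean(recovered)),
        "null_below_5_fraction": null_below / n_seeds,
        "n": n_seeds,
    }
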