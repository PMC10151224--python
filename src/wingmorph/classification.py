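"""Cross-validated classification and identification of new specimens.

Two leave-one-out classifiers mirror the usual wing-morphometry validation:
a size classifier (per-group univariate normal maximum likelihood on centroid
size, equal priors) and a shape classifier (closest group by Mahalanobis
distance on retained PC scores).  Group statistics are refit without the
held-out specimen; the GPA consensus and PC basis are computed without group
labels and therefore stay fixed.

Identification projects test specimens into the frozen reference morphospace
(reference consensus, tangent plane, PC basis, pooled covariance) and assigns
each to the closest reference group; a joint UPGMA tree over reference and
test shape variables illustrates their similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import DendrogramNode, shape_distance_matrix, upgma_tree
from .landmark_io import LandmarkDataset
from .shape_analysis import (
    PCAResult,
    _safe_inverse,
    pooled_within_covariance,
    retained_components,
)
from .superimposition import AlignedDataset, aligned_config_from_raw

logger = logging.getLogger(__name__)


@dataclass
class AssignmentRecord:
    specimen_id: str
    true_group: tuple[str, str] | None
    assigned_group: tuple[str, str]
    scores: dict[tuple[str, str], float]   # per-group distance (min wins) or log-density (max wins)
    criterion: str                          # "distance" or "log_likelihood"


@dataclass
class ConfusionTable:
    """Assigned-vs-observed counts with per-group, pooled-by-sex, and overall accuracy."""

    groups: list[tuple[str, str]]
    matrix: np.ndarray          # observed (rows) x assigned (columns)
    records: list[AssignmentRecord]

    @property
    def observed_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def correct_counts(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    @property
    def per_group_accuracy(self) -> dict[tuple[str, str], float]:
        obs = self.observed_counts
        return {
            g: 100.0 * self.matrix[i, i] / obs[i] if obs[i] else float("nan")
            for i, g in enumerate(self.groups)
        }

    @property
    def overall_accuracy(self) -> float:
        total = self.matrix.sum()
        return 100.0 * np.trace(self.matrix) / total if total else float("nan")

    @property
    def pooled_by_sex_accuracy(self) -> dict[str, float]:
        out = {}
        for sex in sorted({sex for _, sex in self.groups}):
            idx = [i for i, (_, s) in enumerate(self.groups) if s == sex]
            correct = sum(self.matrix[i, i] for i in idx)
            observed = sum(self.observed_counts[i] for i in idx)
            out[sex] = 100.0 * correct / observed if observed else float("nan")
        return out

    def summary_table(self) -> pd.DataFrame:
        """One row per group plus a Total row: % accuracy and assigned/observed."""
        rows = []
        for i, (species, sex) in enumerate(self.groups):
            obs = int(self.observed_counts[i])
            cor = int(self.matrix[i, i])
            rows.append(
                {
                    "species": species,
                    "sex": sex,
                    "accuracy_pct": round(100.0 * cor / obs, 1) if obs else float("nan"),
                    "assigned_observed": f"{cor}/{obs}",
                }
            )
        total_obs = int(self.matrix.sum())
        total_cor = int(np.trace(self.matrix))
        rows.append(
            {
                "species": "Total",
                "sex": "",
                "accuracy_pct": round(100.0 * total_cor / total_obs, 1) if total_obs else float("nan"),
                "assigned_observed": f"{total_cor}/{total_obs}",
            }
        )
        return pd.DataFrame(rows)


def confusion_summary(records: list[AssignmentRecord]) -> ConfusionTable:
    """Tabulate assignment records (all must carry a true group)."""
    if not records:
        return ConfusionTable(groups=[], matrix=np.zeros((0, 0), dtype=int), records=[])
    if any(r.true_group is None for r in records):
        raise ValueError("all records must carry a true group")
    groups = sorted({r.true_group for r in records} | {r.assigned_group for r in records})
    idx = {g: i for i, g in enumerate(groups)}
    matrix = np.zeros((len(groups), len(groups)), dtype=int)
    for r in records:
        matrix[idx[r.true_group], idx[r.assigned_group]] += 1
    return ConfusionTable(groups=groups, matrix=matrix, records=records)


def confusion_from_counts(
    counts: dict[tuple[str, str], tuple[int, int]]
) -> ConfusionTable:
    """Build a confusion table from per-group (correct, observed) counts.

    Used when only the per-group tallies of an external classification are
    available.  Misassigned specimens are attributed to the next group in
    order; per-group, pooled, and overall accuracies do not depend on where
    they go.
    """
    groups = sorted(counts)
    matrix = np.zeros((len(groups), len(groups)), dtype=int)
    for i, g in enumerate(groups):
        correct, observed = counts[g]
        if not 0 <= correct <= observed:
            raise ValueError(f"bad counts for {g}: {correct}/{observed}")
        matrix[i, i] = correct
        matrix[i, (i + 1) % len(groups)] += observed - correct
    return ConfusionTable(groups=groups, matrix=matrix, records=[])


def _tie_break_argbest(
    values: dict[tuple[str, str], float], best: str
) -> tuple[str, str]:
    """Arg-min/max with deterministic ties: earliest group in sorted order wins."""
    opt = min(values.values()) if best == "min" else max(values.values())
    for g in sorted(values):
        if values[g] == opt:
            return g
    raise RuntimeError("unreachable")


def loo_classify_shape(aligned: AlignedDataset, pca: PCAResult) -> ConfusionTable:
    """Leave-one-out shape classification by closest group (Mahalanobis).

    For each specimen, group means and the pooled within-group covariance on
    retained PC scores are recomputed without it; the specimen goes to the
    group at minimal Mahalanobis distance.  The GPA and PC basis stay fixed.
    """
    labels = aligned.group_labels
    groups = aligned.groups
    g = len(groups)
    code_of = {grp: i for i, grp in enumerate(groups)}
    codes = np.array([code_of[lab] for lab in labels])
    for gi, grp in enumerate(groups):
        if np.sum(codes == gi) < 3:
            raise ValueError(f"group {grp} has fewer than 3 specimens")
    p = retained_components(pca, g)
    X = pca.scores[:, :p]
    n = X.shape[0]
    records = []
    for i in range(n):
        if np.sum(codes == codes[i]) <= 1:
            logger.warning("skipping %s: removal empties its group", aligned.specimen_ids[i])
            continue
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xr, cr = X[mask], codes[mask]
        S_inv = _safe_inverse(pooled_within_covariance(Xr, cr, g))
        dists = {}
        for gi, grp in enumerate(groups):
            mu = Xr[cr == gi].mean(axis=0)
            d = X[i] - mu
            dists[grp] = float(np.sqrt(d @ S_inv @ d))
        assigned = _tie_break_argbest(dists, "min")
        records.append(
            AssignmentRecord(aligned.specimen_ids[i], labels[i], assigned, dists, "distance")
        )
    return confusion_summary(records)


def loo_classify_size(aligned: AlignedDataset) -> ConfusionTable:
    """Leave-one-out size classification by per-group normal maximum likelihood.

    Each group's centroid-size distribution is modeled as a univariate normal
    (mean, unbiased variance) refit without the held-out specimen; the
    specimen is assigned to the group with the highest density (equal priors).
    """
    cs = aligned.centroid_sizes
    labels = aligned.group_labels
    groups = aligned.groups
    code_of = {grp: i for i, grp in enumerate(groups)}
    codes = np.array([code_of[lab] for lab in labels])
    for gi, grp in enumerate(groups):
        if np.sum(codes == gi) < 3:
            raise ValueError(f"group {grp} has fewer than 3 specimens")
    records = []
    for i in range(len(cs)):
        loglik = {}
        for gi, grp in enumerate(groups):
            vals = cs[(codes == gi) & (np.arange(len(cs)) != i)]
            mu, var = vals.mean(), vals.var(ddof=1)
            if var <= 0:
                raise ValueError(f"zero centroid-size variance in group {grp}")
            loglik[grp] = float(-0.5 * np.log(2 * np.pi * var) - (cs[i] - mu) ** 2 / (2 * var))
        assigned = _tie_break_argbest(loglik, "max")
        records.append(
            AssignmentRecord(aligned.specimen_ids[i], labels[i], assigned, loglik, "log_likelihood")
        )
    return confusion_summary(records)


def ml_size_assign(
    cs_value: float, models: dict[tuple[str, str], tuple[float, float]]
) -> tuple[tuple[str, str], dict[tuple[str, str], float]]:
    """Assign one centroid size to the most likely of fixed normal models.

    ``models`` maps group -> (mean, sd).  Returns the winning group and the
    per-group log-densities.
    """
    loglik = {
        g: float(-0.5 * np.log(2 * np.pi * sd**2) - (cs_value - mu) ** 2 / (2 * sd**2))
        for g, (mu, sd) in models.items()
    }
    return _tie_break_argbest(loglik, "max"), loglik


def identify_test_specimens(
    aligned_ref: AlignedDataset,
    pca_ref: PCAResult,
    tests: LandmarkDataset,
) -> tuple[list[AssignmentRecord], DendrogramNode]:
    """Identify test specimens against a frozen reference morphospace.

    Each test configuration is centered, unit-scaled, rotated onto the
    reference consensus, tangent-projected there, and expressed in the
    reference PC basis; it is assigned to the reference group at minimal
    Mahalanobis distance under the reference pooled within-group covariance.
    A joint UPGMA tree over reference + test shape variables is returned.
    The reference space is never modified.
    """
    if tests.k != aligned_ref.k:
        raise ValueError(f"landmark count mismatch: tests k={tests.k}, reference k={aligned_ref.k}")
    groups = aligned_ref.groups
    g = len(groups)
    code_of = {grp: i for i, grp in enumerate(groups)}
    codes = np.array([code_of[lab] for lab in aligned_ref.group_labels])
    p = retained_components(pca_ref, g)
    X = pca_ref.scores[:, :p]
    S_inv = _safe_inverse(pooled_within_covariance(X, codes, g))
    means = {grp: X[codes == gi].mean(axis=0) for gi, grp in enumerate(groups)}

    records = []
    test_vars = np.empty((len(tests), 2 * tests.k))
    for t_i, config in enumerate(tests):
        _, t = aligned_config_from_raw(config.coords, aligned_ref)
        test_vars[t_i] = t
        score = (t - pca_ref.mean) @ pca_ref.axes[:, :p]
        dists = {}
        for grp in groups:
            d = score - means[grp]
            dists[grp] = float(np.sqrt(d @ S_inv @ d))
        assigned = _tie_break_argbest(dists, "min")
        true = config.group if config.species != "unknown" else None
        records.append(AssignmentRecord(config.specimen_id, true, assigned, dists, "distance"))

    joint = np.vstack([aligned_ref.shape_variables, test_vars])
    ref_labels = [
        f"{c.species}|{c.sex}|{c.specimen_id}" for c in aligned_ref.dataset
    ]
    test_labels = [f"test|{c.sex}|{c.specimen_id}" for c in tests]
    tree = upgma_tree(shape_distance_matrix(joint), ref_labels + test_labels)
    return records, tree


def assignment_table(records: list[AssignmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "specimen_id": r.specimen_id,
            "true_group": f"{r.true_group[0]} ({r.true_group[1]})" if r.true_group else "unknown",
            "assigned_group": f"{r.assigned_group[0]} ({r.assigned_group[1]})",
            "criterion": r.criterion,
        }
        for g, v in sorted(r.scores.items()):
            row[f"score[{g[0]} ({g[1]})]"] = v
        rows.append(row)
    return pd.DataFrame(rows)
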