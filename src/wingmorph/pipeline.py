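"""Orchestration of the full reference analysis and the identification workflow.

Everything is driven by an :class:`AnalysisConfig` (loadable from YAML): a
reference landmark table or TPS file, optional test specimens, optional
replicated digitizations, permutation count, alpha, seed, and an output
directory.  Outputs are plain delimited text plus newick; given the same
config and seed, every emitted number is identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import classification, clustering, repeatability, shape_analysis, size_analysis
from .landmark_io import LandmarkDataset, read_landmark_table, read_tps, validate_dataset
from .superimposition import AlignedDataset, generalized_procrustes

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("wingmorph")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class AnalysisConfig:
    reference_path: str
    output_dir: str = "wingmorph_out"
    tests_path: str | None = None
    replicated_path: str | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    min_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_dataset(path: str | Path) -> LandmarkDataset:
    """Load a dataset, dispatching on extension (.tps vs delimited table)."""
    path = Path(path)
    if path.suffix.lower() == ".tps":
        return read_tps(path)
    return read_landmark_table(path)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_reference_analysis(cfg: AnalysisConfig) -> dict[str, Path]:
    """Run the whole reference pipeline; returns paths of the emitted reports.

    Stages (each failure is reported with its stage name): validation, GPA,
    size summary + permutation ANOVA, shape PCA + DFA + pairwise Mahalanobis,
    LOO size and shape classification, UPGMA clustering, allometry, and —
    when a replicated dataset is configured — Procrustes-ANOVA repeatability.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        ds = load_dataset(cfg.reference_path)
        report = validate_dataset(ds, cfg.min_per_group)
        if not report.ok:
            raise ValueError("; ".join(report.problems()))
    except Exception as exc:
        raise RuntimeError(f"[load/validate] {exc}") from exc

    if cfg.replicated_path:
        try:
            stage("repeatability")
            rep_ds = load_dataset(cfg.replicated_path)
            rep = repeatability.procrustes_anova_repeatability(rep_ds)
            df = pd.DataFrame(
                [
                    {
                        "ms_among": rep.ms_among,
                        "ms_within": rep.ms_within,
                        "repeatability_pct": rep.repeatability_percent,
                        "measurement_error_pct": rep.measurement_error_percent,
                        "n_specimens": rep.n_specimens,
                        "m_replicates": rep.m_replicates,
                    }
                ]
            )
            _write(df, out / "repeatability.tsv")
            written["repeatability"] = out / "repeatability.tsv"
        except Exception as exc:
            raise RuntimeError(f"[repeatability] {exc}") from exc

    try:
        stage("gpa")
        aligned = generalized_procrustes(ds)
    except Exception as exc:
        raise RuntimeError(f"[gpa] {exc}") from exc

    try:
        stage("size")
        summary = size_analysis.size_summary(aligned)
        test = size_analysis.cs_anova_permutation(
            aligned, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
        )
        summary["letter"] = [
            test.letters[(r.species, r.sex)] for r in summary.itertuples()
        ]
        _write(summary, out / "size_summary.tsv")
        _write(test.pairwise_table(), out / "size_pairwise_tests.tsv")
        written["size_summary"] = out / "size_summary.tsv"
        written["size_tests"] = out / "size_pairwise_tests.tsv"
    except Exception as exc:
        raise RuntimeError(f"[size] {exc}") from exc

    try:
        stage("shape")
        pca = shape_analysis.shape_pca(aligned)
        dfa = shape_analysis.discriminant_analysis(pca, aligned.group_labels)
        maha = shape_analysis.mahalanobis_pairwise_test(
            pca, aligned.group_labels, n_perm=cfg.n_perm, seed=cfg.seed
        )
        scores = pd.DataFrame(
            {
                "specimen_id": aligned.specimen_ids,
                "species": [s for s, _ in aligned.group_labels],
                "sex": [x for _, x in aligned.group_labels],
                "PC1": pca.scores[:, 0],
                "PC2": pca.scores[:, 1] if pca.scores.shape[1] > 1 else 0.0,
                "DF1": dfa.scores[:, 0],
                "DF2": dfa.scores[:, 1] if dfa.scores.shape[1] > 1 else 0.0,
            }
        )
        _write(scores, out / "factor_scores.tsv")
        shape_analysis.distance_table(maha).to_csv(out / "mahalanobis.tsv", sep="\t")
        written["factor_scores"] = out / "factor_scores.tsv"
        written["mahalanobis"] = out / "mahalanobis.tsv"
    except Exception as exc:
        raise RuntimeError(f"[shape] {exc}") from exc

    try:
        stage("classification")
        shape_conf = classification.loo_classify_shape(aligned, pca)
        size_conf = classification.loo_classify_size(aligned)
        sz = size_conf.summary_table().add_prefix("size_")
        sh = shape_conf.summary_table().add_prefix("shape_")
        table4 = pd.concat(
            [sz.rename(columns={"size_species": "species", "size_sex": "sex"}), sh[["shape_accuracy_pct", "shape_assigned_observed"]]],
            axis=1,
        )
        _write(table4, out / "classification.tsv")
        written["classification"] = out / "classification.tsv"
    except Exception as exc:
        raise RuntimeError(f"[classification] {exc}") from exc

    try:
        stage("clustering")
        dist = clustering.shape_distance_matrix(aligned.shape_variables)
        labels = [f"{c.species}|{c.sex}|{c.specimen_id}" for c in ds]
        tree = clustering.upgma_tree(dist, labels)
        (out / "hac_tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
        written["hac_tree"] = out / "hac_tree.nwk"
    except Exception as exc:
        raise RuntimeError(f"[clustering] {exc}") from exc

    try:
        stage("allometry")
        allo = shape_analysis.allometry_regression(aligned, pca)
        _write(
            pd.DataFrame(
                [
                    {
                        "species": a.species,
                        "n": a.n,
                        "slope": a.slope,
                        "intercept": a.intercept,
                        "r_squared_pct": a.r_squared_percent,
                        "p": a.p,
                    }
                    for a in allo
                ]
            ),
            out / "allometry.tsv",
        )
        written["allometry"] = out / "allometry.tsv"
    except Exception as exc:
        raise RuntimeError(f"[allometry] {exc}") from exc

    log = out / "run_log.txt"
    log.write_text(
        "\n".join(
            [
                f"wingmorph version: {_package_version()}",
                f"reference: {cfg.reference_path}",
                f"n specimens: {len(ds)}; k: {ds.k}; groups: {aligned.groups}",
                f"seed: {cfg.seed}; n_perm: {cfg.n_perm}; alpha: {cfg.alpha}",
                f"retained PCs: {shape_analysis.retained_components(pca, len(aligned.groups))}",
                f"GPA iterations: {aligned.n_iterations}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    written["run_log"] = log
    return written


def run_identification(cfg: AnalysisConfig) -> dict[str, Path]:
    """Build the frozen reference space and identify the configured test specimens."""
    if not cfg.tests_path:
        raise ValueError("identification requires tests_path")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ref = load_dataset(cfg.reference_path)
        tests = load_dataset(cfg.tests_path)
        aligned = generalized_procrustes(ref)
        pca = shape_analysis.shape_pca(aligned)
        records, tree = classification.identify_test_specimens(aligned, pca, tests)
    except Exception as exc:
        raise RuntimeError(f"[identification] {exc}") from exc
    _write(classification.assignment_table(records), out / "assignments.tsv")
    (out / "combined_tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
    return {"assignments": out / "assignments.tsv", "combined_tree": out / "combined_tree.nwk"}
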