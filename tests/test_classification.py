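import numpy as np
import pytest
from dataclasses import replace

from conftest import random_similarity
from wingmorph.classification import (
    AssignmentRecord,
    confusion_from_counts,
    confusion_summary,
    identify_test_specimens,
    loo_classify_shape,
    loo_classify_size,
    ml_size_assign,
)
from wingmorph.landmark_io import LandmarkDataset
from wingmorph.shape_analysis import shape_pca
from wingmorph.superimposition import generalized_procrustes
from wingmorph.synthetic_data import (
    GroupSpec,
    SimulationSpec,
    margin_offset,
    simulate_reference_dataset,
    study_design_spec,
    template_wing_shape,
)

#: Per-group univariate normal CS models of the four-group reference design.
SIZE_MODELS = {
    ("H. sanguinolenta", "male"): (3.94, 0.28),
    ("H. sanguinolenta", "female"): (3.93, 0.33),
    ("H. aberrans", "male"): (2.99, 0.12),
    ("H. aberrans", "female"): (3.07, 0.20),
}


def two_group_dataset(offset_mult, n=25, noise=0.01, seed=0, same=False):
    k = 10
    off = np.zeros((k, 2)) if same else margin_offset(k, offset_mult, -offset_mult, 1, noise)
    spec = SimulationSpec(
        template=template_wing_shape(k),
        groups=[
            GroupSpec("A", "male", n, 3.5, 0.2, np.zeros((k, 2))),
            GroupSpec("B", "male", n, 3.5, 0.2, off),
        ],
        landmark_noise_sd=noise,
        seed=seed,
    )
    return simulate_reference_dataset(spec)


class TestConfusionSummary:
    def test_row_sums_and_overall(self, small_aligned):
        pca = shape_pca(small_aligned)
        conf = loo_classify_shape(small_aligned, pca)
        np.testing.assert_array_equal(
            conf.matrix.sum(axis=1),
            [small_aligned.group_labels.count(g) for g in conf.groups],
        )
        assert conf.overall_accuracy == pytest.approx(
            100 * np.trace(conf.matrix) / conf.matrix.sum()
        )

    def test_empty_input(self):
        conf = confusion_summary([])
        assert conf.groups == [] and np.isnan(conf.overall_accuracy)

    def test_printed_count_aggregation(self):
        """Feeding external per-group correct/observed counts reproduces the
        derived overall and pooled-by-sex percentages."""
        size_counts = {
            ("H. sanguinolenta", "male"): (2, 50),
            ("H. sanguinolenta", "female"): (41, 50),
            ("H. aberrans", "male"): (11, 20),
            ("H. aberrans", "female"): (12, 20),
        }
        conf = confusion_from_counts(size_counts)
        assert round(conf.overall_accuracy, 1) == 47.1
        assert round(conf.pooled_by_sex_accuracy["male"], 1) == 18.6
        assert round(conf.pooled_by_sex_accuracy["female"], 1) == 75.7

    def test_summary_table_has_total_row(self, small_aligned):
        conf = loo_classify_size(small_aligned)
        tab = conf.summary_table()
        assert tab.iloc[-1]["species"] == "Total"
        total = tab.iloc[-1]["assigned_observed"]
        assert int(total.split("/")[1]) == small_aligned.n


class TestShapeLOO:
    def test_separable_groups_classified_perfectly(self):
        ds = two_group_dataset(offset_mult=6.0, seed=1)
        aligned = generalized_procrustes(ds)
        conf = loo_classify_shape(aligned, shape_pca(aligned))
        assert conf.overall_accuracy == 100.0

    def test_identical_groups_at_chance(self):
        ds = two_group_dataset(offset_mult=0.0, n=50, seed=2, same=True)
        aligned = generalized_procrustes(ds)
        conf = loo_classify_shape(aligned, shape_pca(aligned))
        assert 35.0 <= conf.overall_accuracy <= 65.0

    def test_duplicated_dataset_classified_by_twin(self, small_dataset):
        twins = []
        for c in small_dataset:
            twins.extend([c, replace(c, specimen_id=c.specimen_id + "b")])
        doubled = LandmarkDataset(twins)
        aligned = generalized_procrustes(doubled)
        conf = loo_classify_shape(aligned, shape_pca(aligned))
        assert conf.overall_accuracy == 100.0

    def test_study_design_shape_beats_size(self, study_aligned, study_pca):
        shape_conf = loo_classify_shape(study_aligned, study_pca)
        size_conf = loo_classify_size(study_aligned)
        assert shape_conf.overall_accuracy >= 95.0
        assert size_conf.overall_accuracy < shape_conf.overall_accuracy


class TestSizeML:
    def test_small_specimen_goes_to_small_male_group(self):
        assigned, _ = ml_size_assign(3.0, SIZE_MODELS)
        assert assigned == ("H. aberrans", "male")

    def test_density_beats_z_score_for_unequal_sd(self):
        """cs = 3.5: highest normal density, not nearest z, decides."""
        assigned, loglik = ml_size_assign(3.5, SIZE_MODELS)
        assert assigned == ("H. sanguinolenta", "female")
        # oracle: direct normal densities
        from scipy.stats import norm

        dens = {g: norm(mu, sd).logpdf(3.5) for g, (mu, sd) in SIZE_MODELS.items()}
        assert max(dens, key=dens.get) == assigned
        for g in SIZE_MODELS:
            assert loglik[g] == pytest.approx(dens[g], abs=1e-10)

    def test_identical_size_distributions_at_chance(self):
        ds = two_group_dataset(0.0, n=50, seed=3, same=True)
        aligned = generalized_procrustes(ds)
        conf = loo_classify_size(aligned)
        assert 30.0 <= conf.overall_accuracy <= 70.0


class TestIdentification:
    def test_reference_replay_assigned_to_own_group(self, study_aligned, study_pca):
        subset = LandmarkDataset(list(study_aligned.dataset)[:5])
        records, _ = identify_test_specimens(study_aligned, study_pca, subset)
        for rec in records:
            assert rec.assigned_group == rec.true_group

    def test_field_specimens_recovered(self, study_aligned, study_pca):
        """New draws from the generating groups are assigned back >= 95 %."""
        tests = simulate_reference_dataset(study_design_spec(seed=99, n_scale=0.2))
        records, tree = identify_test_specimens(study_aligned, study_pca, tests)
        correct = sum(r.assigned_group == r.true_group for r in records)
        assert correct / len(records) >= 0.95
        assert len(tree.leaves()) == study_aligned.n + len(tests)

    def test_tests_join_their_groups_clade(self, study_aligned, study_pca):
        """In the joint tree, test specimens first join reference specimens of
        their own (species, sex) group (>= 90 %; occasional tail draws join a
        neighboring clade, as one real specimen did)."""
        tests = simulate_reference_dataset(study_design_spec(seed=55, n_scale=0.1))
        _, tree = identify_test_specimens(study_aligned, study_pca, tests)
        true_group = {c.specimen_id: f"{c.species}|{c.sex}" for c in tests}
        labels, coph = tree.cophenetic()
        ref_idx = [i for i, lab in enumerate(labels) if not lab.startswith("test|")]
        correct = total = 0
        for i, lab in enumerate(labels):
            if not lab.startswith("test|"):
                continue
            total += 1
            dists = coph[i, ref_idx]
            nearest = [ref_idx[j] for j in np.flatnonzero(dists <= dists.min() + 1e-12)]
            groups = ["|".join(labels[j].split("|")[:2]) for j in nearest]
            majority = max(set(groups), key=groups.count)
            correct += majority == true_group[lab.split("|")[2]]
        assert correct / total >= 0.9

    def test_similarity_invariance_of_test_inputs(self, study_aligned, study_pca):
        rng = np.random.default_rng(13)
        tests = LandmarkDataset(list(study_aligned.dataset)[:4])
        moved = LandmarkDataset(
            [replace(c, coords=random_similarity(rng, c.coords)) for c in tests]
        )
        rec_a, _ = identify_test_specimens(study_aligned, study_pca, tests)
        rec_b, _ = identify_test_specimens(study_aligned, study_pca, moved)
        for ra, rb in zip(rec_a, rec_b):
            assert ra.assigned_group == rb.assigned_group
            for g in ra.scores:
                assert rb.scores[g] == pytest.approx(ra.scores[g], abs=1e-8)

    def test_k_mismatch_rejected(self, study_aligned, study_pca):
        k6 = SimulationSpec(
            template=template_wing_shape(6),
            groups=[GroupSpec("A", "male", 3, 3.0, 0.1, np.zeros((6, 2)))],
            seed=0,
        )
        tests = simulate_reference_dataset(k6)
        with pytest.raises(ValueError, match="mismatch"):
            identify_test_specimens(study_aligned, study_pca, tests)
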