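import numpy as np
import pytest

from wingmorph.landmark_io import LandmarkConfiguration, LandmarkDataset
from wingmorph.shape_analysis import (
    PCAResult,
    allometry_regression,
    discriminant_analysis,
    mahalanobis_pairwise_test,
    retained_components,
    shape_pca,
)
from wingmorph.superimposition import generalized_procrustes
from wingmorph.synthetic_data import (
    GroupSpec,
    SimulationSpec,
    margin_offset,
    simulate_reference_dataset,
    template_wing_shape,
)


def pca_from_scores(scores):
    """Wrap raw score vectors as a PCAResult (identity basis) for distance tests."""
    scores = np.asarray(scores, float)
    n, p = scores.shape
    mean = scores.mean(axis=0)
    return PCAResult(
        axes=np.eye(p),
        scores=scores - mean,
        eigenvalues=np.var(scores, axis=0, ddof=1),
        variance_fractions=np.full(p, 1.0 / p),
        mean=mean,
    )


def two_group_spec(offset_mult, n=30, noise=0.01, seed=0):
    k = 10
    off = margin_offset(k, offset_mult, -offset_mult, axis=1, noise_sd=noise)
    groups = [
        GroupSpec("A", "male", n, 1.0, 0.05, np.zeros((k, 2))),
        GroupSpec("B", "male", n, 1.0, 0.05, off),
    ]
    return SimulationSpec(template=template_wing_shape(k), groups=groups,
                          landmark_noise_sd=noise, seed=seed)


class TestPCA:
    def test_identical_shapes_have_zero_eigenvalues(self):
        base = template_wing_shape()
        ds = LandmarkDataset(
            [LandmarkConfiguration(f"s{i}", base * 2.0) for i in range(5)]
        )
        pca = shape_pca(generalized_procrustes(ds))
        assert np.all(pca.eigenvalues < 1e-16)

    def test_reconstruction_identity(self, study_aligned, study_pca):
        np.testing.assert_allclose(
            study_pca.reconstruct(), study_aligned.shape_variables, atol=1e-9
        )

    def test_axes_orthonormal_and_ordered(self, study_pca):
        g = study_pca.axes.T @ study_pca.axes
        np.testing.assert_allclose(g, np.eye(g.shape[0]), atol=1e-10)
        assert np.all(np.diff(study_pca.eigenvalues) <= 1e-15)
        assert study_pca.variance_fractions.sum() == pytest.approx(1.0)

    def test_scores_centered(self, study_pca):
        assert np.abs(study_pca.scores.mean(axis=0)).max() < 1e-10

    def test_sign_convention_largest_loading_positive(self, study_pca):
        for j in range(study_pca.axes.shape[1]):
            col = study_pca.axes[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_pc1_separates_offset_groups_with_oracle_fraction(self):
        """Dominant between-group offset: PC1 splits groups; its variance
        fraction matches (between + within) / total from the construction."""
        ds = simulate_reference_dataset(two_group_spec(offset_mult=6.0, n=60, seed=5))
        aligned = generalized_procrustes(ds)
        pca = shape_pca(aligned)
        labels = np.array([c.species for c in ds])
        pc1 = pca.scores[:, 0]
        assert (pc1[labels == "A"].max() < pc1[labels == "B"].min()) or (
            pc1[labels == "B"].max() < pc1[labels == "A"].min()
        )
        # oracle: per-coordinate noise var s2 in 16 tangent dims; offset norm d
        s2 = 0.01**2
        d2 = (6.0 * 0.01) ** 2 * 6          # 6 landmarks displaced
        expect = (d2 / 4 + s2) / (d2 / 4 + 16 * s2)  # balanced two-point between-var d^2/4
        assert pca.variance_fractions[0] == pytest.approx(expect, rel=0.2)


class TestDFA:
    def test_two_groups_single_axis_full_fraction(self):
        ds = simulate_reference_dataset(two_group_spec(3.0, n=20, seed=6))
        aligned = generalized_procrustes(ds)
        pca = shape_pca(aligned)
        dfa = discriminant_analysis(pca, aligned.group_labels)
        assert dfa.scores.shape[1] == 1
        assert dfa.variance_fractions[0] == pytest.approx(1.0)

    def test_four_groups_three_axes(self, study_aligned, study_pca):
        dfa = discriminant_analysis(study_pca, study_aligned.group_labels)
        assert dfa.scores.shape[1] == 3
        assert dfa.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(dfa.variance_fractions) <= 1e-12)

    def test_separated_groups_bimodal_no_overlap(self):
        ds = simulate_reference_dataset(two_group_spec(6.0, n=25, seed=7))
        aligned = generalized_procrustes(ds)
        dfa = discriminant_analysis(shape_pca(aligned), aligned.group_labels)
        labels = np.array([c.species for c in ds])
        a, b = dfa.scores[labels == "A", 0], dfa.scores[labels == "B", 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_two_group_separation_equals_mahalanobis(self):
        """Squared DF-space distance of group means equals D^2."""
        ds = simulate_reference_dataset(two_group_spec(3.0, n=20, seed=8))
        aligned = generalized_procrustes(ds)
        pca = shape_pca(aligned)
        dfa = discriminant_analysis(pca, aligned.group_labels)
        res = mahalanobis_pairwise_test(pca, aligned.group_labels, n_perm=1, seed=0)
        means = list(dfa.group_means.values())
        sep2 = float(np.sum((means[0] - means[1]) ** 2))
        assert sep2 == pytest.approx(res[0].distance ** 2, rel=1e-6)


class TestMahalanobis:
    def test_identical_groups_zero_distance(self):
        scores = np.tile(np.arange(6, dtype=float)[:, None], (2, 1))
        labels = [("a", "male")] * 6 + [("b", "male")] * 6
        res = mahalanobis_pairwise_test(pca_from_scores(scores), labels, n_perm=9, seed=0)
        assert res[0].distance == pytest.approx(0.0, abs=1e-9)

    def test_univariate_closed_form(self):
        # means 0 and 2, pooled variance 1 -> D = 2
        scores = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        labels = [("a", "male")] * 3 + [("b", "male")] * 3
        res = mahalanobis_pairwise_test(pca_from_scores(scores), labels, n_perm=9, seed=0)
        assert res[0].distance == pytest.approx(2.0, abs=1e-10)

    def test_bivariate_euclidean_reduction(self):
        # identity pooled covariance, mean offset (3, 4) -> D = 5
        cloud = np.sqrt(2) * np.array([[1, 0], [-1, 0], [0, 1], [0, -1], [0, 0]], float)
        scores = np.vstack([cloud, cloud + np.array([3.0, 4.0])])
        labels = [("a", "male")] * 5 + [("b", "male")] * 5
        res = mahalanobis_pairwise_test(pca_from_scores(scores), labels, n_perm=9, seed=0)
        assert res[0].distance == pytest.approx(5.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(40, 5))
        scores[20:] += rng.normal(size=5)
        labels = [("a", "male")] * 20 + [("b", "male")] * 20
        d0 = mahalanobis_pairwise_test(pca_from_scores(scores), labels, n_perm=1, seed=0)[0].distance
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        d1 = mahalanobis_pairwise_test(
            pca_from_scores(scores @ A), labels, n_perm=1, seed=0
        )[0].distance
        assert d1 == pytest.approx(d0, rel=1e-6)

    def test_distances_symmetric_nonnegative(self, study_aligned, study_pca):
        res = mahalanobis_pairwise_test(study_pca, study_aligned.group_labels, n_perm=9, seed=0)
        assert len(res) == 6
        for r in res:
            assert r.distance >= 0
            assert r.raw_p <= r.adjusted_p <= 1.0


class TestRetention:
    def test_cap_keeps_pooled_covariance_invertible(self, study_pca):
        p = retained_components(study_pca, n_groups=4)
        assert p == 16  # 2k - 4 for k = 10 when n = 140 allows it

    def test_cap_binds_for_small_n(self):
        rng = np.random.default_rng(1)
        pca = pca_from_scores(rng.normal(size=(10, 8)))
        assert retained_components(pca, n_groups=2) == 7


class TestAllometry:
    def test_perfect_dependence(self):
        """PC1 exactly proportional to CS gives r^2 = 100 %."""
        spec = SimulationSpec(
            template=template_wing_shape(),
            groups=[GroupSpec("A", "male", 30, 3.9, 0.3, np.zeros((10, 2)))],
            landmark_noise_sd=0.0,
            allometric_coef=0.05,
            seed=3,
        )
        ds = simulate_reference_dataset(spec)
        aligned = generalized_procrustes(ds)
        res = allometry_regression(aligned, shape_pca(aligned))[0]
        assert res.r_squared_percent > 99.99
        assert res.p < 1e-10

    def test_variance_fraction_oracle(self):
        """Allometric coefficient set for a 30 % share of PC1's variance
        (b^2 var(CS) / var(PC1)) recovers r^2 ~ 30."""
        noise, cs_sd = 0.01, 0.28
        axis_total = 10 * noise**2
        b = np.sqrt(0.3 * axis_total) / cs_sd
        spec = SimulationSpec(
            template=template_wing_shape(),
            groups=[GroupSpec("A", "male", 200, 3.94, cs_sd, np.zeros((10, 2)))],
            landmark_noise_sd=noise,
            allometric_coef=b,
            major_axis_sd=float(np.sqrt(0.7 * axis_total - noise**2)),
            seed=4,
        )
        ds = simulate_reference_dataset(spec)
        aligned = generalized_procrustes(ds)
        res = allometry_regression(aligned, shape_pca(aligned))[0]
        assert res.r_squared_percent == pytest.approx(30.0, abs=10.0)

    def test_null_r2_small(self):
        spec = SimulationSpec(
            template=template_wing_shape(),
            groups=[GroupSpec("A", "male", 100, 3.9, 0.3, np.zeros((10, 2)))],
            landmark_noise_sd=0.01,
            seed=5,
        )
        aligned = generalized_procrustes(simulate_reference_dataset(spec))
        res = allometry_regression(aligned, shape_pca(aligned))[0]
        assert res.r_squared_percent < 10.0

    def test_one_fit_per_species_sexes_pooled(self, study_aligned, study_pca):
        res = allometry_regression(study_aligned, study_pca)
        assert [a.species for a in res] == ["H. aberrans", "H. sanguinolenta"]
        assert [a.n for a in res] == [40, 100]
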