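import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_similarity
from wingmorph.landmark_io import LandmarkConfiguration, LandmarkDataset
from wingmorph.superimposition import (
    DegenerateConfigurationError,
    centroid_size,
    fit_pair_superimposition,
    generalized_procrustes,
    optimal_rotation,
    tangent_project,
)
from wingmorph.synthetic_data import simulate_reference_dataset, study_design_spec, template_wing_shape


class TestCentroidSize:
    def test_diamond(self):
        assert centroid_size(np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)) == pytest.approx(2.0)

    def test_right_triangle_closed_form(self):
        # centroid (1/3, 1/3); squared distances 2/9 + 5/9 + 5/9 = 4/3
        cs = centroid_size(np.array([[0, 0], [1, 0], [0, 1]], float))
        assert cs == pytest.approx(2 / np.sqrt(3), abs=1e-12)

    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity_and_rigid_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(8, 2))
        base = centroid_size(coords)
        assert centroid_size(coords * scale) == pytest.approx(base * scale, rel=1e-10)
        assert centroid_size(random_similarity(rng, coords) / 1.0) > 0
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
        assert centroid_size(coords @ rot + 5.0) == pytest.approx(base, rel=1e-10)

    def test_coincident_gives_zero(self):
        assert centroid_size(np.ones((5, 2))) == 0.0


class TestPairFit:
    def test_similarity_transform_gives_zero_distance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 2))
        b = random_similarity(rng, a)
        _, dist = fit_pair_superimposition(a, b)
        assert dist < 1e-10

    def test_self_fit_identity(self):
        a = template_wing_shape()
        aligned, dist = fit_pair_superimposition(a, a)
        assert dist < 1e-12
        np.testing.assert_allclose(aligned, a / np.linalg.norm(a - a.mean(0)), atol=1e-12)

    def test_rotation_matches_grid_search_oracle(self):
        """Fitted rotation agrees with a brute-force 1e-4 rad grid minimizer."""
        rng = np.random.default_rng(3)
        thetas = np.arange(-np.pi, np.pi, 1e-4)
        cos, sin = np.cos(thetas), np.sin(thetas)
        for _ in range(5):
            a = rng.normal(size=(6, 2))
            b = rng.normal(size=(6, 2))
            a = a - a.mean(0)
            a /= np.linalg.norm(a)
            b = b - b.mean(0)
            b /= np.linalg.norm(b)
            # objective over the grid, computed from scratch
            xr = np.einsum("ki,ti->tk", a, np.stack([cos, -sin], 1))  # x components
            yr = np.einsum("ki,ti->tk", a, np.stack([sin, cos], 1))
            cost = ((xr - b[:, 0]) ** 2 + (yr - b[:, 1]) ** 2).sum(axis=1)
            theta_star = thetas[np.argmin(cost)]
            r = optimal_rotation(a, b)
            theta_fit = np.arctan2(r[0, 1], r[0, 0])
            delta = np.angle(np.exp(1j * (theta_fit - theta_star)))
            assert abs(delta) < 1e-3

    def test_no_reflection(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=(2, 7, 2))
            r = optimal_rotation(a - a.mean(0), b - b.mean(0))
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            fit_pair_superimposition(np.ones((4, 2)), np.eye(4, 2))


def _dataset_of_copies(n=5, seed=0):
    rng = np.random.default_rng(seed)
    base = template_wing_shape()
    return LandmarkDataset(
        [
            LandmarkConfiguration(f"c{i}", random_similarity(rng, base))
            for i in range(n)
        ]
    )


class TestGPA:
    def test_copies_align_exactly(self):
        aligned = generalized_procrustes(_dataset_of_copies())
        spread = aligned.aligned_coords - aligned.aligned_coords[0]
        assert np.abs(spread).max() < 1e-8
        assert np.abs(aligned.shape_variables).max() < 1e-8

    def test_output_invariants(self, study_aligned):
        assert np.abs(study_aligned.consensus.mean(axis=0)).max() < 1e-10
        assert np.linalg.norm(study_aligned.consensus) == pytest.approx(1.0, abs=1e-10)
        cs = np.linalg.norm(study_aligned.aligned_coords.reshape(study_aligned.n, -1), axis=1)
        np.testing.assert_allclose(cs, 1.0, atol=1e-8)
        assert np.abs(study_aligned.shape_variables.mean(axis=0)).max() < 1e-8

    def test_shape_space_rank_bound(self, study_aligned):
        """Covariance of shape variables has at most 2k - 4 nonzero eigenvalues."""
        ev = np.linalg.eigvalsh(np.cov(study_aligned.shape_variables.T))
        assert int(np.sum(ev > 1e-12)) <= 2 * study_aligned.k - 4

    def test_consensus_is_fixed_point(self, small_aligned):
        rerun = generalized_procrustes(
            LandmarkDataset(
                [
                    LandmarkConfiguration(f"r{i}", small_aligned.aligned_coords[i])
                    for i in range(small_aligned.n)
                ]
            )
        )
        assert np.abs(rerun.consensus - small_aligned.consensus).max() < 1e-9

    def test_procrustes_ss_decreases_monotonically(self, small_aligned):
        path = small_aligned.sum_of_squares_path
        assert all(b <= a + 1e-12 for a, b in zip(path, path[1:]))

    def test_similarity_invariance_of_shape_variables(self, small_dataset, small_aligned):
        rng = np.random.default_rng(11)
        transformed = LandmarkDataset(
            [
                LandmarkConfiguration(c.specimen_id, random_similarity(rng, c.coords),
                                      c.species, c.sex, c.site, c.user_id, c.replicate)
                for c in small_dataset
            ]
        )
        aligned2 = generalized_procrustes(transformed)
        assert np.abs(aligned2.shape_variables - small_aligned.shape_variables).max() < 1e-8

    def test_centroid_sizes_recorded_before_scaling(self, small_dataset, small_aligned):
        expected = [centroid_size(c) for c in small_dataset]
        np.testing.assert_allclose(small_aligned.centroid_sizes, expected, rtol=1e-12)

    def test_requires_two_specimens(self):
        with pytest.raises(ValueError):
            generalized_procrustes(LandmarkDataset([_dataset_of_copies()[0]]))


class TestTangentProjection:
    def test_consensus_maps_to_zero(self, study_aligned):
        c = study_aligned.consensus.ravel()
        assert np.abs(tangent_project(c[None, :], c)).max() < 1e-12

    def test_idempotent(self, study_aligned):
        c = study_aligned.consensus.ravel()
        once = tangent_project(study_aligned.aligned_coords.reshape(study_aligned.n, -1), c)
        twice = tangent_project(once, c)
        assert np.abs(twice - once).max() < 1e-12

    def test_small_angle_norm_matches_procrustes_distance(self):
        """For small deviations, |tangent vector| ~ Procrustes distance to consensus."""
        ds = simulate_reference_dataset(study_design_spec(seed=7, n_scale=0.2))
        aligned = generalized_procrustes(ds)
        norms = np.linalg.norm(aligned.shape_variables, axis=1)
        dists = np.linalg.norm(
            aligned.aligned_coords.reshape(aligned.n, -1) - aligned.consensus.ravel(), axis=1
        )
        np.testing.assert_allclose(norms, dists, rtol=0.01)
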