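"""Procrustes superimposition and tangent-space shape variables.

Size and shape are separated in the classical way: centroid size (CS) carries
scale, and shape is what remains after translating every configuration to the
origin, scaling it to unit CS, and rotating it onto an iteratively refined
consensus (generalized Procrustes analysis, GPA).  Aligned configurations are
then projected orthogonally onto the tangent plane of the unit shape sphere at
the consensus, giving Euclidean "shape variables" suitable for PCA and
discriminant analysis.

All wings in the motivating study are same-side wings, so reflections are
never introduced: every fitted rotation is proper (determinant +1).  An
opt-in flag on the pairwise fit allows reflection for mixed-side data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration with zero centroid size reaches a fit."""


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Scales linearly under uniform scaling and is invariant to rotation and
    translation.  A fully coincident configuration returns 0; downstream
    superimposition rejects such inputs.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    centered = coords - coords.mean(axis=0)
    return float(np.linalg.norm(centered))


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    cs = float(np.linalg.norm(centered))
    if cs < 1e-300:
        raise DegenerateConfigurationError("configuration has zero centroid size")
    return centered / cs, cs


def optimal_rotation(moving: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal matrix R minimizing ||moving @ R - target||_F via SVD.

    Both inputs are assumed centered.  Unless ``allow_reflection``, R is
    constrained to a proper rotation (det +1).
    """
    u, _, vt = np.linalg.svd(moving.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _rotation_angles(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper-rotation angles of each centered config in ``stack`` onto ``target``.

    Closed form for the planar case: theta = atan2(sum of cross products,
    sum of dot products); equivalent to the SVD solution restricted to
    det +1.
    """
    dots = np.einsum("nki,ki->n", stack, target)
    crosses = stack[:, :, 0] @ target[:, 1] - stack[:, :, 1] @ target[:, 0]
    return np.arctan2(crosses, dots)


def _rotate_stack(stack: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    rot = np.empty((len(angles), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = s
    rot[:, 1, 0] = -s
    rot[:, 1, 1] = c
    return np.einsum("nki,nij->nkj", stack, rot)


def fit_pair_superimposition(
    moving: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of one configuration onto another.

    Both are centered and scaled to unit centroid size; the moving one is then
    rotated to minimize the summed squared landmark distance to the target.
    Returns the aligned moving coordinates and the Procrustes distance (root
    summed squared residual).
    """
    mov = moving.coords if isinstance(moving, LandmarkConfiguration) else np.asarray(moving)
    tgt = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target)
    if mov.shape != tgt.shape:
        raise ValueError(f"landmark count mismatch: {mov.shape[0]} vs {tgt.shape[0]}")
    mov, _ = _center_scale(mov)
    tgt, _ = _center_scale(tgt)
    r = optimal_rotation(mov, tgt, allow_reflection=allow_reflection)
    aligned = mov @ r
    return aligned, float(np.linalg.norm(aligned - tgt))


@dataclass
class AlignedDataset:
    """GPA output: consensus, aligned configurations, sizes, shape variables."""

    dataset: LandmarkDataset
    consensus: np.ndarray            # (k, 2), centroid at origin, unit CS
    aligned_coords: np.ndarray       # (n, k, 2), each unit CS
    centroid_sizes: np.ndarray       # (n,), mm, recorded before scaling
    shape_variables: np.ndarray      # (n, 2k), tangent-plane deviations
    n_iterations: int = 0
    sum_of_squares_path: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.centroid_sizes)

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def group_labels(self) -> list[tuple[str, str]]:
        return self.dataset.group_labels

    @property
    def groups(self) -> list[tuple[str, str]]:
        return self.dataset.groups

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.dataset]


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting the consensus' major principal axis on x.

    The axis is defined modulo pi; the sign is fixed by requiring the landmark
    with the largest |x| to have positive x, so the output orientation is
    reproducible regardless of input orientation.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    major = vecs[:, -1]                      # largest eigenvalue last
    angle = np.arctan2(major[1], major[0])
    c, s = np.cos(-angle), np.sin(-angle)
    r = np.array([[c, s], [-s, c]])          # proper rotation by -angle
    rotated = consensus @ r
    imax = int(np.argmax(np.abs(rotated[:, 0])))
    if rotated[imax, 0] < 0:
        r = -r                               # extra pi rotation, still det +1
    return r


def generalized_procrustes(
    ds: LandmarkDataset, tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER
) -> AlignedDataset:
    """Generalized Procrustes analysis over a dataset.

    All configurations are centered and scaled to unit centroid size (sizes
    recorded first), then iteratively rotated onto a consensus initialized
    from the first configuration; the consensus is recomputed as the
    coordinate-wise mean, re-centered and re-scaled, until its change (root
    summed squared coordinate difference) drops below ``tol``.  The final
    consensus is rotated so its major principal axis lies on the x-axis,
    making the output orientation reproducible.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("GPA requires at least 2 specimens")
    raw = ds.coords_array()
    sizes = np.empty(n)
    stack = np.empty_like(raw)
    for i in range(n):
        stack[i], sizes[i] = _center_scale(raw[i])

    consensus = stack[0].copy()
    target = np.broadcast_to(consensus, stack.shape)
    ss_path: list[float] = []
    converged = False
    last_change = np.inf
    for iteration in range(1, max_iter + 1):
        angles = _rotation_angles(stack, consensus)
        stack = _rotate_stack(stack, angles)
        new_consensus = stack.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        ss_path.append(float(np.sum((stack - new_consensus) ** 2)))
        last_change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if last_change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {last_change:.3e})"
        )

    # reproducible orientation, then one final rotation pass onto the fixed consensus
    r = _principal_axis_rotation(consensus)
    consensus = consensus @ r
    stack = np.einsum("nki,ij->nkj", stack, r)
    angles = _rotation_angles(stack, consensus)
    stack = _rotate_stack(stack, angles)

    aligned = AlignedDataset(
        dataset=ds,
        consensus=consensus,
        aligned_coords=stack,
        centroid_sizes=sizes,
        shape_variables=np.empty((n, 2 * ds.k)),
        n_iterations=iteration,
        sum_of_squares_path=ss_path,
    )
    aligned.shape_variables = tangent_shape_variables(aligned)
    return aligned


def tangent_project(flat_coords: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Project flattened aligned coordinates onto the tangent plane at the consensus.

    The projection matrix is I - c c^T for the unit consensus vector c; the
    result is the deviation from the consensus within the tangent plane (the
    component along c is removed, and c itself maps to the zero vector).
    """
    c = consensus_flat / np.linalg.norm(consensus_flat)
    return flat_coords - np.outer(flat_coords @ c, c)


def tangent_shape_variables(aligned: AlignedDataset) -> np.ndarray:
    """Per-specimen 2k tangent shape variables of an aligned dataset."""
    flat = aligned.aligned_coords.reshape(aligned.n, -1)
    c = aligned.consensus.ravel()
    return tangent_project(flat, c)


def aligned_config_from_raw(
    coords: np.ndarray, aligned_ref: AlignedDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Superimpose a new configuration into an existing reference space.

    The configuration is centered, unit-scaled, rotated onto the reference
    consensus, and tangent-projected there.  Returns (aligned k x 2
    coordinates, 2k shape-variable vector).  The reference is not modified.
    """
    aligned, _ = fit_pair_superimposition(coords, aligned_ref.consensus)
    t = tangent_project(aligned.ravel()[None, :], aligned_ref.consensus.ravel())[0]
    return aligned, t
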