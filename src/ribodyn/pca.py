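"""Principal component analysis of backbone (C5') coordinate covariance.

Frames are superposed to the average structure of the selection (rotation
and translation removed), the 3N x 3N positional covariance matrix is
eigendecomposed, and frames can be projected onto the leading
eigenvectors. Conformational substates are found by complete-linkage
hierarchical clustering in the PC1-PC2 plane.

Covariance uses the population (n_frames) denominator by default; the
eigenvector sign is fixed by making each vector's largest-magnitude
component positive so outputs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import (
    InsufficientFramesError,
    ParameterError,
    TopologyMismatchError,
    ZeroVarianceError,
)
from .structure_io import AtomSelection, Trajectory
from .superpose import superpose_frames

__all__ = ["PcaModel", "PcProjection", "fit_pca", "pc_rmsf", "project", "cluster_pc_subspace", "extreme_frames"]


@dataclass(frozen=True)
class PcaModel:
    """Eigenstructure of the positional covariance of a selection."""

    mean: np.ndarray  # (n_sel, 3) average structure of the selection, Å
    eigenvalues: np.ndarray  # (3N,) descending, Å^2
    eigenvectors: np.ndarray  # (3N, 3N) orthonormal columns
    selection_indices: np.ndarray
    ddof: int = 0

    @property
    def fractional_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total

    @property
    def n_sel(self) -> int:
        return int(self.selection_indices.size)


@dataclass(frozen=True)
class PcProjection:
    """Per-frame scores on selected principal components (Å)."""

    scores: np.ndarray  # (n_frames, len(pcs))
    pcs: tuple[int, ...]  # 0-based component indices


def _superpose_to_mean(frames_sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit frames to their average structure (fit -> recompute mean, twice).

    The second pass makes the returned mean self-consistent: frames
    re-fitted onto it (as projection does) reproduce it to high accuracy.
    """
    all_idx = np.arange(frames_sel.shape[1])
    mean = frames_sel.mean(axis=0)
    for _ in range(2):
        fitted = superpose_frames(frames_sel, mean, all_idx)
        mean = fitted.mean(axis=0)
    return fitted, mean


def fit_pca(trajectory: Trajectory, selection: AtomSelection, ddof: int = 0) -> PcaModel:
    """Fit a PCA model to the selection's superposed coordinates.

    Frames are restricted to the selection, superposed onto their average
    structure, and the 3N x 3N covariance matrix of Cartesian coordinates
    is eigendecomposed. Fractional variance of component k is
    lambda_k / sum(lambda).
    """
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("PCA needs at least 2 frames")
    frames_sel = trajectory.frames[:, selection.indices, :]
    fitted, mean = _superpose_to_mean(frames_sel)

    x = (fitted - mean).reshape(trajectory.n_frames, -1)
    total_var = float(np.sum(x * x)) / max(trajectory.n_frames - ddof, 1)
    if total_var < 1e-12:
        raise ZeroVarianceError("all frames identical: covariance has zero variance")
    cov = (x.T @ x) / max(trajectory.n_frames - ddof, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # reproducible sign: largest-magnitude component of each vector positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    return PcaModel(
        mean=mean,
        eigenvalues=np.clip(evals, 0.0, None) + 0.0,
        eigenvectors=evecs,
        selection_indices=selection.indices,
        ddof=ddof,
    )


def pc_rmsf(model: PcaModel, pcs: list[int]) -> np.ndarray:
    """Per-atom RMSF contributed by the chosen components only.

    RMSF_i = sqrt(sum_k lambda_k * |v_k restricted to atom i|^2), so the
    full component set reproduces the total RMSF about the mean.
    """
    rank = model.eigenvalues.size
    for k in pcs:
        if not 0 <= k < rank:
            raise ParameterError(f"PC index {k} out of range (rank {rank})")
    n = model.n_sel
    acc = np.zeros(n)
    for k in pcs:
        v = model.eigenvectors[:, k].reshape(n, 3)
        acc += model.eigenvalues[k] * np.sum(v * v, axis=1)
    return np.sqrt(acc)


def project(
    trajectory: Trajectory, model: PcaModel, pcs: list[int]
) -> PcProjection:
    """Project frames onto principal components after superposing each
    frame onto the model's mean structure."""
    if trajectory.frames.shape[1] <= int(model.selection_indices.max()):
        raise TopologyMismatchError("trajectory does not cover the model selection")
    frames_sel = trajectory.frames[:, model.selection_indices, :]
    all_idx = np.arange(frames_sel.shape[1])
    fitted = superpose_frames(frames_sel, model.mean, all_idx)
    x = (fitted - model.mean).reshape(trajectory.n_frames, -1)
    scores = x @ model.eigenvectors[:, list(pcs)]
    return PcProjection(scores=scores, pcs=tuple(int(p) for p in pcs))


def cluster_pc_subspace(projection: PcProjection, k: int) -> np.ndarray:
    """Complete-linkage hierarchical clustering in the PC1-PC2 plane.

    Euclidean distances between per-frame (PC1, PC2) scores are clustered
    agglomeratively with the complete linkage rule (the hclust 'complete'
    method); returns per-frame labels 1..k.
    """
    scores = projection.scores
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ParameterError("clustering expects exactly 2 principal components")
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"cluster count k={k} must be in [1, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    z = linkage(scores, method="complete")
    return fcluster(z, t=k, criterion="maxclust")


def extreme_frames(model: PcaModel, pc: int, amplitude: float | None = None, n_steps: int = 2) -> np.ndarray:
    """Selection coordinates interpolated along one component.

    Returns (n_steps, n_sel, 3) coordinates from -amplitude to +amplitude
    along the component (default amplitude: 2 sqrt(lambda)); useful for
    writing the motion as a small multi-model PDB.
    """
    if amplitude is None:
        amplitude = 2.0 * float(np.sqrt(model.eigenvalues[pc]))
    v = model.eigenvectors[:, pc].reshape(model.n_sel, 3)
    scales = np.linspace(-amplitude, amplitude, max(n_steps, 2))
    return np.array([model.mean + s * v for s in scales])
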