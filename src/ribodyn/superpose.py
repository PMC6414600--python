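"""Least-squares superposition and RMSD/RMSF metrics.

Two reference conventions are used deliberately and exposed separately:
per-region RMSD series are measured against the *initial* structure after
fitting each frame onto the region's own heavy atoms, while RMSF (and PCA
elsewhere) superpose frames onto the *average* structure. No mass
weighting is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AnnotationError,
    DegenerateFitError,
    InsufficientFramesError,
)
from .structure_io import (
    AtomSelection,
    Structure,
    SubstructureAnnotation,
    Trajectory,
    select_atoms,
)

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "kabsch_rotation",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
]


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD of one region plus its summary statistics (Å)."""

    region: str
    values: np.ndarray
    reference: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        # population SD: the summary describes the sampled frames themselves
        return float(np.std(self.values))


@dataclass(frozen=True)
class RmsfProfile:
    """Per-atom (or per-residue) root-mean-square fluctuation in Å."""

    values: np.ndarray
    descriptor: str
    residue_indices: np.ndarray | None = None  # set for per-residue profiles


def _check_fit_points(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit points are collinear")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det +1) aligning centered ``mobile`` onto
    centered ``reference`` in the least-squares sense."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` fitting on ``fit_indices``.

    Returns the transformed copy of *all* mobile atoms and the RMSD over
    the fit atoms. Both inputs must have the same atom count.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DegenerateFitError("mobile and reference atom counts differ")
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices, dtype=int)
    mob_fit = mobile[fit_indices]
    ref_fit = reference[fit_indices]
    _check_fit_points(mob_fit)
    mob_center = mob_fit.mean(axis=0)
    ref_center = ref_fit.mean(axis=0)
    rot = kabsch_rotation(mob_fit - mob_center, ref_fit - ref_center)
    moved = (mobile - mob_center) @ rot + ref_center
    fit_rmsd = rmsd(moved[fit_indices], ref_fit)
    return moved, fit_rmsd


def superpose_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray,
) -> np.ndarray:
    """Batched Kabsch superposition of every frame onto ``reference``.

    Vectorized over frames (stacked 3x3 SVDs), so microsecond-scale frame
    counts stay cheap.
    """
    frames = np.asarray(frames, dtype=float)
    fit_indices = np.asarray(fit_indices, dtype=int)
    ref_fit = reference[fit_indices]
    _check_fit_points(ref_fit)
    ref_center = ref_fit.mean(axis=0)
    ref_c = ref_fit - ref_center

    mob_fit = frames[:, fit_indices, :]
    mob_center = mob_fit.mean(axis=1, keepdims=True)
    mob_c = mob_fit - mob_center

    h = np.einsum("fni,nj->fij", mob_c, ref_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    u_fixed = u.copy()
    u_fixed[:, :, 2] *= det[:, None]
    rot = np.einsum("fij,fjk->fik", u_fixed, vt)
    return np.einsum("fni,fij->fnj", frames - mob_center, rot) + ref_center


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between two conformers."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=-1))))


def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    region: str,
    annotation: SubstructureAnnotation,
    fit_region: str | None = None,
    descriptor: str = "heavy",
) -> RmsdSeries:
    """Per-frame RMSD of a substructure, fitted to its respective part.

    Each frame is superposed onto the reference using the fit region's
    atoms (by default the measured region itself), then the RMSD is taken
    over the measured region's atoms of the given descriptor (heavy atoms
    by default). The reference is meant to be the initial production
    frame.
    """
    if region not in annotation.regions:
        raise AnnotationError(f"region {region!r} not present in annotation")
    fit_name = fit_region if fit_region is not None else region
    if fit_name not in annotation.regions:
        raise AnnotationError(f"fit region {fit_name!r} not present in annotation")
    measure_sel = select_atoms(reference, descriptor, annotation.residues(region))
    fit_sel = select_atoms(reference, descriptor, annotation.residues(fit_name))

    fitted = superpose_frames(trajectory.frames, reference.coords, fit_sel.indices)
    diff = fitted[:, measure_sel.indices, :] - reference.coords[measure_sel.indices]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return RmsdSeries(region=region, values=values, reference="initial structure")


def rmsf_profile(
    trajectory: Trajectory,
    fit_selection: AtomSelection,
    measure_selection: AtomSelection,
    per_residue: bool = False,
    iterate: bool = False,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> RmsfProfile:
    """RMSF about the time-average position after fitting to the average.

    The average structure is obtained by one fit-to-frame-mean pass
    (fit frames to the raw frame mean, then recompute the mean); with
    ``iterate=True`` the fit/average cycle is repeated to convergence.
    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames; ``per_residue`` averages
    the per-atom values within each residue of the measured selection.
    """
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    frames = trajectory.frames
    mean = frames.mean(axis=0)
    fitted = superpose_frames(frames, mean, fit_selection.indices)
    mean = fitted.mean(axis=0)
    if iterate:
        for _ in range(max_iter):
            fitted = superpose_frames(frames, mean, fit_selection.indices)
            new_mean = fitted.mean(axis=0)
            if np.max(np.abs(new_mean - mean)) < tol:
                mean = new_mean
                break
            mean = new_mean

    disp = fitted[:, measure_selection.indices, :] - mean[measure_selection.indices]
    per_atom = np.sqrt(np.mean(np.sum(disp * disp, axis=2), axis=0))
    if not per_residue:
        return RmsfProfile(per_atom, measure_selection.descriptor)

    res_ids = trajectory.topology.residue_indices[measure_selection.indices]
    unique = np.unique(res_ids)
    values = np.array([per_atom[res_ids == r].mean() for r in unique])
    return RmsfProfile(values, measure_selection.descriptor, residue_indices=unique)
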