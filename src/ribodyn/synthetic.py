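"""Synthetic trajectories with planted, analytically known statistics.

This is a statistical emulator, not a simulator: no force field, no
integrator, no solvent. Each residue carries a small nucleotide-like atom
template (backbone phosphate/C5', a polar donor with its hydrogen, an
acceptor oxygen) arranged on an ideal helix. Frames fluctuate around
that reference with

* residue-level displacements from a one-factor-per-block Gaussian model,
  so any requested pairwise correlation rho inside a block appears in the
  DCCM by construction (loading sqrt(rho) on the shared factor);
* near-rigid "anchor" residues with tiny fluctuation so least-squares
  superposition is always well conditioned;
* optional global rigid-body drift (translation + small rotation), which
  every superposition-based analysis must remove;
* planted hydrogen-bond geometries toggled by seeded Bernoulli draws, so
  occupancy fractions are known exactly in expectation.

All randomness flows from the single recorded seed; a manifest written
with a fixture bundle is sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .errors import SyntheticSpecError
from .hbonds import find_attached_hydrogen, resolve_atom
from .structure_io import (
    Structure,
    SubstructureAnnotation,
    Trajectory,
    parse_annotation_text,
    write_pdb,
    write_trajectory_pdb,
)

__all__ = [
    "SyntheticSpec",
    "DEFAULT_TEMPLATE",
    "make_reference",
    "make_trajectory",
    "default_annotation",
    "write_fixture_bundle",
    "spec_from_manifest",
    "load_bundle",
]

# name, element, offset from the residue centre (C5') in Å
DEFAULT_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("P", "P", (-1.2, 0.8, -2.0)),
    ("O5'", "O", (-0.5, 0.3, -1.0)),
    ("C5'", "C", (0.0, 0.0, 0.0)),
    ("C1'", "C", (1.4, 0.4, 0.6)),
    ("N1", "N", (2.6, -0.3, 1.0)),
    ("N2", "N", (3.6, 0.5, 1.4)),
    ("H21", "H", (4.5, 0.2, 1.6)),
    ("O2", "O", (2.9, -1.6, 1.2)),
)

_HELIX_RADIUS = 9.0  # Å
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 20.0  # degrees per residue
_RESIDUE_NAMES = ("G", "A", "U", "C")

_HB_ON_DISTANCE = 2.9  # Å, donor-acceptor when the planted bond is formed
_HB_OFF_DISTANCE = 5.0  # Å, when it is broken


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic study; the seed is part of the spec."""

    n_residues: int = 40
    n_frames: int = 2000
    sigma: float = 0.5  # Å residue-level fluctuation scale
    atom_jitter: float = 0.05  # Å independent per-atom jitter
    correlation_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    hbond_schedule: tuple[
        tuple[tuple[int, str], tuple[int, str], float], ...
    ] = ()
    drift_amplitude: float = 0.0  # Å translational scale; rotation scales with it
    anchor_residues: tuple[int, ...] | None = None  # default: 3 at each end
    anchor_scale: float = 0.02
    atom_template: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
        DEFAULT_TEMPLATE
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise SyntheticSpecError("need at least 2 residues")
        if not any(name == "C5'" for name, _, _ in self.atom_template):
            raise SyntheticSpecError("atom template must contain a C5' atom")
        seen: set[int] = set()
        for residues, rho in self.correlation_blocks:
            if not -1.0 < rho < 1.0:
                raise SyntheticSpecError(f"target correlation {rho} outside (-1, 1)")
            if rho < 0.0 and len(residues) > 2:
                raise SyntheticSpecError(
                    "negative target correlation only feasible for 2-residue blocks"
                )
            if seen & set(residues):
                raise SyntheticSpecError("correlation blocks must not overlap")
            seen |= set(residues)
            for r in residues:
                if not 1 <= r <= self.n_residues:
                    raise SyntheticSpecError(f"block residue {r} out of range")
        for _, _, occupancy in self.hbond_schedule:
            if not 0.0 <= occupancy <= 1.0:
                raise SyntheticSpecError("occupancy fractions must lie in [0, 1]")

    def anchors(self) -> tuple[int, ...]:
        if self.anchor_residues is not None:
            return self.anchor_residues
        n = self.n_residues
        ends = min(3, n // 2)
        return tuple(range(1, ends + 1)) + tuple(range(n - ends + 1, n + 1))


def _rotation_z(angle_deg: float) -> np.ndarray:
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_reference(spec: SyntheticSpec) -> Structure:
    """Idealized helical reference structure for a spec (deterministic)."""
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    coords: list[np.ndarray] = []
    for r in range(1, spec.n_residues + 1):
        theta = _HELIX_TWIST * (r - 1)
        rot = _rotation_z(theta)
        centre = np.array(
            [
                _HELIX_RADIUS * np.cos(np.radians(theta)),
                _HELIX_RADIUS * np.sin(np.radians(theta)),
                _HELIX_RISE * (r - 1),
            ]
        )
        for name, element, offset in spec.atom_template:
            names.append(name)
            elements.append(element)
            res_idx.append(r)
            res_names.append(_RESIDUE_NAMES[(r - 1) % len(_RESIDUE_NAMES)])
            coords.append(centre + rot @ np.asarray(offset, dtype=float))
    n = len(names)
    return Structure(
        tuple(names),
        tuple(elements),
        np.array(res_idx, dtype=int),
        tuple(res_names),
        ("A",) * n,
        ("",) * n,
        np.asarray(coords),
    )


def rigid_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the rigid-body subspace at a configuration.

    Returns a (3N, 6) matrix whose columns span the three translations and
    three infinitesimal rotations of the point set; displacement fields
    orthogonal to these columns are exactly invisible to least-squares
    superposition (to first order in the displacement).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    centered = points - points.mean(axis=0)
    columns = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        columns.append(t.ravel())
    for axis in np.eye(3):
        columns.append(np.cross(centered, axis).ravel())
    q, r = np.linalg.qr(np.array(columns).T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def _absorb_rigid_component(
    disp: np.ndarray, centers: np.ndarray, anchors: tuple[int, ...]
) -> np.ndarray:
    """Make each frame's residue-displacement field rigid-motion free.

    The net translation/rotation of the field is projected out by adding a
    least-norm correction to the anchor residues only, so the planted
    correlation structure of the non-anchor residues is untouched while
    superposition onto the reference becomes the identity in expectation.
    """
    if len(anchors) < 2:
        return disp
    q = rigid_basis(centers)
    n_res = centers.shape[0]
    anchor_dofs = np.concatenate(
        [np.arange(3 * (a - 1), 3 * (a - 1) + 3) for a in anchors]
    )
    m = q[anchor_dofs, :].T  # (6, 3*n_anchor)
    pinv = np.linalg.pinv(m)
    flat = disp.reshape(disp.shape[0], 3 * n_res)
    coeff = flat @ q  # rigid coefficients per frame
    correction = -coeff @ pinv.T
    flat[:, anchor_dofs] += correction
    return flat.reshape(disp.shape)


def _random_rotation(rng: np.random.Generator, angle_scale: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(scale=angle_scale)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def make_trajectory(reference: Structure, spec: SyntheticSpec) -> Trajectory:
    """Sample a trajectory realizing the spec's planted statistics.

    Residues move rigidly with their displacement draw plus small per-atom
    jitter; hydrogen-bond acceptors in the schedule are repositioned along
    the donor's D-H axis (2.9 Å when "on", 5.0 Å when "off"); an optional
    global rigid drift is applied last.
    """
    if reference.residue_count != spec.n_residues:
        raise SyntheticSpecError("reference does not match spec residue count")
    n_frames = spec.n_frames
    n_res = spec.n_residues
    ss = np.random.SeedSequence(spec.seed)
    rng_disp, rng_hb, rng_drift = (np.random.default_rng(s) for s in ss.spawn(3))

    sigma_res = np.full(n_res, spec.sigma)
    for r in spec.anchors():
        sigma_res[r - 1] *= spec.anchor_scale

    eps = rng_disp.normal(size=(n_frames, n_res, 3))
    disp = eps.copy()
    for residues, rho in spec.correlation_blocks:
        z = rng_disp.normal(size=(n_frames, 3))
        root = np.sqrt(abs(rho))
        tail = np.sqrt(1.0 - abs(rho))
        for pos, r in enumerate(residues):
            sign = -1.0 if (rho < 0.0 and pos % 2 == 1) else 1.0
            disp[:, r - 1, :] = sign * root * z + tail * eps[:, r - 1, :]
    disp *= sigma_res[None, :, None]

    # anchors absorb each frame's net rigid component so superposition-based
    # analyses (DCCM, PCA, RMSF) see the planted statistics unbiased
    c5p = np.array(
        [
            reference.coords[resolve_atom(reference, r, "C5'")]
            for r in range(1, n_res + 1)
        ]
    )
    disp = _absorb_rigid_component(disp, c5p, spec.anchors())

    atoms_per_res = [reference.atoms_of_residue(r) for r in range(1, n_res + 1)]
    frames = np.broadcast_to(
        reference.coords, (n_frames, reference.n_atoms, 3)
    ).copy()
    for r, atom_idx in enumerate(atoms_per_res):
        frames[:, atom_idx, :] += disp[:, r, None, :]
    jitter = rng_disp.normal(scale=spec.atom_jitter, size=frames.shape)
    jitter *= sigma_res[reference.residue_indices - 1, None] / spec.sigma
    frames += jitter

    for (dres, dname), (ares, aname), occupancy in spec.hbond_schedule:
        d = resolve_atom(reference, dres, dname)
        a = resolve_atom(reference, ares, aname)
        h = find_attached_hydrogen(reference, d)
        on = rng_hb.random(n_frames) < occupancy
        u = frames[:, h, :] - frames[:, d, :]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dist = np.where(on, _HB_ON_DISTANCE, _HB_OFF_DISTANCE)
        frames[:, a, :] = frames[:, d, :] + dist[:, None] * u

    if spec.drift_amplitude > 0.0:
        angle_scale = spec.drift_amplitude / 100.0  # radians; modest tumbling
        centre = reference.coords.mean(axis=0)
        for f in range(n_frames):
            rot = _random_rotation(rng_drift, angle_scale)
            shift = rng_drift.normal(scale=spec.drift_amplitude, size=3)
            frames[f] = (frames[f] - centre) @ rot.T + centre + shift

    return Trajectory(reference, frames)


def default_annotation(n_residues: int) -> SubstructureAnnotation:
    """Contiguous named regions in riboswitch style plus 'whole'.

    Splits the chain into seven roughly equal stretches named after the
    aptamer substructures (P1, P2, P3-L3, J2-4, J3-2, P4-P5, L5); purely
    a labelling convenience for synthetic studies.
    """
    names = ("P1", "P2", "P3-L3", "J2-4", "J3-2", "P4-P5", "L5")
    bounds = np.linspace(1, n_residues + 1, len(names) + 1).astype(int)
    regions = {
        "whole": frozenset(range(1, n_residues + 1)),
    }
    for i, name in enumerate(names):
        lo, hi = bounds[i], bounds[i + 1]
        if hi > lo:
            regions[name] = frozenset(range(lo, hi))
    return SubstructureAnnotation(regions)


def _annotation_text(annotation: SubstructureAnnotation) -> str:
    lines = []
    for name, residues in annotation.regions.items():
        ordered = sorted(residues)
        ranges = []
        start = prev = ordered[0]
        for r in ordered[1:]:
            if r == prev + 1:
                prev = r
                continue
            ranges.append((start, prev))
            start = prev = r
        ranges.append((start, prev))
        spec = ", ".join(f"{a}-{b}" if a != b else str(a) for a, b in ranges)
        lines.append(f"{name}: {spec}")
    return "\n".join(lines) + "\n"


def _spec_to_jsonable(spec: SyntheticSpec) -> dict:
    payload = asdict(spec)
    payload["atom_template"] = [
        [name, element, list(offset)] for name, element, offset in spec.atom_template
    ]
    payload["correlation_blocks"] = [
        [list(residues), rho] for residues, rho in spec.correlation_blocks
    ]
    payload["hbond_schedule"] = [
        [list(donor), list(acceptor), occ]
        for donor, acceptor, occ in spec.hbond_schedule
    ]
    if spec.anchor_residues is not None:
        payload["anchor_residues"] = list(spec.anchor_residues)
    return payload


def spec_from_manifest(manifest: dict) -> SyntheticSpec:
    """Rebuild a spec from a bundle manifest; refuses manifests without a seed."""
    payload = dict(manifest.get("spec", manifest))
    if "seed" not in payload or payload["seed"] is None:
        raise SyntheticSpecError("manifest lacks a seed: cannot regenerate")
    if "atom_template" in payload:
        payload["atom_template"] = tuple(
            (name, element, tuple(offset))
            for name, element, offset in payload["atom_template"]
        )
    if "correlation_blocks" in payload:
        payload["correlation_blocks"] = tuple(
            (tuple(residues), float(rho)) for residues, rho in payload["correlation_blocks"]
        )
    if "hbond_schedule" in payload:
        payload["hbond_schedule"] = tuple(
            ((d[0], d[1]), (a[0], a[1]), float(occ))
            for d, a, occ in payload["hbond_schedule"]
        )
    if payload.get("anchor_residues") is not None:
        payload["anchor_residues"] = tuple(payload["anchor_residues"])
    unknown = set(payload) - set(SyntheticSpec.__dataclass_fields__)
    if unknown:
        raise SyntheticSpecError(f"unknown spec fields: {sorted(unknown)}")
    return SyntheticSpec(**payload)


def write_fixture_bundle(spec: SyntheticSpec, directory: str) -> dict:
    """Write a complete regenerable fixture bundle; returns the manifest.

    Files: reference.pdb, trajectory.pdb (multi-model), annotation.txt,
    pairs.csv (the planted donor/acceptor schedule) and manifest.json
    containing the full spec including the seed.
    """
    os.makedirs(directory, exist_ok=True)
    reference = make_reference(spec)
    trajectory = make_trajectory(reference, spec)
    annotation = default_annotation(spec.n_residues)

    paths = {
        "reference": os.path.join(directory, "reference.pdb"),
        "trajectory": os.path.join(directory, "trajectory.pdb"),
        "annotation": os.path.join(directory, "annotation.txt"),
        "pairs": os.path.join(directory, "pairs.csv"),
    }
    write_pdb(reference, paths["reference"])
    write_trajectory_pdb(trajectory, paths["trajectory"])
    with open(paths["annotation"], "w") as handle:
        handle.write(_annotation_text(annotation))
    with open(paths["pairs"], "w") as handle:
        handle.write("donor_residue,donor_atom,acceptor_residue,acceptor_atom,planted_occupancy\n")
        for (dres, dname), (ares, aname), occ in spec.hbond_schedule:
            handle.write(f"{dres},{dname},{ares},{aname},{occ}\n")

    hashes = {}
    for key, path in paths.items():
        with open(path, "rb") as handle:
            hashes[key] = hashlib.sha256(handle.read()).hexdigest()
    manifest = {"spec": _spec_to_jsonable(spec), "files": hashes}
    with open(os.path.join(directory, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def load_bundle(directory: str):
    """Load (reference, trajectory, annotation, pairs) from a bundle."""
    from .structure_io import load_annotation, read_multimodel_trajectory, read_pdb

    reference = read_pdb(os.path.join(directory, "reference.pdb"))
    trajectory = read_multimodel_trajectory(
        os.path.join(directory, "trajectory.pdb"), reference
    )
    annotation = load_annotation(os.path.join(directory, "annotation.txt"), reference)
    pairs = []
    pairs_path = os.path.join(directory, "pairs.csv")
    if os.path.exists(pairs_path):
        with open(pairs_path) as handle:
            next(handle)
            for line in handle:
                dres, dname, ares, aname, occ = line.strip().split(",")
                pairs.append(((int(dres), dname), (int(ares), aname), float(occ)))
    return reference, trajectory, annotation, pairs
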