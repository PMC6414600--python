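"""Geometric hydrogen-bond detection, occupancy and residue contact maps.

A hydrogen bond is scored with the classic geometric criterion: the
distance between the two polar heavy atoms (donor D, acceptor A) must be
below a cutoff (default 3.5 Å) and the D-H...A angle must deviate from
linearity by at most an angular cutoff (default 30°, i.e. the D-H-A angle
must be ≥ 150°). The angular cutoff is a *deviation from linearity* — the
opposite reading would invert every occupancy, so this convention is
stated here prominently.

Donor and acceptor atoms are polar N/O heavy atoms; a donor must carry at
least one hydrogen, which is inferred geometrically from the topology
(hydrogen within a covalent-bond distance of the donor) when explicit
bonds are absent, as is typical for plain PDB inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import HBondDefinitionError, ParameterError, SelectionError
from .structure_io import Structure, Trajectory, select_atoms

__all__ = [
    "HBondCriterion",
    "OccupancyRecord",
    "DistanceStat",
    "ContactMask",
    "resolve_atom",
    "find_attached_hydrogen",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "distance_stats",
    "contact_mask",
]

_POLAR_ELEMENTS = {"N", "O"}
_COVALENT_H_CUTOFF = 1.25  # Å, upper bound for an X-H covalent bond


@dataclass(frozen=True)
class HBondCriterion:
    distance_cutoff: float = 3.5  # Å between donor and acceptor heavy atoms
    angle_cutoff: float = 30.0  # degrees of deviation from D-H-A linearity

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ParameterError("hydrogen-bond cutoffs must be strictly positive")


@dataclass(frozen=True)
class OccupancyRecord:
    donor: str
    acceptor: str
    frames_observed: int
    n_frames: int

    @property
    def occupancy(self) -> float:
        """Percent of frames in which the bond satisfied the criterion."""
        return 100.0 * self.frames_observed / self.n_frames


@dataclass(frozen=True)
class DistanceStat:
    pair: tuple[str, str]
    mean: float  # Å
    std: float  # Å, population convention


@dataclass(frozen=True)
class ContactMask:
    """Persistent-contact matrix over residues.

    ``mask[i, j]`` is true when the minimum heavy-atom distance between
    residues i and j stayed below ``cutoff`` in at least a ``persistence``
    fraction of frames. The diagonal is true by convention.
    """

    mask: np.ndarray
    residue_indices: np.ndarray
    cutoff: float = 4.5
    persistence: float = 0.75
    contact_fraction: np.ndarray | None = field(default=None, compare=False)


def resolve_atom(structure: Structure, residue_index: int, atom_name: str) -> int:
    """Resolve (residue index, atom name) to a flat atom index."""
    for i in structure.atoms_of_residue(int(residue_index)):
        if structure.atom_names[i] == atom_name:
            return int(i)
    raise SelectionError(
        f"atom {atom_name!r} not found in residue {residue_index}"
    )


def find_attached_hydrogen(structure: Structure, donor_index: int) -> int:
    """Find a hydrogen covalently attached to a donor heavy atom.

    Uses a name/distance heuristic on the reference coordinates: the
    nearest hydrogen of the same residue within 1.25 Å.
    """
    donor_index = int(donor_index)
    residue = structure.residue_indices[donor_index]
    best, best_d = -1, np.inf
    for i in structure.atoms_of_residue(int(residue)):
        if structure.elements[i] not in ("H", "D"):
            continue
        d = float(np.linalg.norm(structure.coords[i] - structure.coords[donor_index]))
        if d < best_d:
            best, best_d = int(i), d
    if best < 0 or best_d > _COVALENT_H_CUTOFF:
        raise HBondDefinitionError(
            f"donor atom {structure.atom_names[donor_index]!r} of residue "
            f"{residue} has no attached hydrogen"
        )
    return best


def _dha_deviation(frame: np.ndarray, d: int, h: int, a: int) -> float:
    """Deviation of the D-H-A angle from linearity, in degrees."""
    v1 = frame[d] - frame[h]
    v2 = frame[a] - frame[h]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def detect_hbonds_frame(
    frame: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criterion: HBondCriterion = HBondCriterion(),
) -> set[tuple[int, int]]:
    """Hydrogen bonds present in one frame.

    ``donors`` is a list of (donor heavy atom, attached hydrogen) index
    pairs; ``acceptors`` a list of acceptor heavy-atom indices. Returns
    the set of (donor, acceptor) hits; a donor is never paired with
    itself.
    """
    frame = np.asarray(frame, dtype=float)
    hits: set[tuple[int, int]] = set()
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(frame[d] - frame[a]) >= criterion.distance_cutoff:
                continue
            if _dha_deviation(frame, d, h, a) <= criterion.angle_cutoff:
                hits.add((int(d), int(a)))
    return hits


def _resolve_pair(structure, pair):
    """Pair spec: ((res, donor_name), (res, acceptor_name)) or atom indices."""
    (dres, dname), (ares, aname) = pair
    d = resolve_atom(structure, dres, dname)
    a = resolve_atom(structure, ares, aname)
    return d, a


def hbond_occupancy(
    trajectory: Trajectory,
    pairs: list[tuple[tuple[int, str], tuple[int, str]]],
    criterion: HBondCriterion = HBondCriterion(),
) -> list[OccupancyRecord]:
    """Occupancy (% of frames) of user-specified donor/acceptor pairs.

    Each pair is ((residue, donor atom name), (residue, acceptor atom
    name)); the donor's hydrogen is inferred from the topology. Occupancy
    is 100 x hits / n_frames, vectorized over frames.
    """
    topo = trajectory.topology
    records = []
    for pair in pairs:
        d, a = _resolve_pair(topo, pair)
        h = find_attached_hydrogen(topo, d)
        frames = trajectory.frames
        dist = np.linalg.norm(frames[:, d] - frames[:, a], axis=1)
        v1 = frames[:, d] - frames[:, h]
        v2 = frames[:, a] - frames[:, h]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        hit = (dist < criterion.distance_cutoff) & (180.0 - angle <= criterion.angle_cutoff)
        (dres, dname), (ares, aname) = pair
        records.append(
            OccupancyRecord(
                donor=f"{dres}:{dname}",
                acceptor=f"{ares}:{aname}",
                frames_observed=int(hit.sum()),
                n_frames=trajectory.n_frames,
            )
        )
    return records


def distance_stats(
    trajectory: Trajectory,
    pairs: list[tuple[tuple[int, str], tuple[int, str]]],
) -> list[DistanceStat]:
    """Mean and (population) SD of atom-pair distances over all frames."""
    topo = trajectory.topology
    stats = []
    for pair in pairs:
        i, j = _resolve_pair(topo, pair)
        dist = np.linalg.norm(trajectory.frames[:, i] - trajectory.frames[:, j], axis=1)
        (ires, iname), (jres, jname) = pair
        stats.append(
            DistanceStat(
                pair=(f"{ires}:{iname}", f"{jres}:{jname}"),
                mean=float(dist.mean()),
                std=float(dist.std()),
            )
        )
    return stats


def contact_mask(
    trajectory: Trajectory,
    cutoff: float = 4.5,
    persistence: float = 0.75,
    descriptor: str = "heavy",
) -> ContactMask:
    """Persistent residue-residue contacts over a trajectory.

    A residue pair is in contact in a frame when the minimum distance
    between their selected atoms (heavy atoms by default, a C5'-only
    alternative via ``descriptor``) is below ``cutoff``; the mask is true
    when that held for at least a ``persistence`` fraction of frames
    (inclusive threshold).
    """
    if not (0.0 <= persistence <= 1.0):
        raise ParameterError("persistence must lie in [0, 1]")
    topo = trajectory.topology
    sel = select_atoms(topo, descriptor)
    res_of_atom = topo.residue_indices[sel.indices]
    residues = np.unique(res_of_atom)
    n_res = residues.size

    # order selected atoms by residue so each residue is one contiguous block
    order = np.argsort(res_of_atom, kind="stable")
    atom_idx = sel.indices[order]
    res_sorted = res_of_atom[order]
    starts = np.searchsorted(res_sorted, residues)

    counts = np.zeros((n_res, n_res), dtype=int)
    for f in range(trajectory.n_frames):
        coords = trajectory.frames[f, atom_idx]
        d = cdist(coords, coords)
        per_res_rows = np.minimum.reduceat(d, starts, axis=0)
        per_res = np.minimum.reduceat(per_res_rows, starts, axis=1)
        counts += per_res < cutoff
    fraction = counts / trajectory.n_frames
    mask = fraction >= persistence
    np.fill_diagonal(mask, True)
    return ContactMask(
        mask=mask,
        residue_indices=residues,
        cutoff=cutoff,
        persistence=persistence,
        contact_fraction=fraction,
    )
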