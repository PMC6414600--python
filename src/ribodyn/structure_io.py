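"""Structures, trajectories, selections and substructure annotations.

The on-disk formats are deliberately plain text: single-model PDB for
topologies, multi-model PDB for trajectories (one MODEL block per frame),
and a small ``name: range-list`` grammar for substructure annotations::

    # comment
    P1: 1-8, 92-99
    L5: 55-62

Residue numbering is 1-based author numbering throughout, matching PDB
conventions and the nucleotide labels used for riboswitch substructures
(P1, P2, P3-L3, J2-4, L5, ...). Only model 1 of a PDB file is a topology;
multi-model files become trajectories only when read explicitly as such.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import (
    AnnotationError,
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    TopologyMismatchError,
)

__all__ = [
    "Structure",
    "Trajectory",
    "SubstructureAnnotation",
    "AtomSelection",
    "read_pdb",
    "read_multimodel_trajectory",
    "write_pdb",
    "write_trajectory_pdb",
    "select_atoms",
    "load_annotation",
    "parse_annotation_text",
    "concat_trajectories",
]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Structure:
    """A single conformer: parallel per-atom arrays plus coordinates in Å."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    residue_indices: np.ndarray  # (n_atoms,) int, author numbering
    residue_names: tuple[str, ...]
    chain_ids: tuple[str, ...]
    icodes: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) float, Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise FormatError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite coordinates in structure")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(
            self, "residue_indices", np.asarray(self.residue_indices, dtype=int)
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom residue identity (chain, author index, insertion code)."""
        return list(zip(self.chain_ids, self.residue_indices.tolist(), self.icodes))

    def unique_residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for key in self.residue_keys():
            seen.setdefault(key)
        return list(seen)

    @property
    def residue_count(self) -> int:
        return len(self.unique_residues())

    def residue_index_set(self) -> frozenset[int]:
        return frozenset(self.residue_indices.tolist())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.atom_names,
            self.elements,
            self.residue_indices,
            self.residue_names,
            self.chain_ids,
            self.icodes,
            np.asarray(coords, dtype=float),
        )

    def atoms_of_residue(self, residue_index: int) -> np.ndarray:
        return np.nonzero(self.residue_indices == residue_index)[0]


@dataclass
class Trajectory:
    """Ordered frames of coordinates bound to a topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; atom order is the
    topology's atom order in every frame.
    """

    topology: Structure
    frames: np.ndarray
    frame_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyMismatchError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise TopologyMismatchError("a trajectory needs at least one frame")
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels, dtype=int)
            if self.frame_labels.shape != (self.n_frames,):
                raise TopologyMismatchError("frame_labels length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])


@dataclass(frozen=True)
class SubstructureAnnotation:
    """Named residue sets (regions may overlap, e.g. 'whole' vs 'P3-L3')."""

    regions: dict[str, frozenset[int]]

    def residues(self, region: str) -> frozenset[int]:
        try:
            return self.regions[region]
        except KeyError:
            raise AnnotationError(f"region {region!r} not present in annotation") from None

    def names(self) -> list[str]:
        return list(self.regions)


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: the descriptor and sorted unique indices."""

    descriptor: str
    indices: np.ndarray
    residues: frozenset[int] | None = None

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _prevalidate_pdb(path: str) -> None:
    """Check coordinate fields of ATOM/HETATM records; name the bad line."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"{path}: truncated coordinate record at line {lineno}")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise FormatError(
                            f"{path}: unparseable coordinate at line {lineno}"
                        ) from None


def _model_to_structure(model) -> Structure:
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    chains: list[str] = []
    icodes: list[str] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "", "A"):
                    continue  # single-conformer convention: altloc A or blank
                names.append(atom.get_name())
                element = (atom.element or "").strip().upper()
                if not element:
                    element = atom.get_name().strip()[:1].upper()
                elements.append(element)
                res_idx.append(int(resseq))
                res_names.append(residue.get_resname().strip())
                chains.append(chain.id)
                icodes.append(icode.strip())
                coords.append(atom.get_coord())
    if not coords:
        raise EmptyStructureError("model contains no atoms")
    return Structure(
        tuple(names),
        tuple(elements),
        np.array(res_idx, dtype=int),
        tuple(res_names),
        tuple(chains),
        tuple(icodes),
        np.asarray(coords, dtype=float),
    )


def _parse_models(path: str):
    _prevalidate_pdb(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            pdb_structure = parser.get_structure("pdb", path)
        except Exception as exc:  # Bio.PDB raises several construction errors
            raise FormatError(f"{path}: {exc}") from exc
    models = list(pdb_structure)
    if not models:
        raise EmptyStructureError(f"{path}: no models found")
    return models


def read_pdb(path: str) -> Structure:
    """Read model 1 of a PDB file as a single-conformer :class:`Structure`.

    ATOM and HETATM records are both kept; alternate locations other than
    'A'/blank are discarded; insertion codes are preserved in residue
    identity.
    """
    return _model_to_structure(_parse_models(path)[0])


def read_multimodel_trajectory(path: str, topology: Structure) -> Trajectory:
    """Read a multi-model PDB as a trajectory over ``topology``'s atoms.

    Every MODEL block must contain the same atoms in the same order as the
    topology; a mismatch raises :class:`TopologyMismatchError` naming the
    offending model.
    """
    models = _parse_models(path)
    frames = np.empty((len(models), topology.n_atoms, 3), dtype=float)
    labels = []
    for pos, model in enumerate(models):
        structure = _model_to_structure(model)
        if structure.n_atoms != topology.n_atoms:
            raise TopologyMismatchError(
                f"{path}: model {model.id + 1} has {structure.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        if structure.atom_names != topology.atom_names:
            raise TopologyMismatchError(
                f"{path}: model {model.id + 1} atom names differ from topology"
            )
        frames[pos] = structure.coords
        labels.append(model.id + 1)
    return Trajectory(topology, frames, np.array(labels, dtype=int))


def _format_atom_line(serial, name, resname, chain, resseq, icode, xyz, element) -> str:
    # PDB fixed columns; 4-char atom names start in column 13, shorter in 14
    if len(name) >= 4:
        name_field = name[:4]
    else:
        name_field = f" {name:<3s}"
    record = "HETATM" if resname in {"HOH", "TPP", "MG"} else "ATOM  "
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def _write_model(handle: io.TextIOBase, structure: Structure, coords: np.ndarray) -> None:
    for i in range(structure.n_atoms):
        handle.write(
            _format_atom_line(
                (i % 99999) + 1,
                structure.atom_names[i],
                structure.residue_names[i],
                structure.chain_ids[i],
                int(structure.residue_indices[i]),
                structure.icodes[i],
                coords[i],
                structure.elements[i],
            )
        )


def write_pdb(structure: Structure, path: str) -> None:
    """Write a single-model PDB file (coordinates at PDB 1e-3 Å precision)."""
    with open(path, "w") as handle:
        _write_model(handle, structure, structure.coords)
        handle.write("END\n")


def write_trajectory_pdb(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB, one MODEL block per frame."""
    with open(path, "w") as handle:
        for f in range(trajectory.n_frames):
            handle.write(f"MODEL     {f + 1:>4d}\n")
            _write_model(handle, trajectory.topology, trajectory.frames[f])
            handle.write("ENDMDL\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def select_atoms(
    structure: Structure,
    descriptor: str,
    residues: Iterable[int] | None = None,
) -> AtomSelection:
    """Resolve a selection descriptor to sorted atom indices.

    ``descriptor`` is either an exact atom name (e.g. ``"C5'"``), the
    keyword ``"heavy"`` (everything except hydrogen/deuterium) or ``"all"``.
    ``residues`` optionally restricts the selection to a residue-index set.
    """
    names = np.array(structure.atom_names)
    elements = np.array(structure.elements)
    if descriptor == "heavy":
        mask = ~np.isin(elements, list(_HYDROGEN_ELEMENTS))
    elif descriptor == "all":
        mask = np.ones(structure.n_atoms, dtype=bool)
    else:
        mask = names == descriptor
    if residues is not None:
        residue_set = frozenset(int(r) for r in residues)
        mask &= np.isin(structure.residue_indices, list(residue_set))
    else:
        residue_set = None
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise EmptySelectionError(
            f"selection {descriptor!r} matched no atoms"
            + (f" within residues {sorted(residue_set)}" if residue_set else "")
        )
    return AtomSelection(descriptor, indices, residue_set)


# ---------------------------------------------------------------------------
# Substructure annotations
# ---------------------------------------------------------------------------


def parse_annotation_text(text: str) -> dict[str, frozenset[int]]:
    """Parse the ``name: 1-8, 92-99`` annotation grammar (inclusive ranges)."""
    regions: dict[str, frozenset[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise FormatError(f"annotation line {lineno}: expected 'name: ranges'")
        name, _, spec = line.partition(":")
        name = name.strip()
        if not name:
            raise FormatError(f"annotation line {lineno}: empty region name")
        if name in regions:
            raise FormatError(f"annotation line {lineno}: duplicate region {name!r}")
        residues: set[int] = set()
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            if "-" in token[1:]:  # allow negative single numbers just in case
                lo_s, _, hi_s = token.partition("-")
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise FormatError(
                        f"annotation line {lineno}: bad range {token!r}"
                    ) from None
                if hi < lo:
                    raise FormatError(f"annotation line {lineno}: inverted range {token!r}")
                residues.update(range(lo, hi + 1))
            else:
                try:
                    residues.add(int(token))
                except ValueError:
                    raise FormatError(
                        f"annotation line {lineno}: bad residue {token!r}"
                    ) from None
        if not residues:
            raise FormatError(f"annotation line {lineno}: region {name!r} is empty")
        regions[name] = frozenset(residues)
    return regions


def load_annotation(path: str, structure: Structure) -> SubstructureAnnotation:
    """Load an annotation file and validate it against a topology."""
    with open(path) as handle:
        regions = parse_annotation_text(handle.read())
    known = structure.residue_index_set()
    for name, residues in regions.items():
        missing = residues - known
        if missing:
            raise AnnotationError(
                f"region {name!r} references residues absent from the "
                f"structure: {sorted(missing)[:5]}"
            )
    return SubstructureAnnotation(regions)


# ---------------------------------------------------------------------------
# Trajectory concatenation
# ---------------------------------------------------------------------------


def concat_trajectories(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Concatenate trajectories that share a topology, preserving frame order.

    This mirrors the common practice of pooling independent replica
    simulations into one sample of conformations when only structural
    (not temporal) statistics are wanted.
    """
    if not trajectories:
        raise TopologyMismatchError("nothing to concatenate")
    first = trajectories[0]
    for traj in trajectories[1:]:
        if traj.topology.atom_names != first.topology.atom_names:
            raise TopologyMismatchError("topologies differ between trajectories")
    frames = np.concatenate([t.frames for t in trajectories], axis=0)
    return Trajectory(first.topology, frames)
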