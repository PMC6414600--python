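"""Pairwise comparison of two crystal structures of homologous RNAs.

Residue correspondence between the two chains is established by a global
sequence alignment of the nucleotide one-letter sequences; for each
aligned residue pair the atoms present (by name) in both residues are
matched. The structures are then superposed by a least-squares fit on the
matched RNA heavy atoms, and RMSDs are reported for the RNA and,
optionally, for a bound ligand whose atoms are matched by name. This is
how the free/bound aptamer crystal forms (e.g. the bacterial and plant
thiamine-pyrophosphate riboswitch structures) are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner

from .errors import SelectionError
from .structure_io import Structure
from .superpose import kabsch_rotation, rmsd

__all__ = ["CrystalComparison", "compare_crystal_structures"]

_NUCLEOTIDES = {"A", "G", "C", "U", "DA", "DG", "DC", "DT", "T"}


@dataclass(frozen=True)
class CrystalComparison:
    rna_rmsd: float  # Å over matched RNA heavy atoms after superposition
    ligand_rmsd: float | None  # Å over matched ligand atoms, same fit
    n_rna_atoms: int
    n_ligand_atoms: int
    n_aligned_residues: int


def _nucleotide_residues(structure: Structure) -> list[tuple[tuple[str, int, str], str]]:
    """Ordered (residue key, one-letter code) for nucleotide residues."""
    out = []
    seen = set()
    for i in range(structure.n_atoms):
        key = (
            structure.chain_ids[i],
            int(structure.residue_indices[i]),
            structure.icodes[i],
        )
        if key in seen:
            continue
        seen.add(key)
        name = structure.residue_names[i].strip().upper()
        if name in _NUCLEOTIDES:
            out.append((key, name[-1]))
    return out


def _residue_atoms(structure: Structure, key: tuple[str, int, str]) -> dict[str, int]:
    chain, idx, icode = key
    atoms = {}
    for i in range(structure.n_atoms):
        if (
            structure.chain_ids[i] == chain
            and int(structure.residue_indices[i]) == idx
            and structure.icodes[i] == icode
            and structure.elements[i] not in ("H", "D")
        ):
            atoms[structure.atom_names[i]] = i
    return atoms


def _ligand_atoms(structure: Structure, resname: str) -> dict[str, int]:
    atoms = {}
    for i in range(structure.n_atoms):
        if (
            structure.residue_names[i].strip().upper() == resname.upper()
            and structure.elements[i] not in ("H", "D")
        ):
            atoms[structure.atom_names[i]] = i
    return atoms


def compare_crystal_structures(
    a: Structure,
    b: Structure,
    ligand_resname: str | None = None,
) -> CrystalComparison:
    """Superpose two homologous RNA structures and report heavy-atom RMSDs.

    The fit is computed on the RNA heavy atoms shared by sequence-aligned
    residues; the ligand RMSD (if a ligand residue name is given) is
    measured under that same RNA fit, matching ligand atoms by name.
    """
    res_a = _nucleotide_residues(a)
    res_b = _nucleotide_residues(b)
    if not res_a or not res_b:
        raise SelectionError("both structures need nucleotide residues")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    seq_a = "".join(code for _, code in res_a)
    seq_b = "".join(code for _, code in res_b)
    alignment = aligner.align(seq_a, seq_b)[0]

    idx_a: list[int] = []
    idx_b: list[int] = []
    pairs = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for off in range(a1 - a0):
            key_a = res_a[a0 + off][0]
            key_b = res_b[b0 + off][0]
            atoms_a = _residue_atoms(a, key_a)
            atoms_b = _residue_atoms(b, key_b)
            shared = sorted(set(atoms_a) & set(atoms_b))
            if shared:
                pairs += 1
                idx_a.extend(atoms_a[name] for name in shared)
                idx_b.extend(atoms_b[name] for name in shared)
    if len(idx_a) < 3:
        raise SelectionError("fewer than 3 matched RNA heavy atoms")

    xa = a.coords[idx_a]
    xb = b.coords[idx_b]
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    rot = kabsch_rotation(xb - cb, xa - ca)

    def transform(points: np.ndarray) -> np.ndarray:
        return (points - cb) @ rot + ca

    rna_rmsd = rmsd(transform(xb), xa)

    ligand_rmsd = None
    n_lig = 0
    if ligand_resname is not None:
        lig_a = _ligand_atoms(a, ligand_resname)
        lig_b = _ligand_atoms(b, ligand_resname)
        shared = sorted(set(lig_a) & set(lig_b))
        if not shared:
            raise SelectionError(f"no shared {ligand_resname!r} atoms to compare")
        la = a.coords[[lig_a[name] for name in shared]]
        lb = b.coords[[lig_b[name] for name in shared]]
        ligand_rmsd = rmsd(transform(lb), la)
        n_lig = len(shared)

    return CrystalComparison(
        rna_rmsd=rna_rmsd,
        ligand_rmsd=ligand_rmsd,
        n_rna_atoms=len(idx_a),
        n_ligand_atoms=n_lig,
        n_aligned_residues=pairs,
    )
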