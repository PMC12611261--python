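"""Ligand-fit confidence scoring from predicted structures.

Structure-prediction tools that place ligands (e.g. AlphaFold-family
models) store a per-atom pLDDT confidence (0-100) in the B-factor field of
the emitted mmCIF/PDB file.  A simple, interpretable ligand-fit score is
the mean pLDDT over the protein residues in contact with the ligand: a
confidently modelled binding pocket scores high, a poorly fitting ligand
drags the surrounding confidence down.

Contacts are heavy-atom distances: a polymer residue interacts with the
ligand when any of its non-hydrogen atoms lies within ``cutoff_A``
(default 5.0 Angstrom) of any ligand heavy atom.  Averaging is two-stage —
atoms to residue, residues to score — so large residues do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from mmtpp.errors import ValidationError

__all__ = [
    "StructureAtom",
    "StructureModel",
    "LigandContactScore",
    "read_structure",
    "find_interacting_residues",
    "mean_plddt",
    "score_ligand_fit",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class StructureAtom:
    """One atom with coordinates and its pLDDT (from the B-factor field)."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    plddt: float
    is_polymer: bool

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


class StructureModel:
    """Flat atom list of one predicted model with polymer/ligand split."""

    def __init__(self, atoms: list[StructureAtom]):
        if not atoms:
            raise ValidationError("structure contains no atoms")
        for a in atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValidationError(f"non-finite coordinates on atom {a}")
            if not (0.0 <= a.plddt <= 100.0):
                raise ValidationError(
                    f"pLDDT {a.plddt} outside [0, 100] on atom "
                    f"{a.chain}/{a.residue_number}/{a.atom_name}"
                )
        self.atoms = list(atoms)

    def ligand_components(self) -> set[str]:
        """Residue names of non-polymer, non-water components."""
        return {
            a.residue_name
            for a in self.atoms
            if not a.is_polymer and a.residue_name not in WATER_NAMES
        }

    def atoms_of_ligand(self, ligand_id: str) -> list[StructureAtom]:
        return [
            a
            for a in self.atoms
            if not a.is_polymer and a.residue_name == ligand_id and not a.is_hydrogen
        ]

    def polymer_heavy_atoms(self) -> list[StructureAtom]:
        return [a for a in self.atoms if a.is_polymer and not a.is_hydrogen]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (useful for invariance checks)."""
        R = np.asarray(rotation, dtype=float)
        tvec = np.asarray(translation, dtype=float)
        atoms = [
            StructureAtom(
                a.chain,
                a.residue_number,
                a.residue_name,
                a.atom_name,
                a.element,
                tuple(R @ np.asarray(a.xyz) + tvec),
                a.plddt,
                a.is_polymer,
            )
            for a in self.atoms
        ]
        return StructureModel(atoms)


@dataclass
class LigandContactScore:
    """Mean pLDDT over the residues in contact with one ligand."""

    ligand_id: str
    cutoff_A: float
    n_residues: int
    residue_list: list[tuple[str, int, str]]
    residue_plddt: dict[tuple[str, int, str], float]
    mean_plddt: float


def read_structure(path: str) -> StructureModel:
    """Read an mmCIF or PDB file into a StructureModel.

    pLDDT is taken from the B-factor column; a file whose B-factors are all
    zero (typically a truncated or B-factor-less file) is rejected because
    no confidence information is available.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValidationError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[StructureAtom] = []
    if len(st) == 0:
        raise ValidationError(f"{path}: structure has no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            is_polymer = info is not None and (
                info.is_amino_acid() or info.is_nucleic_acid()
            )
            for atom in residue:
                atoms.append(
                    StructureAtom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        plddt=atom.b_iso,
                        is_polymer=is_polymer,
                    )
                )
    if not atoms:
        raise ValidationError(f"{path}: structure has no atoms")
    if all(a.plddt == 0.0 for a in atoms):
        raise ValidationError(
            f"{path}: all B-factors are zero; no pLDDT information present"
        )
    return StructureModel(atoms)


def find_interacting_residues(
    model: StructureModel, ligand_id: str, cutoff_A: float = 5.0
) -> list[tuple[str, int, str]]:
    """Polymer residues with >= 1 heavy atom within cutoff of the ligand.

    Multiple copies of the ligand contribute their union of contacts.
    Returns sorted residue keys ``(chain, residue_number, residue_name)``.
    """
    if cutoff_A <= 0:
        raise ValidationError("cutoff_A must be > 0")
    ligand_atoms = model.atoms_of_ligand(ligand_id)
    if not ligand_atoms:
        available = sorted(model.ligand_components())
        raise ValidationError(
            f"ligand {ligand_id!r} not found; available components: {available}"
        )
    poly = model.polymer_heavy_atoms()
    if not poly:
        raise ValidationError("structure has no polymer heavy atoms")
    tree = cKDTree([a.xyz for a in ligand_atoms])
    dists, _ = tree.query([a.xyz for a in poly], k=1)
    hits = {a.residue_key for a, d in zip(poly, dists) if d <= cutoff_A}
    return sorted(hits)


def mean_plddt(
    model: StructureModel, residues: list[tuple[str, int, str]]
) -> dict[tuple[str, int, str], float]:
    """Per-residue pLDDT: mean over each residue's heavy-atom values."""
    if not residues:
        raise ValidationError("no contacts at this cutoff")
    wanted = set(residues)
    sums: dict[tuple[str, int, str], list[float]] = {k: [] for k in wanted}
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        if a.residue_key in wanted:
            sums[a.residue_key].append(a.plddt)
    empty = [k for k, v in sums.items() if not v]
    if empty:
        raise ValidationError(f"residues without heavy atoms: {sorted(empty)}")
    return {k: float(np.mean(v)) for k, v in sums.items()}


def score_ligand_fit(
    model: StructureModel, ligand_id: str, cutoff_A: float = 5.0
) -> LigandContactScore:
    """Ligand-fit confidence: unweighted mean of contact-residue pLDDTs."""
    residues = find_interacting_residues(model, ligand_id, cutoff_A)
    per_residue = mean_plddt(model, residues)
    return LigandContactScore(
        ligand_id=ligand_id,
        cutoff_A=cutoff_A,
        n_residues=len(residues),
        residue_list=residues,
        residue_plddt=per_residue,
        mean_plddt=float(np.mean(list(per_residue.values()))),
    )
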