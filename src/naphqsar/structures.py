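"""3D conformers, Gasteiger charges, and 14-atom core superposition.

All molecules in the series share a maximal common substructure — the
1-hydroxynaphthalene ring system plus the peptide-like amide motif — whose
14 atoms (naphthalene C1..C8a, hydroxyl O, carbonyl C, carbonyl O, amide N)
serve as the rigid-body alignment frame.  Every compound is embedded once
(seeded distance-geometry + force-field relaxation), charged with the
Gasteiger scheme, and superimposed on the template (compound 1 by default)
by least-squares fit of the mapped core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

# SMARTS of the common core; match order:
#  0 hydroxyl O, 1 C1, 2 C2, 3 carbonyl C, 4 carbonyl O, 5 amide N,
#  6 C3, 7 C4, 8 C4a, 9-12 C5..C8, 13 C8a
_CORE_SMARTS = Chem.MolFromSmarts("[OX2H1]c1c(C(=O)[NX3])ccc2ccccc21")

# reorder into the package's fixed core ordering:
# naphthalene C1,C2,C3,C4,C4a,C5,C6,C7,C8,C8a, hydroxyl O, carbonyl C/O, N
_CORE_ORDER = (1, 2, 6, 7, 8, 9, 10, 11, 12, 13, 0, 3, 4, 5)

CORE_SIZE = 14


class EmbeddingError(RuntimeError):
    """3D embedding failed for a compound."""


@dataclass(frozen=True)
class Conformer:
    """A single 3D structure with optional partial charges.

    ``core_map`` lists the atom indices of the 14 shared core atoms in the
    package's fixed order; it is empty only for non-series molecules.
    """

    compound_id: str
    mol: Chem.Mol
    core_map: tuple[int, ...]

    @property
    def symbols(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [
                a.GetDoubleProp("_GasteigerCharge") if a.HasProp("_GasteigerCharge") else 0.0
                for a in self.mol.GetAtoms()
            ]
        )

    @property
    def core_coords(self) -> np.ndarray:
        return self.coords[list(self.core_map)]

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)


def find_core(mol: Chem.Mol) -> tuple[int, ...]:
    """Indices of the 14 core atoms in canonical order; empty if absent."""
    match = mol.GetSubstructMatch(_CORE_SMARTS)
    if not match:
        return ()
    return tuple(match[i] for i in _CORE_ORDER)


def embed_3d(smiles: str, seed: int = 7, compound_id: str = "") -> Conformer:
    """Deterministic 3D embedding: seeded ETKDG followed by MMFF relaxation."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EmbeddingError(f"invalid SMILES for {compound_id!r}: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"embedding failed for {compound_id!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    return Conformer(compound_id=compound_id, mol=mol, core_map=find_core(mol))


def assign_gasteiger(conformer: Conformer) -> Conformer:
    """Attach Gasteiger partial charges (sum equals the net formal charge)."""
    mol = Chem.Mol(conformer.mol)
    AllChem.ComputeGasteigerCharges(mol)
    charges = [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
    if not all(np.isfinite(charges)):
        raise ValueError(f"Gasteiger charges undefined for {conformer.compound_id!r}")
    return replace(conformer, mol=mol)


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with moving @ R.T + t ~ target."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def align_core(conformer: Conformer, template: Conformer) -> tuple[Conformer, float]:
    """Rigid-body superposition of the 14 mapped core atoms onto the template.

    Returns the transformed copy and the core RMSD in angstroms; the template
    is never modified and internal geometry is preserved exactly.
    """
    for c in (conformer, template):
        if len(c.core_map) != CORE_SIZE:
            raise ValueError(f"incomplete core map on {c.compound_id!r}: {c.core_map}")
    rot, trans = _kabsch(conformer.core_coords, template.core_coords)
    mol = Chem.Mol(conformer.mol)
    conf = mol.GetConformer()
    new = conformer.coords @ rot.T + trans
    for i, xyz in enumerate(new):
        conf.SetAtomPosition(i, xyz.tolist())
    moved = replace(conformer, mol=mol)
    rmsd = float(np.sqrt(np.mean(np.sum((moved.core_coords - template.core_coords) ** 2, axis=1))))
    return moved, rmsd


def build_aligned_series(
    smiles_by_id: dict[str, str], template_id: str = "1", seed: int = 7
) -> dict[str, Conformer]:
    """Embed, charge, and align the whole series onto one template compound."""
    if template_id not in smiles_by_id:
        raise KeyError(f"template {template_id!r} not in series")
    conformers = {
        cid: assign_gasteiger(embed_3d(smi, seed=seed, compound_id=cid))
        for cid, smi in smiles_by_id.items()
    }
    template = conformers[template_id]
    aligned = {}
    for cid, conf in conformers.items():
        aligned[cid], _ = align_core(conf, template)
    return aligned
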