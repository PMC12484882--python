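"""Conformer file I/O: XYZ (single- and multi-frame) and SDF (V2000).

SDF reading and SMILES→conformer embedding delegate to RDKit when it is
importable; both raise an informative ImportError otherwise. XYZ is written
and parsed directly (element symbol + three coordinates per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .molgraph import Conformation

__all__ = ["read_xyz", "write_xyz", "write_xyz_trajectory", "read_sdf",
           "smiles_to_conformer", "ELEMENT_SYMBOLS", "ATOMIC_NUMBERS"]

ELEMENT_SYMBOLS = {
    1: "H", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 35: "Br", 53: "I",
}
ATOMIC_NUMBERS = {sym: z for z, sym in ELEMENT_SYMBOLS.items()}


def _symbol(z: int) -> str:
    try:
        return ELEMENT_SYMBOLS[int(z)]
    except KeyError:
        raise ValueError(f"unsupported element Z={z}; supported: "
                         f"{sorted(ELEMENT_SYMBOLS)}") from None


def _frame_lines(conf: Conformation, comment: str) -> list[str]:
    lines = [str(conf.n_atoms), comment]
    for z, p in zip(conf.elements, conf.positions):
        lines.append(f"{_symbol(z):<2} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}")
    return lines


def write_xyz(path, conf: Conformation, comment: str | None = None) -> None:
    Path(path).write_text(
        "\n".join(_frame_lines(conf, comment if comment is not None else conf.mol_id)) + "\n")


def write_xyz_trajectory(path, frames: list[Conformation],
                         comments: list[str] | None = None) -> None:
    """Concatenate frames into a multi-frame XYZ trajectory."""
    lines: list[str] = []
    for k, conf in enumerate(frames):
        comment = comments[k] if comments is not None else f"frame {k}"
        lines.extend(_frame_lines(conf, comment))
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> list[Conformation]:
    """Parse a (possibly multi-frame) XYZ file into conformations."""
    lines = Path(path).read_text().splitlines()
    frames: list[Conformation] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        comment = lines[k + 1].strip()
        elements, positions = [], []
        for row in lines[k + 2: k + 2 + n]:
            parts = row.split()
            sym = parts[0].capitalize()
            if sym not in ATOMIC_NUMBERS:
                raise ValueError(f"unsupported element symbol {parts[0]!r}")
            elements.append(ATOMIC_NUMBERS[sym])
            positions.append([float(x) for x in parts[1:4]])
        frames.append(Conformation(np.array(elements), np.array(positions), mol_id=comment))
        k += 2 + n
    return frames


def _require_rdkit():
    try:
        from rdkit import Chem  # noqa: F401
        return Chem
    except ImportError as exc:  # pragma: no cover - exercised only without rdkit
        raise ImportError(
            "RDKit is required for SDF/SMILES input but is not installed; "
            "install the 'chem' extra or provide XYZ conformers instead") from exc


def read_sdf(path) -> list[Conformation]:
    """Read all molecules from an SDF (V2000) file via RDKit."""
    Chem = _require_rdkit()
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            continue
        c = mol.GetConformer()
        elements = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
        positions = np.array([[c.GetAtomPosition(i).x, c.GetAtomPosition(i).y,
                               c.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(Conformation(elements, positions, mol_id=name))
    return out


def smiles_to_conformer(smiles: str, seed: int = 0, optimize: bool = True) -> Conformation:
    """Embed a SMILES string into a 3D conformer (distance geometry + MMFF).

    Requires RDKit. The MMFF-optimized geometry is stored as the equilibrium
    geometry so downstream perturbation/relaxation can supervise against it.
    """
    Chem = _require_rdkit()
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"conformer embedding failed for SMILES: {smiles!r}")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol)
    c = mol.GetConformer()
    elements = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
    positions = np.array([[c.GetAtomPosition(i).x, c.GetAtomPosition(i).y,
                           c.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    return Conformation(elements, positions, equilibrium_positions=positions.copy(),
                        perturbation=np.zeros_like(positions), mol_id=smiles)
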