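"""Structure-format conversion and geometric bond perception.

The pipeline compares pre- and post-optimization connectivity by
perceiving bonds from Cartesian coordinates: two atoms are bonded when
their distance is below the sum of their covalent radii plus an additive
tolerance (0.45 A by default, the common choice in XYZ->SDF converters).
Bond orders are not assigned; the connectivity graph is all the
workflow needs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import InputError

__all__ = [
    "read_xyz",
    "write_xyz",
    "perceive_bonds",
    "xyz_to_mol",
    "mol_to_xyz_block",
    "write_sdf",
]

_PT = Chem.GetPeriodicTable()

DEFAULT_BOND_TOLERANCE = 0.45  # Angstrom


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Parse an XYZ file into (symbols, coords). Reports the offending
    line number on malformed input."""
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise InputError(f"{path}:1: expected an atom count") from exc
    symbols, coords = [], []
    for lineno in range(2, 2 + n):
        try:
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ValueError("fewer than 4 fields")
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        except (IndexError, ValueError) as exc:
            raise InputError(f"{path}:{lineno + 1}: malformed atom line") from exc
    return symbols, np.asarray(coords, dtype=float)


def write_xyz(path, symbols, coords, comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, coords):
            fh.write(f"{s:<3s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def perceive_bonds(
    symbols: list[str],
    coords: np.ndarray,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> set[frozenset[int]]:
    """Distance-based connectivity: atoms i,j bonded iff
    ``d(i,j) <= r_cov(i) + r_cov(j) + tolerance``."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([_PT.GetRcovalent(s) for s in symbols])
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    cut = radii[:, None] + radii[None, :] + tolerance
    bonded = set()
    n = len(symbols)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= cut[i, j]:
                bonded.add(frozenset((i, j)))
    return bonded


def xyz_to_mol(path, tolerance: float = DEFAULT_BOND_TOLERANCE) -> Chem.Mol:
    """Build an RDKit molecule (single bonds only, no sanitization of
    valences) from an XYZ file, with perceived connectivity and a 3D
    conformer attached."""
    symbols, coords = read_xyz(path)
    rw = Chem.RWMol()
    for s in symbols:
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for bond in perceive_bonds(symbols, coords, tolerance):
        i, j = sorted(bond)
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(symbols))
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


def mol_to_xyz_block(mol: Chem.Mol, conf_id: int = -1, comment: str = "") -> str:
    conf = mol.GetConformer(conf_id)
    lines = [str(mol.GetNumAtoms()), comment]
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        lines.append(f"{atom.GetSymbol():<3s} {p.x:14.8f} {p.y:14.8f} {p.z:14.8f}")
    return "\n".join(lines) + "\n"


def write_sdf(path, mols_and_coords: list[tuple[Chem.Mol, np.ndarray]]) -> None:
    """Write a multi-record SDF.  Dative P->Pd bonds are downgraded to
    single bonds for V2000 compatibility; intended for visual
    inspection, not round-tripping the electronic structure."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol, coords in mols_and_coords:
            m = Chem.RWMol(mol)
            for bond in m.GetBonds():
                if bond.GetBondType() == Chem.BondType.DATIVE:
                    bond.SetBondType(Chem.BondType.SINGLE)
            conf = Chem.Conformer(m.GetNumAtoms())
            for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            m.RemoveAllConformers()
            m.AddConformer(conf)
            writer.write(m)
    finally:
        writer.close()
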