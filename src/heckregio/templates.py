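"""Catalyst-core 3D templates for constrained embedding.

A template is the handful of atoms whose relative 3D arrangement is held
fixed while conformers of a post-insertion complex are generated: the Pd
centre, its phosphine phosphorus atom(s), the Pd-bound alkyl carbon and,
on the neutral pathway, the halide/triflate attachment atom.  The cores
are idealized square-planar Pd(II) fragments (Pd-C 2.0 A, Pd-P 2.3 A,
Pd-X 2.4-2.7 A depending on X) shipped as versioned XYZ assets; they are
a geometric idealization, not literature-optimized structures.

For the neutral pathway two variants exist, with X *cis* (90 deg) or
*trans* (180 deg) to the alkyl carbon.  The stored asset carries Cl in
the X slot; :func:`load_template` substitutes the element and Pd-X bond
length of the actual leaving group (the OTf attachment atom is its ester
oxygen).  The cationic core has two phosphines and no X.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

from .errors import TemplateError

__all__ = ["TemplateStructure", "load_template"]

_ASSET_PKG = "heckregio.data.templates"


@dataclass(frozen=True)
class TemplateStructure:
    pathway: str
    variant: str | None  # cis | trans for neutral, None for cationic
    leaving_group: str | None
    symbols: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    charge: int
    query_smarts: str

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.query_smarts)

    def match(self, mol: Chem.Mol) -> tuple[int, ...]:
        """First substructure match of the template into *mol*; atom
        order corresponds to the template's own atom order."""
        m = mol.GetSubstructMatch(self.query)
        if not m:
            raise TemplateError(
                f"complex does not contain the {self.pathway} catalyst core "
                f"({self.query_smarts})"
            )
        return m


def _read_xyz_asset(name: str) -> tuple[list[str], np.ndarray]:
    try:
        text = (resources.files(_ASSET_PKG) / name).read_text()
    except FileNotFoundError as exc:
        raise TemplateError(f"missing template asset {name!r}") from exc
    lines = text.strip().splitlines()
    n = int(lines[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.asarray(coords, dtype=float)


def _meta() -> dict:
    return json.loads((resources.files(_ASSET_PKG) / "meta.json").read_text())


def load_template(
    pathway: str,
    leaving_group: str | None = None,
    variant: str | None = None,
) -> TemplateStructure:
    """Load the catalyst-core template for a pathway.

    For the neutral pathway the Cl placeholder in the asset is replaced
    by the actual leaving group (element and Pd-X distance); *variant*
    selects the cis or trans core and defaults to ``cis``.  The cationic
    template is independent of the leaving group.
    """
    meta = _meta()
    if pathway == "cationic":
        symbols, coords = _read_xyz_asset("cationic.xyz")
        return TemplateStructure(
            pathway="cationic",
            variant=None,
            leaving_group=None,
            symbols=tuple(symbols),
            coords=coords,
            charge=meta["charges"]["cationic"],
            query_smarts="[Pd](~[#6])(~[#15])~[#15]",
        )
    if pathway != "neutral":
        raise TemplateError(f"unknown pathway {pathway!r}")
    if leaving_group not in meta["pd_x_distance"]:
        raise TemplateError(
            f"leaving group {leaving_group!r} not supported (expected one of "
            f"{sorted(meta['pd_x_distance'])})"
        )
    variant = variant or "cis"
    if variant not in ("cis", "trans"):
        raise TemplateError(f"unknown neutral geometry variant {variant!r}")
    symbols, coords = _read_xyz_asset(f"neutral_{variant}.xyz")

    # Substitute the X slot: atom order in the assets is Pd, C, X, P.
    x_idx = symbols.index("Cl")
    elem = meta["x_attachment_element"][leaving_group]
    dist = meta["pd_x_distance"][leaving_group]
    symbols[x_idx] = elem
    direction = coords[x_idx] - coords[0]
    coords = coords.copy()
    coords[x_idx] = coords[0] + direction / np.linalg.norm(direction) * dist

    x_num = Chem.GetPeriodicTable().GetAtomicNumber(elem)
    return TemplateStructure(
        pathway="neutral",
        variant=variant,
        leaving_group=leaving_group,
        symbols=tuple(symbols),
        coords=coords,
        charge=meta["charges"]["neutral"],
        query_smarts=f"[Pd](~[#6])(~[#{x_num}])~[#15]",
    )
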