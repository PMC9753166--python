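"""Template-constrained conformer generation and RMSD deduplication.

Each post-insertion complex gets ``min(1 + 3*n_rot, 80)`` distance-
geometry conformers (``n_rot`` = rotatable bonds of the organic
product), embedded with the catalyst-core atoms pinned to the template
coordinates.  The ensemble is then thinned to spatially unique members
by Butina sphere-exclusion clustering on the pairwise heavy-atom
best-fit RMSD with a 0.5 A threshold, keeping cluster centroids only.

The RMSD is the optimal-superposition (Kabsch) heavy-atom RMSD with the
identity atom mapping; no graph-symmetry correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from .enumeration import ComplexSpec
from .errors import EmbeddingError
from .util import quiet_rdkit
from .templates import TemplateStructure

__all__ = [
    "Conformer",
    "count_conformers",
    "embed_conformers",
    "heavy_atom_rmsd",
    "butina_cluster",
    "cluster_unique",
    "CONFORMER_CAP",
]

CONFORMER_CAP = 80


@dataclass
class Conformer:
    """One 3D realisation of a complex.

    ``mol`` is the shared hydrogen-explicit topology of the parent
    complex; ``coords`` are this conformer's own coordinates (Angstrom).
    ``energies`` records each pipeline stage's energy in kJ/mol; the
    last stage written is the working energy.
    """

    complex_id: str
    mol: Chem.Mol
    coords: np.ndarray
    seed: int
    index: int
    energies: dict[str, float] = field(default_factory=dict)
    valid: bool = True
    connectivity_ok: bool = True

    @property
    def energy(self) -> float | None:
        if not self.energies:
            return None
        return next(reversed(self.energies.values()))

    @property
    def heavy_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)


def count_conformers(n_rot: int, cap: int = CONFORMER_CAP) -> int:
    """Number of initial conformers for a product with *n_rot* rotatable
    bonds: ``min(1 + 3*n_rot, cap)`` with the cap at 80."""
    if n_rot < 0:
        raise ValueError("n_rot must be nonnegative")
    return min(1 + 3 * n_rot, cap)


def embed_conformers(
    spec: ComplexSpec,
    template: TemplateStructure,
    n: int,
    seed: int,
) -> list[Conformer]:
    """Generate up to *n* conformers of *spec* with the catalyst core
    pinned to the template coordinates.

    Distance-geometry embedding with a coordinate map: the matched
    template atoms are fixed at the template's 3D positions and the rest
    of the complex is built around them.  Reproducible for a given seed.
    Returns fewer than *n* conformers (possibly zero, with a warning) if
    embeddings fail.
    """
    from rdkit.Geometry import Point3D

    mol = Chem.AddHs(spec.mol)
    match = template.match(mol)  # raises TemplateError on mismatch
    coord_map = {
        mol_idx: Point3D(*template.coords[t_idx])
        for t_idx, mol_idx in enumerate(match)
    }
    with quiet_rdkit():
        conf_ids = list(
            AllChem.EmbedMultipleConfs(
            mol,
            numConfs=n,
            coordMap=coord_map,
            randomSeed=seed,
            useRandomCoords=True,
                numThreads=1,
            )
        )
    if not conf_ids:
        warnings.warn(
            f"all {n} embeddings failed for {spec.complex_id}", stacklevel=2
        )
        return []
    conformers = []
    for i, cid in enumerate(conf_ids):
        coords = np.asarray(mol.GetConformer(cid).GetPositions(), dtype=float)
        if not np.all(np.isfinite(coords)):
            continue
        conformers.append(
            Conformer(
                complex_id=spec.complex_id,
                mol=mol,
                coords=coords,
                seed=seed,
                index=i,
            )
        )
    return conformers


def heavy_atom_rmsd(
    a: np.ndarray, b: np.ndarray, heavy_indices: list[int] | None = None
) -> float:
    """Best-fit (Kabsch) RMSD between two coordinate sets, restricted to
    *heavy_indices* when given.  Identity atom mapping, no symmetry."""
    if heavy_indices is not None:
        a = a[heavy_indices]
        b = b[heavy_indices]
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # planar/linear fragments make the optimal rotation non-unique;
        # the residual (all we use) is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def butina_cluster(
    dist: np.ndarray, threshold: float
) -> list[tuple[int, list[int]]]:
    """Butina sphere-exclusion clustering of a symmetric distance matrix.

    Neighbour counts (distance <= threshold, self included) are computed
    once; candidates are processed in descending neighbour count with
    ties broken by lowest index, so the output is deterministic.
    Returns ``(centroid, members)`` pairs; members include the centroid.
    """
    n = len(dist)
    neighbors = [set(np.flatnonzero(dist[i] <= threshold).tolist()) | {i} for i in range(n)]
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    unassigned = set(range(n))
    clusters = []
    for i in order:
        if i not in unassigned:
            continue
        members = sorted(neighbors[i] & unassigned)
        clusters.append((i, members))
        unassigned -= set(members)
    return clusters


def cluster_unique(
    conformers: list[Conformer], rmsd_threshold: float = 0.5
) -> list[Conformer]:
    """Keep only the Butina cluster centroids of a conformer ensemble.

    Every input conformer lies within *rmsd_threshold* of some returned
    centroid; clustering the returned centroids again is a no-op.
    """
    if not conformers:
        raise ValueError("cannot cluster an empty ensemble")
    n_atoms = {len(c.coords) for c in conformers}
    if len(n_atoms) != 1:
        raise ValueError("conformers differ in atom count")
    heavy = conformers[0].heavy_indices
    n = len(conformers)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = heavy_atom_rmsd(conformers[i].coords, conformers[j].coords, heavy)
            dist[i, j] = dist[j, i] = d
    clusters = butina_cluster(dist, rmsd_threshold)
    centroid_ids = sorted(c for c, _ in clusters)
    return [conformers[i] for i in centroid_ids]
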