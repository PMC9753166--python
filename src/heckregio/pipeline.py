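"""Staged energy refinement of post-insertion complex ensembles.

Stage order (asserted in every audit trail):

1.  constrained distance-geometry embedding around the catalyst core;
2.  Butina RMSD deduplication;
3.  constrained force-field optimization (prescreen);
4.  10 kJ/mol energy-window filter + re-clustering;
5.  constrained semiempirical optimization (optionally followed by the
    same window filter + re-clustering, off by default);
6.  free semiempirical relaxation;
7.  connectivity sanity check: bonds perceived from the relaxed
    geometry are compared to the complex graph with all Pd bonds
    masked; a broken or newly created bond sets the conformer's energy
    to 60,000 kJ/mol so it can never win the final ranking;
8.  DFT single point on the surviving geometries;
9.  selection of the minimum-energy conformer.

The per-complex result carries the full audit trail; a complex whose
ensemble empties at any stage is flagged failed and later reported as
``undetermined`` by the classifier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .backends import CalculatorBackend, EnergyRequest, make_backend
from .config import PipelineConfig
from .convert import perceive_bonds
from .embedding import Conformer, cluster_unique, count_conformers, embed_conformers
from .enumeration import ComplexSpec
from .errors import PipelineError, TemplateError
from .templates import TemplateStructure, load_template

__all__ = [
    "StageResult",
    "IntermediateResult",
    "match_constrained_atoms",
    "optimize",
    "filter_energy_window",
    "check_connectivity",
    "single_point",
    "run_pipeline",
    "run_complexes",
    "build_backends",
    "PENALTY_ENERGY",
    "STAGE_ORDER",
]

PENALTY_ENERGY = 60_000.0  # kJ/mol; sentinel for broken connectivity

STAGE_ORDER = (
    "embed",
    "cluster_initial",
    "ff_constrained",
    "energy_window",
    "cluster_postff",
    "se_constrained",
    "se_free",
    "connectivity",
    "dft_singlepoint",
    "select_minimum",
)


@dataclass
class StageResult:
    """Outcome of one backend call on one conformer."""

    conformer_index: int
    stage: str
    energy: float
    coords: np.ndarray
    converged: bool
    connectivity_ok: bool = True


@dataclass
class IntermediateResult:
    """Lowest-energy intermediate found for one complex, plus audit."""

    spec: ComplexSpec
    failed: bool
    reason: str | None
    best: Conformer | None
    final_energy: float | None
    audit: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "complex_id": self.spec.complex_id,
            "pathway": self.spec.pathway,
            "regiochemistry": self.spec.regiochemistry,
            "geometry_variant": self.spec.geometry_variant,
            "product_smiles": self.spec.product_smiles,
            "failed": self.failed,
            "reason": self.reason,
            "final_energy_kj_mol": self.final_energy,
            "audit": self.audit,
        }


def match_constrained_atoms(
    spec_or_mol: ComplexSpec | Chem.Mol, template: TemplateStructure
) -> tuple[int, ...]:
    """Atom indices of the complex to hold fixed during constrained
    optimization: the first canonical substructure match of the
    catalyst-core template (Pd, phosphine P, alkyl C and, for the
    neutral pathway, the halide/triflate attachment atom)."""
    mol = spec_or_mol.mol if isinstance(spec_or_mol, ComplexSpec) else spec_or_mol
    try:
        return template.match(mol)
    except TemplateError as exc:
        raise PipelineError(str(exc)) from exc


def optimize(
    conformer: Conformer,
    backend: CalculatorBackend,
    constraints: tuple[int, ...],
    stage: str,
    charge: int,
) -> StageResult:
    """Run one (possibly constrained) optimization; a backend crash is
    reported as ``converged=False`` and never raises."""
    if not backend.supports_optimization:
        raise PipelineError(f"backend {backend.name} cannot optimize")
    res = backend.compute(
        EnergyRequest(
            mol=conformer.mol,
            coords=conformer.coords,
            charge=charge,
            stage=stage,
            tag=conformer.complex_id,
            constraints=constraints,
            optimize=True,
        )
    )
    return StageResult(
        conformer_index=conformer.index,
        stage=stage,
        energy=res.energy,
        coords=res.coords,
        converged=res.converged,
    )


def filter_energy_window(conformers: list[Conformer], window: float = 10.0) -> list[Conformer]:
    """Keep conformers within *window* kJ/mol of the ensemble minimum
    (the minimum itself always survives)."""
    if not conformers:
        return []
    energies = [c.energy for c in conformers]
    if any(e is None for e in energies):
        raise PipelineError("cannot window-filter conformers without energies")
    e_min = min(energies)
    return [c for c, e in zip(conformers, energies) if e - e_min <= window]


def reference_adjacency(mol: Chem.Mol, mask_element: str = "Pd") -> set[frozenset[int]]:
    """Bond set of the molecular graph with every bond touching
    *mask_element* removed."""
    masked = {a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == mask_element}
    return {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
        if not ({b.GetBeginAtomIdx(), b.GetEndAtomIdx()} & masked)
    }


def check_connectivity(
    conformer: Conformer,
    penalty: float = PENALTY_ENERGY,
    tolerance: float = 0.45,
) -> Conformer:
    """Compare geometry-perceived bonds against the complex graph.

    Bonds to Pd are masked on both sides (the Pd coordination sphere is
    allowed to rearrange); any other broken or newly created bond marks
    the conformer and sets its working energy to the penalty value.
    A bond-perception failure is treated as a mismatch.
    """
    mol = conformer.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    pd_atoms = {i for i, s in enumerate(symbols) if s == "Pd"}
    try:
        perceived = {
            b
            for b in perceive_bonds(symbols, conformer.coords, tolerance)
            if not (set(b) & pd_atoms)
        }
        ok = perceived == reference_adjacency(mol)
    except Exception:
        ok = False
    conformer.connectivity_ok = ok
    if not ok:
        conformer.energies["connectivity"] = penalty
    return conformer


def single_point(
    conformer: Conformer, backend: CalculatorBackend, charge: int, stage: str = "dft_singlepoint"
) -> StageResult:
    """Energy at fixed geometry; coordinates are untouched by contract."""
    res = backend.compute(
        EnergyRequest(
            mol=conformer.mol,
            coords=conformer.coords,
            charge=charge,
            stage=stage,
            tag=conformer.complex_id,
            constraints=(),
            optimize=False,
        )
    )
    return StageResult(
        conformer_index=conformer.index,
        stage=stage,
        energy=res.energy,
        coords=conformer.coords,  # never replaced for a single point
        converged=res.converged,
    )


def build_backends(config: PipelineConfig) -> dict[str, CalculatorBackend]:
    """Instantiate the three stage backends named in the config."""
    out = {}
    for level in ("forcefield", "semiempirical", "dft_singlepoint"):
        out[level] = make_backend(config.backends[level], level)
    return out


def _derive_seed(base_seed: int, complex_id: str) -> int:
    digest = hashlib.md5(f"{base_seed}:{complex_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _apply_stage(
    conformers: list[Conformer],
    backend: CalculatorBackend,
    constraints: tuple[int, ...],
    stage: str,
    charge: int,
) -> list[Conformer]:
    survivors = []
    for c in conformers:
        sr = optimize(c, backend, constraints, stage, charge)
        if not sr.converged or not np.isfinite(sr.energy):
            c.valid = False
            continue
        c.coords = sr.coords
        c.energies[stage] = sr.energy
        survivors.append(c)
    return survivors


def run_pipeline(
    spec: ComplexSpec,
    config: PipelineConfig | None = None,
    backends: dict[str, CalculatorBackend] | None = None,
) -> IntermediateResult:
    """Full energy ladder for one post-insertion complex.

    Returns the minimum-energy surviving conformer with a stage-by-stage
    audit trail; an ensemble that empties at any stage yields a result
    flagged ``failed`` (classified downstream as missing data).
    """
    config = config or PipelineConfig()
    backends = backends or build_backends(config)
    audit: list[dict] = []

    def log(stage: str, n_in: int, n_out: int, **params):
        entry = {"stage": stage, "n_in": n_in, "n_out": n_out}
        if params:
            entry["params"] = params
        audit.append(entry)

    def failed(reason: str) -> IntermediateResult:
        return IntermediateResult(
            spec=spec, failed=True, reason=reason, best=None, final_energy=None, audit=audit
        )

    template = load_template(
        spec.pathway, spec.site.leaving_group, spec.geometry_variant
    )
    n_req = count_conformers(spec.n_rotatable_product, config.conformer_cap)
    seed = _derive_seed(config.seed, spec.complex_id)
    conformers = embed_conformers(spec, template, n_req, seed)
    log("embed", n_req, len(conformers), seed=seed, n_rot=spec.n_rotatable_product)
    if not conformers:
        return failed("all embeddings failed")

    constraints = match_constrained_atoms(conformers[0].mol, template)

    conformers = cluster_unique(conformers, config.rmsd_threshold)
    log("cluster_initial", audit[-1]["n_out"], len(conformers), rmsd=config.rmsd_threshold)

    n_in = len(conformers)
    conformers = _apply_stage(
        conformers, backends["forcefield"], constraints, "ff_constrained", spec.charge
    )
    log("ff_constrained", n_in, len(conformers), backend=backends["forcefield"].name)
    if not conformers:
        return failed("no converged force-field conformer")

    n_in = len(conformers)
    conformers = filter_energy_window(conformers, config.energy_window)
    log("energy_window", n_in, len(conformers), window=config.energy_window)

    n_in = len(conformers)
    conformers = cluster_unique(conformers, config.rmsd_threshold)
    log("cluster_postff", n_in, len(conformers), rmsd=config.rmsd_threshold)

    n_in = len(conformers)
    conformers = _apply_stage(
        conformers, backends["semiempirical"], constraints, "se_constrained", spec.charge
    )
    log("se_constrained", n_in, len(conformers), backend=backends["semiempirical"].name)
    if not conformers:
        return failed("no converged constrained semiempirical conformer")

    if config.refilter_after_semiempirical:
        n_in = len(conformers)
        conformers = filter_energy_window(conformers, config.energy_window)
        log("energy_window_se", n_in, len(conformers), window=config.energy_window)
        n_in = len(conformers)
        conformers = cluster_unique(conformers, config.rmsd_threshold)
        log("cluster_postse", n_in, len(conformers), rmsd=config.rmsd_threshold)

    n_in = len(conformers)
    conformers = _apply_stage(
        conformers, backends["semiempirical"], (), "se_free", spec.charge
    )
    log("se_free", n_in, len(conformers), backend=backends["semiempirical"].name)
    if not conformers:
        return failed("no converged relaxed conformer")

    if config.check_connectivity:
        n_in = len(conformers)
        for c in conformers:
            check_connectivity(
                c, config.penalty_energy, config.bond_perception_tolerance
            )
        survivors = [c for c in conformers if c.connectivity_ok]
        log(
            "connectivity",
            n_in,
            len(survivors),
            penalty=config.penalty_energy,
            tolerance=config.bond_perception_tolerance,
        )
        if not survivors:
            return failed("connectivity changed in every conformer")
        conformers = survivors

    survivors = []
    for c in conformers:
        sr = single_point(c, backends["dft_singlepoint"], spec.charge)
        if sr.converged and np.isfinite(sr.energy):
            c.energies["dft_singlepoint"] = sr.energy
            survivors.append(c)
    log("dft_singlepoint", len(conformers), len(survivors), backend=backends["dft_singlepoint"].name)
    if not survivors:
        return failed("no converged DFT single point")

    best = min(survivors, key=lambda c: c.energies["dft_singlepoint"])
    log("select_minimum", len(survivors), 1, best_index=best.index)
    audit_energy = {
        str(c.index): round(float(c.energies["dft_singlepoint"]), 6) for c in survivors
    }
    audit[-1]["final_energies"] = audit_energy
    return IntermediateResult(
        spec=spec,
        failed=False,
        reason=None,
        best=best,
        final_energy=float(best.energies["dft_singlepoint"]),
        audit=audit,
    )


def run_complexes(
    specs: list[ComplexSpec],
    config: PipelineConfig | None = None,
    backends: dict[str, CalculatorBackend] | None = None,
) -> list[IntermediateResult]:
    """Run the ladder over a list of complexes, never aborting on
    individual failures."""
    config = config or PipelineConfig()
    backends = backends or build_backends(config)
    return [run_pipeline(spec, config, backends) for spec in specs]
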