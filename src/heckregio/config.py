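"""Pipeline configuration.

All numeric defaults are the workflow's published operating point:
10 kJ/mol conformer energy window, 0.5 A Butina RMSD threshold,
12.6 kJ/mol (3 kcal/mol) selectivity cutoff, 60,000 kJ/mol penalty for
broken connectivity, at most 80 conformers per complex, phenol
(eps = 12.4) implicit solvent for the force-field/tight-binding stages
and dichloromethane (eps = 9.08) for the DFT single points.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "SolventSpec"]


@dataclass(frozen=True)
class SolventSpec:
    name: str
    dielectric: float


@dataclass
class PipelineConfig:
    """Knobs of the energy-refinement pipeline.

    Attributes
    ----------
    energy_window:
        kJ/mol window above the ensemble minimum within which conformers
        survive the post-force-field filter.
    rmsd_threshold:
        Heavy-atom RMSD (Angstrom) under which two conformers are
        considered duplicates by Butina clustering.
    selectivity_cutoff:
        kJ/mol; alpha/beta intermediate gaps at or below this value are
        called a mix.
    penalty_energy:
        kJ/mol assigned to conformers whose optimization broke or formed
        a covalent bond (Pd bonds excluded from the comparison).
    conformer_cap:
        Upper bound on initial conformers per complex; the requested
        count is min(1 + 3*n_rot, cap).
    refilter_after_semiempirical:
        Apply the energy window + re-clustering again after the
        constrained tight-binding stage (the prescreen "procedure" is
        repeated there; whether that includes the filter is a judgement
        call, so it is a flag).
    """

    backends: dict[str, str] = field(
        default_factory=lambda: {
            "forcefield": "mock",
            "semiempirical": "mock",
            "dft_singlepoint": "mock",
        }
    )
    energy_window: float = 10.0
    rmsd_threshold: float = 0.5
    selectivity_cutoff: float = 12.6
    penalty_energy: float = 60_000.0
    conformer_cap: int = 80
    prescreen_solvent: SolventSpec = field(
        default_factory=lambda: SolventSpec("phenol", 12.4)
    )
    dft_solvent: SolventSpec = field(default_factory=lambda: SolventSpec("dcm", 9.08))
    seed: int = 0xC0FFEE % 2**16
    pathways: tuple[str, ...] = ("neutral", "cationic")
    refilter_after_semiempirical: bool = False
    check_connectivity: bool = True
    bond_perception_tolerance: float = 0.45  # Angstrom added to covalent radii sum

    def __post_init__(self) -> None:
        for name in (
            "energy_window",
            "rmsd_threshold",
            "selectivity_cutoff",
            "penalty_energy",
            "conformer_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.prescreen_solvent, dict):
            self.prescreen_solvent = SolventSpec(**self.prescreen_solvent)
        if isinstance(self.dft_solvent, dict):
            self.dft_solvent = SolventSpec(**self.dft_solvent)
        if isinstance(self.pathways, list):
            self.pathways = tuple(self.pathways)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathways"] = list(self.pathways)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Stable short hash of the full configuration, stamped into
        every report for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:12]
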