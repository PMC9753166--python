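"""Energy backends behind a common calculator contract.

The pipeline's three rungs -- force-field prescreen, semiempirical
tight-binding optimization, DFT single point -- are driven through one
interface so the workflow logic never knows which engine it is talking
to.  Four families are provided:

``MockBackend``
    A pure deterministic function of (coordinate hash, stage) producing
    chemically plausible energy spreads, with injectable per-complex
    offsets so any alpha/beta/mix outcome can be forced.  This is the
    primary test surface: the whole pipeline runs in seconds with it.
``RDKitUFFBackend``
    A real force field (UFF, gas phase) for live prescreening without
    external executables.
``XTBBackend`` / ``OrcaBackend``
    Drivers for the external ``xtb`` (GFN-FF / GFN2, ALPB solvation) and
    ORCA (r2SCAN-3c, C-PCM) engines via generated input files.  Input
    generation and output parsing are plain functions, usable and
    testable without the executables; a missing or crashing engine
    yields ``converged=False`` instead of aborting the ensemble.

All energies are kJ/mol internally; unit conversion happens at the
engine boundary only.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .config import SolventSpec
from .convert import write_xyz
from .errors import PipelineError
from .util import quiet_rdkit

__all__ = [
    "EnergyRequest",
    "EnergyResult",
    "CalculatorBackend",
    "MockBackend",
    "RDKitUFFBackend",
    "XTBBackend",
    "OrcaBackend",
    "make_backend",
    "HARTREE_TO_KJ",
    "KCAL_TO_KJ",
]

HARTREE_TO_KJ = 2625.4996394799
KCAL_TO_KJ = 4.184

LEVELS = ("forcefield", "semiempirical", "dft_singlepoint", "mock")


@dataclass
class EnergyRequest:
    """One energy/optimization task on a single conformer."""

    mol: Chem.Mol  # hydrogen-explicit topology
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    charge: int
    stage: str  # pipeline stage name, recorded in the audit trail
    tag: str = ""  # complex id; lets the mock backend bias ensembles
    constraints: tuple[int, ...] = ()  # atom indices held fixed; () = free
    optimize: bool = True


@dataclass
class EnergyResult:
    energy: float  # kJ/mol
    coords: np.ndarray
    converged: bool = True


class CalculatorBackend(ABC):
    name: str = "abstract"
    level: str = "mock"
    solvent: SolventSpec | None = None
    supports_constraints: bool = True
    supports_optimization: bool = True

    @abstractmethod
    def compute(self, request: EnergyRequest) -> EnergyResult: ...


# ---------------------------------------------------------------------------


def _coords_hash_unit(coords: np.ndarray, stage: str) -> float:
    """Stable uniform variate in [0, 1) from rounded coordinates and the
    stage name.  Rounding to 1e-4 A makes the hash robust to printing
    round-trips while still separating genuinely distinct conformers."""
    blob = np.round(np.asarray(coords, dtype=float), 4).tobytes() + stage.encode()
    digest = hashlib.md5(blob).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class MockBackend(CalculatorBackend):
    """Deterministic stand-in engine for fast, reproducible pipelines.

    energy = base[level] + spread * U(coords, stage) + sum of biases
    whose key is a substring of the request tag.  Geometry is never
    changed, so the single-point contract holds trivially at every
    level.  ``fail_tags`` simulates engine crashes for the named
    complexes.
    """

    # Plausible absolute scales so reports look like each stage's output.
    _BASES = {
        "forcefield": 250.0,
        "semiempirical": -450_000.0,
        "dft_singlepoint": -6_800_000.0,
        "mock": 0.0,
    }

    def __init__(
        self,
        level: str = "mock",
        bias: dict[str, float] | None = None,
        spread: float = 8.0,
        fail_tags: tuple[str, ...] = (),
        solvent: SolventSpec | None = None,
    ):
        if level not in LEVELS:
            raise PipelineError(f"unknown backend level {level!r}")
        self.level = level
        self.name = f"mock-{level}"
        self.bias = dict(bias or {})
        self.spread = float(spread)
        self.fail_tags = tuple(fail_tags)
        self.solvent = solvent

    def compute(self, request: EnergyRequest) -> EnergyResult:
        if any(t in request.tag for t in self.fail_tags):
            return EnergyResult(float("nan"), request.coords, converged=False)
        u = _coords_hash_unit(request.coords, request.stage)
        offset = sum(v for k, v in self.bias.items() if k in request.tag)
        energy = self._BASES[self.level] + self.spread * u + offset
        return EnergyResult(energy, request.coords.copy(), converged=True)


# ---------------------------------------------------------------------------


class RDKitUFFBackend(CalculatorBackend):
    """UFF optimization/energy via RDKit (gas phase, no implicit solvent).

    Constrained atoms are true fixed points of the force field.  UFF has
    parameters across the periodic table, so Pd complexes are handled,
    if crudely; this backend is meant for the geometric prescreen rung
    only.
    """

    level = "forcefield"
    name = "uff"

    def __init__(self, max_iterations: int = 500):
        self.max_iterations = max_iterations

    def compute(self, request: EnergyRequest) -> EnergyResult:
        mol = Chem.Mol(request.mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(np.asarray(request.coords, dtype=float)):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.RemoveAllConformers()
        cid = mol.AddConformer(conf)
        try:
            with quiet_rdkit():  # UFF atom-typing chatter for Pd
                ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
                if ff is None:
                    return EnergyResult(float("nan"), request.coords, converged=False)
                for idx in request.constraints:
                    ff.AddFixedPoint(int(idx))
                ff.Initialize()
                converged = True
                if request.optimize:
                    converged = ff.Minimize(maxIts=self.max_iterations) == 0
                energy = ff.CalcEnergy() * KCAL_TO_KJ
            out = np.asarray(mol.GetConformer(cid).GetPositions(), dtype=float)
            return EnergyResult(energy, out, converged=converged)
        except Exception:
            return EnergyResult(float("nan"), request.coords, converged=False)


# ---------------------------------------------------------------------------


@dataclass
class XTBBackend(CalculatorBackend):
    """Driver for the external ``xtb`` binary (GFN-FF or GFN2-xTB with
    ALPB implicit solvation)."""

    method: str = "gfn2"  # "gfnff" | "gfn2"
    solvent: SolventSpec | None = field(
        default_factory=lambda: SolventSpec("phenol", 12.4)
    )
    executable: str = "xtb"

    def __post_init__(self):
        self.level = "forcefield" if self.method == "gfnff" else "semiempirical"
        self.name = f"xtb-{self.method}"

    def write_inputs(self, request: EnergyRequest, workdir: Path) -> list[str]:
        """Write geometry + control files; return the command line."""
        workdir = Path(workdir)
        symbols = [a.GetSymbol() for a in request.mol.GetAtoms()]
        write_xyz(workdir / "geom.xyz", symbols, request.coords, comment=request.tag)
        control = []
        if request.constraints:
            # xtb atom lists are 1-based
            atoms = ",".join(str(i + 1) for i in sorted(request.constraints))
            control += ["$fix", f"   atoms: {atoms}", "$end"]
        (workdir / "xcontrol").write_text("\n".join(control) + "\n")
        cmd = [self.executable, "geom.xyz", "--chrg", str(request.charge)]
        cmd += ["--gfnff"] if self.method == "gfnff" else ["--gfn", "2"]
        if request.optimize:
            cmd.append("--opt")
        if self.solvent is not None:
            cmd += ["--alpb", self.solvent.name]
        if request.constraints:
            cmd += ["--input", "xcontrol"]
        return cmd

    @staticmethod
    def parse_energy(output: str) -> float:
        """Total energy (kJ/mol) from xtb stdout."""
        for line in reversed(output.splitlines()):
            if "TOTAL ENERGY" in line:
                return float(line.split()[-3]) * HARTREE_TO_KJ
        raise ValueError("no TOTAL ENERGY line in xtb output")

    def compute(self, request: EnergyRequest) -> EnergyResult:
        if shutil.which(self.executable) is None:
            return EnergyResult(float("nan"), request.coords, converged=False)
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            cmd = self.write_inputs(request, tmp)
            try:
                proc = subprocess.run(
                    cmd, cwd=tmp, capture_output=True, text=True, timeout=3600
                )
                energy = self.parse_energy(proc.stdout)
                coords = request.coords
                opt_file = tmp / "xtbopt.xyz"
                if request.optimize and opt_file.exists():
                    from .convert import read_xyz

                    _, coords = read_xyz(opt_file)
                return EnergyResult(energy, coords, converged=proc.returncode == 0)
            except Exception:
                return EnergyResult(float("nan"), request.coords, converged=False)


@dataclass
class OrcaBackend(CalculatorBackend):
    """Driver for ORCA composite-DFT single points (r2SCAN-3c, C-PCM)."""

    keywords: str = "r2SCAN-3c"
    solvent: SolventSpec | None = field(
        default_factory=lambda: SolventSpec("ch2cl2", 9.08)
    )
    executable: str = "orca"
    level = "dft_singlepoint"
    name = "orca-r2scan-3c"
    supports_optimization = False
    supports_constraints = False

    def input_deck(self, request: EnergyRequest) -> str:
        solv = f" CPCM({self.solvent.name})" if self.solvent else ""
        lines = [f"! {self.keywords}{solv} TightSCF", "%pal nprocs 1 end"]
        lines.append(f"* xyz {request.charge} 1")
        for atom, (x, y, z) in zip(
            request.mol.GetAtoms(), np.asarray(request.coords, dtype=float)
        ):
            lines.append(f"  {atom.GetSymbol():<3s} {x:14.8f} {y:14.8f} {z:14.8f}")
        lines.append("*")
        return "\n".join(lines) + "\n"

    @staticmethod
    def parse_energy(output: str) -> float:
        """Final single-point energy (kJ/mol) from ORCA output."""
        for line in reversed(output.splitlines()):
            if "FINAL SINGLE POINT ENERGY" in line:
                return float(line.split()[-1]) * HARTREE_TO_KJ
        raise ValueError("no FINAL SINGLE POINT ENERGY line in ORCA output")

    def compute(self, request: EnergyRequest) -> EnergyResult:
        if shutil.which(self.executable) is None:
            return EnergyResult(float("nan"), request.coords, converged=False)
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            (tmp / "sp.inp").write_text(self.input_deck(request))
            try:
                proc = subprocess.run(
                    [self.executable, "sp.inp"],
                    cwd=tmp,
                    capture_output=True,
                    text=True,
                    timeout=86400,
                )
                energy = self.parse_energy(proc.stdout)
                # single point: geometry untouched by contract
                return EnergyResult(
                    energy, request.coords, converged=proc.returncode == 0
                )
            except Exception:
                return EnergyResult(float("nan"), request.coords, converged=False)


# ---------------------------------------------------------------------------

_FACTORY = {
    "mock": lambda level, **kw: MockBackend(level=level, **kw),
    "uff": lambda level, **kw: RDKitUFFBackend(**kw),
    "xtb-gfnff": lambda level, **kw: XTBBackend(method="gfnff", **kw),
    "xtb-gfn2": lambda level, **kw: XTBBackend(method="gfn2", **kw),
    "orca": lambda level, **kw: OrcaBackend(**kw),
}


def make_backend(name: str, level: str, **kwargs) -> CalculatorBackend:
    """Instantiate a backend by registry name for a pipeline stage level."""
    try:
        factory = _FACTORY[name]
    except KeyError:
        raise PipelineError(
            f"unknown backend {name!r}; available: {sorted(_FACTORY)}"
        ) from None
    return factory(level, **kwargs)
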