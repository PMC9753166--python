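"""Deterministic synthetic inputs for tests and demonstrations.

Everything here is generated programmatically from a seed: substrate
pairs (valid and deliberately broken), multi-halide electrophiles,
registry-style reaction-record tables covering every curation category,
and mock-energy bias sets that force any desired alpha/beta/mix
outcome through the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enumeration import enumerate_products, parse_substrates, rank_reactive_sites

__all__ = [
    "SUBSTRATE_CASES",
    "MULTISITE_PARTNERS",
    "mock_bias_for_deltas",
    "generate_records",
    "generate_fixtures",
]

# (alkene, partner, expected) where expected is "ok" or the error family
SUBSTRATE_CASES = [
    ("C=Cc1ccccc1", "Clc1ccccc1", "ok"),  # styrene + chlorobenzene
    ("C=CC(=O)OC", "Brc1ccccc1", "ok"),  # methyl acrylate + bromobenzene
    ("C=CC#N", "Ic1ccc(C)cc1", "ok"),  # acrylonitrile + 4-iodotoluene
    ("C=COCCCC", "OS(=O)(=O)C(F)(F)F", "substrate_error"),  # no C on OTf
    ("C=CC#N", "c1ccccc1OS(=O)(=O)C(F)(F)F", "ok"),  # aryl triflate
    ("CC=CC", "Brc1ccccc1", "substrate_error"),  # internal alkene
    ("CC(=C)C", "Brc1ccccc1", "substrate_error"),  # 1,1-disubstituted
    ("c1ccccc1", "Brc1ccccc1", "substrate_error"),  # no alkene at all
    ("C=Cc1ccccc1", "c1ccccc1", "substrate_error"),  # no C-X
    ("not a smiles", "Brc1ccccc1", "input_error"),
    ("C=Cc1ccccc1", "C=Cc1ccc(Br)cc1", "substrate_error"),  # bifunctional partner
]

# partners with several halide sites and the leaving group(s) expected
# to react (most reactive halide; all sites on a tie)
MULTISITE_PARTNERS = [
    ("Brc1ccc(I)cc1", ["I"]),
    ("Brc1ccc(Br)cc1", ["Br", "Br"]),
    ("Clc1ccc(OS(=O)(=O)C(F)(F)F)cc1", ["OTf"]),
    ("Ic1ccc(I)cc1", ["I", "I"]),
    ("Clc1cccc(Cl)c1", ["Cl", "Cl"]),
]

_RECORD_ALKENES = ["C=COCCCC", "C=CC(=O)OC", "C=Cc1ccccc1", "C=CC#N", "C=CN1CCCC1=O"]
# aryl electrophiles: halobenzenes with varied para substitution plus two
# triflates, large enough that accidental reaction duplicates are rare
_PARA_SUBS = ["", "C", "F", "OC", "C(F)(F)F", "C#N", "CC", "OCC", "N(C)C"]
_RECORD_PARTNERS = [
    f"{hal}c1ccc({sub})cc1" if sub else f"{hal}c1ccccc1"
    for hal in ("Br", "I", "Cl")
    for sub in _PARA_SUBS
] + [
    "c1ccc(OS(=O)(=O)C(F)(F)F)cc1C",
    "COc1ccc(OS(=O)(=O)C(F)(F)F)cc1",
]
_LIGANDS = ["PPh3", "DPPP", "DPPE", ""]
_SOLVENTS = ["DMF", "MeCN", "toluene", "DMAc"]
# long-chain alkene whose products exceed the 600 g/mol cut
_HEAVY_ALKENE = "C=C" + "C" * 40


def mock_bias_for_deltas(
    neutral_delta: float | None = None, cationic_delta: float | None = None
) -> dict[str, float]:
    """Bias set for the mock backend forcing E(alpha)-E(beta) per pathway.

    A positive delta puts the alpha intermediate above the beta one.
    The bias is applied to the alpha complexes of the pathway; keys are
    matched as substrings of the complex id.
    """
    bias: dict[str, float] = {}
    if neutral_delta is not None:
        bias["neutral-alpha"] = float(neutral_delta)
    if cationic_delta is not None:
        bias["cationic-alpha"] = float(cationic_delta)
    return bias


def _record_row(i, rxn, catalyst, ligand, additives, solvent):
    return {
        "record_id": f"r{i:04d}",
        "rxn_smiles": rxn,
        "catalyst": catalyst,
        "ligand": ligand,
        "additives": additives,
        "solvent": solvent,
    }


def generate_records(n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Registry-style reaction records covering every curation category.

    Roughly: 40% beta-only, 15% alpha-only, 10% mix, 10% no-match, 5%
    intramolecular, 10% duplicates of earlier rows, 5% over-weight
    products, 5% lithium-containing; a silver-additive flag is set on a
    subset of the alpha records to emulate cationic conditions.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    kinds = rng.choice(
        ["beta", "alpha", "mix", "no_match", "intra", "dup", "over_mw", "lithium"],
        size=n,
        p=[0.40, 0.15, 0.10, 0.10, 0.05, 0.10, 0.05, 0.05],
    )
    for i, kind in enumerate(kinds):
        alkene = _RECORD_ALKENES[rng.integers(len(_RECORD_ALKENES))]
        partner = _RECORD_PARTNERS[rng.integers(len(_RECORD_PARTNERS))]
        ligand = _LIGANDS[rng.integers(len(_LIGANDS))]
        solvent = _SOLVENTS[rng.integers(len(_SOLVENTS))]
        catalyst = "Pd(OAc)2"
        additives = "K2CO3"
        if kind == "dup" and rows:
            src = rows[rng.integers(len(rows))]
            rows.append(
                _record_row(i, src["rxn_smiles"], src["catalyst"], src["ligand"],
                            src["additives"], src["solvent"])
            )
            continue
        if kind == "lithium":
            additives = "K2CO3;LiCl"
        if kind == "over_mw":
            alkene = _HEAVY_ALKENE
        pair = parse_substrates(alkene, partner)
        site = rank_reactive_sites(pair)[0]
        prods = enumerate_products(pair, site)
        if kind == "alpha":
            reported = prods["alpha"]
            if rng.random() < 0.5:
                additives = "K2CO3;AgOAc"
        elif kind == "mix":
            reported = f"{prods['alpha']}.{prods['beta']}"
        elif kind == "no_match":
            reported = "CCO"
        else:  # beta, dup handled above, over_mw/lithium report beta
            reported = prods["beta"]
        if kind == "intra":
            # alkene tethered to the aryl bromide in a single molecule
            mol = "C=CCCCCOc1ccccc1Br"
            rxn = f"{mol}>>C1=CCCCCOc2ccccc21"
        else:
            rxn = f"{alkene}.{partner}>>{reported}"
        rows.append(_record_row(i, rxn, catalyst, ligand, additives, solvent))
    return pd.DataFrame(rows)


def generate_fixtures(kind: str, seed: int, outdir) -> Path:
    """Write one deterministic fixture file and return its path.

    Kinds: ``substrates`` (valid/invalid pair table), ``multisite``
    (multi-halide partner table), ``records`` (200 reaction records),
    ``mock_energies`` (bias sets forcing beta / alpha / mix outcomes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "substrates":
        path = outdir / "substrates.csv"
        pd.DataFrame(
            SUBSTRATE_CASES, columns=["alkene_smiles", "partner_smiles", "expected"]
        ).to_csv(path, index=False)
    elif kind == "multisite":
        path = outdir / "multisite.csv"
        pd.DataFrame(
            [(smi, ";".join(lgs)) for smi, lgs in MULTISITE_PARTNERS],
            columns=["partner_smiles", "expected_leaving_groups"],
        ).to_csv(path, index=False)
    elif kind == "records":
        path = outdir / "records.csv"
        generate_records(200, seed).to_csv(path, index=False)
    elif kind == "mock_energies":
        path = outdir / "mock_energies.json"
        payload = {
            "force_beta": mock_bias_for_deltas(52.0, 52.0),
            "force_alpha": mock_bias_for_deltas(-52.0, -52.0),
            "force_mix": mock_bias_for_deltas(0.0, 0.0),
            "reference_pattern": mock_bias_for_deltas(52.0, 5.0),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
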