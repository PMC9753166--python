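#!/usr/bin/env python
"""Opt-in live-engine integration runs (require ``xtb`` and ``orca``).

These drive the real energy ladder -- GFN-FF prescreen and GFN2-xTB
optimizations in ALPB phenol, r2SCAN-3c/C-PCM(DCM) single points -- and
therefore take hours of CPU; they are deliberately not part of the
default test suite.

Tasks
-----
reference
    Styrene + chlorobenzene.  Reports the alpha-beta intermediate gaps
    of the two neutral geometry variants and of the cationic pathway;
    the workflow's reference values are 52, 27 and 5 kJ/mol, and a
    deviation band of +-8 kJ/mol is reasonable given the stochastic
    conformational search.
substrate-set
    Twelve monosubstituted alkenes coupled with iodobenzene (neutral
    pathway) and phenyl triflate (cationic pathway); prints the call
    per pathway next to the expected pattern (neutral: all beta except
    the 2-pyrrolidone mix; cationic: mostly alpha for strong N/O
    donors, beta for acceptors, mixes in between).

Usage:  python scripts/integration_live_engines.py --task reference --out out.json
"""

from __future__ import annotations

import argparse
import json
import shutil
import sys
from pathlib import Path

from heckregio import PipelineConfig, classify_pathway, run_complexes
from heckregio import enumerate_complexes, parse_substrates, rank_reactive_sites
from heckregio.backends import OrcaBackend, XTBBackend

REFERENCE_GAPS = {"neutral-cis": 27.0, "neutral-trans": 52.0, "cationic": 5.0}
GAP_TOLERANCE = 8.0  # kJ/mol

# (label, alkene SMILES, expected neutral call, expected cationic call)
SUBSTRATE_SET = [
    ("a butyl-vinyl-ether", "C=COCCCC", "beta", "beta"),
    ("b N-vinylpyrrolidone", "C=CN1CCCC1=O", "mix", "alpha"),
    ("c N-methyl-N-vinylacetamide", "C=CN(C)C(C)=O", "beta", "alpha"),
    ("g vinyl-acetate", "C=COC(C)=O", "beta", "beta"),
    ("i N-vinylsuccinimide", "C=CN1C(=O)CCC1=O", "beta", "alpha"),
    ("f 3-buten-1-ol", "C=CCCO", "beta", "alpha"),
    ("- 1-hexene", "C=CCCCC", "beta", "mix"),
    ("h styrene", "C=Cc1ccccc1", "beta", "mix"),
    ("d allyl-alcohol", "C=CCO", "beta", "alpha"),
    ("e 3-buten-2-ol", "C=CC(C)O", "beta", "alpha"),
    ("k acrylonitrile", "C=CC#N", "beta", "beta"),
    ("j methyl-acrylate", "C=CC(=O)OC", "beta", "beta"),
]


def live_backends():
    for exe in ("xtb", "orca"):
        if shutil.which(exe) is None:
            sys.exit(f"error: {exe!r} not found on PATH; live runs need it")
    return {
        "forcefield": XTBBackend(method="gfnff"),
        "semiempirical": XTBBackend(method="gfn2"),
        "dft_singlepoint": OrcaBackend(),
    }


def run_pairs(alkene: str, partner: str, config, backends):
    pair = parse_substrates(alkene, partner)
    specs = []
    for site in rank_reactive_sites(pair):
        specs.extend(enumerate_complexes(pair, site))
    return run_complexes(specs, config, backends)


def task_reference(config, backends) -> dict:
    results = run_pairs("C=Cc1ccccc1", "Clc1ccccc1", config, backends)
    by_id = {r.spec.complex_id: r for r in results}

    def gap(alpha_id, beta_id):
        a, b = by_id[alpha_id], by_id[beta_id]
        if a.failed or b.failed:
            return None
        return a.final_energy - b.final_energy

    neutral_gaps = sorted(
        g
        for g in (
            gap("neutral-alpha-cis-site1", "neutral-beta-cis-site1"),
            gap("neutral-alpha-trans-site1", "neutral-beta-trans-site1"),
        )
        if g is not None
    )
    cationic_gap = gap("cationic-alpha-na-site1", "cationic-beta-na-site1")
    # The two neutral geometry variants are matched to the reference
    # gaps by magnitude; which variant carries which gap is not part of
    # the check.
    expected_neutral = sorted(
        v for k, v in REFERENCE_GAPS.items() if k.startswith("neutral")
    )
    report = {
        "neutral_gaps_kj_mol": neutral_gaps,
        "neutral_reference_kj_mol": expected_neutral,
        "cationic_gap_kj_mol": cationic_gap,
        "cationic_reference_kj_mol": REFERENCE_GAPS["cationic"],
        "within_tolerance": (
            len(neutral_gaps) == 2
            and cationic_gap is not None
            and all(
                abs(m - e) <= GAP_TOLERANCE
                for m, e in zip(neutral_gaps, expected_neutral)
            )
            and abs(cationic_gap - REFERENCE_GAPS["cationic"]) <= GAP_TOLERANCE
        ),
    }
    return report


def task_substrate_set(config, backends) -> dict:
    partners = {
        "neutral": "Ic1ccccc1",
        "cationic": "c1ccccc1OS(=O)(=O)C(F)(F)F",
    }
    report = {}
    for label, alkene, exp_neutral, exp_cationic in SUBSTRATE_SET:
        entry = {}
        for pathway, expected in (("neutral", exp_neutral), ("cationic", exp_cationic)):
            cfg = PipelineConfig(
                seed=config.seed, pathways=(pathway,), backends=config.backends
            )
            results = run_pairs(alkene, partners[pathway], cfg, backends)
            pred = classify_pathway(results, pathway, cfg.selectivity_cutoff)
            entry[pathway] = {
                "call": pred.call,
                "expected": expected,
                "delta_kj_mol": pred.delta,
            }
        report[label] = entry
        print(label, json.dumps(entry), flush=True)
    return report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--task", choices=["reference", "substrate-set"], required=True)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    config = PipelineConfig(seed=args.seed % 2**31)
    backends = live_backends()
    report = (
        task_reference(config, backends)
        if args.task == "reference"
        else task_substrate_set(config, backends)
    )
    text = json.dumps(report, indent=2)
    print(text)
    if args.out:
        Path(args.out).write_text(text + "\n")


if __name__ == "__main__":
    main()
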