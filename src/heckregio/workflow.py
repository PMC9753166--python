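"""End-to-end prediction: SMILES in, per-pathway selectivity report out."""

from __future__ import annotations

from .backends import CalculatorBackend
from .config import PipelineConfig
from .enumeration import enumerate_complexes, parse_substrates, rank_reactive_sites
from .pipeline import IntermediateResult, build_backends, run_complexes
from .selectivity import classify_pathway, compare_sites, render_report

__all__ = ["predict"]


def predict(
    alkene_smiles: str,
    partner_smiles: str,
    config: PipelineConfig | None = None,
    backends: dict[str, CalculatorBackend] | None = None,
) -> tuple[dict, str, list[IntermediateResult]]:
    """Run the whole workflow for one substrate pair.

    Parses and validates the substrates, enumerates the post-insertion
    complexes of every top-ranked reactive site, runs the energy ladder
    on each, classifies both pathways (energies pooled across sites and
    geometry variants) and renders the ranked-product report.

    Returns ``(report_dict, report_text, intermediate_results)``.
    """
    config = config or PipelineConfig()
    backends = backends or build_backends(config)
    pair = parse_substrates(alkene_smiles, partner_smiles)
    sites = rank_reactive_sites(pair)
    specs = []
    for site in sites:
        specs.extend(enumerate_complexes(pair, site, pathways=config.pathways))
    results = run_complexes(specs, config, backends)
    predictions = [
        classify_pathway(results, pw, config.selectivity_cutoff)
        for pw in config.pathways
    ]
    comparisons = None
    if len(sites) > 1:
        comparisons = [
            compare_sites(results, pw, config.selectivity_cutoff)
            for pw in config.pathways
        ]
    report, text = render_report(
        predictions, results, comparisons, config_hash=config.config_hash
    )
    report["input"] = {
        "alkene_smiles": alkene_smiles,
        "partner_smiles": partner_smiles,
        "n_reactive_sites": len(sites),
        "leaving_groups": [s.leaving_group for s in sites],
    }
    report["complexes"] = [r.to_dict() for r in results]
    return report, text, results
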