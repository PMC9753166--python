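"""Regioselectivity calls from intermediate energies.

The proxy for the regiochemical outcome is the energy gap between the
lowest alpha and lowest beta post-insertion intermediate of a pathway,

    delta = E_alpha_min - E_beta_min   (kJ/mol),

minimised over geometry variants (neutral: cis and trans) and
conformers.  With the 3 kcal/mol ~ 12.6 kJ/mol method-accuracy cutoff:

* delta < -cutoff  -> alpha (branched) product predicted,
* delta > +cutoff  -> beta (linear) product predicted,
* |delta| <= cutoff -> mix (the boundary counts as mix),
* either minimum missing -> undetermined.

Neutral and cationic pathways are classified independently and reported
side by side; no attempt is made to weigh them into a single call,
because which pathway operates depends on reaction conditions the
energies alone cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pipeline import IntermediateResult

__all__ = [
    "PathwayPrediction",
    "SiteComparison",
    "classify_pathway",
    "compare_sites",
    "render_report",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 12.6  # kJ/mol, ~3 kcal/mol

REPORT_SCHEMA_VERSION = "1"


@dataclass
class PathwayPrediction:
    pathway: str
    e_alpha_min: float | None
    e_beta_min: float | None
    cutoff: float
    call: str  # "alpha" | "beta" | "mix" | "undetermined"
    reason: str | None = None
    # per-complex energies backing the call, keyed by complex_id
    energies: dict[str, float] = field(default_factory=dict)

    @property
    def delta(self) -> float | None:
        if self.e_alpha_min is None or self.e_beta_min is None:
            return None
        return self.e_alpha_min - self.e_beta_min

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "e_alpha_min_kj_mol": self.e_alpha_min,
            "e_beta_min_kj_mol": self.e_beta_min,
            "delta_kj_mol": self.delta,
            "cutoff_kj_mol": self.cutoff,
            "call": self.call,
            "reason": self.reason,
            "energies_kj_mol": self.energies,
        }


def _call_from_delta(delta: float, cutoff: float) -> str:
    if delta < -cutoff:
        return "alpha"
    if delta > cutoff:
        return "beta"
    return "mix"


def classify_pathway(
    results: list[IntermediateResult],
    pathway: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> PathwayPrediction:
    """Call alpha/beta/mix for one pathway from per-complex results.

    Minima are pooled over geometry variants and conformers; a pathway
    missing a successful alpha or beta intermediate is undetermined.
    """
    mine = [r for r in results if r.spec.pathway == pathway]
    energies = {
        r.spec.complex_id: r.final_energy for r in mine if not r.failed
    }

    def regio_min(regio: str) -> float | None:
        vals = [
            r.final_energy
            for r in mine
            if not r.failed and r.spec.regiochemistry == regio
        ]
        return min(vals) if vals else None

    e_a, e_b = regio_min("alpha"), regio_min("beta")
    if e_a is None or e_b is None:
        missing = [r for r in ("alpha", "beta") if regio_min(r) is None]
        return PathwayPrediction(
            pathway=pathway,
            e_alpha_min=e_a,
            e_beta_min=e_b,
            cutoff=cutoff,
            call="undetermined",
            reason=f"no successful {' or '.join(missing)} intermediate",
            energies=energies,
        )
    return PathwayPrediction(
        pathway=pathway,
        e_alpha_min=e_a,
        e_beta_min=e_b,
        cutoff=cutoff,
        call=_call_from_delta(e_a - e_b, cutoff),
        energies=energies,
    )


@dataclass
class SiteComparison:
    """Pooled prediction across several reactive sites of one partner.

    All site x regiochemistry intermediate energies of a pathway are
    referenced to the global minimum; products within the cutoff of that
    minimum form the predicted mixture set, the rest are ranked by
    increasing relative energy.
    """

    pathway: str
    cutoff: float
    failed: bool
    # (product_smiles, site_index, relative energy) ascending
    ranking: list[tuple[str, int, float]] = field(default_factory=list)
    mixture_set: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "cutoff_kj_mol": self.cutoff,
            "failed": self.failed,
            "ranking": [
                {"product_smiles": p, "site": s, "relative_energy_kj_mol": e}
                for p, s, e in self.ranking
            ],
            "predicted_products": self.mixture_set,
        }


def compare_sites(
    results: list[IntermediateResult],
    pathway: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> SiteComparison:
    """Rank products across all reactive sites of a pathway.

    With a single site this reduces to the information behind
    :func:`classify_pathway`; with several tied top-reactivity sites it
    predicts both the preferred site and the regiochemistry.
    """
    pool: dict[tuple[str, int], float] = {}
    for r in results:
        if r.failed or r.spec.pathway != pathway:
            continue
        key = (r.spec.product_smiles, r.spec.site.carbon_index)
        e = r.final_energy
        if key not in pool or e < pool[key]:
            pool[key] = e
    if not pool:
        return SiteComparison(pathway=pathway, cutoff=cutoff, failed=True)
    e_min = min(pool.values())
    ranking = sorted(
        ((p, s, e - e_min) for (p, s), e in pool.items()), key=lambda t: (t[2], t[0], t[1])
    )
    mixture = [p for p, _, rel in ranking if rel <= cutoff]
    # preserve ranking order but drop duplicate product entries
    seen: set[str] = set()
    mixture = [p for p in mixture if not (p in seen or seen.add(p))]
    return SiteComparison(
        pathway=pathway, cutoff=cutoff, failed=False, ranking=ranking, mixture_set=mixture
    )


def render_report(
    predictions: list[PathwayPrediction],
    results: list[IntermediateResult] | None = None,
    site_comparisons: list[SiteComparison] | None = None,
    config_hash: str | None = None,
) -> tuple[dict, str]:
    """Build the machine-readable report and its text rendering.

    Per pathway, products are listed in order of increasing intermediate
    energy (ties broken by regiochemistry then geometry variant, so the
    listing is stable).
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if config_hash:
        report["config_hash"] = config_hash
    report["pathways"] = {}
    lines: list[str] = []
    for pred in predictions:
        entry = pred.to_dict()
        if results is not None:
            ranked = sorted(
                (
                    (
                        r.final_energy,
                        r.spec.regiochemistry,
                        r.spec.geometry_variant or "",
                        r.spec.product_smiles,
                        r.spec.complex_id,
                    )
                    for r in results
                    if r.spec.pathway == pred.pathway and not r.failed
                ),
            )
            entry["products_by_energy"] = [
                {
                    "complex_id": cid,
                    "regiochemistry": regio,
                    "geometry_variant": var or None,
                    "product_smiles": smi,
                    "energy_kj_mol": e,
                }
                for e, regio, var, smi, cid in ranked
            ]
        report["pathways"][pred.pathway] = entry

        lines.append(f"pathway: {pred.pathway}")
        lines.append(f"  call: {pred.call}" + (f" ({pred.reason})" if pred.reason else ""))
        if pred.delta is not None:
            lines.append(
                f"  E(alpha)-E(beta) = {pred.delta:+.1f} kJ/mol"
                f"  (cutoff {pred.cutoff:.1f})"
            )
        for item in entry.get("products_by_energy", []):
            lines.append(
                f"    {item['regiochemistry']:<5s} "
                f"{(item['geometry_variant'] or '-'):<5s} "
                f"{item['energy_kj_mol']:>14.1f} kJ/mol  {item['product_smiles']}"
            )
    if site_comparisons:
        report["site_comparisons"] = {
            sc.pathway: sc.to_dict() for sc in site_comparisons
        }
    return report, "\n".join(lines) + "\n"
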