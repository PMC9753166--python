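"""Substrate validation and post-insertion complex enumeration.

The Heck coupling considered here joins a monosubstituted alkene
``CH2=CH-R`` with an aryl or vinyl electrophile ``Ar-X``
(X = I, OTf, Br, Cl) under Pd(0)/PPh3 catalysis.  The regiochemical
outcome is decided at the migratory-insertion step, so the objects this
module enumerates are the Pd(II) *post-insertion* complexes, one per
combination of

* pathway  -- ``neutral`` (X stays on Pd) or ``cationic`` (X dissociated,
  complex carries +1 charge and a second phosphine);
* regiochemistry -- ``alpha`` (branched: aryl adds to the substituted
  alkene carbon, Pd to the terminal CH2) or ``beta`` (linear: the
  reverse);
* geometry variant -- for the neutral pathway the halide can sit *cis*
  or *trans* to the Pd-bound alkyl carbon in the square-planar complex;
  the two variants share one molecular graph and differ only in the 3D
  template used downstream.

For a single reactive site this yields exactly six complexes
(4 neutral + 2 cationic).  The rewrite rules are explicit reaction
SMARTS (diagrams below), applied with RDKit's ``RunReactants``.

Insertion rewrite (alpha shown; beta swaps the roles of C1 and C2)::

    CH2=CH-R   +   Ar-X      -->      [Pd]-CH2-CH(Ar)(R)     + (X on Pd
     C1   C2                            |    C1   C2            for the
                                     L, (X)                     neutral
                                                                path)

beta-hydride elimination of these alkyls (not modelled, but used to name
the organic product of each complex) gives ``CH2=C(Ar)R`` (branched,
alpha) and ``R-CH=CH-Ar`` (linear, beta; double-bond stereochemistry
left unspecified because it is set later in the catalytic cycle).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdMolDescriptors

from .util import quiet_rdkit
from .errors import (
    AmbiguousSubstrateError,
    EnumerationError,
    InputError,
    SubstrateError,
)

__all__ = [
    "ReactiveSite",
    "SubstratePair",
    "ComplexSpec",
    "parse_substrates",
    "rank_reactive_sites",
    "enumerate_complexes",
    "REACTIVITY_ORDER",
]

# Empirical oxidative-addition reactivity order of the leaving group.
# Lower rank = more reactive; reactions are assumed to occur only at the
# top-ranked site(s) present in the electrophile.
REACTIVITY_ORDER: dict[str, int] = {"I": 0, "OTf": 1, "Br": 2, "Cl": 3}

PATHWAYS = ("neutral", "cationic")
REGIOCHEMISTRIES = ("alpha", "beta")
NEUTRAL_VARIANTS = ("cis", "trans")

# --- substrate patterns -------------------------------------------------
# Monosubstituted alkene: a CH2 terminus double-bonded to a CH carrying
# exactly one non-hydrogen substituent.
_MONOSUB_ALKENE = Chem.MolFromSmarts("[CH2]=[CH][!#1]")
# Any C=C at all, used to tell "internal alkene" apart from "no alkene"
# in error messages.
_ANY_ALKENE = Chem.MolFromSmarts("[#6]=[#6]")

# Electrophilic carbon: aromatic, or sp2 carbon of a vinyl unit.
_SP2_C = "$([c]),$([#6]=[#6])"
_HALIDE_SITE = Chem.MolFromSmarts(f"[{_SP2_C}][Cl,Br,I]")
_TRIFLATE_SITE = Chem.MolFromSmarts(f"[{_SP2_C}]OS(=O)(=O)C(F)(F)F")

# --- rewrite templates --------------------------------------------------
_PPH3 = "P(c1ccccc1)(c1ccccc1)c1ccccc1"
_ALKENE_Q = "[CH2:1]=[CH:2][!#1:3]"
_ARX_HAL_Q = f"[{_SP2_C}:4][Cl,Br,I:5]"
# The triflate ester is matched atom-by-atom so the whole group can be
# transferred to Pd in the neutral pathway.
_OTF_TAIL = "[S:6](=[O:7])(=[O:8])[C:9]([F:10])([F:11])[F:12]"
_ARX_OTF_Q = f"[{_SP2_C}:4][O:5]{_OTF_TAIL}"

# Pd fragments on the product side.  ``<-`` denotes a dative bond from
# phosphorus; the neutral complex keeps X as a covalent Pd ligand, the
# cationic complex drops X and binds a second phosphine.
_PD_NEUTRAL_HAL = f"[Pd]([*:5])<-{_PPH3}"
_PD_NEUTRAL_OTF = f"[Pd]([O:5]{_OTF_TAIL})<-{_PPH3}"
_PD_CATIONIC = f"[Pd+](<-{_PPH3})<-{_PPH3}"


def _insertion_rxn(lhs: str, pd_frag: str, regio: str) -> str:
    if regio == "alpha":
        # Pd on the terminal CH2 (C1), aryl on the substituted carbon (C2).
        rhs = f"[CH2:1]({pd_frag})[CH:2]([*:4])[*:3]"
    else:
        # Pd on the substituted carbon (C2), aryl on the CH2 terminus (C1).
        rhs = f"[CH:2]([*:3])({pd_frag})[CH2:1][*:4]"
    return f"{lhs}>>{rhs}"


def _product_rxn(lhs: str, regio: str) -> str:
    if regio == "alpha":
        rhs = "[CH2:1]=[C:2]([*:4])[*:3]"  # branched CH2=C(Ar)R
    else:
        rhs = "[*:3][CH:2]=[CH:1][*:4]"  # linear R-CH=CH-Ar, stereo unset
    return f"{lhs}>>{rhs}"


def _compile_reactions() -> dict:
    """Build all rewrite rules once, silencing RDKit's warning about the
    intentionally dropped leaving group on the cationic side."""
    lg_queries = {"halide": f"{_ALKENE_Q}.{_ARX_HAL_Q}", "OTf": f"{_ALKENE_Q}.{_ARX_OTF_Q}"}
    pd_frags = {
        ("neutral", "halide"): _PD_NEUTRAL_HAL,
        ("neutral", "OTf"): _PD_NEUTRAL_OTF,
        ("cationic", "halide"): _PD_CATIONIC,
        ("cationic", "OTf"): _PD_CATIONIC,
    }
    RDLogger.DisableLog("rdApp.*")
    try:
        rxns = {}
        for (pathway, lg_kind), frag in pd_frags.items():
            for regio in REGIOCHEMISTRIES:
                sma = _insertion_rxn(lg_queries[lg_kind], frag, regio)
                rxns[("complex", pathway, regio, lg_kind)] = AllChem.ReactionFromSmarts(sma)
        for lg_kind, lhs in lg_queries.items():
            for regio in REGIOCHEMISTRIES:
                rxns[("product", regio, lg_kind)] = AllChem.ReactionFromSmarts(
                    _product_rxn(lhs, regio)
                )
        return rxns
    finally:
        RDLogger.EnableLog("rdApp.error")
        RDLogger.EnableLog("rdApp.warning")


_REACTIONS = _compile_reactions()


# --- domain types -------------------------------------------------------


@dataclass(frozen=True)
class ReactiveSite:
    """One electrophilic C-X site on the coupling partner.

    ``carbon_index``/``x_index`` are atom indices into the partner
    molecule; for a triflate ``x_index`` is the ester oxygen.
    """

    carbon_index: int
    x_index: int
    leaving_group: str  # "I" | "OTf" | "Br" | "Cl"
    rank: int

    @property
    def leaving_group_atoms(self) -> int:
        """Heavy atoms lost with the leaving group (1 for halides, 8 for OTf)."""
        return 8 if self.leaving_group == "OTf" else 1


@dataclass
class SubstratePair:
    """Validated alkene + electrophile pair ready for enumeration."""

    alkene: Chem.Mol
    partner: Chem.Mol
    alkene_smiles: str
    partner_smiles: str
    # (CH2, CH, substituent) atom-index triples; normally length 1
    alkene_matches: list[tuple[int, int, int]] = field(default_factory=list)
    sites: list[ReactiveSite] = field(default_factory=list)
    ambiguous_alkene: bool = False


@dataclass
class ComplexSpec:
    """One post-insertion Pd complex and the organic product it leads to."""

    pathway: str  # "neutral" | "cationic"
    regiochemistry: str  # "alpha" | "beta"
    geometry_variant: str | None  # "cis" | "trans" | None
    charge: int
    mol: Chem.Mol
    product_smiles: str
    site: ReactiveSite

    @property
    def complex_id(self) -> str:
        variant = self.geometry_variant or "na"
        return (
            f"{self.pathway}-{self.regiochemistry}-{variant}"
            f"-site{self.site.carbon_index}"
        )

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def n_rotatable_product(self) -> int:
        """Rotatable bonds of the organic product (strict definition:
        non-ring single bonds between heavy atoms each bearing another
        heavy neighbour, amide C-N excluded)."""
        prod = Chem.MolFromSmiles(self.product_smiles)
        return rdMolDescriptors.CalcNumRotatableBonds(
            prod, rdMolDescriptors.NumRotatableBondsOptions.Strict
        )

    def to_dict(self) -> dict:
        return {
            "complex_id": self.complex_id,
            "pathway": self.pathway,
            "regiochemistry": self.regiochemistry,
            "geometry_variant": self.geometry_variant,
            "charge": self.charge,
            "smiles": self.smiles,
            "product_smiles": self.product_smiles,
            "site": {
                "carbon_index": self.site.carbon_index,
                "x_index": self.site.x_index,
                "leaving_group": self.site.leaving_group,
            },
        }


# --- operations ---------------------------------------------------------


def _find_sites(partner: Chem.Mol) -> list[ReactiveSite]:
    sites: list[ReactiveSite] = []
    # Triflates first so the ester oxygen is not double-counted: the
    # halide pattern cannot match O, so no overlap is possible, but
    # ordering keeps site lists stable.
    for match in partner.GetSubstructMatches(_TRIFLATE_SITE):
        carbon, oxygen = match[0], match[1]
        sites.append(ReactiveSite(carbon, oxygen, "OTf", REACTIVITY_ORDER["OTf"]))
    for carbon, x in partner.GetSubstructMatches(_HALIDE_SITE):
        sym = partner.GetAtomWithIdx(x).GetSymbol()
        sites.append(ReactiveSite(carbon, x, sym, REACTIVITY_ORDER[sym]))
    sites.sort(key=lambda s: (s.rank, s.carbon_index))
    return sites


def _distinct_alkene_matches(mol: Chem.Mol) -> list[tuple[int, int, int]]:
    seen: set[frozenset[int]] = set()
    out = []
    for match in mol.GetSubstructMatches(_MONOSUB_ALKENE):
        key = frozenset(match[:2])  # the C=C unit
        if key not in seen:
            seen.add(key)
            out.append(tuple(match))
    return out


def parse_substrates(
    alkene_smiles: str,
    partner_smiles: str,
    *,
    allow_ambiguous_alkene: bool = False,
    allow_bifunctional: bool = False,
) -> SubstratePair:
    """Parse and validate the two reactants.

    Parameters
    ----------
    alkene_smiles, partner_smiles:
        SMILES of the monosubstituted alkene and of the aryl/vinyl
        halide or triflate.
    allow_ambiguous_alkene:
        If the alkene molecule contains several distinct monosubstituted
        C=C units, keep all of them instead of raising
        :class:`AmbiguousSubstrateError`.
    allow_bifunctional:
        Accept molecules that carry both functionalities (an alkene that
        also bears a C-X bond, or a partner that also contains a
        monosubstituted alkene).  Off by default because such inputs
        usually signal an intramolecular reaction, which this tool does
        not model.

    Raises
    ------
    InputError
        A SMILES string did not parse.
    SubstrateError
        The alkene has no (or no *mono*-substituted) C=C, or the partner
        has no reactive C-X bond.
    """
    alkene = Chem.MolFromSmiles(alkene_smiles)
    if alkene is None:
        raise InputError(f"could not parse alkene SMILES {alkene_smiles!r}")
    partner = Chem.MolFromSmiles(partner_smiles)
    if partner is None:
        raise InputError(f"could not parse partner SMILES {partner_smiles!r}")

    matches = _distinct_alkene_matches(alkene)
    if not matches:
        if alkene.HasSubstructMatch(_ANY_ALKENE):
            raise SubstrateError(
                f"alkene {alkene_smiles!r} has no monosubstituted C=C: both "
                "alkene carbons carry substituents (or the terminus is not CH2)"
            )
        raise SubstrateError(f"no C=C double bond found in {alkene_smiles!r}")
    if len(matches) > 1 and not allow_ambiguous_alkene:
        raise AmbiguousSubstrateError(
            f"{len(matches)} distinct monosubstituted alkenes in "
            f"{alkene_smiles!r}; pass allow_ambiguous_alkene=True to "
            "enumerate all of them"
        )

    sites = _find_sites(partner)
    if not sites:
        raise SubstrateError(
            f"no aryl/vinyl C-X bond (X = I, OTf, Br, Cl) in {partner_smiles!r}"
        )

    if not allow_bifunctional:
        if _find_sites(alkene):
            raise SubstrateError(
                f"alkene {alkene_smiles!r} also carries a reactive C-X bond; "
                "intramolecular couplings are not modelled "
                "(pass allow_bifunctional=True to override)"
            )
        if _distinct_alkene_matches(partner):
            raise SubstrateError(
                f"partner {partner_smiles!r} also contains a monosubstituted "
                "alkene; intramolecular couplings are not modelled "
                "(pass allow_bifunctional=True to override)"
            )

    return SubstratePair(
        alkene=alkene,
        partner=partner,
        alkene_smiles=alkene_smiles,
        partner_smiles=partner_smiles,
        alkene_matches=matches,
        sites=sites,
        ambiguous_alkene=len(matches) > 1,
    )


def rank_reactive_sites(pair: SubstratePair) -> list[ReactiveSite]:
    """Return the site(s) carrying the most reactive leaving group.

    The reactivity order is I >> OTf > Br >> Cl; only top-ranked sites
    react.  Several sites tie when the same best leaving group occurs
    more than once, and all of them are then returned.
    """
    best = min(s.rank for s in pair.sites)
    return [s for s in pair.sites if s.rank == best]


def _run_site_specific(rxn, pair: SubstratePair, site: ReactiveSite) -> list[Chem.Mol]:
    """Apply one rewrite and keep only products arising from *site*.

    ``RunReactants`` tries every match; product atoms remember their
    reactant atom index, so the ipso carbon (map 4) identifies which
    C-X site was consumed.
    """
    products = []
    seen: set[str] = set()
    with quiet_rdkit():
        product_sets = rxn.RunReactants((pair.alkene, pair.partner))
    for prods in product_sets:
        mol = prods[0]
        ipso = next(
            a for a in mol.GetAtoms() if a.HasProp("old_mapno") and a.GetIntProp("old_mapno") == 4
        )
        if a_idx(ipso) != site.carbon_index:
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - exotic valence inputs
            raise EnumerationError(
                f"rewrite produced an unsanitizable structure: {exc}",
                pattern=AllChem.ReactionToSmarts(rxn),
            ) from exc
        smi = Chem.MolToSmiles(mol)
        if smi not in seen:
            seen.add(smi)
            products.append(mol)
    return products


def a_idx(atom: Chem.Atom) -> int:
    """Original reactant atom index recorded by RunReactants."""
    return atom.GetIntProp("react_atom_idx")


def enumerate_products(
    pair: SubstratePair, site: ReactiveSite
) -> dict[str, str]:
    """Canonical SMILES of the two organic products for one site,
    keyed by regiochemistry (``alpha`` branched, ``beta`` linear with
    unspecified double-bond stereochemistry)."""
    lg_kind = "OTf" if site.leaving_group == "OTf" else "halide"
    out = {}
    for regio in REGIOCHEMISTRIES:
        mols = _run_site_specific(_REACTIONS[("product", regio, lg_kind)], pair, site)
        if not mols:
            raise EnumerationError(f"product rewrite matched no atoms for {regio}")
        out[regio] = Chem.MolToSmiles(mols[0])
    return out


def enumerate_complexes(
    pair: SubstratePair,
    site: ReactiveSite,
    pathways: tuple[str, ...] = PATHWAYS,
) -> list[ComplexSpec]:
    """Generate every post-insertion complex for one reactive site.

    Returns 4 neutral (alpha/beta x cis/trans) + 2 cationic specs when
    both pathways are requested.  The two neutral geometry variants
    share a molecular graph; they differ in which 3D catalyst-core
    template constrains the embedding later on.
    """
    if site not in pair.sites:
        raise EnumerationError("site does not belong to this substrate pair")
    lg_kind = "OTf" if site.leaving_group == "OTf" else "halide"
    specs: list[ComplexSpec] = []
    for pathway in pathways:
        if pathway not in PATHWAYS:
            raise EnumerationError(f"unknown pathway {pathway!r}")
        charge = 0 if pathway == "neutral" else 1
        variants = NEUTRAL_VARIANTS if pathway == "neutral" else (None,)
        for regio in REGIOCHEMISTRIES:
            rxn = _REACTIONS[("complex", pathway, regio, lg_kind)]
            mols = _run_site_specific(rxn, pair, site)
            if not mols:
                raise EnumerationError(
                    f"insertion rewrite matched no atoms for {pathway}/{regio}",
                    pattern=AllChem.ReactionToSmarts(rxn),
                )
            prod_rxn = _REACTIONS[("product", regio, lg_kind)]
            prod_mols = _run_site_specific(prod_rxn, pair, site)
            product_smiles = Chem.MolToSmiles(prod_mols[0])
            for mol, variant in itertools.product(mols, variants):
                specs.append(
                    ComplexSpec(
                        pathway=pathway,
                        regiochemistry=regio,
                        geometry_variant=variant,
                        charge=charge,
                        mol=mol,
                        product_smiles=product_smiles,
                        site=site,
                    )
                )
    return specs
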