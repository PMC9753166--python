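"""Curation and scoring of literature Heck-reaction records.

Consumes a flat CSV of reaction records (reaction SMILES plus free-text
condition fields, the shape of a typical registry export) and

* classifies each record by matching its reported products against the
  template-generated alpha/beta products of the detected coupling
  partners (``inter_alpha`` / ``inter_beta`` / ``inter_mix`` /
  ``intra`` / ``no_match``),
* annotates ligand denticity, "cationic conditions" (triflate partner
  or a halide-scavenger additive) and the classical alkene-substituent
  class (electron-donating O/N vs electron-withdrawing carbonyl/aryl),
* filters duplicates, oversized products and excluded additives, and
* scores regioselectivity predictions against reported outcomes with
  3x3 confusion matrices and the relaxed "not-alpha"/"not-beta"
  accuracies in which a predicted mix is credited to the observed
  isomer.

The precatalyst allowlist and additive exclusion lists are editable
configuration; the defaults shipped here are deliberately small,
documented placeholders rather than a literature-complete set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .enumeration import (
    enumerate_products,
    parse_substrates,
    rank_reactive_sites,
)
from .errors import CurationError, HeckRegioError
from .util import quiet_rdkit

__all__ = [
    "ReactionRecord",
    "CurationLabel",
    "CurationConfig",
    "classify_record",
    "filter_records",
    "score_predictions",
    "records_from_dataframe",
    "ScoreReport",
]

CATEGORIES = ("inter_alpha", "inter_beta", "inter_mix", "intra", "no_match")
CALL_CLASSES = ("alpha", "beta", "mix")

# Classical alkene-substituent classes: the atom bonded to the vinyl CH
# is O/N (or an sp3 carbon bonded to O/N) for the donor class, a
# carbonyl carbon or an aromatic carbon for the acceptor class.
_EDG_PATTERNS = [
    Chem.MolFromSmarts("[CH2]=[CH][#8,#7]"),
    Chem.MolFromSmarts("[CH2]=[CH][CX4][#8,#7]"),
]
_EWG_PATTERNS = [
    Chem.MolFromSmarts("[CH2]=[CH][CX3]=[OX1]"),
    Chem.MolFromSmarts("[CH2]=[CH][c]"),
]

_MONOSUB = Chem.MolFromSmarts("[CH2]=[CH][!#1]")


@dataclass(frozen=True)
class ReactionRecord:
    record_id: str
    rxn_smiles: str
    catalyst: str = ""
    ligand: str = ""
    additives: tuple[str, ...] = ()
    solvent: str = ""


@dataclass(frozen=True)
class CurationLabel:
    record_id: str
    category: str  # one of CATEGORIES
    ligand_class: str  # monodentate | bidentate | undefined
    cationic_conditions: bool
    substituent_class: str  # EDG_ON | EWG_carbonyl_aryl | other
    reason: str | None = None

    @property
    def observed_call(self) -> str | None:
        return {
            "inter_alpha": "alpha",
            "inter_beta": "beta",
            "inter_mix": "mix",
        }.get(self.category)


@dataclass
class CurationConfig:
    """Editable curation lists and thresholds."""

    mw_limit: float = 600.0
    # element symbols whose presence in an additive excludes the record
    excluded_elements: tuple[str, ...] = ("Li",)
    excluded_names: tuple[str, ...] = ("lithium",)
    # halide scavengers switching the mechanism to the cationic pathway
    scavenger_elements: tuple[str, ...] = ("Ag", "Tl")
    scavenger_names: tuple[str, ...] = ("silver", "thallium")
    monodentate_ligands: tuple[str, ...] = ("pph3", "triphenylphosphine", "p(ph)3")
    bidentate_ligands: tuple[str, ...] = ("dppp", "dppe")
    # None = allow every catalyst (placeholder; supply your own list)
    precatalyst_allowlist: tuple[str, ...] | None = None


def _mentions_element(text: str, element: str) -> bool:
    # Case-sensitive symbol token: "LiCl" yes, "aniline" no.
    return re.search(rf"(?<![A-Za-z]){element}(?![a-z])", text) is not None


def _mentions(texts: tuple[str, ...], elements, names) -> bool:
    for t in texts:
        if any(_mentions_element(t, e) for e in elements):
            return True
        low = t.lower()
        if any(n in low for n in names):
            return True
    return False


def _ligand_class(ligand: str, config: CurationConfig) -> str:
    low = ligand.lower().replace(" ", "")
    if any(tok in low for tok in config.bidentate_ligands):
        return "bidentate"
    if any(tok in low for tok in config.monodentate_ligands):
        return "monodentate"
    return "undefined"


def _substituent_class(alkene: Chem.Mol) -> str:
    if any(alkene.HasSubstructMatch(p) for p in _EDG_PATTERNS):
        return "EDG_ON"
    if any(alkene.HasSubstructMatch(p) for p in _EWG_PATTERNS):
        return "EWG_carbonyl_aryl"
    return "other"


def _stereo_insensitive(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def split_reaction_smiles(rxn_smiles: str) -> tuple[list[str], list[str]]:
    """(reactants, products) fragment SMILES of a reaction SMILES;
    agents in the middle field are ignored."""
    parts = rxn_smiles.split(">")
    if len(parts) != 3:
        raise CurationError(f"malformed reaction SMILES {rxn_smiles!r}")
    reactants = [s for s in parts[0].split(".") if s]
    products = [s for s in parts[2].split(".") if s]
    return reactants, products


def classify_record(
    record: ReactionRecord, config: CurationConfig | None = None
) -> CurationLabel:
    """Assign the match category and condition annotations for one record.

    Coupling partners are detected among the reactants (a molecule
    carrying both the alkene and the C-X bond marks the record
    intramolecular), the template products are generated for every
    top-ranked reactive site, and reported products are compared by
    stereochemistry-insensitive canonical SMILES.
    """
    config = config or CurationConfig()

    def label(category, substituent="other", reason=None, alkene_mol=None):
        return CurationLabel(
            record_id=record.record_id,
            category=category,
            ligand_class=_ligand_class(record.ligand, config),
            cationic_conditions=cationic,
            substituent_class=(
                _substituent_class(alkene_mol) if alkene_mol is not None else substituent
            ),
            reason=reason,
        )

    cationic = _mentions(
        record.additives, config.scavenger_elements, config.scavenger_names
    )
    try:
        reactant_smis, product_smis = split_reaction_smiles(record.rxn_smiles)
    except CurationError as exc:
        return label("no_match", reason=str(exc))

    reactants = [(s, Chem.MolFromSmiles(s)) for s in reactant_smis]
    if any(m is None for _, m in reactants) or not product_smis:
        return label("no_match", reason="unparseable reactant or empty products")

    # Triflate electrophiles also count as cationic conditions.
    triflate = Chem.MolFromSmarts("[c,$([#6]=[#6])]OS(=O)(=O)C(F)(F)F")
    if any(m.HasSubstructMatch(triflate) for _, m in reactants):
        cationic = True

    alkenes = [(s, m) for s, m in reactants if m.HasSubstructMatch(_MONOSUB)]
    from .enumeration import _find_sites  # site detection shared with enumeration

    electrophiles = [(s, m) for s, m in reactants if _find_sites(m)]
    bifunctional = [s for s, m in alkenes if _find_sites(m)]
    if bifunctional:
        return label("intra", reason="alkene and C-X bond on one molecule")
    if not alkenes or not electrophiles:
        return label("no_match", reason="coupling partners not detected")

    reported = {
        canon
        for s in product_smis
        if (canon := _stereo_insensitive(s)) is not None
    }

    matched_alpha = matched_beta = False
    alkene_used = alkenes[0][1]
    for (alk_s, alk_m) in alkenes:
        for (el_s, el_m) in electrophiles:
            if alk_s == el_s:
                continue
            try:
                with quiet_rdkit():
                    pair = parse_substrates(
                        alk_s, el_s, allow_ambiguous_alkene=True, allow_bifunctional=True
                    )
                    for site in rank_reactive_sites(pair):
                        prods = enumerate_products(pair, site)
                        if _stereo_insensitive(prods["alpha"]) in reported:
                            matched_alpha = True
                            alkene_used = alk_m
                        if _stereo_insensitive(prods["beta"]) in reported:
                            matched_beta = True
                            alkene_used = alk_m
            except HeckRegioError:
                continue

    if matched_alpha and matched_beta:
        return label("inter_mix", alkene_mol=alkene_used)
    if matched_alpha:
        return label("inter_alpha", alkene_mol=alkene_used)
    if matched_beta:
        return label("inter_beta", alkene_mol=alkene_used)
    return label("no_match", reason="no generated product among reported products")


# ---------------------------------------------------------------------------


def _canonical_reaction_key(rxn_smiles: str) -> str | None:
    try:
        reactants, products = split_reaction_smiles(rxn_smiles)
    except CurationError:
        return None
    def canon(frags):
        out = []
        for f in frags:
            m = Chem.MolFromSmiles(f)
            if m is None:
                return None
            out.append(Chem.MolToSmiles(m))
        return ".".join(sorted(out))
    r, p = canon(reactants), canon(products)
    if r is None or p is None:
        return None
    return f"{r}>>{p}"


def _max_product_mw(rxn_smiles: str) -> float | None:
    try:
        _, products = split_reaction_smiles(rxn_smiles)
    except CurationError:
        return None
    mws = []
    for s in products:
        m = Chem.MolFromSmiles(s)
        if m is not None:
            mws.append(Descriptors.MolWt(m))
    return max(mws) if mws else None


def filter_records(
    records: list[ReactionRecord], config: CurationConfig | None = None
) -> tuple[list[ReactionRecord], dict[str, int]]:
    """Apply the curation filters; returns the kept records plus audit
    counts of what each filter removed.

    Duplicates are collapsed on a canonical reaction key (fragment-
    canonicalized, order-independent reactant and product sets); the
    molecular-weight cut removes reactions whose largest reported
    product exceeds the limit; additive and precatalyst rules apply the
    configured lists.
    """
    config = config or CurationConfig()
    counts = {
        "input": len(records),
        "duplicate": 0,
        "over_mw": 0,
        "excluded_additive": 0,
        "precatalyst": 0,
        "kept": 0,
    }
    seen: set[str] = set()
    kept: list[ReactionRecord] = []
    for rec in records:
        if _mentions(rec.additives, config.excluded_elements, config.excluded_names):
            counts["excluded_additive"] += 1
            continue
        if config.precatalyst_allowlist is not None:
            low = rec.catalyst.lower()
            if not any(tok.lower() in low for tok in config.precatalyst_allowlist):
                counts["precatalyst"] += 1
                continue
        mw = _max_product_mw(rec.rxn_smiles)
        if mw is not None and mw > config.mw_limit:
            counts["over_mw"] += 1
            continue
        key = _canonical_reaction_key(rec.rxn_smiles) or rec.rxn_smiles
        if key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(key)
        kept.append(rec)
    counts["kept"] = len(kept)
    return kept, counts


# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    confusion: pd.DataFrame  # rows = observed, columns = predicted
    n_scored: int
    n_undetermined: int
    strict_accuracy: dict[str, float]
    relaxed_accuracy: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "confusion": {
                obs: {pred: int(self.confusion.loc[obs, pred]) for pred in self.confusion.columns}
                for obs in self.confusion.index
            },
            "n_scored": self.n_scored,
            "n_undetermined": self.n_undetermined,
            "strict_accuracy": self.strict_accuracy,
            "relaxed_accuracy": self.relaxed_accuracy,
        }


def score_predictions(
    observed: dict[str, str], predicted: dict[str, str]
) -> ScoreReport:
    """Confusion matrix and accuracies of alpha/beta/mix predictions.

    *observed* and *predicted* map record ids to calls; the id sets must
    match.  Predictions of ``undetermined`` are counted separately and
    excluded from the matrix.  The relaxed accuracy credits a predicted
    mix to the observed isomer: for observed beta it is the "not alpha"
    hit rate (beta or mix predicted), and symmetrically for alpha.
    """
    if set(observed) != set(predicted):
        raise CurationError("observed and predicted record ids do not match")
    confusion = pd.DataFrame(
        0, index=list(CALL_CLASSES), columns=list(CALL_CLASSES), dtype=int
    )
    n_undet = 0
    for rid, obs in observed.items():
        pred = predicted[rid]
        if obs not in CALL_CLASSES:
            raise CurationError(f"observed class {obs!r} for {rid!r}")
        if pred == "undetermined":
            n_undet += 1
            continue
        if pred not in CALL_CLASSES:
            raise CurationError(f"predicted class {pred!r} for {rid!r}")
        confusion.loc[obs, pred] += 1
    strict, relaxed = {}, {}
    for cls in CALL_CLASSES:
        total = int(confusion.loc[cls].sum())
        if total == 0:
            continue
        strict[cls] = confusion.loc[cls, cls] / total
        if cls == "mix":
            relaxed[cls] = strict[cls]
        else:
            relaxed[cls] = (confusion.loc[cls, cls] + confusion.loc[cls, "mix"]) / total
    return ScoreReport(
        confusion=confusion,
        n_scored=int(confusion.values.sum()),
        n_undetermined=n_undet,
        strict_accuracy=strict,
        relaxed_accuracy=relaxed,
    )


# ---------------------------------------------------------------------------


def records_from_dataframe(df: pd.DataFrame) -> list[ReactionRecord]:
    """Build records from the documented CSV schema: columns
    ``record_id, rxn_smiles, catalyst, ligand, additives, solvent``
    (additives separated by semicolons)."""
    required = {"record_id", "rxn_smiles"}
    missing = required - set(df.columns)
    if missing:
        raise CurationError(f"records table lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        additives = getattr(row, "additives", "") or ""
        if not isinstance(additives, str):
            additives = ""
        records.append(
            ReactionRecord(
                record_id=str(row.record_id),
                rxn_smiles=str(row.rxn_smiles),
                catalyst=str(getattr(row, "catalyst", "") or ""),
                ligand=str(getattr(row, "ligand", "") or ""),
                additives=tuple(a.strip() for a in additives.split(";") if a.strip()),
                solvent=str(getattr(row, "solvent", "") or ""),
            )
        )
    return records
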