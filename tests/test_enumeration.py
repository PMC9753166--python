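"""Substrate validation, site ranking and complex enumeration."""

from __future__ import annotations

from collections import Counter

import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from heckregio.enumeration import (
    enumerate_complexes,
    enumerate_products,
    parse_substrates,
    rank_reactive_sites,
)
from heckregio.errors import (
    AmbiguousSubstrateError,
    EnumerationError,
    InputError,
    SubstrateError,
)


def formula(smiles_or_mol) -> Counter:
    """Element -> count including hydrogens, for conservation checks."""
    mol = (
        Chem.MolFromSmiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    return counts


PPH3 = formula("P(c1ccccc1)(c1ccccc1)c1ccccc1")

VALID_PAIRS = [
    ("C=Cc1ccccc1", "Clc1ccccc1"),
    ("C=CC(=O)OC", "Brc1ccccc1"),
    ("C=CC#N", "Ic1ccc(C)cc1"),
    ("C=COCCCC", "Brc1ccncc1"),  # heteroaryl bromide
    ("C=CC#N", "c1ccccc1OS(=O)(=O)C(F)(F)F"),  # aryl triflate
    ("C=Cc1ccccc1", "BrC=Cc1ccccc1"),  # vinyl bromide partner
]


class TestParseSubstrates:
    def test_styrene_chlorobenzene_valid(self, styrene_pair):
        assert len(styrene_pair.alkene_matches) == 1
        [site] = styrene_pair.sites
        assert site.leaving_group == "Cl"
        assert styrene_pair.partner.GetAtomWithIdx(site.carbon_index).GetIsAromatic()

    def test_triflate_recognized_on_ester_oxygen(self):
        pair = parse_substrates("C=CC#N", "c1ccccc1OS(=O)(=O)C(F)(F)F")
        [site] = pair.sites
        assert site.leaving_group == "OTf"
        x_atom = pair.partner.GetAtomWithIdx(site.x_index)
        assert x_atom.GetSymbol() == "O"
        assert pair.partner.GetAtomWithIdx(site.carbon_index).GetIsAromatic()

    @pytest.mark.parametrize(
        "alkene, partner, err",
        [
            ("CC=CC", "Brc1ccccc1", SubstrateError),  # internal alkene
            ("CC(=C)C", "Brc1ccccc1", SubstrateError),  # 1,1-disubstituted
            ("c1ccccc1", "Brc1ccccc1", SubstrateError),  # no alkene
            ("C=Cc1ccccc1", "c1ccccc1", SubstrateError),  # no C-X
            ("C=Cc1ccccc1", "Fc1ccccc1", SubstrateError),  # F not a leaving group
            ("](", "Brc1ccccc1", InputError),
            ("C=Cc1ccccc1", "](", InputError),
            ("C=CCCC=C", "Brc1ccccc1", AmbiguousSubstrateError),  # two alkenes
            ("C=Cc1ccc(Br)cc1", "Brc1ccccc1", SubstrateError),  # bifunctional
            ("C=Cc1ccccc1", "C=Cc1ccc(Br)cc1", SubstrateError),  # bifunctional
        ],
    )
    def test_invalid_substrates(self, alkene, partner, err):
        with pytest.raises(err):
            parse_substrates(alkene, partner)

    def test_ambiguous_alkene_opt_in(self):
        pair = parse_substrates("C=CCCC=C", "Brc1ccccc1", allow_ambiguous_alkene=True)
        assert pair.ambiguous_alkene
        assert len(pair.alkene_matches) == 2


class TestRankReactiveSites:
    def test_iodide_beats_bromide(self):
        pair = parse_substrates("C=CC#N", "Brc1ccc(I)cc1")
        sites = rank_reactive_sites(pair)
        assert [s.leaving_group for s in sites] == ["I"]

    def test_triflate_beats_bromide_and_chloride(self):
        pair = parse_substrates(
            "C=CC#N", "Clc1ccc(OS(=O)(=O)C(F)(F)F)cc1"
        )
        assert [s.leaving_group for s in rank_reactive_sites(pair)] == ["OTf"]

    def test_single_site_returned_as_is(self, styrene_pair):
        assert [s.leaving_group for s in rank_reactive_sites(styrene_pair)] == ["Cl"]

    def test_tied_top_halides_all_returned(self):
        pair = parse_substrates("C=CC#N", "Brc1ccc(Br)cc1")
        sites = rank_reactive_sites(pair)
        assert [s.leaving_group for s in sites] == ["Br", "Br"]
        assert sites[0].carbon_index != sites[1].carbon_index


class TestEnumerateComplexes:
    def test_styrene_chlorobenzene_complete_set(self, styrene_specs):
        assert len(styrene_specs) == 6
        neutral = [s for s in styrene_specs if s.pathway == "neutral"]
        cationic = [s for s in styrene_specs if s.pathway == "cationic"]
        assert len(neutral) == 4 and len(cationic) == 2
        for s in neutral:
            assert s.charge == 0
            assert any(a.GetSymbol() == "Cl" for a in s.mol.GetAtoms())
        for s in cationic:
            assert s.charge == 1
            assert Chem.GetFormalCharge(s.mol) == 1
            assert not any(a.GetSymbol() == "Cl" for a in s.mol.GetAtoms())

    @pytest.mark.parametrize("alkene,partner", VALID_PAIRS)
    def test_four_neutral_two_cationic_for_any_valid_pair(self, alkene, partner):
        pair = parse_substrates(alkene, partner)
        specs = enumerate_complexes(pair, rank_reactive_sites(pair)[0])
        kinds = Counter((s.pathway, s.regiochemistry) for s in specs)
        assert kinds == {
            ("neutral", "alpha"): 2,
            ("neutral", "beta"): 2,
            ("cationic", "alpha"): 1,
            ("cationic", "beta"): 1,
        }

    @pytest.mark.parametrize("alkene,partner", VALID_PAIRS)
    def test_formula_conservation(self, alkene, partner):
        """Complex formula = alkene + partner + ligand(s) + Pd, with the
        leaving group removed on the cationic pathway."""
        pair = parse_substrates(alkene, partner)
        site = rank_reactive_sites(pair)[0]
        lg_smiles = (
            "OS(=O)(=O)C(F)(F)F" if site.leaving_group == "OTf" else site.leaving_group
        )
        lg = formula(lg_smiles)
        lg["H"] -= 1  # leaving group as a substituent, not the free acid
        lg_actual = Counter({k: v for k, v in lg.items() if v})
        base = formula(pair.alkene) + formula(pair.partner) + Counter({"Pd": 1})
        for spec in enumerate_complexes(pair, site):
            n_ligands = 1 if spec.pathway == "neutral" else 2
            expected = base.copy()
            for _ in range(n_ligands):
                expected += PPH3
            if spec.pathway == "cationic":
                expected -= lg_actual
            assert formula(spec.mol) == expected

    @pytest.mark.parametrize("alkene,partner", VALID_PAIRS)
    def test_products_are_distinct_constitutional_isomers(self, alkene, partner):
        pair = parse_substrates(alkene, partner)
        prods = enumerate_products(pair, rank_reactive_sites(pair)[0])
        assert prods["alpha"] != prods["beta"]
        assert formula(prods["alpha"]) == formula(prods["beta"])

    def test_acrylonitrile_products_match_manual_rewrite(self):
        """Acrylonitrile + bromobenzene: the linear product is the
        cinnamonitrile skeleton, the branched one 2-phenylacrylonitrile."""
        pair = parse_substrates("C=CC#N", "Brc1ccccc1")
        prods = enumerate_products(pair, rank_reactive_sites(pair)[0])
        assert prods["beta"] == Chem.CanonSmiles("N#CC=Cc1ccccc1")
        assert prods["alpha"] == Chem.CanonSmiles("C=C(C#N)c1ccccc1")

    def test_beta_product_has_unspecified_stereochemistry(self, styrene_specs):
        beta = next(s for s in styrene_specs if s.regiochemistry == "beta")
        mol = Chem.MolFromSmiles(beta.product_smiles)
        db = [b for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE]
        assert all(b.GetStereo() == Chem.BondStereo.STEREONONE for b in db)

    def test_enumeration_is_deterministic(self, styrene_pair):
        site = rank_reactive_sites(styrene_pair)[0]
        a = [s.smiles for s in enumerate_complexes(styrene_pair, site)]
        b = [s.smiles for s in enumerate_complexes(styrene_pair, site)]
        assert a == b

    def test_foreign_site_rejected(self, styrene_pair):
        pair2 = parse_substrates("C=CC#N", "Brc1ccccc1")
        with pytest.raises(EnumerationError):
            enumerate_complexes(styrene_pair, rank_reactive_sites(pair2)[0])

    def test_otf_neutral_complex_carries_whole_triflate(self):
        pair = parse_substrates("C=CC#N", "c1ccccc1OS(=O)(=O)C(F)(F)F")
        specs = enumerate_complexes(pair, rank_reactive_sites(pair)[0])
        for spec in specs:
            has_f = any(a.GetSymbol() == "F" for a in spec.mol.GetAtoms())
            assert has_f == (spec.pathway == "neutral")

    def test_rotatable_bond_count_on_product(self):
        pair = parse_substrates("C=CCCCC", "Brc1ccccc1")
        spec = enumerate_complexes(pair, rank_reactive_sites(pair)[0])[0]
        prod = Chem.MolFromSmiles(spec.product_smiles)
        assert spec.n_rotatable_product == rdMolDescriptors.CalcNumRotatableBonds(
            prod, rdMolDescriptors.NumRotatableBondsOptions.Strict
        )
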