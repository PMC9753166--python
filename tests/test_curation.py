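"""Record classification, filtering and prediction scoring."""

from __future__ import annotations

import numpy as np
import pytest

from heckregio.curation import (
    CurationConfig,
    ReactionRecord,
    classify_record,
    filter_records,
    records_from_dataframe,
    score_predictions,
)
from heckregio.errors import CurationError
from heckregio.fixtures import generate_records

ALPHA = "C=C(C#N)c1ccccc1"  # branched product of acrylonitrile + PhBr
BETA = "N#C/C=C/c1ccccc1"  # linear product (stereo deliberately set)


def record(rxn, ligand="", additives=(), rid="r1", catalyst="Pd(OAc)2"):
    return ReactionRecord(
        record_id=rid, rxn_smiles=rxn, catalyst=catalyst, ligand=ligand,
        additives=tuple(additives),
    )


class TestClassifyRecord:
    def test_beta_only_report(self):
        lab = classify_record(record(f"C=CC#N.Brc1ccccc1>>{BETA}"))
        assert lab.category == "inter_beta"

    def test_both_regioisomers_are_a_mix(self):
        lab = classify_record(record(f"C=CC#N.Brc1ccccc1>>{ALPHA}.{BETA}"))
        assert lab.category == "inter_mix"

    def test_beta_match_is_stereo_insensitive(self):
        z_isomer = "N#C/C=C\\c1ccccc1"
        lab = classify_record(record(f"C=CC#N.Brc1ccccc1>>{z_isomer}"))
        assert lab.category == "inter_beta"

    def test_unrelated_product_no_match(self):
        lab = classify_record(record("C=CC#N.Brc1ccccc1>>CCO"))
        assert lab.category == "no_match"

    def test_tethered_substrate_is_intramolecular(self):
        lab = classify_record(record("C=CCCCCOc1ccccc1Br>>C1=CCCCCOc2ccccc21"))
        assert lab.category == "intra"

    def test_unparseable_reaction_smiles(self):
        lab = classify_record(record("this is not a reaction"))
        assert lab.category == "no_match"
        assert lab.reason

    @pytest.mark.parametrize(
        "ligand,expected",
        [("PPh3", "monodentate"), ("triphenylphosphine", "monodentate"),
         ("DPPP", "bidentate"), ("dppe", "bidentate"), ("", "undefined"),
         ("XPhos", "undefined")],
    )
    def test_ligand_denticity(self, ligand, expected):
        lab = classify_record(record(f"C=CC#N.Brc1ccccc1>>{BETA}", ligand=ligand))
        assert lab.ligand_class == expected

    def test_cationic_conditions_from_scavenger(self):
        lab = classify_record(
            record(f"C=CC#N.Brc1ccccc1>>{BETA}", additives=("AgOAc",))
        )
        assert lab.cationic_conditions

    def test_cationic_conditions_from_triflate(self):
        rxn = f"C=CC#N.c1ccccc1OS(=O)(=O)C(F)(F)F>>{BETA}"
        assert classify_record(record(rxn)).cationic_conditions

    def test_plain_halide_base_not_cationic(self):
        lab = classify_record(
            record(f"C=CC#N.Brc1ccccc1>>{BETA}", additives=("K2CO3",))
        )
        assert not lab.cationic_conditions

    @pytest.mark.parametrize(
        "alkene,expected",
        [
            ("C=COCCCC", "EDG_ON"),  # enol ether: O on the alkene
            ("C=CN1CCCC1=O", "EDG_ON"),  # enamide: N on the alkene
            ("C=CCO", "EDG_ON"),  # allylic alcohol: sp3 C bearing O
            ("C=CC(=O)OC", "EWG_carbonyl_aryl"),  # acrylate
            ("C=Cc1ccccc1", "EWG_carbonyl_aryl"),  # styrene
            ("C=CC#N", "other"),  # nitrile carbon is neither
            ("C=CCCCC", "other"),
        ],
    )
    def test_alkene_substituent_classes(self, alkene, expected):
        from heckregio.enumeration import enumerate_products, parse_substrates, rank_reactive_sites

        pair = parse_substrates(alkene, "Brc1ccccc1")
        beta = enumerate_products(pair, rank_reactive_sites(pair)[0])["beta"]
        lab = classify_record(record(f"{alkene}.Brc1ccccc1>>{beta}"))
        assert lab.category == "inter_beta"
        assert lab.substituent_class == expected

    def test_classification_is_idempotent(self):
        rec = record(f"C=CC#N.Brc1ccccc1>>{ALPHA}")
        assert classify_record(rec) == classify_record(rec)


class TestFilterRecords:
    def test_duplicates_collapse_on_canonical_reaction(self):
        a = record(f"C=CC#N.Brc1ccccc1>>{BETA}", rid="a")
        # same reaction written with reordered fragments
        b = record(f"Brc1ccccc1.C=CC#N>>{BETA}", rid="b")
        kept, counts = filter_records([a, b])
        assert [r.record_id for r in kept] == ["a"]
        assert counts["duplicate"] == 1

    def test_lithium_additive_excluded(self):
        rec = record(f"C=CC#N.Brc1ccccc1>>{BETA}", additives=("LiCl",))
        kept, counts = filter_records([rec])
        assert not kept and counts["excluded_additive"] == 1

    def test_lithium_not_confused_with_aniline(self):
        rec = record(f"C=CC#N.Brc1ccccc1>>{BETA}", additives=("aniline",))
        kept, _ = filter_records([rec])
        assert kept

    def test_heavy_product_excluded(self):
        heavy = "C=C" + "C" * 40
        rxn = f"{heavy}.Brc1ccccc1>>{heavy}c1ccccc1"
        kept, counts = filter_records([record(rxn)])
        assert not kept and counts["over_mw"] == 1

    def test_precatalyst_allowlist(self):
        rec = record(f"C=CC#N.Brc1ccccc1>>{BETA}", catalyst="PdCl2(MeCN)2")
        config = CurationConfig(precatalyst_allowlist=("Pd(OAc)2",))
        kept, counts = filter_records([rec], config)
        assert not kept and counts["precatalyst"] == 1

    def test_empty_input(self):
        kept, counts = filter_records([])
        assert kept == [] and counts["input"] == 0


class TestScorePredictions:
    def test_perfect_agreement_is_identity(self):
        obs = {"a": "alpha", "b": "beta", "m": "mix"}
        rep = score_predictions(obs, dict(obs))
        assert np.trace(rep.confusion.values) == 3
        assert rep.strict_accuracy == {"alpha": 1.0, "beta": 1.0, "mix": 1.0}

    def test_all_mix_vs_all_beta(self):
        obs = {f"r{i}": "beta" for i in range(10)}
        pred = {k: "mix" for k in obs}
        rep = score_predictions(obs, pred)
        assert rep.strict_accuracy["beta"] == 0.0
        assert rep.relaxed_accuracy["beta"] == 1.0  # the "not alpha" credit

    def test_id_mismatch_rejected(self):
        with pytest.raises(CurationError):
            score_predictions({"a": "beta"}, {"b": "beta"})

    def test_undetermined_counted_separately(self):
        obs = {"a": "beta", "b": "beta"}
        rep = score_predictions(obs, {"a": "beta", "b": "undetermined"})
        assert rep.n_scored == 1 and rep.n_undetermined == 1

    def test_matrix_matches_brute_force_tally_on_synthetic_records(self):
        """Confusion matrix equals a direct double loop over 200
        synthetic records with pseudo-random predictions."""
        df = generate_records(200, seed=11)
        labels = [classify_record(r) for r in records_from_dataframe(df)]
        observed = {
            l.record_id: l.observed_call for l in labels if l.observed_call
        }
        rng = np.random.default_rng(3)
        classes = ["alpha", "beta", "mix"]
        predicted = {
            rid: classes[rng.integers(3)] for rid in observed
        }
        rep = score_predictions(observed, predicted)
        for obs_cls in classes:
            row_total = sum(1 for v in observed.values() if v == obs_cls)
            assert rep.confusion.loc[obs_cls].sum() == row_total
            for pred_cls in classes:
                tally = sum(
                    1
                    for rid in observed
                    if observed[rid] == obs_cls and predicted[rid] == pred_cls
                )
                assert rep.confusion.loc[obs_cls, pred_cls] == tally
        for cls in ("alpha", "beta"):
            if cls in rep.strict_accuracy:
                assert rep.relaxed_accuracy[cls] >= rep.strict_accuracy[cls]
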