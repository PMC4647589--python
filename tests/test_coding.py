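import io
import warnings

import numpy as np
import pandas as pd
import pytest

import pherotrace as pt
from pherotrace.coding import (
    COMPOUND_CLASSES,
    UNKNOWN_CLASS,
    BinaryCharacterMatrix,
    CasteProfile,
    ChemProfile,
    CompoundRecord,
    FertilityCriterion,
)
from pherotrace.simulate import SimulationConfig, simulate_chem_profiles


def make_profile(fertile_vals, nonfertile_vals, compound="x", species="sp",
                 sociality="eusocial"):
    fg, ng = (("queen", "worker") if sociality == "eusocial"
              else ("mature_female", "virgin_female"))
    return ChemProfile(
        species=species, sociality=sociality,
        fertile=CasteProfile(species, fg, pd.DataFrame({compound: fertile_vals})),
        nonfertile=CasteProfile(species, ng, pd.DataFrame({compound: nonfertile_vals})),
    )


class TestClassifyCompound:
    @pytest.mark.parametrize("name,expected", [
        ("pentacosane", "linear alkane"),
        ("heneicosane", "linear alkane"),
        ("hentriacontane", "linear alkane"),
        ("13-methylpentacosane", "branched alkane"),
        ("3,7-dimethylheptacosane", "branched alkane"),
        ("9-tricosene", "alkene"),
        ("6,9-pentacosadiene", "alkadiene"),
        ("hexadecanal", "aldehyde"),
        ("hexadecanol", "alcohol"),
        ("hexadecanoic acid", "fatty acid"),
        ("(Z)-9-octadecenoic acid", "fatty acid"),
        ("9-ODA", "keto acid"),
        ("9-oxo-decenoic acid", "keto acid"),
        ("9-oxo-2-decenoic acid", "keto acid"),
        ("decyl decanoate", "ester"),
        ("hexadecanoic acid methyl ester", "ester"),
        ("octadecenoic acid methyl ester", "ester"),
        ("farnesene", "terpene"),
        ("geraniol", "terpene alcohol"),
        ("gamma-dodecalactone", "lactone"),
    ])
    def test_name_based_assignment(self, name, expected):
        assert pt.classify_compound(CompoundRecord(name=name)) == expected

    def test_every_name_gets_exactly_one_of_the_twelve_or_unknown(self):
        names = ["pentacosane", "9-ODA", "decyl decanoate", "mystery-17"]
        for name in names:
            cls = pt.classify_compound(CompoundRecord(name=name))
            assert cls in COMPOUND_CLASSES or cls == UNKNOWN_CLASS

    def test_descriptor_fallback_functional_group_beats_hydrocarbon(self):
        # an unsaturated acid is a fatty acid, not an alkene
        rec = CompoundRecord(name="cmpd-a", chain_length=18,
                             saturation="ene", functional_group="acid")
        assert pt.classify_compound(rec) == "fatty acid"

    def test_descriptor_methyl_branched_alkene_is_alkene(self):
        rec = CompoundRecord(name="cmpd-b", chain_length=25, saturation="ene",
                             functional_group="hydrocarbon", methyl_branches=1)
        assert pt.classify_compound(rec) == "alkene"

    def test_descriptor_saturated_branched_is_branched_alkane(self):
        rec = CompoundRecord(name="cmpd-c", chain_length=27,
                             functional_group="hydrocarbon", methyl_branches=2)
        assert pt.classify_compound(rec) == "branched alkane"

    def test_unknown_is_surfaced_not_guessed(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pherotrace.coding"):
            cls = pt.classify_compound(CompoundRecord(name="unobtainium-42"))
        assert cls == UNKNOWN_CLASS
        assert any("unobtainium-42" in r.message for r in caplog.records)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            CompoundRecord()


class TestCallFertilityLinked:
    def test_qualitative_rule(self):
        prof = make_profile([10.0] * 5, [0.0] * 5)
        assert pt.call_fertility_linked(prof, "x") is True

    def test_identical_distributions_not_linked(self):
        vals = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        prof = make_profile(vals, list(vals))
        assert pt.call_fertility_linked(prof, "x") is False

    def test_absent_from_both_castes_warns_false(self):
        prof = make_profile([0.0] * 4, [0.0] * 4)
        with pytest.warns(UserWarning, match="absent from both"):
            assert pt.call_fertility_linked(prof, "x") is False

    def test_single_individual_uses_qualitative_only(self):
        prof = make_profile([10.0], [1.0, 1.2, 0.9])
        with pytest.warns(UserWarning, match="single-individual"):
            assert pt.call_fertility_linked(prof, "x") is False
        prof2 = make_profile([10.0], [0.0, 0.0, 0.0])
        assert pt.call_fertility_linked(prof2, "x") is True

    def test_invariant_to_global_rescaling(self, rng):
        f = 4.0 * np.exp(rng.normal(0, 1.0, 10))
        w = np.exp(rng.normal(0, 1.0, 10))
        for scale in (1.0, 1e-3, 1e6):
            prof = make_profile(f * scale, w * scale)
            assert pt.call_fertility_linked(prof, "x") is True

    def test_solitary_group_labels(self):
        prof = make_profile([10.0] * 4, [0.0] * 4, sociality="solitary")
        assert prof.fertile.group == "mature_female"
        assert pt.call_fertility_linked(prof, "x") is True

    def test_inconsistent_group_labels_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ChemProfile(
                species="sp", sociality="solitary",
                fertile=CasteProfile("sp", "queen", pd.DataFrame({"x": [1.0]})),
                nonfertile=CasteProfile("sp", "worker", pd.DataFrame({"x": [1.0]})),
            )

    def test_detection_calibration_power_and_null(self):
        """With the default criterion and generator noise, a 4-fold queen
        excess (n = 12/caste) is detected in >= 90% of replicates and a null
        1-fold 'excess' in <= 10%."""
        rng = np.random.default_rng(0)
        calls = {1.0: 0, 4.0: 0}
        n_rep = {1.0: 500, 4.0: 500}
        for fold in calls:
            for _ in range(n_rep[fold]):
                f = fold * 100 * np.exp(rng.normal(0, 1.05, 12))
                w = 100 * np.exp(rng.normal(0, 1.05, 12))
                calls[fold] += pt.call_fertility_linked(make_profile(f, w), "x")
        assert calls[4.0] / n_rep[4.0] >= 0.90
        assert calls[1.0] / n_rep[1.0] <= 0.10


class TestBinaryCharacterMatrix:
    def test_cells_validated(self):
        with pytest.raises(ValueError, match="cells"):
            BinaryCharacterMatrix.from_dict({"sp1": {"linear alkane": "2"}})

    def test_duplicate_species_rejected(self):
        frame = pd.DataFrame([["1"] * 12, ["0"] * 12],
                             index=["sp1", "sp1"], columns=COMPOUND_CLASSES)
        with pytest.raises(ValueError, match="duplicate species"):
            BinaryCharacterMatrix(frame)

    def test_tsv_round_trip(self):
        mat = BinaryCharacterMatrix.from_dict(
            {"Apis mellifera": {"linear alkane": 1, "keto acid": 1},
             "Centris analis": {"linear alkane": 1}})
        buf = io.StringIO(mat.to_tsv())
        again = BinaryCharacterMatrix.from_tsv(buf)
        assert again == mat
        assert again.cell("Apis mellifera", "keto acid") == "1"
        assert again.cell("Centris analis", "ester") == "?"

    def test_nexus_round_trip(self):
        mat = BinaryCharacterMatrix.from_dict(
            {"Apis mellifera": dict.fromkeys(COMPOUND_CLASSES, 1),
             "Centris analis": {**dict.fromkeys(COMPOUND_CLASSES, 0),
                                "alkene": "?"}})
        text = mat.to_nexus()
        assert "STANDARD" in text.upper()
        again = BinaryCharacterMatrix.from_nexus(text)
        assert again == mat


class TestBuildCharacterMatrix:
    def test_single_linked_compound_codes_one_class(self):
        prof = make_profile([10.0] * 5, [0.0] * 5, compound="pentacosane")
        mat = pt.build_character_matrix([prof])
        assert mat.cell("sp", "linear alkane") == "1"
        for cls in COMPOUND_CLASSES:
            if cls != "linear alkane":
                assert mat.cell("sp", cls) == "0"

    def test_empty_profile_list_gives_empty_matrix(self):
        mat = pt.build_character_matrix([])
        assert mat.shape == (0, 12)

    def test_duplicate_species_rejected(self):
        prof = make_profile([1.0] * 3, [1.0] * 3)
        with pytest.raises(ValueError, match="duplicate species"):
            pt.build_character_matrix([prof, prof])

    def test_species_with_no_compounds_gets_missing_row(self):
        empty = ChemProfile(
            species="sp", sociality="eusocial",
            fertile=CasteProfile("sp", "queen", pd.DataFrame(index=[0])),
            nonfertile=CasteProfile("sp", "worker", pd.DataFrame(index=[0])),
        )
        with pytest.warns(UserWarning, match="no compounds"):
            mat = pt.build_character_matrix([empty])
        assert all(mat.cell("sp", cls) == "?" for cls in COMPOUND_CLASSES)

    def test_recovers_generator_truth_in_qualitative_regime(self):
        config = SimulationConfig(n_tips=10, fold_change=float("inf"), seed=7)
        profiles, truth = simulate_chem_profiles(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = pt.build_character_matrix(
                profiles, FertilityCriterion(qualitative_only=True))
        assert mat == truth

    def test_order_independence(self):
        config = SimulationConfig(n_tips=6, fold_change=float("inf"), seed=9)
        profiles, _ = simulate_chem_profiles(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pt.build_character_matrix(profiles)
            b = pt.build_character_matrix(list(reversed(profiles)))
        assert a == b


class TestProfilesTsv:
    def test_round_trip(self):
        config = SimulationConfig(n_tips=4, seed=3, n_individuals=3)
        profiles, _ = simulate_chem_profiles(config)
        text = pt.write_profiles_tsv(profiles)
        again = pt.read_profiles_tsv(io.StringIO(text))
        assert [p.species for p in again] == sorted(p.species for p in profiles)
        sp = {p.species: p for p in profiles}
        for p in again:
            orig = sp[p.species]
            assert p.sociality == orig.sociality
            assert p.fertile.n_individuals == orig.fertile.n_individuals
            np.testing.assert_allclose(
                p.fertile.abundances.sort_index(axis=1).to_numpy(),
                orig.fertile.abundances.sort_index(axis=1).sort_index().to_numpy(),
                rtol=1e-5,
            )

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            pt.read_profiles_tsv(io.StringIO("species\tgroup\nx\ty\n"))
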