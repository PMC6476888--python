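"""Activity-table parsing, SMILES construction, and table analytics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from naphqsar import datasets
from naphqsar.datasets import (
    ActivityValue,
    ParseError,
    ValidationError,
    build_smiles,
    censoring_summary,
    count_active,
    parse_activity_table,
    parse_substituent_code,
    selectivity_index,
    to_p_activity,
    write_activity_table,
)


class TestParsing:
    def test_packaged_table_has_102_records(self, records):
        assert len(records) == 102
        assert len({r.id for r in records}) == 102

    def test_8c_row_values(self, by_id):
        acts = by_id["8c"].activities
        assert acts["HCT116+/+"].ic50 == pytest.approx(0.41)
        assert acts["HCT116+/+"].sd == pytest.approx(0.05)
        assert acts["HCT116-/-"].ic50 == pytest.approx(0.69)
        assert acts["NHDF"].ic50 == pytest.approx(12.30)

    def test_fully_censored_row_has_no_numeric_value(self, by_id):
        acts = by_id["1"].activities
        assert acts["HCT116+/+"].censored and acts["HCT116-/-"].censored
        assert acts["NHDF"].missing
        assert not any(v.is_numeric for v in acts.values())

    def test_round_trip_preserves_all_states(self, records, tmp_path):
        path = tmp_path / "table.csv"
        write_activity_table(records, path)
        again = parse_activity_table(path)
        assert again == records

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,substituent_code,hct116_wt,hct116_null,nhdf\n1,H,abc,>25,\n"
        )
        with pytest.raises(ParseError, match="row '1'.*hct116_wt"):
            parse_activity_table(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "id,substituent_code,hct116_wt,hct116_null,nhdf\n"
            "1,H,1.0,1.0,1.0\n1,H,2.0,2.0,2.0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            parse_activity_table(path)

    def test_activity_value_state_exclusivity(self):
        with pytest.raises(ValidationError):
            ActivityValue(ic50=1.0, censored=True)
        with pytest.raises(ValidationError):
            ActivityValue()
        with pytest.raises(ValidationError):
            ActivityValue(ic50=-1.0)


class TestSubstituentCodes:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("H", ()),
            ("4-NO2", ((4, "NO2"),)),
            ("3,5-CF3", ((3, "CF3"), (5, "CF3"))),
            ("2-Cl-3,5-CF3", ((2, "Cl"), (3, "CF3"), (5, "CF3"))),
            ("2,3,4,5,6-F", tuple((p, "F") for p in range(2, 7))),
            ("2,6-Br-3-Cl-4-F", ((2, "Br"), (6, "Br"), (3, "Cl"), (4, "F"))),
        ],
    )
    def test_code_expansion(self, code, expected):
        assert parse_substituent_code(code) == expected

    def test_unknown_group_lists_allowed_codes(self):
        with pytest.raises(ParseError, match="allowed.*CF3"):
            parse_substituent_code("2-XYZ")

    def test_position_clash_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            parse_substituent_code("2-Cl-2-F")


class TestSmiles:
    def test_parent_compound_matches_scaffold(self, by_id):
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("Oc1c(ccc2ccccc12)C(=O)Nc1ccccc1"))
        assert build_smiles(by_id["1"]) == expected

    def test_canonicalization_idempotent(self, by_id):
        smi = build_smiles(by_id["5u"])
        assert Chem.MolToSmiles(Chem.MolFromSmiles(smi)) == smi

    def test_bis_trifluoromethyl_has_six_fluorines(self, by_id):
        mol = Chem.MolFromSmiles(build_smiles(by_id["7f"]))
        assert sum(a.GetSymbol() == "F" for a in mol.GetAtoms()) == 6

    def test_dimethoxy_molecular_formula(self, by_id):
        mol = Chem.MolFromSmiles(build_smiles(by_id["2d"]))
        assert CalcMolFormula(mol) == "C19H17NO4"

    def test_all_102_build_and_contain_scaffold(self, records):
        scaffold = Chem.MolFromSmarts("O=C(Nc1ccccc1)c1ccc2ccccc2c1[OX2H1]")
        for rec in records:
            mol = Chem.MolFromSmiles(build_smiles(rec))
            assert mol is not None and mol.HasSubstructMatch(scaffold), rec.id


class TestPActivity:
    def test_definition_at_one_micromolar(self):
        assert to_p_activity(ActivityValue(ic50=1.0)).value == pytest.approx(6.0)

    def test_potent_compound(self):
        got = to_p_activity(ActivityValue(ic50=0.41))
        assert got.value == pytest.approx(6.387, abs=5e-4)
        assert not got.censored

    def test_censored_clamp_and_exclude_policies(self):
        val = ActivityValue(censored=True)
        clamped = to_p_activity(val, "clamp-at-25")
        assert clamped.value == pytest.approx(4.602, abs=5e-4)
        assert clamped.censored
        assert to_p_activity(val, "exclude") is None

    def test_missing_always_excluded(self):
        assert to_p_activity(ActivityValue(missing=True)) is None

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            to_p_activity(ActivityValue(ic50=1.0), "midpoint")


class TestSelectivity:
    def test_8c_selectivity_index_is_30(self, by_id):
        sel = selectivity_index(by_id["8c"], "NHDF", "HCT116+/+")
        assert sel.ratio == pytest.approx(30.0, abs=0.01)
        assert not sel.lower_bound

    def test_5s_p53_null_preference(self, by_id):
        sel = selectivity_index(by_id["5s"], "HCT116+/+", "HCT116-/-")
        assert sel.ratio == pytest.approx(8.28, abs=0.01)

    def test_censored_numerator_gives_lower_bound(self, by_id):
        sel = selectivity_index(by_id["5s"], "NHDF", "HCT116+/+")  # NHDF is >25
        assert sel.lower_bound and sel.ratio == pytest.approx(25 / 6.87, rel=1e-9)

    def test_missing_value_is_an_error(self, by_id):
        with pytest.raises(ValueError):
            selectivity_index(by_id["1"], "NHDF", "HCT116+/+")

    @given(a=st.floats(0.01, 25), b=st.floats(0.01, 25))
    @settings(max_examples=30, deadline=None)
    def test_reciprocal_identity(self, a, b):
        rec = datasets.CompoundRecord(
            id="t", series=1, substituent_code="H", substituents=(),
            activities={
                "HCT116+/+": ActivityValue(ic50=a),
                "HCT116-/-": ActivityValue(ic50=b),
                "NHDF": ActivityValue(missing=True),
            },
        )
        fwd = selectivity_index(rec, "HCT116+/+", "HCT116-/-").ratio
        rev = selectivity_index(rec, "HCT116-/-", "HCT116+/+").ratio
        assert fwd * rev == pytest.approx(1.0)


class TestTableAnalytics:
    def test_censoring_summary_matches_table(self, records):
        pct = censoring_summary(records)
        assert pct["HCT116+/+"] == pytest.approx(100 * 30 / 102)
        assert pct["HCT116-/-"] == pytest.approx(100 * 35 / 102)
        assert pct["NHDF"] == pytest.approx(100 * 74 / 102)

    def test_all_numeric_table_has_zero_censoring(self):
        recs = [
            datasets.CompoundRecord(
                id=f"c{i}", series=1, substituent_code="H", substituents=(),
                activities={ln: ActivityValue(ic50=1.0) for ln in datasets.CELL_LINES},
            )
            for i in range(4)
        ]
        assert all(v == 0.0 for v in censoring_summary(recs).values())

    def test_more_than_50_compounds_reach_micromolar_activity(self, records):
        assert count_active(records, "HCT116+/+", 10.0) > 50

    def test_submicromolar_compounds_enumerated(self, records):
        sub = [r.id for r in records
               if r.activities["HCT116+/+"].is_numeric and r.activities["HCT116+/+"].ic50 < 1.0]
        assert sorted(sub) == ["5u", "7f", "8c"]

    def test_zero_threshold_counts_nothing(self, records):
        assert count_active(records, "HCT116+/+", 0.0) == 0

    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_count_active_monotone_in_threshold(self, thresholds):
        recs = [
            datasets.CompoundRecord(
                id=f"c{i}", series=1, substituent_code="H", substituents=(),
                activities={
                    "HCT116+/+": ActivityValue(ic50=float(i + 0.5)),
                    "HCT116-/-": ActivityValue(censored=True),
                    "NHDF": ActivityValue(missing=True),
                },
            )
            for i in range(10)
        ]
        counts = [count_active(recs, "HCT116+/+", t) for t in sorted(thresholds)]
        assert counts == sorted(counts)
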