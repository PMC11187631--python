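import math
from collections import Counter

import numpy as np
import pytest

import hergsuite as hs
from hergsuite.curation import (
    EXCLUDE,
    KEEP_AS_ACTIVE,
    KEEP_AS_INACTIVE,
    KEEP_AS_IS,
)
from hergsuite.records_io import ActivityRecord, DatasetTable


def rec(relation, value_um):
    return ActivityRecord("X", "CCO", "SP", relation, value_um, "uM")


class TestNormalizeStructure:
    def test_salt_stripped_and_neutralized(self):
        assert hs.normalize_structure("CC(=O)[O-].[Na+]") == ("CC(=O)O", None)

    def test_inorganic_removed(self):
        assert hs.normalize_structure("[Na+].[Cl-]") == (None, "inorganic")

    def test_stereo_stripped(self):
        canonical, reason = hs.normalize_structure("C[C@H](N)C(=O)O")
        assert reason is None
        assert canonical == hs.normalize_structure("CC(N)C(=O)O")[0]

    def test_mixture_and_unparseable(self):
        assert hs.normalize_structure("CCO.c1ccccc1") == (None, "mixture")
        assert hs.normalize_structure("not-a-smiles") == (None, "unparseable")

    def test_duplicate_organic_fragments_are_not_a_mixture(self):
        assert hs.normalize_structure("CCO.CCO") == ("CCO", None)


class TestPic50:
    @pytest.mark.parametrize("molar,expected", [
        (1e-5, 5.0),
        (1e-6, 6.0),
        (2.85e-9, 8.5452),   # published 0.00285 uM potency
    ])
    def test_values(self, molar, expected):
        assert hs.ic50_to_pic50(molar) == pytest.approx(expected, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hs.ic50_to_pic50(0.0)


class TestQualifierFilter:
    @pytest.mark.parametrize("relation,value_um,task,decision", [
        ("gt", 5.0, "binary", EXCLUDE),          # ">" below 10 uM: useless
        ("gt", 10.0, "binary", KEEP_AS_INACTIVE),
        ("gt", 50.0, "binary", KEEP_AS_INACTIVE),
        ("lt", 8.0, "binary", KEEP_AS_ACTIVE),   # "<" at/below 10 uM: active
        ("lt", 10.0, "binary", KEEP_AS_ACTIVE),
        ("lt", 30.0, "binary", EXCLUDE),
        ("eq", 3.0, "binary", KEEP_AS_IS),
        ("ge", 5.0, "multiclass", EXCLUDE),      # ">=" treated as ">"
        ("le", 10.0, "multiclass", KEEP_AS_ACTIVE),
        ("lt", 3.0, "regression", EXCLUDE),      # regression: exact only
        ("gt", 50.0, "regression", EXCLUDE),
        ("eq", 3.0, "regression", KEEP_AS_IS),
    ])
    def test_decision_table(self, relation, value_um, task, decision):
        assert hs.apply_qualifier_filter(rec(relation, value_um), task) == decision


class TestLabeling:
    @pytest.mark.parametrize("pic50,expected", [
        (5.0, "nonblocker"),    # exactly 10 uM is inactive
        (5.01, "blocker"),
        (3.0, "nonblocker"),
        (8.0, "blocker"),
    ])
    def test_binary(self, pic50, expected):
        assert hs.label_binary(pic50) == expected

    @pytest.mark.parametrize("pic50,expected", [
        (6.0, "strong"),
        (7.5, "strong"),
        (5.5, "moderate_weak"),
        (5.0, "moderate_weak"),
        (4.99, "nonblocker"),
    ])
    def test_multiclass(self, pic50, expected):
        assert hs.label_multiclass(pic50) == expected

    def test_label_consistency_binary_vs_multiclass(self):
        # any strong/moderate_weak compound above pIC50 5 is a binary blocker;
        # exactly 5.0 is the single documented boundary exception
        for pic50 in np.linspace(3.0, 9.0, 241):
            multi = hs.label_multiclass(pic50)
            binary = hs.label_binary(pic50)
            if multi in ("strong", "moderate_weak") and pic50 > 5.0:
                assert binary == "blocker"
            if pic50 == 5.0:
                assert (multi, binary) == ("moderate_weak", "nonblocker")


class TestDeduplication:
    def test_classification_scenarios(self):
        groups = {
            "s1": [("blocker", 6.0), ("blocker", 6.2)],                      # (i)
            "s2": [("blocker", 6.0), ("blocker", 6.1), ("nonblocker", 4.0)], # (ii)
            "s3": [("blocker", 6.0), ("nonblocker", 4.0)],                   # (iii)
        }
        kept, removals = hs.deduplicate_classification(groups)
        by_smiles = {c.smiles: c for c in kept}
        assert by_smiles["s1"].label == "blocker"
        assert by_smiles["s2"].label == "blocker"
        assert "s3" not in by_smiles
        assert removals["duplicate_conflict"] == 2
        assert removals["duplicate_merged"] == 1 + 2

    @pytest.mark.parametrize("values,kept_expected,pic50_expected", [
        ([5.0, 5.1], True, 5.05),    # sample SD 0.0707 <= 0.2
        ([5.0, 6.0], False, None),   # sample SD 0.7071 > 0.2
        ([5.3], True, 5.3),
    ])
    def test_regression_sd_gate(self, values, kept_expected, pic50_expected):
        kept, removals, groups = hs.deduplicate_regression({"s": values}, sd_max=0.2)
        if kept_expected:
            assert len(kept) == 1
            assert kept[0].pic50 == pytest.approx(pic50_expected)
        else:
            assert not kept
            assert removals["duplicate_high_sd"] == len(values)

    @pytest.mark.parametrize("groups,expected", [
        ([[5.0, 5.2]], 0.1),
        ([[5.0, 5.0, 5.0]], 0.0),
        ([[5.0, 5.2], [6.0, 6.4]], 0.15),   # record-weighted mean of 0.1, 0.2
    ])
    def test_experimental_mae(self, groups, expected):
        assert hs.experimental_mae(groups) == pytest.approx(expected)

    def test_experimental_mae_needs_duplicates(self):
        with pytest.raises(ValueError):
            hs.experimental_mae([[5.0]])


class TestCurateDataset:
    def test_planted_truth_counts(self, planted):
        table, truth, _ = planted
        for task in ("binary", "regression"):
            ds = hs.curate_dataset(table, hs.CurationConfig(task=task))
            report = ds.report.as_dict()
            for rule, count in truth["expected_report"][task].items():
                assert report[rule] == count, (task, rule)
            assert ds.report.balanced()

    def test_count_conservation_and_order_invariance(self, planted):
        table, _, _ = planted
        ds = hs.curate_dataset(table, hs.CurationConfig(task="binary"))
        assert ds.report.balanced()
        shuffled = DatasetTable(records=list(reversed(table.records)))
        ds2 = hs.curate_dataset(shuffled, hs.CurationConfig(task="binary"))
        assert ds2.report.counts == ds.report.counts
        assert Counter((c.smiles, c.label) for c in ds2.compounds) == \
               Counter((c.smiles, c.label) for c in ds.compounds)

    @pytest.mark.parametrize("task", ["binary", "multiclass", "regression"])
    def test_idempotence(self, planted, task):
        table, _, _ = planted
        once = hs.curate_dataset(table, hs.CurationConfig(task=task))
        twice = hs.curate_dataset(once.to_table(), hs.CurationConfig(task=task))
        removals = {k: v for k, v in twice.report.counts.items() if v}
        assert removals == {}
        assert len(twice) == len(once)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hs.curate_dataset(DatasetTable(), hs.CurationConfig())

    def test_all_removed_is_valid_empty_dataset(self):
        table = DatasetTable(records=[
            ActivityRecord("A", "[Na+].[Cl-]", "SP", "eq", 1.0, "uM"),
            ActivityRecord("B", "gibberish", "SP", "eq", 1.0, "uM"),
        ])
        ds = hs.curate_dataset(table, hs.CurationConfig(task="binary"))
        assert len(ds) == 0 and ds.report.balanced()

    def test_regression_experimental_error_estimate(self, planted):
        table, truth, _ = planted
        ds = hs.curate_dataset(table, hs.CurationConfig(task="regression"))
        # exact duplicates contribute 0 deviation; conflict pairs dominate
        assert ds.report.experimental_mae is not None
        assert ds.report.experimental_mae > 0
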