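import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from claudinlow.data_io import load_cell_line_profiles
from claudinlow.ihc import (
    ADHESION_MARKERS, BASAL_LIKE, CLAUDIN_LOW, HER2_ENRICHED, LUMINAL_A,
    LUMINAL_B, TN_OTHER, UNCLASSIFIED, AllredScore, MarkerCutoffRules,
    TumorIHCProfile, aggregate_cores, allred_raw, classify_cohort,
    classify_tumor, proportion_category, resolve_her2, stemness_phenotype,
)


def all_valid_allred_inputs():
    """Every (intensity, percent) combination on a dense percent grid."""
    percents = [0.0, 0.3, 0.5, 0.9, 1.0] + [float(p) for p in range(2, 101)]
    for intensity in range(4):
        for pct in percents:
            if (intensity == 0) != (pct == 0):
                continue
            yield intensity, pct


class TestAllredScoring:
    def test_scheme_bounds_and_gap_at_one(self):
        """Raw scores span {0, 2..8}: max 8, min nonzero 2, 1 unattainable."""
        raws = {allred_raw(i, p).raw for i, p in all_valid_allred_inputs()}
        assert raws == {0, 2, 3, 4, 5, 6, 7, 8}
        assert max(raws) == 8
        assert min(r for r in raws if r > 0) == 2
        assert 1 not in raws

    @pytest.mark.parametrize(
        "intensity, pct, category, raw",
        [(3, 80.0, 5, 8), (0, 0.0, 0, 0), (1, 0.5, 1, 2),
         (2, 10.0, 2, 4), (2, 11.0, 3, 5), (3, 33.0, 3, 6), (1, 67.0, 5, 6)],
    )
    def test_proportion_bins(self, intensity, pct, category, raw):
        score = allred_raw(intensity, pct)
        assert score.proportion_category == category
        assert score.raw == raw

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            allred_raw(2, 0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            allred_raw(0, 5.0)
        with pytest.raises(ValueError):
            proportion_category(101.0)

    def test_allred_score_invariants_enforced(self):
        with pytest.raises(ValueError):
            AllredScore(intensity=0, proportion_category=1)
        with pytest.raises(ValueError):
            AllredScore(intensity=1, proportion_category=0)


class TestCoreAggregation:
    @pytest.mark.parametrize(
        "scores, expected",
        [([3, 5], 5), ([3, 5, np.nan], 5), ([0, 0, 0], 0), ([], None), ([7], 7)],
    )
    def test_highest_score_wins(self, scores, expected):
        assert aggregate_cores(scores) == expected

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cores([1])


class TestHer2Resolution:
    @pytest.mark.parametrize(
        "raw, fish, expected",
        [(6, None, True), (7, None, True), (8, 0.5, True),
         (0, None, False), (2, None, False), (3, None, False),
         (4, 2.5, True), (4, 2.0, True), (5, 1.2, False), (5, None, None),
         (4, None, None)],
    )
    def test_cutoffs_and_fish(self, raw, fish, expected):
        assert resolve_her2(raw, fish) is expected

    def test_invalid_raw_rejected(self):
        with pytest.raises(ValueError):
            resolve_her2(1)


def make_profile(scores, ki67=None, fish=None, tumor_id="T"):
    return TumorIHCProfile(tumor_id=tumor_id, marker_scores=scores,
                           ki67_percent=ki67, fish_ratio=fish)


class TestDecisionRules:
    def test_cell_line_assignments(self):
        """The nine reference cell lines reproduce their known calls."""
        profiles = load_cell_line_profiles()
        calls = {
            name: classify_tumor(make_profile(info["scores"], tumor_id=name)).subtype
            for name, info in profiles.items()
        }
        assert calls["BT549"] == CLAUDIN_LOW
        assert calls["MDAMB231"] == CLAUDIN_LOW  # despite EGFR 8: CL precedence
        assert calls["BT20"] == BASAL_LIKE       # only 1 low adhesion marker
        assert calls["SKBR3"] == HER2_ENRICHED
        assert calls["HCC1954"] == HER2_ENRICHED
        assert calls["BT474"] == LUMINAL_B       # ER+ and HER2+
        assert calls["MDAMB361"] == LUMINAL_B    # ER 4 is positive, HER2 8
        # ER+, HER2-negative lines need Ki67 for the luminal A/B split
        assert calls["MCF7"] == UNCLASSIFIED
        # ZR751 has an equivocal HER2 (5) and no FISH
        assert calls["ZR751"] == UNCLASSIFIED
        assert sum(1 for c in calls.values() if c == CLAUDIN_LOW) == 2

    @pytest.mark.parametrize(
        "scores, ki67, expected",
        [
            # luminal split
            ({"ER": 7, "PR": 0, "HER2": 0}, 5.0, LUMINAL_A),
            ({"ER": 7, "PR": 0, "HER2": 0}, 20.0, LUMINAL_B),
            ({"ER": 0, "PR": 5, "HER2": 7}, None, LUMINAL_B),
            # TN splits
            ({"ER": 0, "PR": 0, "HER2": 0, "CLDN3": 0, "CLDN4": 3,
              "CLDN7": 8, "ECAD": 8, "CK5": 8, "EGFR": 8}, None, CLAUDIN_LOW),
            ({"ER": 0, "PR": 0, "HER2": 0, "CLDN3": 8, "CLDN4": 8,
              "CLDN7": 8, "ECAD": 8, "CK5": 8, "EGFR": 0}, None, BASAL_LIKE),
            ({"ER": 0, "PR": 0, "HER2": 0, "CLDN3": 8, "CLDN4": 8,
              "CLDN7": 8, "ECAD": 8, "CK5": 0, "EGFR": 0}, None, TN_OTHER),
        ],
    )
    def test_rule_table(self, scores, ki67, expected):
        assert classify_tumor(make_profile(scores, ki67=ki67)).subtype == expected

    def test_missing_marker_blocks_with_name(self):
        call = classify_tumor(make_profile({"ER": 7, "HER2": 0, "PR": 0}))
        assert call.subtype == UNCLASSIFIED and "Ki67" in call.reason
        call = classify_tumor(make_profile({"ER": 0, "PR": 0}))
        assert call.subtype == UNCLASSIFIED and "HER2" in call.reason
        call = classify_tumor(make_profile({"PR": 0, "HER2": 0}))
        assert call.subtype == UNCLASSIFIED and "ER" in call.reason
        # TN with one low adhesion marker and one missing: could still be CL
        call = classify_tumor(make_profile(
            {"ER": 0, "PR": 0, "HER2": 0, "CLDN3": 0, "CLDN4": 8, "CLDN7": 8}))
        assert call.subtype == UNCLASSIFIED and "ECAD" in call.reason

    def test_equivocal_her2_resolved_by_fish(self):
        scores = {"ER": 0, "PR": 0, "HER2": 5, "CLDN3": 8, "CLDN4": 8,
                  "CLDN7": 8, "ECAD": 8, "CK5": 8, "EGFR": 8}
        assert classify_tumor(make_profile(scores, fish=3.0)).subtype == HER2_ENRICHED
        assert classify_tumor(make_profile(scores, fish=1.0)).subtype == BASAL_LIKE
        assert classify_tumor(make_profile(scores)).subtype == UNCLASSIFIED

    @given(st.fixed_dictionaries(
        {m: st.sampled_from([0, 2, 3, 4, 5, 6, 7, 8]) for m in ADHESION_MARKERS}),
           st.sampled_from(ADHESION_MARKERS))
    def test_raising_adhesion_never_creates_claudin_low(self, adhesion, marker):
        """Monotonicity: pushing an adhesion marker above 'low' cannot turn a
        non-claudin-low tumor into claudin-low."""
        base = {"ER": 0, "PR": 0, "HER2": 0, "CK5": 8, "EGFR": 8, **adhesion}
        before = classify_tumor(make_profile(base)).subtype
        raised = dict(base, **{marker: 8})
        after = classify_tumor(make_profile(raised)).subtype
        if before != CLAUDIN_LOW:
            assert after != CLAUDIN_LOW

    @given(st.fixed_dictionaries(
        {m: st.sampled_from([0, 2, 3, 4, 5, 6, 7, 8])
         for m in ("ER", "PR", "HER2", "CK5", "EGFR") + ADHESION_MARKERS}))
    def test_claudin_low_calls_are_triple_negative(self, scores):
        call = classify_tumor(make_profile(scores, ki67=10.0))
        if call.subtype == CLAUDIN_LOW:
            p = make_profile(scores)
            assert p.er_pos is False and p.pr_pos is False
            assert p.her2_status is not True


class TestStemness:
    @pytest.mark.parametrize(
        "scores, aldh1, cd44_cd24",
        [({"ALDH1": 4, "CD44": 8, "CD24": 0}, True, True),
         ({"ALDH1": 3, "CD44": 8, "CD24": 4}, False, False),
         ({"ALDH1": 0, "CD44": 3, "CD24": 0}, False, False),
         ({"CD44": 8}, None, None)],
    )
    def test_marker_calls(self, scores, aldh1, cd44_cd24):
        got = stemness_phenotype(make_profile(scores))
        assert got == (aldh1, cd44_cd24)


class TestCohortClassification:
    def test_cell_lines_as_pseudo_cohort(self):
        """Running the 9 cell lines through the cohort path yields 2 CL."""
        rows = []
        for name, info in load_cell_line_profiles().items():
            for marker, score in info["scores"].items():
                rows.append({"tumor_id": name, "core_index": 1, "marker": marker,
                             "allred_raw": score, "ki67_percent": np.nan,
                             "fish_ratio": np.nan})
        cores = pd.DataFrame(rows)
        calls, freq = classify_cohort(cores)
        assert (calls["subtype"] == CLAUDIN_LOW).sum() == 2
        assert int(freq.loc[freq["subtype"] == CLAUDIN_LOW, "n"].iloc[0]) == 2

    def test_empty_input(self):
        cores = pd.DataFrame(columns=["tumor_id", "core_index", "marker",
                                      "allred_raw", "ki67_percent", "fish_ratio"])
        calls, freq = classify_cohort(cores)
        assert calls.empty
        assert math.isnan(freq["percent"].iloc[0])

    def test_orphan_tumor_warns_but_classifies(self):
        cores = pd.DataFrame([
            {"tumor_id": "T1", "core_index": 1, "marker": m, "allred_raw": 0,
             "ki67_percent": np.nan, "fish_ratio": np.nan}
            for m in ("ER", "PR", "HER2", "CLDN3", "CLDN4", "CLDN7", "ECAD")
        ])
        clinical = pd.DataFrame({"tumor_id": ["T2"]})
        with pytest.warns(UserWarning, match="absent from the clinical table"):
            calls, _ = classify_cohort(cores, clinical)
        assert calls["subtype"].tolist() == [CLAUDIN_LOW]

    def test_rules_override_changes_calls(self):
        scores = {"ER": 0, "PR": 0, "HER2": 0, "CLDN3": 5, "CLDN4": 5,
                  "CLDN7": 8, "ECAD": 8, "CK5": 8, "EGFR": 8}
        default = classify_tumor(make_profile(scores))
        assert default.subtype == BASAL_LIKE
        relaxed = MarkerCutoffRules(adhesion_low_max=5)
        assert classify_tumor(make_profile(scores), rules=relaxed).subtype == CLAUDIN_LOW
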