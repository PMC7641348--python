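"""Project deduplication, keyword screening, and allocation statistics."""

import numpy as np
import pandas as pd
import pytest

from heatscreen import interventions as iv


def raw_rows(rows):
    cols = ["project_id", "tract_id", "year", "project_description",
            "dac_benefits_description", "other_benefits_description"]
    return pd.DataFrame(rows, columns=cols)


def assessments_frame(spec):
    """spec: {tract_id: (ces, hhai, svi)} flag triples."""
    return pd.DataFrame([
        {"tract_id": t, "vulnerable_ces": c, "vulnerable_hhai": h,
         "vulnerable_svi": s, "compound_score": int(c) + int(h) + int(s)}
        for t, (c, h, s) in spec.items()])


RULES = {
    "heat": iv.KeywordRule("heat", include=["cooling center", "extreme heat"],
                           exclude=["manure management"]),
    "greening_surfaces": iv.KeywordRule("greening_surfaces",
                                        include=["tree canopy"], exclude=[]),
}


class TestDedupe:
    def test_multi_year_rows_collapse_to_earliest_year(self):
        rows = raw_rows([("P1", "T1", 2018, "a", "", ""),
                         ("P1", "T1", 2017, "b", "", ""),
                         ("P2", "T1", 2017, "c", "", "")])
        out = iv.dedupe_tract_interventions(rows)
        assert len(out) == 2
        p1 = out.loc[out["project_id"] == "P1"].iloc[0]
        assert p1["year"] == 2017
        assert p1["project_description"] == "b; a"  # concatenated in year order

    def test_distinct_pairs_unchanged(self):
        rows = raw_rows([("P1", "T1", 2017, "", "", ""),
                         ("P1", "T2", 2017, "", "", "")])
        assert len(iv.dedupe_tract_interventions(rows)) == 2

    def test_duplicate_text_not_repeated(self):
        rows = raw_rows([("P1", "T1", 2017, "same", "", ""),
                         ("P1", "T1", 2018, "same", "", "")])
        out = iv.dedupe_tract_interventions(rows)
        assert out["project_description"].iloc[0] == "same"

    def test_missing_identifiers_rejected(self):
        rows = raw_rows([("P1", "T1", 2017, "", "", ""),
                         (None, "T1", 2017, "", "", ""),
                         ("P2", None, 2017, "", "", "")])
        assert len(iv.dedupe_tract_interventions(rows)) == 1

    def test_idempotent(self):
        rows = raw_rows([("P1", "T1", 2018, "a", "x", ""),
                         ("P1", "T1", 2017, "b", "x", ""),
                         ("P3", "T2", 2016, "c", "", "z")])
        once = iv.dedupe_tract_interventions(rows)
        twice = iv.dedupe_tract_interventions(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_empty_input_gives_empty_output(self):
        assert iv.dedupe_tract_interventions(raw_rows([])).empty


class TestPhraseFrequency:
    def test_counts_are_per_intervention(self):
        rows = raw_rows([("P1", "T1", 2017, "tree canopy and tree canopy", "", ""),
                         ("P2", "T1", 2017, "", "tree canopy", ""),
                         ("P3", "T1", 2017, "nothing", "", "")])
        out = iv.phrase_frequency_table(rows, ["tree canopy", "absent phrase"])
        assert out.set_index("phrase")["n_interventions"].to_dict() == {
            "tree canopy": 2, "absent phrase": 0}

    def test_matching_is_case_insensitive_and_whitespace_normalized(self):
        rows = raw_rows([("P1", "T1", 2017, "Tree   CANOPY planting", "", "")])
        out = iv.phrase_frequency_table(rows, ["tree canopy"])
        assert out["n_interventions"].iloc[0] == 1

    def test_empty_phrase_list_is_an_error(self):
        with pytest.raises(ValueError):
            iv.phrase_frequency_table(raw_rows([]), [])


class TestKeywordScreen:
    def test_include_assigns_category(self):
        rows = raw_rows([("P1", "T1", 2017, "planting urban tree canopy for shade", "", "")])
        out = iv.keyword_screen(rows, RULES)
        assert out["category_greening_surfaces"].iloc[0]
        assert not out["category_heat"].iloc[0]

    def test_exclusion_dominates_inclusion(self):
        rows = raw_rows([("P1", "T1", 2017,
                          "cooling center at the manure management facility", "", "")])
        out = iv.keyword_screen(rows, RULES)
        assert not out["category_heat"].iloc[0]

    def test_multiple_categories_allowed(self):
        rows = raw_rows([("P1", "T1", 2017, "cooling center with tree canopy", "", "")])
        out = iv.keyword_screen(rows, RULES)
        assert out["category_heat"].iloc[0] and out["category_greening_surfaces"].iloc[0]
        assert out["heat_related"].iloc[0]

    def test_empty_include_list_is_an_error(self):
        bad = {"heat": iv.KeywordRule("heat", include=[], exclude=["x"])}
        with pytest.raises(ValueError):
            iv.keyword_screen(raw_rows([]), bad)

    def test_word_boundary_mode_blocks_mid_word_matches(self):
        rows = raw_rows([("P1", "T1", 2017, "overheating issues", "", "")])
        loose = {"heat": iv.KeywordRule("heat", include=["heat"], exclude=[])}
        assert iv.keyword_screen(rows, loose)["category_heat"].iloc[0]
        assert not iv.keyword_screen(rows, loose,
                                     word_boundary=True)["category_heat"].iloc[0]

    def test_adding_include_never_removes_adding_exclude_never_adds(self):
        rows = raw_rows([("P%d" % i, "T1", 2017, text, "", "") for i, text in enumerate(
            ["cooling center", "tree canopy", "extreme heat and manure management",
             "nothing at all", "cooling center and tree canopy"])])
        base = iv.keyword_screen(rows, RULES)
        richer = {k: iv.KeywordRule(k, include=r.include + ["nothing at all"],
                                    exclude=r.exclude) for k, r in RULES.items()}
        out_r = iv.keyword_screen(rows, richer)
        for col in ("category_heat", "category_greening_surfaces"):
            assert (out_r[col] | ~base[col]).all()  # no classification lost
        stricter = {k: iv.KeywordRule(k, include=r.include,
                                      exclude=r.exclude + ["tree"])
                    for k, r in RULES.items()}
        out_s = iv.keyword_screen(rows, stricter)
        for col in ("category_heat", "category_greening_surfaces"):
            assert (~out_s[col] | base[col]).all()  # no classification gained


class TestAllocationByScore:
    def test_percentages_from_enumerated_example(self):
        assessments = assessments_frame({
            "T3a": (True, True, True), "T3b": (True, True, True),
            "T2": (True, True, False), "T0": (False, False, False)})
        classified = pd.DataFrame({
            "project_id": list("abcd"),
            "tract_id": ["T3a", "T3b", "T2", "T0"],
            "heat_related": True, "category_heat": True})
        alloc = iv.allocation_by_compound_score(classified, assessments)
        row = alloc.table.loc["all_heat_related"]
        assert row["pct_score_ge2"] == pytest.approx(75.0)
        assert row["pct_score_0"] == pytest.approx(25.0)
        assert alloc.reference_pct_score_ge1 == pytest.approx(75.0)

    def test_all_score_zero(self):
        assessments = assessments_frame({"T0": (False, False, False)})
        classified = pd.DataFrame({"project_id": ["a"], "tract_id": ["T0"],
                                   "heat_related": True, "category_heat": True})
        alloc = iv.allocation_by_compound_score(classified, assessments)
        assert alloc.table.loc["heat", "pct_score_0"] == 100.0

    def test_empty_category_yields_nan_not_error(self):
        assessments = assessments_frame({"T0": (False, False, False)})
        classified = pd.DataFrame({"project_id": ["a"], "tract_id": ["T0"],
                                   "heat_related": False, "category_heat": False})
        alloc = iv.allocation_by_compound_score(classified, assessments)
        assert np.isnan(alloc.table.loc["heat", "pct_score_0"])

    def test_percentages_sum_to_100(self, classified_interventions, assessments):
        alloc = iv.allocation_by_compound_score(classified_interventions, assessments)
        sums = alloc.table[[f"pct_score_{s}" for s in range(4)]].sum(axis=1)
        filled = alloc.table["n"] > 0
        assert np.allclose(sums[filled], 100.0)


class TestAllocationByIndex:
    def test_disjoint_set_ratio(self):
        assessments = assessments_frame({"A": (True, False, False),
                                         "B": (False, True, False)})
        classified = pd.DataFrame({
            "project_id": [str(i) for i in range(15)],
            "tract_id": ["A"] * 10 + ["B"] * 5})
        out = iv.allocation_by_index(classified, assessments)
        assert out.ces_not_hhai == 10 and out.hhai_not_ces == 5
        assert out.ratio == pytest.approx(2.0)

    def test_zero_denominator_gives_undefined_ratio(self):
        assessments = assessments_frame({"A": (False, False, False)})
        classified = pd.DataFrame({"project_id": ["1"], "tract_id": ["A"]})
        out = iv.allocation_by_index(classified, assessments)
        assert np.isnan(out.ratio)

    def test_all_three_tracts_have_empty_disjoint_sets(self):
        assessments = assessments_frame({"A": (True, True, True)})
        classified = pd.DataFrame({"project_id": ["1", "2"], "tract_id": ["A", "A"]})
        out = iv.allocation_by_index(classified, assessments)
        assert out.ces_not_hhai == 0 and out.hhai_not_ces == 0
        assert out.all_three == 2
        assert out.per_index.loc["ces", "pct_in_vulnerable"] == 100.0


class TestAB1550:
    def test_change_in_percentage_points(self):
        assessments = assessments_frame({"D": (True, False, False),
                                         "N": (False, False, False)})
        flags = assessments.assign(low_income=[False, False])
        classified = pd.DataFrame({
            "project_id": [str(i) for i in range(8)],
            "tract_id": ["D", "D", "N", "N", "D", "N", "N", "N"],
            "year": [2015, 2015, 2016, 2016, 2017, 2017, 2018, 2019]})
        out = iv.ab1550_comparison(classified, flags)
        assert out.loc["disadvantaged", "pre_pct"] == pytest.approx(50.0)
        assert out.loc["disadvantaged", "post_pct"] == pytest.approx(25.0)
        assert out.loc["disadvantaged", "change_points"] == pytest.approx(-25.0)

    def test_identical_distributions_change_zero(self):
        assessments = assessments_frame({"D": (True, False, False),
                                         "N": (False, False, False)})
        flags = assessments.assign(low_income=[False, True])
        classified = pd.DataFrame({
            "project_id": [str(i) for i in range(4)],
            "tract_id": ["D", "N", "D", "N"],
            "year": [2015, 2016, 2017, 2018]})
        out = iv.ab1550_comparison(classified, flags)
        assert np.allclose(out["change_points"], 0.0)

    def test_groups_sum_to_100_within_each_era(self):
        assessments = assessments_frame({"D": (True, False, False),
                                         "L": (False, True, False),
                                         "N": (False, False, False)})
        flags = assessments.assign(low_income=[True, True, False])
        classified = pd.DataFrame({
            "project_id": [str(i) for i in range(6)],
            "tract_id": ["D", "L", "N", "D", "L", "N"],
            "year": [2015, 2016, 2015, 2017, 2018, 2019]})
        out = iv.ab1550_comparison(classified, flags)
        assert out["pre_pct"].sum() == pytest.approx(100.0)
        assert out["post_pct"].sum() == pytest.approx(100.0)

    def test_ces_and_low_income_goes_to_disadvantaged_only(self):
        assessments = assessments_frame({"B": (True, False, False)})
        flags = assessments.assign(low_income=[True])
        classified = pd.DataFrame({"project_id": ["1"], "tract_id": ["B"],
                                   "year": [2015]})
        out = iv.ab1550_comparison(classified, flags)
        assert out.loc["disadvantaged", "n_pre"] == 1
        assert out.loc["low_income_not_ces", "n_pre"] == 0

    def test_out_of_range_years_excluded(self):
        assessments = assessments_frame({"D": (True, False, False)})
        flags = assessments.assign(low_income=[False])
        classified = pd.DataFrame({"project_id": ["1", "2"], "tract_id": ["D", "D"],
                                   "year": [2014, 2015]})
        out = iv.ab1550_comparison(classified, flags)
        assert out["n_pre"].sum() == 1 and out["n_post"].sum() == 0
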