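"""Imputation, two-step de-duplication and exclusion rules."""
import numpy as np

from faerspv.io import load_synonyms
from faerspv.preprocess import (apply_exclusions, clean, deduplicate,
                                impute_missing, primary_suspect_map)
from faerspv.synthetic import simulate, study_config

from conftest import make_bundle


def _demo(pid, case, **kw):
    row = {"primaryid": pid, "caseid": case, "i_f_code": "I",
           "event_dt": "20200101", "age": "60", "age_cod": "YR",
           "sex": "F", "reporter_country": "US"}
    row.update(kw)
    return row


class TestImputation:
    def test_single_version_case_unchanged(self):
        b = make_bundle([_demo("1", "1", age="")])
        out, counts = impute_missing(b)
        assert out.demo["age"][0] == ""
        assert counts["age_yr"] == 0

    def test_single_donor_fills_single_missing_field(self):
        b = make_bundle([_demo("1", "1", age="60"),
                         _demo("2", "1", age="")])
        out, counts = impute_missing(b)
        assert out.demo.loc[out.demo["primaryid"] == "2",
                            "age_yr"].iloc[0] == 60.0
        assert counts["age_yr"] == 1

    def test_maximum_rule_over_two_donors(self):
        b = make_bundle([_demo("1", "1", age="55"),
                         _demo("2", "1", age="62"),
                         _demo("3", "1", age="")])
        out, _ = impute_missing(b)
        assert out.demo.loc[out.demo["primaryid"] == "3",
                            "age_yr"].iloc[0] == 62.0

    def test_two_missing_fields_left_untouched(self):
        b = make_bundle([_demo("1", "1"),
                         _demo("2", "1", age="", sex="")])
        out, counts = impute_missing(b)
        recip = out.demo[out.demo["primaryid"] == "2"].iloc[0]
        assert recip["age"] == "" and recip["sex"] == ""
        assert sum(counts.values()) == 0

    def test_incomplete_versions_are_not_donors(self):
        # the only other version misses a field itself -> no donor pool
        b = make_bundle([_demo("1", "1", event_dt=""),
                         _demo("2", "1", age="")])
        out, counts = impute_missing(b)
        assert out.demo.loc[out.demo["primaryid"] == "2", "age"].iloc[0] == ""
        assert sum(counts.values()) == 0


class TestDeduplication:
    def test_identical_versions_collapse_to_largest_id(self):
        b = make_bundle([_demo("1", "1"), _demo("2", "1")],
                        outc_rows=[{"primaryid": "1", "outc_cod": "HO"},
                                   {"primaryid": "2", "outc_cod": "HO"}])
        out, rep = deduplicate(b)
        assert out.demo["primaryid"].tolist() == ["2"]
        assert rep.duplicates_removed == 1

    def test_versions_differing_in_age_survive_step1(self):
        b = make_bundle([_demo("1", "1", age="60"),
                         _demo("2", "1", age="61")])
        out, rep = deduplicate(b)
        assert rep.step1_removed == 0
        # but step 2 does not collapse them either (different age)
        assert len(out.demo) == 2

    def test_cross_case_step2_collapse_on_reaction_profile(self):
        rows = [_demo("1", "1"), _demo("5", "5")]
        reac = [{"primaryid": "1", "pt_code": "10000001", "pt": "x"},
                {"primaryid": "5", "pt_code": "10000001", "pt": "x"}]
        out, rep = deduplicate(make_bundle(rows, reac_rows=reac))
        assert out.demo["primaryid"].tolist() == ["5"]
        assert rep.step2_removed == 1

    def test_idempotent_and_order_independent(self):
        bundle, _ = simulate(study_config(1500, seed=23))
        once, rep1 = deduplicate(bundle)
        twice, rep2 = deduplicate(once)
        assert rep2.duplicates_removed == 0
        assert sorted(twice.demo["primaryid"]) == sorted(once.demo["primaryid"])

        shuffled = bundle.copy()
        rng = np.random.default_rng(0)
        for name in ("demo", "drug", "reac", "outc"):
            t = shuffled.table(name)
            setattr(shuffled, name,
                    t.sample(frac=1, random_state=1).reset_index(drop=True))
        out_s, _ = deduplicate(shuffled)
        assert sorted(out_s.demo["primaryid"]) == sorted(once.demo["primaryid"])

    def test_injected_duplicates_removed_exactly(self):
        cfg = study_config(5000, seed=29, duplicate_rate=0.1,
                           followup_rate=0.0, missingness={})
        bundle, ledger = simulate(cfg)
        _, rep = deduplicate(bundle)
        # step 1 removes exactly the injected duplicate versions; step 2 may
        # additionally collapse coincidentally identical cross-case reports
        assert rep.step1_removed == ledger.counts["n_duplicate_versions"]
        assert rep.duplicates_removed >= rep.step1_removed


class TestExclusions:
    def test_age_boundary_is_strictly_under_18(self):
        b = make_bundle([_demo("1", "1", age="17.9"),
                         _demo("2", "2", age="18"),
                         _demo("3", "3", age="")])
        out, rep = apply_exclusions(b)
        assert sorted(out.demo["primaryid"]) == ["2", "3"]  # unknown kept
        assert rep.under18_removed == 1

    def test_exclusion_idempotent(self):
        b = make_bundle([_demo("1", "1", age="10"), _demo("2", "2")])
        once, _ = apply_exclusions(b)
        twice, rep = apply_exclusions(once)
        assert rep.under18_removed == 0

    def test_count_conservation_invariant(self, small_cleaned):
        _, report, _ = small_cleaned
        report.check()
        assert report.retained == (report.input_reports
                                   - report.duplicates_removed
                                   - report.under18_removed)


class TestStudySelection:
    def test_concomitant_only_alk_use_is_not_selected(self):
        rows = [_demo("1", "1")]
        drugs = [{"primaryid": "1", "drug_seq": "1", "role_cod": "PS",
                  "drugname": "carboplatin"},
                 {"primaryid": "1", "drug_seq": "2", "role_cod": "C",
                  "drugname": "crizotinib"}]
        m = primary_suspect_map(make_bundle(rows, drug_rows=drugs),
                                load_synonyms())
        assert len(m) == 0

    def test_brand_name_primary_suspect_selected(self):
        rows = [_demo("1", "1")]
        drugs = [{"primaryid": "1", "drug_seq": "1", "role_cod": "PS",
                  "drugname": "Xalkori"}]
        m = primary_suspect_map(make_bundle(rows, drug_rows=drugs),
                                load_synonyms())
        assert m.to_dict() == {"1": "crizotinib"}
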