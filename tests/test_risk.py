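"""Logistic risk model, odds-ratio identities and the nomogram."""
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from faerspv.io import load_synonyms
from faerspv.preprocess import primary_suspect_map
from faerspv.risk import (SeparationError, build_case_control, build_nomogram,
                          multivariate_fit, predict_fit, predict_risk,
                          univariate_or)
from faerspv.smq import flag_cases, load_smq
from faerspv.synthetic import simulate_covariate_matrix

from conftest import make_bundle


def _matrix_from_2x2(a, b, c, d, name="x"):
    """exposure x outcome counts -> long covariate matrix."""
    rows = ([{"outcome": 1, name: 1}] * a + [{"outcome": 0, name: 1}] * b
            + [{"outcome": 1, name: 0}] * c + [{"outcome": 0, name: 0}] * d)
    return pd.DataFrame(rows)


class TestUnivariate:
    def test_balanced_null_table(self):
        est, lo, hi, p = univariate_or(_matrix_from_2x2(20, 20, 20, 20), "x")
        assert est == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_cross_product_arithmetic(self):
        est, *_ = univariate_or(_matrix_from_2x2(20, 80, 10, 90), "x")
        assert est == pytest.approx(2.25)

    def test_logistic_fit_reproduces_cross_product_or(self):
        m = _matrix_from_2x2(20, 80, 10, 90)
        fit = multivariate_fit(m, ["x"])
        assert fit.table.at["x", "or"] == pytest.approx(2.25, abs=1e-6)

    def test_empty_stratum_undefined(self):
        est, *_ = univariate_or(_matrix_from_2x2(5, 0, 10, 90), "x")
        assert math.isnan(est)


class TestMultivariate:
    def test_parameter_recovery_on_planted_model(self):
        beta = {"x1": math.log(3.0), "x2": math.log(0.5), "x3": 0.8}
        m = simulate_covariate_matrix(beta, intercept=-2.0, n=20000, seed=4)
        fit = multivariate_fit(m)
        for k, b in beta.items():
            assert fit.table.at[k, "coef"] == pytest.approx(
                b, abs=3 * fit.table.at[k, "se"])
        assert fit.converged

    def test_constant_covariate_dropped_with_warning(self):
        m = simulate_covariate_matrix({"x1": 1.0}, -1.0, 500, seed=1)
        m["zero"] = 0
        with pytest.warns(UserWarning, match="zero"):
            fit = multivariate_fit(m)
        assert "zero" in fit.dropped
        assert "zero" not in fit.covariates

    def test_duplicated_data_halves_variance(self):
        m = simulate_covariate_matrix({"x1": 1.0}, -1.0, 2000, seed=2)
        fit1 = multivariate_fit(m)
        fit2 = multivariate_fit(pd.concat([m, m], ignore_index=True))
        assert fit2.table.at["x1", "coef"] == pytest.approx(
            fit1.table.at["x1", "coef"], abs=1e-6)
        assert fit2.table.at["x1", "se"] == pytest.approx(
            fit1.table.at["x1", "se"] / math.sqrt(2), rel=1e-3)

    def test_perfect_separation_names_covariate(self):
        m = pd.DataFrame({"outcome": [0] * 20 + [1] * 20,
                          "sep": [0] * 20 + [1] * 20})
        with pytest.raises(SeparationError, match="sep"):
            multivariate_fit(m)

    def test_wald_inference_matches_statsmodels(self):
        m = simulate_covariate_matrix({"x1": 0.7, "x2": -0.4}, -1.5,
                                      4000, seed=3)
        fit = multivariate_fit(m)
        ref = sm.Logit(m["outcome"],
                       sm.add_constant(m[["x1", "x2"]].astype(float))).fit(
            disp=0)
        assert fit.table.at["x1", "p"] == pytest.approx(ref.pvalues["x1"])


class TestNomogram:
    def _fit(self, seed=5):
        beta = {"x1": 1.2, "x2": -0.8, "x3": 0.3}
        m = simulate_covariate_matrix(beta, -2.0, 4000, seed=seed)
        return multivariate_fit(m)

    def test_largest_contribution_spans_100_points(self):
        fit = self._fit()
        spec = build_nomogram(fit)
        assert max(e.points_max for e in spec.entries.values()) \
            == pytest.approx(100.0)

    def test_reference_profile_probability(self):
        fit = self._fit()
        spec = build_nomogram(fit)
        # all covariates at their minimum contribution
        profile = {k: (0.0 if e.coef >= 0 else 1.0)
                   for k, e in spec.entries.items()}
        assert spec.total_points(profile) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_matches_model_prediction(self):
        fit = self._fit()
        spec = build_nomogram(fit)
        rng = np.random.default_rng(0)
        for _ in range(100):
            profile = {k: float(rng.integers(0, 2)) for k in spec.entries}
            assert predict_risk(spec, profile) == pytest.approx(
                predict_fit(fit, profile), abs=1e-6)

    def test_monotone_in_positive_coefficient(self):
        fit = self._fit()
        spec = build_nomogram(fit)
        low = {"x1": 0.0, "x2": 0.0, "x3": 0.0}
        high = {"x1": 1.0, "x2": 0.0, "x3": 0.0}
        assert predict_risk(spec, high) > predict_risk(spec, low)
        assert 0.0 < predict_risk(spec, high) < 1.0

    def test_out_of_range_profile_rejected(self):
        spec = build_nomogram(self._fit())
        with pytest.raises(ValueError, match="outside"):
            predict_risk(spec, {"x1": 2.0, "x2": 0.0, "x3": 0.0})
        with pytest.raises(ValueError, match="missing"):
            predict_risk(spec, {"x1": 1.0})

    def test_unconverged_fit_refused(self):
        fit = self._fit()
        fit.converged = False
        with pytest.raises(ValueError, match="unconverged"):
            build_nomogram(fit)


class TestBuildCaseControl:
    def _bundle(self):
        demo = [
            {"primaryid": "1", "caseid": "1", "age": "70", "age_cod": "YR",
             "sex": "F"},
            {"primaryid": "2", "caseid": "2", "age": "50", "age_cod": "YR",
             "sex": "M"},
        ]
        drug = [
            {"primaryid": "1", "drug_seq": "1", "role_cod": "PS",
             "drugname": "brigatinib"},
            {"primaryid": "1", "drug_seq": "2", "role_cod": "C",
             "drugname": "amlodipine"},
            {"primaryid": "2", "drug_seq": "1", "role_cod": "PS",
             "drugname": "lorlatinib"},
        ]
        indi = [{"primaryid": "1", "indi_drug_seq": "2",
                 "indi_pt_code": "10020772", "indi_pt": "Hypertension"}]
        reac = [{"primaryid": "1", "pt_code": "10022611", "pt": "ILD"},
                {"primaryid": "2", "pt_code": "10019211", "pt": "Headache"}]
        return make_bundle(demo, drug_rows=drug, reac_rows=reac,
                           indi_rows=indi)

    def test_outcome_drugs_and_concomitants(self):
        b = self._bundle()
        m = build_case_control(b, primary_suspect_map(b, load_synonyms()),
                               flag_cases(b, load_smq()))
        r1 = m.iloc[0]  # brigatinib + amlodipine, ILD case, age 70 F
        assert r1["outcome"] == 1
        assert r1["drug_brigatinib"] == 1
        assert r1["con_amlodipine"] == 1
        assert r1["dis_hypertension"] == 1
        assert r1["age_65_84"] == 1 and r1["sex_female"] == 1
        r2 = m.iloc[1]  # lorlatinib (reference): all drug indicators zero
        assert r2["outcome"] == 0
        assert not any(v for k, v in r2.items() if k.startswith("drug_"))
        assert not any(v for k, v in r2.items() if k.startswith("con_"))

    def test_planted_covariate_prevalences_recovered(self, small_cleaned):
        bundle, _, ledger = small_cleaned
        smap = primary_suspect_map(bundle, load_synonyms())
        m = build_case_control(bundle, smap, flag_cases(bundle, load_smq()))
        # amlodipine prevalence planted at 0.05: exact binomial 99% bounds
        from scipy.stats import binom
        n = len(m)
        lo, hi = binom.ppf(0.005, n, 0.05), binom.ppf(0.995, n, 0.05)
        assert lo <= m["con_amlodipine"].sum() <= hi
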