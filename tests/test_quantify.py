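"""Delta-Cp algebra, fold changes, clade fractions, inclusion filters."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cladeqpcr as cq
from cladeqpcr.quantify import build_quant_table, survey_report

cycles = st.floats(min_value=5.0, max_value=45.0)


class TestDeltaCpAndFolds:
    def test_delta_cp_worked_examples(self):
        # surface HL: rbcL barely below rnpB, psbA far below
        assert cq.delta_cp(20.98, 21.09) == pytest.approx(-0.11)
        assert cq.delta_cp(20.98, 16.87) == pytest.approx(4.11)
        assert cq.delta_cp(13.0, 13.0) == 0.0
        assert math.isnan(cq.delta_cp(float("nan"), 20.0))

    def test_equal_dcp_gives_unit_fold(self):
        assert cq.fold_change(2.5, 2.5).value == 1.0

    def test_ten_cycle_offset_is_thousandfold_scale(self):
        fc = cq.fold_change(10.0, 0.0)
        assert fc.value == 1024.0
        assert fc.log2_value == 10.0

    def test_surface_vs_deep_hl_rbcl_is_about_fivefold(self):
        fc = cq.fold_change(-0.11, -2.54)
        assert fc.value == pytest.approx(5.39, abs=0.01)

    @settings(derandomize=True, max_examples=200)
    @given(a=cycles, b=cycles)
    def test_fold_antisymmetry(self, a, b):
        prod = cq.fold_change(a, b).value * cq.fold_change(b, a).value
        assert prod == pytest.approx(1.0, rel=1e-12)

    def test_rbcl_psba_ratio_worked_example(self):
        # surface HL: rbcL/psbA = 2^(-0.11 - 4.11)
        fc = cq.rbcl_psba_ratio(-0.11, 4.11)
        assert fc.value == pytest.approx(2.0 ** -4.22, rel=1e-12)
        assert fc.value == pytest.approx(0.054, abs=0.001)


class TestCladeFraction:
    @pytest.mark.parametrize(
        "cp_hl,cp_ll,expected_pct",
        [(20.98, 26.00, 97), (22.65, 18.80, 6), (26.17, 20.67, 2)],
    )
    def test_survey_fractions_from_summary_means(self, cp_hl, cp_ll,
                                                 expected_pct):
        frac = cq.clade_fraction(cp_hl, cp_ll)
        assert round(100.0 * frac.fraction_hl) == expected_pct

    def test_equal_cps_split_evenly(self):
        assert cq.clade_fraction(22.0, 22.0).fraction_hl == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=200)
    @given(cp_hl=cycles, cp_ll=cycles)
    def test_fractions_conserve_and_match_closed_form(self, cp_hl, cp_ll):
        frac = cq.clade_fraction(cp_hl, cp_ll)
        assert frac.fraction_hl + frac.fraction_ll == pytest.approx(1.0)
        # independent route: explicit copy numbers with an arbitrary common k
        k = 7.3e5
        n_hl = k * 2.0 ** -cp_hl
        n_ll = k * 2.0 ** -cp_ll
        assert frac.fraction_hl == pytest.approx(n_hl / (n_hl + n_ll),
                                                 rel=1e-9)

    def test_unequal_efficiency_form(self):
        # E_ll = 0.9: the LL copy estimate uses base 1.9, not 2
        frac = cq.clade_fraction(20.0, 25.0, efficiency_hl=1.0,
                                 efficiency_ll=0.9)
        n_hl, n_ll = 2.0 ** -20.0, 1.9 ** -25.0
        assert frac.fraction_hl == pytest.approx(n_hl / (n_hl + n_ll))
        assert not frac.assumes_equal_efficiency

    def test_censored_input_propagates(self):
        assert math.isnan(cq.clade_fraction(float("nan"), 20.0).fraction_hl)


class TestQuantTableFilters:
    def _calls(self, cp_map, flags=None):
        rows = []
        for target, cp in cp_map.items():
            rows.append({
                "sample_id": "s1", "target": target, "cp": cp,
                "censored": np.isnan(cp),
                "qc_flags": (flags or {}).get(target, ""),
                "replicate_delta": 0.1,
            })
        return pd.DataFrame(rows)

    CPS = {"rnpB-HL": 21.0, "rbcL-HL": 21.1, "psbA-HL": 16.9,
           "rnpB-LL": 26.0, "rbcL-LL": 31.8, "psbA-LL": 25.1}

    def _profiles(self, classes=None):
        return pd.DataFrame([
            {"sample_id": "s1", "target": t,
             "profile_class": (classes or {}).get(t, "single")}
            for t in self.CPS
        ])

    def test_clean_sample_included(self):
        out = build_quant_table(self._calls(self.CPS), self._profiles())
        assert out["included"].all()
        hl = out[out["clade"] == "HL"].iloc[0]
        assert hl["delta_cp_rbcL"] == pytest.approx(-0.1)
        assert hl["ratio"] == pytest.approx(2.0 ** (-0.1 - 4.1))
        assert hl["fraction_HL"] == pytest.approx(
            cq.clade_fraction(21.0, 26.0).fraction_hl)

    def test_double_peak_excludes_with_reason(self):
        out = build_quant_table(
            self._calls(self.CPS),
            self._profiles({"rbcL-LL": "double"}),
        )
        ll = out[out["clade"] == "LL"].iloc[0]
        assert not ll["included"]
        assert "single_peak_rule" in ll["excluded_reason"]
        assert out[out["clade"] == "HL"].iloc[0]["included"]

    def test_replicate_disagreement_excludes(self):
        out = build_quant_table(
            self._calls(self.CPS, flags={"rbcL-HL": "replicate_disagreement"}),
            self._profiles(),
        )
        hl = out[out["clade"] == "HL"].iloc[0]
        assert not hl["included"]
        assert "replicate_disagreement" in hl["excluded_reason"]

    def test_missing_melt_profile_excludes(self):
        out = build_quant_table(self._calls(self.CPS),
                                self._profiles().iloc[:-1])
        ll = out[out["clade"] == "LL"].iloc[0]
        assert not ll["included"]
        assert "missing_melt_profile" in ll["excluded_reason"]


class TestSurveyReport:
    def test_headline_numbers_from_summary_table(self, cp_summary_table):
        rep = survey_report(cp_summary_table)
        assert rep["fraction_hl_pct_rounded"] == {"3m": 97, "DCM": 6,
                                                  "DCM+40": 2}
        assert rep["depth_folds_rounded"]["HL_rbcL_3m_vs_DCM+40"] == 5
        assert rep["depth_folds_rounded"]["HL_psbA_3m_vs_DCM+40"] == 3
        assert rep["depth_folds_rounded"]["LL_rbcL_DCM_vs_3m"] == 3

    def test_noiseless_pipeline_reproduces_fractions(self):
        """sd -> 0 survey pushed through the whole pipeline hits the same
        fractions as the summary-mean arithmetic."""
        summary = {k: (m, 0.0, n) for k, (m, s, n) in
                   cq.DEFAULT_SURVEY_CP.items()}
        ds = cq.simulate_survey(cq.SurveyDesignSpec(
            stations=3, cp_summary=summary, replicate_sd=0.0,
            include_melt=False, seed=0))
        obs = (ds.cp_measurements.groupby(["target", "depth_class"])["cp"]
               .mean().reset_index().rename(columns={"cp": "mean"}))
        rep = survey_report(obs)
        assert rep["fraction_hl_pct_rounded"] == {"3m": 97, "DCM": 6,
                                                  "DCM+40": 2}
        assert rep["depth_folds_rounded"]["HL_rbcL_3m_vs_DCM+40"] == 5
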