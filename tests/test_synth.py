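"""Generator contracts: determinism, closed-form Cp spacing, melt linearity."""
import numpy as np
import pytest

import cladeqpcr as cq
from cladeqpcr.config import ValidationError
from cladeqpcr.melt import derivative_profile


class TestAmplificationGenerator:
    def test_same_seed_bit_identical(self):
        p = cq.AmplificationModelParams(n0=1e4, noise_sd=0.3, seed=42)
        a = cq.simulate_amplification(p).fluorescence
        b = cq.simulate_amplification(p).fluorescence
        np.testing.assert_array_equal(a, b)

    def test_no_template_is_baseline_only(self):
        p = cq.AmplificationModelParams(n0=0.0)
        curve = cq.simulate_amplification(p)
        c = np.arange(1, 46)
        np.testing.assert_allclose(
            curve.fluorescence, p.baseline_intercept + p.baseline_slope * c
        )

    @pytest.mark.parametrize("d", [2, 10, 1024])
    def test_cp_spacing_law(self, d):
        """A d-fold template ratio offsets Cp by log2(d) at 100% efficiency."""
        cps = []
        for n0 in (1e3, 1e3 * d):
            curve = cq.simulate_amplification(
                cq.AmplificationModelParams(n0=n0, efficiency=1.0)
            )
            cps.append(cq.call_cp(curve).cp)
        assert cps[0] - cps[1] == pytest.approx(np.log2(d), abs=0.05)

    def test_monotonicity_in_template(self):
        """Noiseless: more starting template always means earlier Cp."""
        cps = [
            cq.call_cp(cq.simulate_amplification(
                cq.AmplificationModelParams(n0=n0))).cp
            for n0 in 10.0 ** np.arange(2, 8)
        ]
        assert np.all(np.diff(cps) < 0)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n0": -1.0}, "n0"),
            ({"n0": 10.0, "efficiency": 0.0}, "efficiency"),
            ({"n0": 10.0, "efficiency": 1.2}, "efficiency"),
            ({"n0": 10.0, "plateau": 5.0}, "plateau"),
            ({"n0": 10.0, "n_cycles": 5}, "n_cycles"),
            ({"n0": 10.0, "noise_sd": -0.1}, "noise_sd"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            cq.AmplificationModelParams(**kwargs)


class TestMeltGenerator:
    def test_same_seed_bit_identical(self):
        comps = [cq.MeltComponent(tm=84.0)]
        a = cq.simulate_melt(comps, noise_sd=0.1, seed=7).fluorescence
        b = cq.simulate_melt(comps, noise_sd=0.1, seed=7).fluorescence
        np.testing.assert_array_equal(a, b)

    def test_amplitude_scaling_is_linear(self):
        """Scaling all amplitudes by c scales -dF/dT by c; Tm unchanged."""
        base = [cq.MeltComponent(tm=82.0, amplitude=5.0),
                cq.MeltComponent(tm=88.0, amplitude=8.0)]
        scaled = [cq.MeltComponent(tm=p.tm, width=p.width,
                                   amplitude=3.0 * p.amplitude) for p in base]
        c1 = cq.simulate_melt(base, background_intercept=0.0,
                              background_slope=0.0)
        c2 = cq.simulate_melt(scaled, background_intercept=0.0,
                              background_slope=0.0)
        _, d1 = derivative_profile(c1)
        _, d2 = derivative_profile(c2)
        np.testing.assert_allclose(d2, 3.0 * d1, rtol=1e-7,
                                   atol=1e-9 * np.max(np.abs(d1)))
        p1, p2 = cq.analyze_melt_curve(c1), cq.analyze_melt_curve(c2)
        assert [pk.tm for pk in p1.peaks] == [pk.tm for pk in p2.peaks]

    def test_zero_components_has_no_peaks(self):
        curve = cq.simulate_melt([])
        assert cq.analyze_melt_curve(curve).profile_class == "none"

    def test_bad_grid_rejected(self):
        with pytest.raises(ValidationError):
            cq.simulate_melt([], step=0.0)
        with pytest.raises(ValidationError):
            cq.simulate_melt([], t_start=90.0, t_end=80.0)


class TestSurveyGenerator:
    def test_determinism_and_shapes(self):
        spec = cq.SurveyDesignSpec(stations=5, seed=3)
        a, b = cq.simulate_survey(spec), cq.simulate_survey(spec)
        assert a.cp_measurements.equals(b.cp_measurements)
        assert a.truth.equals(b.truth)
        # 5 stations x 3 depths x 6 targets x 2 replicates
        assert len(a.cp_measurements) == 5 * 3 * 6 * 2
        assert len(a.melt_curves) == 5 * 3 * 6

    def test_class_means_recovered(self):
        """Observed per-class mean Cp sits within 2 sd/sqrt(n) of the design."""
        ds = cq.simulate_survey(cq.SurveyDesignSpec(stations=61, seed=11))
        obs = ds.truth.groupby(["target", "depth_class"])["true_cp"].mean()
        # 4 standard errors per cell: 18 simultaneous comparisons
        for (target, depth), (mean, sd, _n) in cq.DEFAULT_SURVEY_CP.items():
            tol = 4.0 * sd / np.sqrt(61)
            assert obs[(target, depth)] == pytest.approx(mean, abs=tol), (
                target, depth)

    def test_noiseless_survey_reproduces_means_exactly(self):
        summary = {k: (m, 0.0, n) for k, (m, s, n) in
                   cq.DEFAULT_SURVEY_CP.items()}
        spec = cq.SurveyDesignSpec(stations=3, cp_summary=summary,
                                   replicate_sd=0.0, seed=0)
        ds = cq.simulate_survey(spec)
        for (target, depth), (mean, _s, _n) in summary.items():
            sub = ds.cp_measurements.query(
                "target == @target and depth_class == @depth")["cp"]
            np.testing.assert_allclose(sub, mean, atol=1e-6)

    def test_pure_synechococcus_surface_classifies_as_such(self):
        spec = cq.SurveyDesignSpec(
            stations=8, seed=5,
            syn_fraction={"3m": 1.0, "DCM": 0.0, "DCM+40": 0.0},
            mixed_fraction={"3m": 0.0, "DCM": 0.0, "DCM+40": 0.0},
        )
        ds = cq.simulate_survey(spec)
        calls = [
            cq.analyze_melt_curve(c).taxon_call
            for c in ds.melt_curves
            if c.target == "rbcL-LL" and c.sample_id.endswith("-3m")
        ]
        assert calls and all(c == "synechococcus" for c in calls)


class TestExposureGenerator:
    def test_unit_effects_no_noise_gives_fold_one(self):
        spec = cq.ExposureDesignSpec(
            fold_effects={"rbcL": 1.0, "psbA": 1.0},
            noise_sd=0.0, seed=0,
        )
        df = cq.simulate_exposure(spec)
        np.testing.assert_allclose(df["fold"], 1.0)

    def test_paired_recovery_of_true_effect(self):
        """With many replicates the paired estimator recovers the 0.82 ratio."""
        spec = cq.ExposureDesignSpec(replicates=50, seed=9)  # 400 pairs/gene
        df = cq.simulate_exposure(spec)
        sub = df[df["gene"] == "rbcL"]
        from cladeqpcr.stats import paired_ratio_test
        res = paired_ratio_test(sub["dcp_treatment"], sub["dcp_control"])
        # mean of per-pair folds estimates E[2^(log2 e + eps)] = e * E[2^eps]
        bias = 2.0 ** 0.0 * np.exp(0.5 * (spec.noise_sd * np.log(2)) ** 2)
        ci_half = 1.96 * res.sd_ratio / np.sqrt(res.n)
        assert abs(res.mean_ratio - 0.82 * bias) < ci_half

    def test_replicates_validated(self):
        with pytest.raises(ValidationError):
            cq.ExposureDesignSpec(replicates=1)
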