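"""Synthetic cohort generator, TRUST/ASL forward models and bundle I/O."""

import numpy as np
import pytest

from cmrkit import (
    CohortEffects,
    StudyConfig,
    fit_t2,
    generate_bundle,
    generate_cohort,
    global_cbf,
    quantify_cbf_map,
    run_pipeline,
    simulate_asl,
    simulate_trust,
    wm_correction_map,
)
from cmrkit.errors import ConfigurationError
from cmrkit.synth import load_bundle, make_phantom, save_bundle


class TestGenerateCohort:
    def test_same_seed_identical_manifest(self):
        a = generate_cohort(5, seed=42).records
        b = generate_cohort(5, seed=42).records
        assert a.equals(b)

    def test_zero_sds_pin_the_baseline_at_the_means(self):
        eff = CohortEffects(
            age_sd=0.0, cbf_sd=0.0, yv_sd=0.0, petco2_sd=0.0,
            dpetco2_co2air=(4.2, 0.0), dpetco2_carbogen=(4.5, 0.0),
            cvr_co2air=(1.7, 0.0), cvr_carbogen=(2.8, 0.0),
            dcmro2_co2air=(-13.4, 0.0), dcmro2_carbogen=(-2.0, 0.0),
            roomair2_cbf_shift=(-1.3, 0.0), roomair2_cmro2_jitter=0.0,
            petco2_roomair2_jitter=0.0,
            ya={c: (m, 0.0) for c, (m, _) in CohortEffects().ya.items()},
        )
        t = generate_cohort(1, seed=0, effects=eff).records.set_index("condition")
        assert t.loc["roomair1", "cbf_true"] == pytest.approx(54.9)
        assert t.loc["roomair1", "yv_true"] == pytest.approx(0.673)
        assert t.loc["roomair1", "p_et_co2"] == pytest.approx(45.0)
        assert t.loc["co2air", "p_et_co2"] == pytest.approx(49.2)
        assert t.loc["co2air", "dcmro2_true_pct"] == pytest.approx(-13.4)
        assert t.loc["co2air", "cmro2_true"] == pytest.approx(
            t.loc["roomair1", "cmro2_true"] * (1 - 0.134)
        )

    def test_sample_mean_matches_configured_effect_at_large_n(self):
        """Law of large numbers: the generated CO2-in-air CMRO2 change
        averages to the configured -13.4% within 0.5 pp."""
        t = generate_cohort(4000, seed=1).records
        d = t[t.condition == "co2air"]["dcmro2_true_pct"]
        assert abs(d.mean() - (-13.4)) < 0.5

    def test_sex_split_and_hct(self):
        t = generate_cohort(10, seed=2).records
        per_subj = t.groupby("subject_id").first()
        assert (per_subj.sex == "M").sum() == 7
        assert (per_subj.sex == "F").sum() == 3
        assert set(per_subj[per_subj.sex == "M"].hct) == {0.42}
        assert set(per_subj[per_subj.sex == "F"].hct) == {0.40}

    def test_truth_is_forward_consistent(self, config):
        """Recomputing CMRO2 from the manifest's (CBF, Yv, gases) matches the
        manifest's CMRO2: truth satisfies the content equations."""
        from cmrkit.pipeline import build_blood_gas, compute_cmro2, contents_from_blood_gas

        t = generate_cohort(3, seed=8).records
        for _, row in t.iterrows():
            bg = build_blood_gas(
                row.condition, row.p_et_co2, row.y_a, row.yv_true,
                row.hct, row.age, config,
            )
            cm = compute_cmro2(row.cbf_true, *contents_from_blood_gas(bg))
            assert cm == pytest.approx(row.cmro2_true, rel=1e-6)

    def test_invalid_n_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(0)


class TestSimulateTrust:
    def test_noiseless_signals_recover_t2_exactly(self, rng):
        from cmrkit import yv_to_t2

        s = simulate_trust(0.70, 0.42, rng, noise_sd=0.0)
        assert fit_t2(s).t2_blood == pytest.approx(yv_to_t2(0.70, 0.42), rel=1e-9)

    def test_ete0_signal_is_s0(self, rng):
        s = simulate_trust(0.70, 0.42, rng, noise_sd=0.0, s0=123.0)
        np.testing.assert_allclose(s.signals[0], 123.0)

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            simulate_trust(0.7, 0.42, rng, noise_sd=-1.0)


class TestSimulateAsl:
    def test_noiseless_gm_only_phantom_recovers_truth(self, params, rng):
        geom = make_phantom((16, 16, 9))
        geom.p_wm[:] = 0.0
        data = simulate_asl(60.0, geom, params, "roomair1", rng, 0.0, 0.0)
        cbf = quantify_cbf_map(data, params, "roomair1")
        sel = data.p_gm > 0
        np.testing.assert_allclose(cbf[sel], 60.0, rtol=1e-12)

    def test_wm_factor_needed_for_unbiased_global(self, params, rng):
        """Mixed phantom: global CBF is exact with the WM correction and
        underestimated without it."""
        geom = make_phantom((24, 24, 13))
        data = simulate_asl(55.0, geom, params, "roomair1", rng, 0.0, 0.0)
        cbf = quantify_cbf_map(data, params, "roomair1")
        wm = wm_correction_map(data, params, "roomair1")
        corrected = global_cbf(cbf, data, wm)
        uncorrected = global_cbf(cbf, data, 1.0)
        assert corrected == pytest.approx(55.0, rel=1e-9)
        assert uncorrected < 55.0 - 0.5

    def test_same_seed_identical_volumes(self, params, phantom):
        a = simulate_asl(55.0, phantom, params, "roomair1", np.random.default_rng(4))
        b = simulate_asl(55.0, phantom, params, "roomair1", np.random.default_rng(4))
        np.testing.assert_array_equal(a.delta_m, b.delta_m)
        np.testing.assert_array_equal(a.m0, b.m0)


class TestPhantom:
    def test_probability_and_inclusion_invariants(self, phantom):
        assert np.all(phantom.p_gm + phantom.p_wm <= 1.0)
        include = (~phantom.exclusion_mask) & ((phantom.p_gm + phantom.p_wm) > 0)
        assert include.any()
        # the exclusion territory contains both tissue-free CSF and tissue
        assert (phantom.exclusion_mask & (phantom.p_gm + phantom.p_wm > 0)).any()


class TestBundle:
    def test_all_generated_values_finite(self):
        b = generate_bundle(n=2, seed=6)
        for s in b.subjects:
            for cd in s.conditions.values():
                for series in cd.trust:
                    assert np.all(np.isfinite(series.signals))
                assert np.all(np.isfinite(cd.asl.delta_m))
                assert np.all(np.isfinite(cd.asl.m0))

    def test_repeat_structure_matches_acquisition(self):
        b = generate_bundle(n=1, seed=0)
        conds = b.subjects[0].conditions
        assert len(conds["roomair1"].trust) == 1
        assert len(conds["co2air"].trust) == 2
        assert len(conds["carbogen"].trust) == 2

    def test_save_load_round_trip(self, tmp_path):
        b = generate_bundle(n=2, seed=13)
        save_bundle(b, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        res_a = run_pipeline(b)
        res_b = run_pipeline(loaded)
        a = res_a.per_subject.set_index(["subject_id", "condition"])
        c = res_b.per_subject.set_index(["subject_id", "condition"])
        # volumes round-trip through float32 NIfTI, so compare loosely
        np.testing.assert_allclose(
            a["cmro2_umol_100g_min"], c["cmro2_umol_100g_min"], rtol=1e-4
        )
        np.testing.assert_allclose(a["yv_pct"], c["yv_pct"], rtol=1e-4)

    def test_noiseless_flag_disables_noise(self):
        b = generate_bundle(n=1, seed=0, noiseless=True)
        cd = b.subjects[0].conditions["roomair1"]
        sig = cd.trust[0].signals
        # all averages identical without noise
        assert np.allclose(sig, sig[:, :1])
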