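import numpy as np
import pandas as pd
import pytest

from cb1pipe import (BloodProfile, CohortSpec, KineticParams,
                     SCRSessionParams, gen_blood_dataset, gen_cohort,
                     gen_scr_session, gen_symptom_table, gen_tissue_tac)
from cb1pipe.behaviour import auc_trapezoid
from cb1pipe.kinetics import frame_average


class TestBloodDatasetGenerator:
    def test_constant_parent_fraction(self):
        prof = BloodProfile(parent_params=(1.0, 1.0, 1.0, 1.0))
        blood = gen_blood_dataset(prof)
        assert np.allclose(blood.discrete_parent_fraction, 1.0)

    def test_unit_ratio_plasma_equals_whole_blood(self):
        prof = BloodProfile(ratio_params=(1.0, 1.0, 1.0, 1.0))
        blood = gen_blood_dataset(prof)
        assert np.allclose(blood.discrete_plasma, blood.discrete_whole_blood)

    def test_determinism(self):
        b1 = gen_blood_dataset(seed=1, noise_cv=0.05)
        b2 = gen_blood_dataset(seed=1, noise_cv=0.05)
        assert np.array_equal(b1.continuous_whole_blood, b2.continuous_whole_blood)
        assert np.array_equal(b1.discrete_plasma, b2.discrete_plasma)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            BloodProfile(peak_amplitude=np.nan)
        with pytest.raises(ValueError):
            BloodProfile(peak_amplitude=-3.0)


class TestKineticParams:
    def test_one_tissue_vt(self):
        assert KineticParams(model="one-tissue", K1=0.2, k2=0.05).vt == 4.0

    def test_two_tissue_vt(self):
        p = KineticParams(model="two-tissue", K1=0.1, k2=0.05, k3=0.02, k4=0.01)
        assert p.vt == pytest.approx((0.1 / 0.05) * (1 + 2.0))

    def test_impulse_response_integrates_to_vt(self):
        p = KineticParams(model="two-tissue", K1=0.1, k2=0.05, k3=0.03, k4=0.007)
        total = sum(c / r for c, r in p.impulse_response_terms())
        assert total == pytest.approx(p.vt, rel=1e-12)

    def test_missing_k3_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(model="two-tissue", K1=0.1, k2=0.05)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(K1=0.1, k2=-0.01)


class TestTissueTacGenerator:
    def test_pure_blood_limit(self, input_fn, schedule, whole_blood):
        p = KineticParams(K1=1e-6, k2=1e-4, vb=1.0)
        tac = gen_tissue_tac(input_fn, p, schedule, whole_blood=whole_blood)
        t = np.arange(0.0, schedule.total_duration + 1.0)
        want = frame_average(t, whole_blood(t), schedule)
        assert np.allclose(tac.activity, want, rtol=1e-9)

    def test_seed_determinism(self, input_fn, schedule):
        p = KineticParams(K1=0.05, k2=0.01, vb=0.0)
        a = gen_tissue_tac(input_fn, p, schedule, noise_scale=0.2, seed=9)
        b = gen_tissue_tac(input_fn, p, schedule, noise_scale=0.2, seed=9)
        assert np.array_equal(a.activity, b.activity)

    def test_vb_without_blood_curve_rejected(self, input_fn, schedule):
        with pytest.raises(ValueError, match="whole-blood"):
            gen_tissue_tac(input_fn, KineticParams(K1=0.1, k2=0.02, vb=0.1),
                           schedule)


class TestScrGenerator:
    def test_zero_probability(self, stimulus_table):
        _, truth = gen_scr_session(stimulus_table,
                                   SCRSessionParams(response_prob=0.0), seed=0)
        assert len(truth) == 0

    def test_full_probability_event_count_and_window(self, stimulus_table):
        p = SCRSessionParams(response_prob=1.0, amp_floor=0.05, amp_mean=0.05,
                             amp_cv=0.0, fearful_amp_offset=0.0)
        _, truth = gen_scr_session(stimulus_table, p, seed=4)
        assert len(truth) == 60
        assert truth["onset_latency"].between(0.5, 3.0).all()
        assert (truth["amplitude"] >= 0.05).all()

    def test_fearful_amplitude_offset(self, stimulus_table):
        p = SCRSessionParams(response_prob=1.0, fearful_amp_offset=0.06,
                             amp_cv=0.1)
        _, truth = gen_scr_session(stimulus_table, p, seed=5)
        means = truth.groupby("valence")["amplitude"].mean()
        assert means["fearful"] > means["neutral"]

    def test_min_isi_enforced(self):
        stim = pd.DataFrame({"onset_s": [10.0, 12.0], "valence": ["neutral"] * 2})
        with pytest.raises(ValueError, match="ISI"):
            gen_scr_session(stim, SCRSessionParams(min_isi=4.0), seed=0)

    def test_trace_determinism(self, stimulus_table):
        p = SCRSessionParams(noise_sd=0.002)
        t1, _ = gen_scr_session(stimulus_table, p, seed=2)
        t2, _ = gen_scr_session(stimulus_table, p, seed=2)
        assert np.array_equal(t1.conductance, t2.conductance)


class TestCohortGenerator:
    def test_vt_respects_printed_range(self):
        spec = CohortSpec(n_subjects=500, seed=3)
        coh = gen_cohort(spec)
        assert coh["vt_right_amygdala"].between(7.51, 17.75).all()

    def test_zero_correlations_independent(self):
        spec = CohortSpec(n_subjects=10_000, anxiety_effect_corr=0.0,
                          ssq_effect_corr=0.0, seed=11)
        coh = gen_cohort(spec)
        r1 = np.corrcoef(coh["vt_right_amygdala"], coh["anxiety_delta"])[0, 1]
        r2 = np.corrcoef(coh["vt_right_amygdala"], coh["ssq_effect"])[0, 1]
        assert abs(r1) < 0.1 and abs(r2) < 0.1

    def test_minimal_cohort_and_seed_variation(self):
        spec = CohortSpec(n_subjects=3)
        a, b = gen_cohort(spec, seed=1), gen_cohort(spec, seed=2)
        assert len(a) == 3
        assert not np.allclose(a["vt_right_amygdala"], b["vt_right_amygdala"])

    def test_infeasible_correlation_pair(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            CohortSpec(anxiety_effect_corr=0.9, ssq_effect_corr=0.9,
                       anxiety_ssq_corr=-0.9)

    def test_invalid_spec_fields(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2)
        with pytest.raises(ValueError):
            CohortSpec(vt_sd=0.0)
        with pytest.raises(ValueError):
            CohortSpec(anxiety_effect_corr=1.5)


class TestSymptomTable:
    def test_placebo_change_is_zero(self):
        table = gen_symptom_table(CohortSpec(seed=1))
        plac = table[table["condition"] == "placebo"]
        for (_, scale), grp in plac.groupby(["subject", "scale"]):
            assert grp["value"].nunique() == 1

    def test_zero_effect_matches_placebo_auc(self):
        spec = CohortSpec(seed=2)
        table = gen_symptom_table(spec, effect_scale=0.0)
        stai = table[table["scale"] == "STAI-S"]
        aucs = {}
        for cond, grp in stai.groupby("condition"):
            wide = grp.pivot_table(index="subject", columns="time_h",
                                   values="value")
            aucs[cond] = np.array([auc_trapezoid(wide.columns, row)
                                   for row in wide.to_numpy()])
        assert np.allclose(aucs["drug"], aucs["placebo"])

    def test_stai_bounds(self):
        table = gen_symptom_table(CohortSpec(n_subjects=200, seed=3))
        stai = table[table["scale"] == "STAI-S"]["value"]
        assert stai.between(20, 80).all()

    def test_anxiety_correlation_recovered(self):
        """Monte-Carlo: the generated VT/anxiety-change correlation matches
        the requested population value (0.9) to within 0.03."""
        rs = []
        for rep in range(200):
            spec = CohortSpec(n_subjects=200, anxiety_effect_corr=0.9,
                              seed=20_000 + rep)
            coh = gen_cohort(spec)
            table = gen_symptom_table(spec, cohort=coh)
            stai = table[table["scale"] == "STAI-S"].pivot_table(
                index=["subject", "condition"], columns="time_h", values="value")
            drug = stai.xs("drug", level="condition").sort_index()
            plac = stai.xs("placebo", level="condition").sort_index()
            delta = (drug[1.0] + drug[2.0]) / 2 - (plac[1.0] + plac[2.0]) / 2
            vt = coh.set_index("subject")["vt_right_amygdala"].loc[delta.index]
            rs.append(np.corrcoef(vt, delta)[0, 1])
        assert abs(np.mean(rs) - 0.9) < 0.03
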