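"""Synthetic cohort generation: determinism, ground-truth fidelity, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronotox.cohort import (
    ArmEffect,
    ClockGroundTruth,
    CohortDesign,
    GeneRhythm,
    PROGroundTruth,
    StepsGroundTruth,
    generate_bimodal_phase_cohort,
    generate_cohort,
)
from chronotox.rhythm import circular_phase_difference, cosinor_fit
from conftest import cosinor_curve


def noiseless_truth(**arm_effects):
    return ClockGroundTruth(
        genes={"BMAL1": GeneRhythm(1.0, 0.4, 16.0, 0.0)},
        arm_effects=arm_effects,
        patient_acrophase_sd_h=0.0,
        patient_mesor_sd=0.0,
        patient_amplitude_rel_sd=0.0,
    )


def silent_pro():
    return PROGroundTruth(intercepts={}, couplings={}, residual_sd={})


class TestCohortDesign:
    def test_two_to_one_allocation(self):
        assert CohortDesign(n_patients=42).arm_counts == (28, 14)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_patients=1)
        with pytest.raises(ValueError):
            CohortDesign(sample_times_h=(9.0, 8.0))
        with pytest.raises(ValueError):
            CohortDesign(time_jitter_sd_h=-0.1)


class TestGenerateCohort:
    def test_noiseless_series_is_exactly_cosinor(self):
        design = CohortDesign(n_patients=4, seed=3, time_jitter_sd_h=0.25)
        bundle = generate_cohort(design, noiseless_truth(), silent_pro())
        tc = bundle.timecourse
        truth = pd.DataFrame(bundle.ground_truth["rhythm_parameters"])
        merged = tc.merge(truth, on=["patient_id", "arm", "stage", "gene"])
        expected = cosinor_curve(
            merged["time_h"].to_numpy(),
            merged["mesor"].to_numpy(),
            merged["amplitude"].to_numpy(),
            merged["acrophase_h"].to_numpy(),
        )
        assert np.allclose(merged["value"].to_numpy(), expected, atol=1e-12)
        # cosinor refit residual is numerically zero
        one = tc[(tc["patient_id"] == tc["patient_id"].iloc[0])
                 & (tc["stage"] == "baseline")]
        fit = cosinor_fit(one["time_h"].to_numpy(), one["value"].to_numpy())
        assert fit.resid_sd < 1e-10

    def test_seed_makes_output_byte_identical(self):
        design = CohortDesign(n_patients=6, seed=11)
        a = generate_cohort(design)
        b = generate_cohort(design)
        assert a.timecourse.to_csv() == b.timecourse.to_csv()
        assert a.pro.to_csv() == b.pro.to_csv()
        assert a.steps.to_csv() == b.steps.to_csv()

    def test_different_seed_changes_output(self):
        a = generate_cohort(CohortDesign(n_patients=6, seed=1))
        b = generate_cohort(CohortDesign(n_patients=6, seed=2))
        assert not a.timecourse["value"].equals(b.timecourse["value"])

    def test_arm_effect_applied_only_post_baseline_treated(self):
        truth = noiseless_truth(
            BMAL1=ArmEffect(delta_acrophase_h=-8.0, amplitude_scale=0.5)
        )
        design = CohortDesign(n_patients=6, seed=5, time_jitter_sd_h=0.0,
                              stages=("baseline", "W4"))
        bundle = generate_cohort(design, truth, silent_pro())
        gt = pd.DataFrame(bundle.ground_truth["rhythm_parameters"])
        base = gt[gt["stage"] == "baseline"]
        assert np.allclose(base["acrophase_h"], 16.0)
        w4 = gt[gt["stage"] == "W4"]
        treated = w4[w4["arm"] == "rucaparib"]
        placebo = w4[w4["arm"] == "placebo"]
        assert np.allclose(treated["acrophase_h"], 8.0)
        assert np.allclose(treated["amplitude"], 0.2)
        assert np.allclose(placebo["acrophase_h"], 16.0)
        assert np.allclose(placebo["amplitude"], 0.4)

    def test_null_arm_effect_leaves_arms_indistinguishable(self):
        """With all arm effects zero, arm labels carry no signal: KS tests on
        values across arms reject at roughly the nominal rate."""
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            design = CohortDesign(
                n_patients=8, seed=seed, stages=("baseline", "W4")
            )
            bundle = generate_cohort(
                design,
                ClockGroundTruth(
                    genes={"BMAL1": GeneRhythm(1.0, 0.4, 16.0, 0.1)},
                ),
                silent_pro(),
            )
            tc = bundle.timecourse
            a = tc.loc[tc["arm"] == "rucaparib", "value"]
            b = tc.loc[tc["arm"] == "placebo", "value"]
            if stats.ks_2samp(a, b).pvalue < 0.01:
                rejections += 1
        assert rejections / n_rep <= 0.1  # nominal 0.01 plus slack

    def test_pro_coupling_slope_converges_to_beta(self):
        """OLS of the generated outcome on its true clock covariate recovers
        the configured coupling within 5% at n = 2000 patients."""
        beta_true = 2.0
        pro = PROGroundTruth(
            intercepts={"nausea": 20.0},
            couplings={
                "nausea": {
                    "rucaparib": {"BMAL1_acrophase_h": beta_true},
                    "placebo": {"BMAL1_acrophase_h": beta_true},
                }
            },
            residual_sd={"nausea": 2.0},
        )
        truth = ClockGroundTruth(
            genes={"BMAL1": GeneRhythm(1.0, 0.4, 16.0, 0.0)},
            patient_acrophase_sd_h=2.0,
        )
        design = CohortDesign(n_patients=2000, seed=21, stages=("baseline",))
        bundle = generate_cohort(design, truth, pro)
        gt = pd.DataFrame(bundle.ground_truth["rhythm_parameters"])
        merged = bundle.pro.merge(
            gt[["patient_id", "acrophase_h"]], on="patient_id"
        )
        slope = stats.linregress(merged["acrophase_h"], merged["score"]).slope
        assert slope == pytest.approx(beta_true, rel=0.05)

    def test_steps_negatively_coupled_to_ae_score(self):
        pro = PROGroundTruth(
            intercepts={"nausea": 50.0, "fatigue": 50.0},
            couplings={},
            residual_sd={"nausea": 30.0, "fatigue": 30.0},
        )
        design = CohortDesign(n_patients=200, seed=8, stages=("baseline",))
        bundle = generate_cohort(
            design, noiseless_truth(), pro,
            steps_truth=StepsGroundTruth(slope_per_ae=400.0, sd=100.0),
        )
        ae = (
            bundle.pro[bundle.pro["outcome"].isin(["nausea", "fatigue"])]
            .groupby("patient_id")["score"].mean()
        )
        steps = bundle.steps.groupby("patient_id")["mean_steps"].mean()
        slope = stats.linregress(ae[steps.index], steps).slope
        assert slope == pytest.approx(-400.0 / 10.0, rel=0.15)

    def test_dropout_recorded_in_ground_truth(self):
        design = CohortDesign(n_patients=10, seed=2, dropout_prob=0.5)
        bundle = generate_cohort(design, noiseless_truth(), silent_pro())
        dropped = bundle.ground_truth["dropped_samples"]
        assert len(dropped) > 0
        tc = bundle.timecourse
        for rec in dropped:
            sub = tc[(tc["patient_id"] == rec["patient_id"])
                     & (tc["stage"] == rec["stage"])]
            assert sub.empty

    def test_write_creates_tables(self, tmp_path):
        bundle = generate_cohort(CohortDesign(n_patients=4, seed=1))
        bundle.write(tmp_path)
        for name in ("timecourse.csv", "pro.csv", "steps.csv",
                     "ground_truth.json"):
            assert (tmp_path / name).exists()


class TestBimodalCohort:
    def test_null_fraction_matches_placebo_distribution(self):
        design = CohortDesign(n_patients=60, seed=4, stages=("baseline",))
        bundle = generate_bimodal_phase_cohort(design, 0.0, 8.0)
        gt = pd.DataFrame(bundle.ground_truth["rhythm_parameters"])
        gt = gt[gt["gene"] == "BMAL1"]
        a = gt.loc[gt["arm"] == "rucaparib", "acrophase_h"]
        b = gt.loc[gt["arm"] == "placebo", "acrophase_h"]
        assert stats.ks_2samp(a, b).pvalue > 0.01
        assert bundle.ground_truth["advanced_subgroup"] == []

    def test_advanced_subgroup_ground_truth_phase(self):
        truth = noiseless_truth()
        design = CohortDesign(n_patients=10, seed=9, stages=("baseline",))
        bundle = generate_bimodal_phase_cohort(
            design, 0.4, 8.0, clock_truth=truth, pro_truth=silent_pro()
        )
        advanced = set(bundle.ground_truth["advanced_subgroup"])
        arms = bundle.ground_truth["arms"]
        n_treated = sum(1 for a in arms.values() if a == "rucaparib")
        assert len(advanced) == round(0.4 * n_treated)
        gt = pd.DataFrame(bundle.ground_truth["rhythm_parameters"])
        for _, row in gt.iterrows():
            expect = 8.0 if row["patient_id"] in advanced else 16.0
            assert circular_phase_difference(row["acrophase_h"], expect) < 1e-9

    def test_invalid_arguments_rejected(self):
        design = CohortDesign(n_patients=6, seed=0)
        with pytest.raises(ValueError):
            generate_bimodal_phase_cohort(design, 1.5, 8.0)
        with pytest.raises(ValueError):
            generate_bimodal_phase_cohort(design, 0.5, 24.0)

    def test_treated_arm_phase_histogram_becomes_bimodal(self):
        """With a 0.4 fraction advanced by 8 h the treated-arm acrophase
        histogram occupies both the advanced and baseline 4-h bins in nearly
        every replicate, while the placebo arm stays unimodal (two-bin
        occupancy statistic applied identically to both arms)."""
        both = placebo_both = 0
        n_rep = 30
        for seed in range(n_rep):
            design = CohortDesign(n_patients=15, seed=seed, stages=("baseline",))
            bundle = generate_bimodal_phase_cohort(design, 0.4, 8.0)
            fits = []
            for (pid, arm), grp in bundle.timecourse[
                bundle.timecourse["gene"] == "BMAL1"
            ].groupby(["patient_id", "arm"]):
                fit = cosinor_fit(grp["time_h"].to_numpy(),
                                  grp["value"].to_numpy())
                fits.append((arm, fit.acrophase_h))
            for arm_name, counter in (("rucaparib", "t"), ("placebo", "p")):
                phases = np.array([p for a, p in fits if a == arm_name])
                adv = np.sum((phases >= 4) & (phases < 12))
                base = np.sum((phases >= 12) & (phases < 20))
                hit = adv > 0 and base > 0
                if arm_name == "rucaparib":
                    both += hit
                else:
                    placebo_both += hit
        assert both / n_rep >= 0.9
        assert placebo_both < both
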