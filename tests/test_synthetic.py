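"""Generator invariants: pedigree conservation, marginals, risk model."""

import math

import numpy as np
import pandas as pd
import pytest

from limbertail import (
    CovariateConfig,
    ResponseConfig,
    RiskModelParams,
    TemplateConfig,
    generate_cohort,
    generate_pedigree,
    generate_questionnaires,
    pearson_correlation,
    reclassify_cohort,
    render_free_text_reports,
    simulate_case_status,
)


class TestPedigree:
    def test_offspring_counts_conserve_cohort_size(self):
        ped = generate_pedigree(250, 30, 40, concentration=0.5, seed=1)
        assert ped["dog_id"].is_unique
        assert ped.groupby("sire_id").size().sum() == 250
        assert ped.groupby("dam_id").size().sum() == 250

    def test_single_parent_degenerate_allocation(self):
        ped = generate_pedigree(100, 1, 1, seed=2)
        assert ped["sire_id"].nunique() == 1 and ped["dam_id"].nunique() == 1

    def test_large_concentration_approaches_uniform(self):
        ped = generate_pedigree(1000, 10, 10, concentration=1e9, seed=3)
        counts = ped.groupby("sire_id").size()
        # multinomial with equal weights: mean 100, sd ~ 9.5
        assert counts.sub(100).abs().max() < 40

    def test_small_concentration_skews_contributions(self):
        ped = generate_pedigree(1000, 50, 50, concentration=0.1, seed=4)
        counts = np.sort(ped.groupby("sire_id").size().to_numpy())[::-1]
        assert counts[0] > 1000 / 50 * 3  # a popular sire dominates

    def test_determinism_byte_identical(self):
        a = generate_pedigree(120, 15, 20, seed=9).to_csv(index=False)
        b = generate_pedigree(120, 15, 20, seed=9).to_csv(index=False)
        assert a == b

    def test_invalid_arguments(self):
        for bad in [(0, 1, 1), (5, 0, 1), (3, 4, 1)]:
            with pytest.raises(ValueError):
                generate_pedigree(*bad, seed=0)
        with pytest.raises(ValueError):
            generate_pedigree(5, 2, 2, concentration=0.0, seed=0)


class TestCohort:
    def test_configured_swim_prevalence(self):
        ped = generate_pedigree(10_000, 500, 600, seed=5)
        cohort = generate_cohort(ped, CovariateConfig(p_swim=0.85), seed=6)
        se = math.sqrt(0.85 * 0.15 / 10_000)
        assert abs(cohort["swims"].mean() - 0.85) < 3 * se

    def test_default_swim_prevalence_matches_control_rate(self):
        ped = generate_pedigree(8000, 400, 500, seed=7)
        cohort = generate_cohort(ped, seed=8)
        target = 68 / 86
        se = math.sqrt(target * (1 - target) / 8000)
        assert abs(cohort["swims"].mean() - target) < 3 * se

    def test_point_mass_purpose(self):
        ped = generate_pedigree(200, 20, 20, seed=9)
        cfg = CovariateConfig(purpose_probs=(0.0, 1.0, 0.0, 0.0))
        cohort = generate_cohort(ped, cfg, seed=10)
        assert (cohort["purpose"] == "working").all()

    def test_latitude_within_uk_range(self):
        ped = generate_pedigree(2000, 100, 100, seed=11)
        cohort = generate_cohort(ped, seed=12)
        assert cohort["latitude"].between(49, 61).all()

    def test_bad_config_rejected(self):
        ped = generate_pedigree(10, 2, 2, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(ped, CovariateConfig(p_swim=1.4), seed=0)
        with pytest.raises(ValueError):
            generate_cohort(ped.iloc[:0], seed=0)


class TestRiskModel:
    def test_constant_risk_limit(self):
        ped = generate_pedigree(20_000, 1000, 1000, seed=13)
        cohort = generate_cohort(ped, seed=14)
        p0 = 0.1
        params = RiskModelParams(
            intercept=math.log(p0 / (1 - p0)), beta_swim=0.0, beta_work=0.0,
            beta_lat=0.0, sire_sd=0.0,
        )
        sim = simulate_case_status(cohort, params, seed=15)
        se = math.sqrt(p0 * (1 - p0) / 20_000)
        assert abs(sim.affected.mean() - p0) < 3 * se

    def test_swimming_effect_recovered_as_sample_or(self):
        ped = generate_pedigree(50_000, 2500, 2500, seed=16)
        cohort = generate_cohort(ped, seed=17)
        params = RiskModelParams(
            intercept=-2.5, beta_swim=math.log(4.7), beta_work=0.0,
            beta_lat=0.0, sire_sd=0.0,
        )
        sim = simulate_case_status(cohort, params, seed=18)
        a = int((sim.affected & cohort.set_index("dog_id")["swims"]).sum())
        b = int((sim.affected & ~cohort.set_index("dog_id")["swims"]).sum())
        c = int((~sim.affected & cohort.set_index("dog_id")["swims"]).sum())
        d = int((~sim.affected & ~cohort.set_index("dog_id")["swims"]).sum())
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or - math.log(4.7)) < 3 * se

    def test_latent_sire_effects_returned(self):
        ped = generate_pedigree(300, 30, 30, seed=19)
        cohort = generate_cohort(ped, seed=20)
        sim = simulate_case_status(cohort, RiskModelParams(sire_sd=1.0), seed=21)
        assert set(sim.sire_effects.index) == set(cohort["sire_id"])
        assert sim.linear_predictor.index.equals(pd.Index(cohort["dog_id"]))

    def test_sire_sd_zero_gives_zero_effects(self):
        ped = generate_pedigree(100, 10, 10, seed=22)
        cohort = generate_cohort(ped, seed=23)
        sim = simulate_case_status(cohort, RiskModelParams(sire_sd=0.0), seed=24)
        assert (sim.sire_effects == 0).all()


@pytest.fixture(scope="module")
def cohort_and_status():
    ped = generate_pedigree(500, 50, 60, seed=25)
    cohort = generate_cohort(ped, seed=26)
    sim = simulate_case_status(cohort, seed=27)
    return cohort, sim.affected


class TestFreeText:
    def test_every_affected_dog_reports(self, cohort_and_status):
        cohort, affected = cohort_and_status
        reports = render_free_text_reports(cohort, affected, seed=28)
        tail_reports = reports[reports["template_class"] != "distractor"]
        assert set(tail_reports["dog_id"]) == set(affected[affected].index)

    def test_no_affected_and_no_distractors_is_empty(self, cohort_and_status):
        cohort, affected = cohort_and_status
        none = affected & False
        reports = render_free_text_reports(cohort, none, distractor_rate=0.0, seed=29)
        assert reports.empty

    def test_distractor_rate_controls_noise(self, cohort_and_status):
        cohort, affected = cohort_and_status
        none = affected & False
        reports = render_free_text_reports(cohort, none, distractor_rate=1.0, seed=30)
        assert len(reports) == len(cohort)
        assert (reports["template_class"] == "distractor").all()

    def test_empty_template_class_rejected(self, cohort_and_status):
        cohort, affected = cohort_and_status
        with pytest.raises(ValueError, match="empty"):
            render_free_text_reports(
                cohort, affected,
                template_config=TemplateConfig(keyword_templates=()), seed=31,
            )


class TestQuestionnaires:
    def test_forced_anal_gland_profile_classifies_as_control(self):
        ped = generate_pedigree(50, 5, 5, seed=32)
        cohort = generate_cohort(ped, seed=33)
        unaffected = pd.Series(False, index=pd.Index(cohort["dog_id"]))
        cfg = ResponseConfig(control_sign_rate=1.0, control_anal_gland_share=1.0)
        quest = generate_questionnaires(cohort, unaffected, cfg, seed=34)
        table, summary = reclassify_cohort(
            quest, {d: "control" for d in quest["dog_id"]}
        )
        assert (table["final"] == "control").all()
        assert (table["reason"] == "attributed_other_cause").all()

    def test_certain_reporting_recovers_truth_exactly(self):
        ped = generate_pedigree(400, 40, 50, seed=35)
        cohort = generate_cohort(ped, seed=36)
        sim = simulate_case_status(cohort, seed=37)
        cfg = ResponseConfig(p_limp_end=1.0, misattribution_rate=0.0,
                             control_sign_rate=0.0)
        quest = generate_questionnaires(cohort, sim.affected, cfg, seed=38)
        prov = {
            d: ("case" if sim.affected.loc[d] else "control")
            for d in quest["dog_id"]
        }
        table, _ = reclassify_cohort(quest, prov)
        predicted = table.set_index("dog_id")["final"] == "case"
        assert predicted.equals(sim.affected.reindex(predicted.index))

    def test_configured_pain_qol_correlation(self):
        ped = generate_pedigree(10_000, 500, 500, seed=39)
        cohort = generate_cohort(ped, seed=40)
        all_affected = pd.Series(True, index=pd.Index(cohort["dog_id"]))
        quest = generate_questionnaires(cohort, all_affected, seed=41)
        r = pearson_correlation(quest["pain_score"], quest["qol_score"])
        target = 0.72
        se = (1 - target**2) / math.sqrt(len(quest))
        assert abs(r - target) < 3 * se

    def test_duration_categories_follow_configured_mix(self):
        ped = generate_pedigree(3000, 150, 150, seed=42)
        cohort = generate_cohort(ped, seed=43)
        all_affected = pd.Series(True, index=pd.Index(cohort["dog_id"]))
        quest = generate_questionnaires(cohort, all_affected, seed=44)
        freq = quest["duration_category"].value_counts(normalize=True)
        cfg = ResponseConfig()
        for cat, p in zip(cfg.duration_categories, cfg.duration_probs):
            assert abs(freq.get(cat, 0.0) - p) < 4 * math.sqrt(p * (1 - p) / 3000)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ResponseConfig(misattribution_rate=1.2).validate()
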