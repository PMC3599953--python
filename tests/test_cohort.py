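"""Synthetic cohort generator: determinism, marginals, calibration."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from caseflag.adjudicate import AdjudicationPolicy, classify_self_report
from caseflag.cohort import (Cohort, ConfigError, FlagProcess, GeneratorConfig,
                             SelfReportParams, calibrate_to_row, generate,
                             generate_combination)
from caseflag.flags import proxy_windows
from caseflag.metrics import confusion, metrics
from caseflag.report import adjudicate_expression_on_cohort, adjudicate_flag_on_cohort


def test_invalid_configs_fail_before_sampling():
    with pytest.raises(ConfigError):
        GeneratorConfig(prevalence=1.5).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(n_participants=0).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(comparison_period=(dt.date(2004, 1, 1),
                                           dt.date(2005, 12, 31))).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(flags={"diagnosis": FlagProcess(1.2, 0.0)}).validate()


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = GeneratorConfig(n_participants=500, seed=11)
    (tmp_path / "a").mkdir(); (tmp_path / "b").mkdir()
    generate(cfg).write(tmp_path / "a")
    generate(cfg).write(tmp_path / "b")
    for name in Cohort.FILES:
        assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
            (tmp_path / "b" / f"{name}.csv").read_bytes()


def test_different_seeds_differ():
    a = generate(GeneratorConfig(n_participants=500, seed=1))
    b = generate(GeneratorConfig(n_participants=500, seed=2))
    assert not a.registry.equals(b.registry)


def test_case_fraction_within_three_binomial_sds():
    n, p = 10_000, 0.014
    cohort = generate(GeneratorConfig(n_participants=n, prevalence=p, seed=1,
                                      flags={}, self_report=None))
    n_cases = cohort.registry["participant_id"].nunique()
    sd = np.sqrt(n * p * (1 - p))
    assert abs(n_cases - n * p) <= 3 * sd  # ~140 expected


def test_zero_prevalence_gives_empty_registry_and_only_false_positives():
    cfg = GeneratorConfig(n_participants=2_000, prevalence=0.0, seed=4,
                          flags={"diagnosis": FlagProcess(0.9, 0.02)},
                          self_report=SelfReportParams(report_prob_noncase=0.01,
                                                       misdated_case_share=0.0))
    cohort = generate(cfg)
    assert cohort.registry.empty
    adj = adjudicate_flag_on_cohort(cohort, "diagnosis", AdjudicationPolicy())
    assert adj["flagged"].sum() > 0
    assert not adj["true_positive"].any()


def test_perfect_flag_limit_recovers_unit_metrics():
    cfg = GeneratorConfig(
        n_participants=3_000, prevalence=0.05, seed=9,
        flags={"diagnosis": FlagProcess(1.0, 0.0, delay_days=(0, 0)),
               "lumpectomy": FlagProcess(1.0, 0.0, delay_days=(0, 0))},
        self_report=SelfReportParams(report_prob_case=1.0, report_prob_noncase=0.0,
                                     misdated_case_share=0.0))
    cohort = generate(cfg)
    policy = AdjudicationPolicy()
    for flag in ("diagnosis", "lumpectomy"):
        m = metrics(confusion(adjudicate_flag_on_cohort(cohort, flag, policy)))
        assert (m.ppv, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
    m = metrics(confusion(adjudicate_expression_on_cohort(
        cohort, "lumpectomy AND diagnosis", policy)))
    assert (m.ppv, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
    sr = metrics(confusion(classify_self_report(
        proxy_windows(cohort.survey), cohort.registry, policy)))
    assert sr.ppv == 1.0 and sr.sensitivity == 1.0 and sr.specificity == 1.0


@pytest.mark.parametrize("mode", ["quota", "bernoulli"])
def test_marginal_event_rates_recovered(mode):
    cfg = GeneratorConfig(
        n_participants=8_000, prevalence=0.1, seed=13,
        calibration_mode=(mode == "quota"),
        flags={"radiotherapy": FlagProcess(0.6, 0.05, delay_days=(0, 300))},
        self_report=None)
    cohort = generate(cfg)
    cases = set(cohort.registry["participant_id"])
    flagged = set(cohort.mbs["participant_id"])
    n_cases = len(cases)
    n_non = cfg.n_participants - n_cases
    rate_case = len(flagged & cases) / n_cases
    rate_non = len(flagged - cases) / n_non
    tol_case = 3 * np.sqrt(0.6 * 0.4 / n_cases) if mode == "bernoulli" else 1 / n_cases
    tol_non = 3 * np.sqrt(0.05 * 0.95 / n_non) if mode == "bernoulli" else 1 / n_non
    assert abs(rate_case - 0.6) <= tol_case
    assert abs(rate_non - 0.05) <= tol_non


def test_survey_invariants():
    cohort = generate(GeneratorConfig(n_participants=4_000, seed=5))
    survey = cohort.survey
    assert survey["age_months"].between(0, 11).all()
    reported = survey["reported_breast_cancer"].eq("yes")
    assert survey.loc[reported, "reported_age_at_diagnosis"].notna().all()
    assert survey.loc[~reported, "reported_age_at_diagnosis"].isna().all()
    assert (survey.loc[reported, "reported_age_at_diagnosis"]
            <= survey.loc[reported, "age_years"]).all()
    assert survey["age_years"].ge(45).all()


def test_registry_one_record_per_participant():
    cohort = generate(GeneratorConfig(n_participants=6_000, seed=5))
    assert not cohort.registry["participant_id"].duplicated().any()
    dates = pd.to_datetime(cohort.registry["diagnosis_date"])
    assert dates.between("2004-07-01", "2008-12-31").all()


def test_cohort_round_trips_through_csv(tmp_path):
    cohort = generate(GeneratorConfig(n_participants=300, seed=21))
    cohort.write(tmp_path)
    reloaded = Cohort.read(tmp_path)
    assert len(reloaded.participants) == 300
    assert reloaded.survey["reported_age_at_diagnosis"].dtype == "Int64"
    assert set(reloaded.hospital.columns) == set(cohort.hospital.columns)


# --- calibration algebra --------------------------------------------------

def test_calibrate_to_row_closed_forms():
    assert calibrate_to_row(1.0, 1.0, 0.5) == (1.0, 0.0)
    cr, ncr = calibrate_to_row(0.5, 0.8, 0.2)
    assert cr == pytest.approx(0.8)
    assert ncr == pytest.approx(0.2)  # 0.2*0.8*0.5 / (0.5*0.8)
    with pytest.raises(ConfigError, match="infeasible"):
        calibrate_to_row(0.01, 1.0, 0.9)


def test_calibrate_to_row_monte_carlo_confirmation():
    """Bernoulli simulation at n=10^6 recovers the targeted PPV and
    sensitivity from the calibrated rates."""
    rng = np.random.default_rng(123)
    n, prev, ppv, se = 1_000_000, 0.1, 0.6, 0.75
    cr, ncr = calibrate_to_row(ppv, se, prev)
    is_case = rng.random(n) < prev
    flagged = np.where(is_case, rng.random(n) < cr, rng.random(n) < ncr)
    tp = (flagged & is_case).sum()
    assert tp / flagged.sum() == pytest.approx(ppv, abs=0.005)
    assert tp / is_case.sum() == pytest.approx(se, abs=0.005)


def test_combination_generator_satisfies_expression_for_signal_cases():
    cfg = GeneratorConfig(n_participants=5_000, prevalence=0.05, seed=2,
                          flags={}, self_report=None)
    expr = "(lumpectomy OR mastectomy) AND diagnosis"
    cohort = generate_combination(cfg, expr, target_ppv=0.8, target_sensitivity=0.7)
    adj = adjudicate_expression_on_cohort(cohort, expr, AdjudicationPolicy())
    m = metrics(confusion(adj))
    assert m.ppv == pytest.approx(0.8, abs=0.02)
    assert m.sensitivity == pytest.approx(0.7, abs=0.02)
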