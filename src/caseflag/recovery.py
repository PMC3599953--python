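"""Parameter-recovery runs: calibrate the generator to a published validity
row, run the full extract -> adjudicate -> metrics pipeline, and return what
it measures.

The published tables come from confidential linked data, so they cannot be
recomputed from raw records; what *can* be verified is that the pipeline
recovers known operating characteristics from data constructed to have
them.  Every function here therefore (1) draws a cohort, (2) calibrates
event rates to the target row using the realized case prevalence, and
(3) measures PPV / sensitivity / specificity through the same code path a
real analysis would use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .adjudicate import AdjudicationPolicy, classify_self_report, misreport_audit
from .cohort import (CALIBRATION_DELAYS, Cohort, FlagProcess, GeneratorConfig,
                     SelfReportParams, calibrate_to_row, generate,
                     generate_combination)
from .flags import proxy_windows
from .metrics import ConfusionCounts, ValidityMetrics, confusion, metrics
from .report import adjudicate_expression_on_cohort, adjudicate_flag_on_cohort


@dataclass(frozen=True)
class RecoveryResult:
    expression: str
    counts: ConfusionCounts
    metrics: ValidityMetrics
    cohort_size: int


def _population_config(n: int, prevalence: float, seed: int) -> GeneratorConfig:
    return GeneratorConfig(n_participants=n, prevalence=prevalence, seed=seed,
                           flags={}, self_report=None)


def _realized_case_count(cohort: Cohort) -> int:
    return cohort.registry["participant_id"].nunique()


def recover_single_flag(flag_name: str, target_ppv: float, target_sensitivity: float,
                        n: int = 50_000, prevalence: float = 0.014, seed: int = 0,
                        policy: Optional[AdjudicationPolicy] = None) -> RecoveryResult:
    """Calibrate one dated flag to a published row and measure it back."""
    base = _population_config(n, prevalence, seed)
    prev_hat = _realized_case_count(generate(base)) / n
    cr, ncr = calibrate_to_row(target_ppv, target_sensitivity, prev_hat)
    cfg = replace(base, flags={flag_name: FlagProcess(
        cr, ncr, CALIBRATION_DELAYS.get(flag_name, (0, 60)))})
    cohort = generate(cfg)
    policy = policy or AdjudicationPolicy()
    adj = adjudicate_flag_on_cohort(cohort, flag_name, policy)
    counts = confusion(adj)
    return RecoveryResult(flag_name, counts, metrics(counts), n)


def recover_expression(expression: str, target_ppv: float, target_sensitivity: float,
                       n: int = 50_000, prevalence: float = 0.014, seed: int = 0,
                       policy: Optional[AdjudicationPolicy] = None) -> RecoveryResult:
    """Calibrate a flag combination as a compound process and measure it back."""
    cfg = _population_config(n, prevalence, seed)
    cohort = generate_combination(cfg, expression, target_ppv, target_sensitivity)
    policy = policy or AdjudicationPolicy()
    adj = adjudicate_expression_on_cohort(cohort, expression, policy)
    counts = confusion(adj)
    return RecoveryResult(expression, counts, metrics(counts), n)


def _self_report_config(target_ppv: float, target_sensitivity: float, n: int,
                        prevalence: float, seed: int,
                        misdated_case_share: float) -> GeneratorConfig:
    base = _population_config(n, prevalence, seed)
    cohort0 = generate(base)
    policy = AdjudicationPolicy()
    dx = pd.to_datetime(cohort0.registry["diagnosis_date"])
    lo = pd.Timestamp(policy.comparison_period[0])
    hi = pd.Timestamp(policy.comparison_period[1])
    n_period_cases = cohort0.registry.loc[(dx >= lo) & (dx <= hi),
                                          "participant_id"].nunique()
    prev_period_hat = n_period_cases / n
    cr, ncr = calibrate_to_row(target_ppv, target_sensitivity, prev_period_hat)
    return replace(base, self_report=SelfReportParams(
        report_prob_case=cr, report_prob_noncase=ncr,
        misdated_case_share=misdated_case_share))


def recover_self_report(target_ppv: float, target_sensitivity: float,
                        n: int = 50_000, prevalence: float = 0.014, seed: int = 0,
                        misdated_case_share: float = 0.69) -> RecoveryResult:
    """Calibrate the self-report process against comparison-period cases."""
    cfg = _self_report_config(target_ppv, target_sensitivity, n, prevalence,
                              seed, misdated_case_share)
    cohort = generate(cfg)
    adj = classify_self_report(proxy_windows(cohort.survey), cohort.registry,
                               AdjudicationPolicy())
    counts = confusion(adj)
    return RecoveryResult("self_report", counts, metrics(counts), n)


def recover_misreport_audit(misdated_case_share: float = 0.69,
                            target_ppv: float = 0.498,
                            target_sensitivity: float = 0.847,
                            n: int = 50_000, prevalence: float = 0.014,
                            seed: int = 0):
    """Run the misreported-age audit on a cohort with a known misdated share."""
    cfg = _self_report_config(target_ppv, target_sensitivity, n, prevalence,
                              seed, misdated_case_share)
    cohort = generate(cfg)
    policy = AdjudicationPolicy()
    adj = classify_self_report(proxy_windows(cohort.survey), cohort.registry, policy)
    return misreport_audit(adj, cohort.registry, policy)
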