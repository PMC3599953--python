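"""Synthetic linked-cohort generator.

Emulates the five linked datasets the validation analysis consumes — cancer
registry, hospital separations, outpatient service claims, prescription
dispensings and a baseline survey — for a cohort of women aged 45 and over,
with the statistical structure the analysis assumes: ~1.4% of participants
are registry cases of invasive breast cancer during the study period, each
ascertainment flag fires with a configurable rate among cases (dated at the
diagnosis date plus a treatment delay) and among non-cases (dated
uniformly), and self-report behaviour includes age-at-diagnosis
misreporting that places genuine cases outside the comparison period.

Two sampling regimes exist.  With ``calibration_mode`` on (the default),
flag events are assigned by fixed-count (quota) sampling, so the realized
per-group event rates equal the configured rates up to integer rounding and
a cohort calibrated to a published validity row — with the default delay
ranges, which lie inside the adjudication windows — reproduces that row's
PPV and sensitivity by construction.  With it off, every draw is Bernoulli;
combined with delay ranges exceeding the windows this is the regime for
follow-up-period sensitivity analyses.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._months import format_ym, month_index_of
from .adjudicate import COMPARISON_PERIOD, STUDY_PERIOD
from .catalog import load_catalog
from .expressions import parse_expression, satisfying_leaves
from .tables import INDIVIDUAL_DATASET_ROWS

RECRUITMENT_WINDOW = (dt.date(2006, 1, 1), dt.date(2009, 4, 30))

#: delay (days after registry diagnosis) support per flag in calibration
#: mode; chosen inside each flag's adjudication window
CALIBRATION_DELAYS = {
    "diagnosis": (0, 60),
    "lumpectomy": (0, 60),
    "mastectomy": (0, 60),
    "radiotherapy": (0, 300),
    "medicines": (0, 300),
}

#: neutral principal-diagnosis code carried on surgery-only admissions
_SURGERY_PRINCIPAL = "N63"


class ConfigError(ValueError):
    pass


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class FlagProcess:
    """Event process for one dated flag."""

    case_rate: float
    noncase_rate: float
    delay_days: tuple[int, int] = (0, 60)

    def validate(self, name: str) -> None:
        _check_prob(self.case_rate, f"{name}.case_rate")
        _check_prob(self.noncase_rate, f"{name}.noncase_rate")
        lo, hi = self.delay_days
        if lo > hi:
            raise ConfigError(f"{name}.delay_days not ordered: {self.delay_days}")


@dataclass(frozen=True)
class SelfReportParams:
    """Self-report behaviour.

    ``report_prob_case`` applies to comparison-period registry cases, who
    report their true age at diagnosis; ``report_prob_noncase`` applies to
    everyone else, who report an age placing the proxy window inside the
    comparison period.  ``misdated_case_share`` is the fraction of those
    false reporters who are genuine registry cases with a diagnosis outside
    the comparison period (age misreported, history real).
    ``age_misreport_prob`` optionally perturbs true reporters' stated age by
    an offset drawn from ``misreport_offset_years``.
    """

    report_prob_case: float = 0.847
    report_prob_noncase: float = 0.004
    misdated_case_share: float = 0.69
    age_misreport_prob: float = 0.0
    misreport_offset_years: tuple[int, ...] = (-2, -1, 1, 2)

    def validate(self) -> None:
        _check_prob(self.report_prob_case, "self_report.report_prob_case")
        _check_prob(self.report_prob_noncase, "self_report.report_prob_noncase")
        _check_prob(self.misdated_case_share, "self_report.misdated_case_share")
        _check_prob(self.age_misreport_prob, "self_report.age_misreport_prob")
        if not self.misreport_offset_years:
            raise ConfigError("misreport_offset_years must be non-empty")


def calibrate_to_row(target_ppv: float, target_sensitivity: float,
                     prevalence: float, n: Optional[int] = None,
                     ) -> tuple[float, float]:
    """Event rates that reproduce a published row's PPV and sensitivity.

    With delays inside the adjudication window every flagged case is a true
    positive, so sensitivity equals the case event rate and PPV follows from
    the case/non-case flagged mix::

        case_rate    = sensitivity
        noncase_rate = prevalence * sensitivity * (1 - PPV)
                       / (PPV * (1 - prevalence))

    Raises when the combination is infeasible (non-case rate above 1).
    """
    if not 0.0 < target_ppv <= 1.0:
        raise ConfigError(f"target_ppv must be in (0, 1], got {target_ppv}")
    if not 0.0 < target_sensitivity <= 1.0:
        raise ConfigError(f"target_sensitivity must be in (0, 1], got {target_sensitivity}")
    if not 0.0 < prevalence < 1.0:
        raise ConfigError(f"prevalence must be in (0, 1), got {prevalence}")
    case_rate = target_sensitivity
    noncase_rate = (prevalence * target_sensitivity * (1.0 - target_ppv)
                    / (target_ppv * (1.0 - prevalence)))
    if noncase_rate > 1.0:
        raise ConfigError(
            f"infeasible target: implied non-case rate {noncase_rate:.3f} exceeds 1 "
            f"(ppv={target_ppv}, sensitivity={target_sensitivity}, prevalence={prevalence})")
    return case_rate, noncase_rate


def _period_fraction(study: tuple[dt.date, dt.date],
                     comparison: tuple[dt.date, dt.date]) -> float:
    study_days = (study[1] - study[0]).days + 1
    comp_days = (comparison[1] - comparison[0]).days + 1
    return comp_days / study_days


def default_flag_processes(prevalence: float = 0.014) -> dict[str, FlagProcess]:
    """Per-flag processes calibrated to the published single-flag rows."""
    out: dict[str, FlagProcess] = {}
    for row in INDIVIDUAL_DATASET_ROWS:
        if row.expression in CALIBRATION_DELAYS:
            cr, ncr = calibrate_to_row(row.ppv, row.sensitivity, prevalence)
            out[row.expression] = FlagProcess(cr, ncr, CALIBRATION_DELAYS[row.expression])
    return out


def default_self_report_params(prevalence: float = 0.014,
                               study: tuple[dt.date, dt.date] = STUDY_PERIOD,
                               comparison: tuple[dt.date, dt.date] = COMPARISON_PERIOD,
                               ) -> SelfReportParams:
    row = next(r for r in INDIVIDUAL_DATASET_ROWS if r.expression == "self_report")
    prev_period = prevalence * _period_fraction(study, comparison)
    cr, ncr = calibrate_to_row(row.ppv, row.sensitivity, prev_period)
    return SelfReportParams(report_prob_case=cr, report_prob_noncase=ncr)


@dataclass(frozen=True)
class GeneratorConfig:
    """All simulation parameters; deterministic given ``seed``."""

    n_participants: int = 10_000
    prevalence: float = 0.014
    study_period: tuple[dt.date, dt.date] = STUDY_PERIOD
    comparison_period: tuple[dt.date, dt.date] = COMPARISON_PERIOD
    recruitment_window: tuple[dt.date, dt.date] = RECRUITMENT_WINDOW
    age_range: tuple[int, int] = (45, 84)
    flags: Mapping[str, FlagProcess] = field(default_factory=default_flag_processes)
    self_report: Optional[SelfReportParams] = field(default_factory=default_self_report_params)
    calibration_mode: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError(f"n_participants must be >= 1, got {self.n_participants}")
        _check_prob(self.prevalence, "prevalence")
        for name, (lo, hi) in (("study_period", self.study_period),
                               ("comparison_period", self.comparison_period),
                               ("recruitment_window", self.recruitment_window)):
            if lo > hi:
                raise ConfigError(f"{name} is not well-ordered: {lo}..{hi}")
        if not (self.study_period[0] <= self.comparison_period[0]
                and self.comparison_period[1] <= self.study_period[1]):
            raise ConfigError("comparison_period must lie inside study_period")
        if self.age_range[0] < 45:
            raise ConfigError("cohort members are aged 45 and over at recruitment")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError(f"age_range not ordered: {self.age_range}")
        for name, proc in self.flags.items():
            proc.validate(name)
        if self.self_report is not None:
            self.self_report.validate()


@dataclass
class Cohort:
    """The five generated datasets (participants table carries the survey ages)."""

    participants: pd.DataFrame
    registry: pd.DataFrame
    hospital: pd.DataFrame
    mbs: pd.DataFrame
    pbs: pd.DataFrame
    survey: pd.DataFrame

    FILES = ("participants", "registry", "hospital", "mbs", "pbs", "survey")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.FILES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       date_format="%Y-%m-%d")

    @classmethod
    def read(cls, in_dir: str | Path) -> "Cohort":
        in_dir = Path(in_dir)
        frames = {}
        for name in cls.FILES:
            path = in_dir / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing cohort file: {path}")
            frames[name] = pd.read_csv(path)
        if "reported_age_at_diagnosis" in frames["survey"]:
            frames["survey"]["reported_age_at_diagnosis"] = \
                frames["survey"]["reported_age_at_diagnosis"].astype("Int64")
        if "procedure_codes" in frames["hospital"]:
            frames["hospital"]["procedure_codes"] = \
                frames["hospital"]["procedure_codes"].fillna("")
        return cls(**frames)


# --- internals -------------------------------------------------------------

def _rng(seed: int, label: str) -> np.random.Generator:
    # stable per-label substream: adding a dataset never perturbs the others
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(label.encode()))))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _uniform_dates(rng: np.random.Generator, lo: dt.date, hi: dt.date,
                   size: int) -> np.ndarray:
    span = (hi - lo).days + 1
    offsets = rng.integers(0, span, size=size)
    base = np.datetime64(lo.isoformat(), "D")
    return base + offsets.astype("timedelta64[D]")


def _select(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    if k > len(pool):
        raise ConfigError(f"quota {k} exceeds pool size {len(pool)}")
    if k == 0:
        return pool[:0]
    return rng.choice(pool, size=k, replace=False)


@dataclass
class _Population:
    ids: np.ndarray
    birth_idx: np.ndarray          # month index of birth
    recruitment: np.ndarray        # datetime64[D]
    age_years: np.ndarray
    age_months: np.ndarray
    is_case: np.ndarray            # bool
    dx_date: np.ndarray            # datetime64[D], NaT for non-cases
    site_code: np.ndarray          # object, "" for non-cases


def _draw_population(config: GeneratorConfig) -> _Population:
    n = config.n_participants
    rng_p = _rng(config.seed, "participants")
    recruitment = _uniform_dates(rng_p, *config.recruitment_window, n)
    age_years = rng_p.integers(config.age_range[0], config.age_range[1] + 1, n)
    age_months = rng_p.integers(0, 12, n)
    rec_idx = np.array([month_index_of(d) for d in recruitment.astype(dt.date)])
    birth_idx = rec_idx - (age_years * 12 + age_months)

    rng_r = _rng(config.seed, "registry")
    is_case = rng_r.random(n) < config.prevalence
    n_cases = int(is_case.sum())
    dx = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    site = np.full(n, "", dtype=object)
    if n_cases:
        dx[is_case] = _uniform_dates(rng_r, *config.study_period, n_cases)
        catalog = load_catalog()
        sites = sorted(catalog.codes("registry_diagnosis"))
        site[is_case] = rng_r.choice(sites, size=n_cases)
    return _Population(np.arange(1, n + 1, dtype="int64"), birth_idx, recruitment,
                       age_years, age_months, is_case, dx, site)


def _flag_members(rng: np.random.Generator, pop: _Population, rate_case: float,
                  rate_noncase: float, quota: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of case and non-case participants that fire the process."""
    case_idx = np.flatnonzero(pop.is_case)
    non_idx = np.flatnonzero(~pop.is_case)
    if quota:
        sel_case = _select(rng, case_idx, _round_half_up(rate_case * len(case_idx)))
        sel_non = _select(rng, non_idx, _round_half_up(rate_noncase * len(non_idx)))
    else:
        sel_case = case_idx[rng.random(len(case_idx)) < rate_case]
        sel_non = non_idx[rng.random(len(non_idx)) < rate_noncase]
    return np.sort(sel_case), np.sort(sel_non)


def _event_dates(rng: np.random.Generator, pop: _Population, sel_case: np.ndarray,
                 sel_non: np.ndarray, delay_days: tuple[int, int],
                 study: tuple[dt.date, dt.date]) -> tuple[np.ndarray, np.ndarray]:
    delays = rng.integers(delay_days[0], delay_days[1] + 1, size=len(sel_case))
    case_dates = pop.dx_date[sel_case] + delays.astype("timedelta64[D]")
    end = np.datetime64(study[1].isoformat(), "D")
    start = np.datetime64(study[0].isoformat(), "D")
    case_dates = np.minimum(np.maximum(case_dates, start), end)
    non_dates = _uniform_dates(rng, *study, len(sel_non))
    return case_dates, non_dates


def generate(config: GeneratorConfig) -> Cohort:
    """Generate the five linked datasets for one synthetic cohort."""
    config.validate()
    pop = _draw_population(config)
    catalog = load_catalog()

    hospital_rows: list[pd.DataFrame] = []
    mbs_rows: list[pd.DataFrame] = []
    pbs_rows: list[pd.DataFrame] = []

    for name in sorted(config.flags):
        proc = config.flags[name]
        if name not in catalog:
            raise ConfigError(f"flag process references unknown flag {name!r}")
        rng = _rng(config.seed, f"flag:{name}")
        delay = proc.delay_days
        sel_case, sel_non = _flag_members(rng, pop, proc.case_rate, proc.noncase_rate,
                                          quota=config.calibration_mode)
        d_case, d_non = _event_dates(rng, pop, sel_case, sel_non, delay,
                                     config.study_period)
        idx = np.concatenate([sel_case, sel_non])
        dates = np.concatenate([d_case, d_non])
        frame = _events_to_rows(name, catalog, rng, pop, idx, dates,
                                n_case_events=len(sel_case))
        dataset = catalog.dataset(name)
        if dataset in ("hospital_dx", "hospital_proc"):
            hospital_rows.append(frame)
        elif dataset == "service_claim":
            mbs_rows.append(frame)
        else:
            pbs_rows.append(frame)

    registry_extra: list[tuple[int, np.datetime64, str]] = []
    survey = _generate_survey(config, pop, registry_extra)

    cohort = _assemble(config, pop, hospital_rows, mbs_rows, pbs_rows, survey,
                       registry_extra)
    return cohort


def _events_to_rows(name: str, catalog, rng: np.random.Generator, pop: _Population,
                    idx: np.ndarray, dates: np.ndarray, n_case_events: int,
                    ) -> pd.DataFrame:
    dataset = catalog.dataset(name)
    pids = pop.ids[idx]
    if dataset == "hospital_dx":
        codes = sorted(catalog.codes(name))
        principal = np.array(rng.choice(codes, size=len(idx)), dtype=object)
        # flagged cases carry their registry site code as principal diagnosis
        principal[:n_case_events] = pop.site_code[idx[:n_case_events]]
        return pd.DataFrame({"participant_id": pids,
                             "admission_date": dates,
                             "principal_diagnosis_code": principal,
                             "procedure_codes": ""})
    if dataset == "hospital_proc":
        codes = sorted(catalog.codes(name))
        procs = rng.choice(codes, size=len(idx))
        return pd.DataFrame({"participant_id": pids,
                             "admission_date": dates,
                             "principal_diagnosis_code": _SURGERY_PRINCIPAL,
                             "procedure_codes": procs})
    codes = sorted(catalog.codes(name))
    items = rng.choice(codes, size=len(idx))
    if dataset == "service_claim":
        return pd.DataFrame({"participant_id": pids, "service_date": dates,
                             "item_code": items})
    return pd.DataFrame({"participant_id": pids, "supply_date": dates,
                         "item_code": items})


def _generate_survey(config: GeneratorConfig, pop: _Population,
                     registry_extra: list[tuple[int, np.datetime64, str]],
                     ) -> pd.DataFrame:
    n = config.n_participants
    reported = np.zeros(n, dtype=bool)
    reported_age = np.full(n, -1, dtype="int64")

    params = config.self_report
    if params is not None:
        rng = _rng(config.seed, "survey")
        comp_lo = np.datetime64(config.comparison_period[0].isoformat(), "D")
        comp_hi = np.datetime64(config.comparison_period[1].isoformat(), "D")
        in_period = pop.is_case & (pop.dx_date >= comp_lo) & (pop.dx_date <= comp_hi)
        period_idx = np.flatnonzero(in_period)
        pool_idx = np.flatnonzero(~in_period)

        if config.calibration_mode:
            true_rep = _select(rng, period_idx,
                               _round_half_up(params.report_prob_case * len(period_idx)))
        else:
            true_rep = period_idx[rng.random(len(period_idx)) < params.report_prob_case]
        dx_month = np.array([month_index_of(d) for d in pop.dx_date[true_rep].astype(dt.date)],
                            dtype="int64") if len(true_rep) else np.empty(0, dtype="int64")
        age_at_dx = (dx_month - pop.birth_idx[true_rep]) // 12
        if params.age_misreport_prob > 0 and len(true_rep):
            perturb = rng.random(len(true_rep)) < params.age_misreport_prob
            offsets = rng.choice(np.array(params.misreport_offset_years), size=len(true_rep))
            age_at_dx = np.where(perturb,
                                 np.clip(age_at_dx + offsets, 0, pop.age_years[true_rep]),
                                 age_at_dx)
        reported[true_rep] = True
        reported_age[true_rep] = age_at_dx

        false_rep = _draw_false_reporters(config, pop, rng, pool_idx, registry_extra)
        if len(false_rep):
            comp_start = month_index_of(config.comparison_period[0])
            comp_end = month_index_of(config.comparison_period[1])
            target = rng.integers(comp_start, comp_end + 1, size=len(false_rep))
            reported[false_rep] = True
            reported_age[false_rep] = (target - pop.birth_idx[false_rep]) // 12

    return pd.DataFrame({
        "participant_id": pop.ids,
        "completion_date": pop.recruitment,
        "age_years": pop.age_years,
        "age_months": pop.age_months,
        "reported_breast_cancer": np.where(reported, "yes", "no"),
        "reported_age_at_diagnosis": np.where(reported, reported_age, 0),
    })


def _draw_false_reporters(config: GeneratorConfig, pop: _Population,
                          rng: np.random.Generator, pool_idx: np.ndarray,
                          registry_extra: list[tuple[int, np.datetime64, str]],
                          ) -> np.ndarray:
    """False reporters: window overlaps the comparison period but no
    comparison-period registry record.  A configured share are genuine cases
    of another period; missing out-of-period records are minted for them."""
    params = config.self_report
    assert params is not None
    if config.calibration_mode:
        k_false = _round_half_up(params.report_prob_noncase * len(pool_idx))
        n_mis = _round_half_up(params.misdated_case_share * k_false)
        oop_cases = pool_idx[pop.is_case[pool_idx]]
        pure = pool_idx[~pop.is_case[pool_idx]]
        mis_existing = _select(rng, oop_cases, min(n_mis, len(oop_cases)))
        mis_new = _select(rng, pure, n_mis - len(mis_existing))
        remaining = np.setdiff1d(pure, mis_new, assume_unique=True)
        plain = _select(rng, remaining, k_false - n_mis)
        false_rep = np.concatenate([mis_existing, mis_new, plain])
    else:
        false_rep = pool_idx[rng.random(len(pool_idx)) < params.report_prob_noncase]
        mis = false_rep[rng.random(len(false_rep)) < params.misdated_case_share]
        mis_new = mis[~pop.is_case[mis]]

    _mint_out_of_period_records(config, pop, rng, mis_new, registry_extra)
    return np.sort(false_rep)


def _mint_out_of_period_records(config: GeneratorConfig, pop: _Population,
                                rng: np.random.Generator, rows: np.ndarray,
                                registry_extra: list[tuple[int, np.datetime64, str]],
                                ) -> None:
    if not len(rows):
        return
    # out-of-comparison-period segments inside the registry extract
    segments: list[tuple[dt.date, dt.date]] = []
    if config.study_period[0] < config.comparison_period[0]:
        segments.append((config.study_period[0],
                         config.comparison_period[0] - dt.timedelta(days=1)))
    if config.comparison_period[1] < config.study_period[1]:
        segments.append((config.comparison_period[1] + dt.timedelta(days=1),
                         config.study_period[1]))
    if not segments:
        raise ConfigError(
            "misdated_case_share > 0 requires the comparison period to be a "
            "strict sub-interval of the study period")
    lengths = np.array([(hi - lo).days + 1 for lo, hi in segments], dtype=float)
    which = rng.choice(len(segments), size=len(rows), p=lengths / lengths.sum())
    catalog = load_catalog()
    sites = sorted(catalog.codes("registry_diagnosis"))
    for row, seg in zip(rows, which):
        lo, hi = segments[seg]
        date = _uniform_dates(rng, lo, hi, 1)[0]
        registry_extra.append((int(pop.ids[row]), date, str(rng.choice(sites))))


def _assemble(config: GeneratorConfig, pop: _Population,
              hospital_rows: list[pd.DataFrame], mbs_rows: list[pd.DataFrame],
              pbs_rows: list[pd.DataFrame], survey: pd.DataFrame,
              registry_extra: list[tuple[int, np.datetime64, str]]) -> Cohort:
    participants = pd.DataFrame({
        "participant_id": pop.ids,
        "birth_month": [format_ym(b) for b in pop.birth_idx],
        "recruitment_date": pop.recruitment,
        "age_years": pop.age_years,
        "age_months": pop.age_months,
    })

    case_rows = np.flatnonzero(pop.is_case)
    registry = pd.DataFrame({
        "participant_id": pop.ids[case_rows],
        "diagnosis_date": pop.dx_date[case_rows],
        "site_code": pop.site_code[case_rows],
        "behaviour": "invasive",
    })
    if registry_extra:
        extra = pd.DataFrame(registry_extra,
                             columns=["participant_id", "diagnosis_date", "site_code"])
        extra["behaviour"] = "invasive"
        registry = pd.concat([registry, extra], ignore_index=True)
    registry = registry.sort_values(["participant_id", "diagnosis_date"],
                                    kind="stable").reset_index(drop=True)

    def cat(frames: list[pd.DataFrame], columns: list[str], date_col: str) -> pd.DataFrame:
        if not frames:
            return pd.DataFrame({c: pd.Series(dtype=("int64" if c == "participant_id"
                                                     else "datetime64[s]" if c == date_col
                                                     else object)) for c in columns})
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["participant_id", date_col],
                               kind="stable").reset_index(drop=True)

    hospital = cat(hospital_rows,
                   ["participant_id", "admission_date", "principal_diagnosis_code",
                    "procedure_codes"], "admission_date")
    mbs = cat(mbs_rows, ["participant_id", "service_date", "item_code"], "service_date")
    pbs = cat(pbs_rows, ["participant_id", "supply_date", "item_code"], "supply_date")

    # blank out the not-applicable reported age for non-reporters
    survey = survey.copy()
    survey["reported_age_at_diagnosis"] = pd.array(
        np.where(survey["reported_breast_cancer"].eq("yes"),
                 survey["reported_age_at_diagnosis"], pd.NA), dtype="Int64")
    return Cohort(participants=participants, registry=registry, hospital=hospital,
                  mbs=mbs, pbs=pbs, survey=survey)


def generate_combination(config: GeneratorConfig, expression: str,
                         target_ppv: float, target_sensitivity: float) -> Cohort:
    """Generate a cohort whose *combined* flag process is calibrated to a
    published combination row.

    The combination is simulated as one compound event process: signal
    participants receive events for a minimal satisfying leaf assignment of
    the expression (all children of an AND, the first child of an OR), with
    case events placed inside each leaf's adjudication window.  The realized
    case prevalence is used for the calibration so the recovered PPV does
    not depend on the binomial draw of case counts.
    """
    config.validate()
    base = replace(config, flags={}, self_report=None)
    pop = _draw_population(base)
    n_cases = int(pop.is_case.sum())
    if n_cases in (0, config.n_participants):
        raise ConfigError("combination calibration needs both cases and non-cases")
    prev_hat = n_cases / config.n_participants
    cr, ncr = calibrate_to_row(target_ppv, target_sensitivity, prev_hat)

    expr = parse_expression(expression)
    leaf_set = sorted(satisfying_leaves(expr))
    catalog = load_catalog()
    for leaf in leaf_set:
        if leaf == "self_report":
            raise ConfigError("compound calibration supports dated-flag leaves only")
        if leaf not in catalog:
            raise ConfigError(f"unknown flag in expression: {leaf!r}")

    rng = _rng(config.seed, f"combination:{expression.lower()}")
    sel_case, sel_non = _flag_members(rng, pop, cr, ncr, quota=config.calibration_mode)

    hospital_rows, mbs_rows, pbs_rows = [], [], []
    non_dates = _uniform_dates(rng, *config.study_period, len(sel_non))
    for leaf in leaf_set:
        delay = CALIBRATION_DELAYS.get(leaf, (0, 60))
        d_case, _ = _event_dates(rng, pop, sel_case, sel_non[:0], delay,
                                 config.study_period)
        idx = np.concatenate([sel_case, sel_non])
        dates = np.concatenate([d_case, non_dates])
        frame = _events_to_rows(leaf, catalog, rng, pop, idx, dates,
                                n_case_events=len(sel_case))
        dataset = catalog.dataset(leaf)
        if dataset in ("hospital_dx", "hospital_proc"):
            hospital_rows.append(frame)
        elif dataset == "service_claim":
            mbs_rows.append(frame)
        else:
            pbs_rows.append(frame)

    survey = _generate_survey(base, pop, [])
    return _assemble(config, pop, hospital_rows, mbs_rows, pbs_rows, survey, [])
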