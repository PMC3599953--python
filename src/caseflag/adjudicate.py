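"""Adjudication of flags against the cancer-registry gold standard.

A participant is a *case* if she has a registry record of invasive breast
cancer inside the study period (July 2004 - December 2008).  A dated flag
event is a *true positive* only when it falls within that flag's
adjudication window of the registry diagnosis date: 3 calendar months for
hospital diagnosis and surgeries, 12 calendar months for radiotherapy and
medicine claims.  Self-reported diagnosis is compared only against registry
cases of the comparison period (July 2004 - December 2005), the interval
over which all participants had uniformly had the chance to report, using
the proxy diagnosis-year overlap rule.

Windows are symmetric by default (a hospital admission may precede the
registry diagnosis date); forward-only matching is available as a policy
switch.  "Months" are calendar months with end-of-month clamping, so the
rules are reproducible without day-count conventions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd
from dateutil.relativedelta import relativedelta

from ._months import MonthInterval, month_index_of
from .expressions import FlagExpression, evaluate_expression, leaves

STUDY_PERIOD = (dt.date(2004, 7, 1), dt.date(2008, 12, 31))
COMPARISON_PERIOD = (dt.date(2004, 7, 1), dt.date(2005, 12, 31))

#: adjudication window, in calendar months, per flag
DEFAULT_WINDOW_MONTHS = {
    "diagnosis": 3,
    "lumpectomy": 3,
    "mastectomy": 3,
    "radiotherapy": 12,
    "medicines": 12,
}


class AdjudicationError(ValueError):
    pass


@dataclass(frozen=True)
class AdjudicationPolicy:
    """Time-window and period rules for adjudication."""

    window_months: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_WINDOW_MONTHS))
    window_direction: str = "symmetric"  # or "forward"
    study_period: tuple[dt.date, dt.date] = STUDY_PERIOD
    comparison_period: tuple[dt.date, dt.date] = COMPARISON_PERIOD

    def __post_init__(self) -> None:
        if self.window_direction not in ("symmetric", "forward"):
            raise AdjudicationError(
                f"window_direction must be 'symmetric' or 'forward', got {self.window_direction!r}")
        for name, months in self.window_months.items():
            if months <= 0:
                raise AdjudicationError(f"window for {name!r} must be positive, got {months}")
        if self.study_period[0] > self.study_period[1]:
            raise AdjudicationError("study_period is not well-ordered")
        if not (self.study_period[0] <= self.comparison_period[0]
                and self.comparison_period[1] <= self.study_period[1]):
            raise AdjudicationError("comparison_period must lie inside study_period")

    def window_for(self, flag_name: str) -> int:
        try:
            return self.window_months[flag_name]
        except KeyError:
            raise AdjudicationError(f"no adjudication window configured for flag {flag_name!r}") from None

    def with_window(self, flag_name: str, months: int) -> "AdjudicationPolicy":
        windows = dict(self.window_months)
        windows[flag_name] = months
        return replace(self, window_months=windows)

    @property
    def comparison_months(self) -> MonthInterval:
        return MonthInterval.from_dates(*self.comparison_period)


def shift_months(date: dt.date, months: int) -> dt.date:
    """Shift by calendar months, clamping to the end of short months."""
    return date + relativedelta(months=months)


def _as_dates(series: pd.Series) -> pd.Series:
    if not pd.api.types.is_datetime64_any_dtype(series):
        series = pd.to_datetime(series, format="ISO8601")
    return series


def registry_anchor_dates(registry: pd.DataFrame,
                          period: tuple[dt.date, dt.date]) -> pd.Series:
    """Earliest registry diagnosis date inside the period, per case."""
    if registry.empty:
        return pd.Series(dtype="datetime64[ns]", name="diagnosis_date")
    dates = _as_dates(registry["diagnosis_date"])
    lo, hi = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    in_period = registry.loc[(dates >= lo) & (dates <= hi)].assign(diagnosis_date=dates)
    return in_period.groupby("participant_id")["diagnosis_date"].min()


def adjudicate_dated_flag(events: pd.DataFrame, registry: pd.DataFrame,
                          policy: AdjudicationPolicy, flag_name: str,
                          participant_ids: Iterable[int]) -> pd.DataFrame:
    """Classify every participant for one dated flag.

    Returns a DataFrame with one row per participant: ``participant_id``,
    ``flagged`` (has >= 1 event), ``is_case`` (registry record in the study
    period), ``true_positive`` (flagged case with >= 1 event inside the
    flag's window of the earliest registry diagnosis date).
    """
    ids = pd.Index(pd.unique(pd.Series(list(participant_ids), dtype="int64")),
                   name="participant_id")
    window = policy.window_for(flag_name)

    if not events.empty:
        unknown = ~events["participant_id"].isin(ids)
        if unknown.any():
            bad = events.loc[unknown, "participant_id"].iloc[0]
            raise AdjudicationError(
                f"event references unknown participant {bad} (linkage violation)")

    anchors = registry_anchor_dates(registry, policy.study_period)
    flagged = ids.isin(events["participant_id"]) if not events.empty else pd.Series(False, index=ids).values
    is_case = ids.isin(anchors.index)

    tp_ids: set[int] = set()
    if not events.empty and len(anchors):
        ev = events.copy()
        ev["event_date"] = _as_dates(ev["event_date"])
        ev = ev.merge(anchors.rename("anchor"), left_on="participant_id", right_index=True)
        if not ev.empty:
            bounds = {
                pid: (shift_months(anchor.date(), -window) if policy.window_direction == "symmetric"
                      else anchor.date(),
                      shift_months(anchor.date(), window))
                for pid, anchor in anchors.items()
            }
            lower = ev["participant_id"].map(lambda p: pd.Timestamp(bounds[p][0]))
            upper = ev["participant_id"].map(lambda p: pd.Timestamp(bounds[p][1]))
            within = (ev["event_date"] >= lower) & (ev["event_date"] <= upper)
            tp_ids = set(ev.loc[within, "participant_id"].unique())

    out = pd.DataFrame({
        "participant_id": ids,
        "flagged": pd.Series(flagged, index=ids).values,
        "is_case": pd.Series(is_case, index=ids).values,
    })
    out["true_positive"] = out["flagged"] & out["is_case"] & out["participant_id"].isin(tp_ids)
    return out.reset_index(drop=True)


def classify_self_report(windows: pd.DataFrame, registry: pd.DataFrame,
                         policy: AdjudicationPolicy) -> pd.DataFrame:
    """Classify self-reported diagnosis against comparison-period cases.

    ``windows`` is the output of :func:`caseflag.flags.proxy_windows`.
    A participant is *flagged* when she reported a diagnosis and her proxy
    diagnosis year overlaps the comparison period; she is a *case* when a
    registry diagnosis date falls inside the comparison period.  True
    positive = flagged and case; the false-negative arm therefore covers
    both non-reporters and reporters whose window misses the period.
    """
    comp = policy.comparison_months
    start = windows["window_start"]
    overlap = windows["reported"] & start.notna() & \
        (start <= comp.end) & (windows["window_end"] >= comp.start)
    anchors = registry_anchor_dates(registry, policy.comparison_period)
    is_case = windows["participant_id"].isin(anchors.index)
    flagged = overlap.fillna(False).astype(bool)
    return pd.DataFrame({
        "participant_id": windows["participant_id"].astype("int64"),
        "flagged": flagged,
        "is_case": is_case,
        "true_positive": flagged & is_case,
    })


def adjudicate_expression(expr: FlagExpression,
                          per_flag_adjudications: Mapping[str, pd.DataFrame],
                          registry: pd.DataFrame,
                          policy: AdjudicationPolicy) -> pd.DataFrame:
    """Adjudicate a boolean combination of flags.

    ``flagged`` applies the expression to each participant's per-flag
    presence indicators; ``true_positive`` requires the participant to be a
    study-period case *and* the expression to hold over per-flag
    window-consistent (individually true-positive) indicators.  A
    self-report leaf contributes its proxy-window classification.
    """
    needed = leaves(expr)
    missing = needed - set(per_flag_adjudications)
    if missing:
        raise AdjudicationError(f"missing adjudication for leaves: {sorted(missing)}")

    frames = {}
    base_ids: Optional[pd.Series] = None
    for name in sorted(needed):
        adj = per_flag_adjudications[name].sort_values("participant_id").reset_index(drop=True)
        if base_ids is None:
            base_ids = adj["participant_id"]
        elif not base_ids.equals(adj["participant_id"]):
            raise AdjudicationError("per-flag adjudications cover different participants")
        frames[name] = adj
    assert base_ids is not None

    anchors = registry_anchor_dates(registry, policy.study_period)
    is_case = base_ids.isin(anchors.index)

    flagged_ind = {name: frames[name]["flagged"].to_numpy() for name in frames}
    tp_ind = {name: frames[name]["true_positive"].to_numpy() for name in frames}

    n = len(base_ids)
    flagged = pd.Series([
        evaluate_expression(expr, {name: flagged_ind[name][i] for name in frames})
        for i in range(n)
    ])
    window_ok = pd.Series([
        evaluate_expression(expr, {name: tp_ind[name][i] for name in frames})
        for i in range(n)
    ])
    return pd.DataFrame({
        "participant_id": base_ids.astype("int64"),
        "flagged": flagged,
        "is_case": is_case.to_numpy(),
        "true_positive": flagged & is_case.to_numpy() & window_ok,
    })


@dataclass(frozen=True)
class MisreportAudit:
    """Outcome of the misreported-age audit among self-report false positives."""

    n_false_positives: int
    n_with_out_of_period_record: int
    proportion: Optional[float]  # None when there are no false positives


def misreport_audit(self_report_adjudications: pd.DataFrame,
                    registry_all_records: pd.DataFrame,
                    policy: AdjudicationPolicy) -> MisreportAudit:
    """Among self-report false positives, the share who are genuine registry
    cases of an earlier or later period (i.e. misreported their age at
    diagnosis, not their history)."""
    adj = self_report_adjudications
    fp_ids = adj.loc[adj["flagged"] & ~adj["is_case"], "participant_id"]
    n_fp = len(fp_ids)
    if n_fp == 0:
        return MisreportAudit(0, 0, None)
    if registry_all_records.empty:
        return MisreportAudit(n_fp, 0, 0.0)
    dates = _as_dates(registry_all_records["diagnosis_date"])
    lo, hi = pd.Timestamp(policy.comparison_period[0]), pd.Timestamp(policy.comparison_period[1])
    outside = registry_all_records.loc[(dates < lo) | (dates > hi), "participant_id"]
    n_misdated = int(fp_ids.isin(set(outside)).sum())
    return MisreportAudit(n_fp, n_misdated, n_misdated / n_fp)
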