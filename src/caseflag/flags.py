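"""Flag extraction: turn dataset rows into per-participant flag events.

Dated flags (hospital diagnosis, surgeries, radiotherapy claims, medicine
dispensings) become ``FlagEvent`` rows with an event date.  The self-report
flag has no date: the survey captures current age in years and months and a
whole-years age at diagnosis, from which a 12-calendar-month proxy
"diagnosis year" window is derived.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._months import MonthInterval, month_index_of
from .catalog import CodeCatalog, code_matches

#: expected date column per source dataset
DATE_COLUMN = {
    "registry": "diagnosis_date",
    "hospital_dx": "admission_date",
    "hospital_proc": "admission_date",
    "service_claim": "service_date",
    "prescription_claim": "supply_date",
}


@dataclass(frozen=True)
class FlagEvent:
    """A dated suspected-case signal for one participant from one dataset."""

    participant_id: int
    flag_name: str
    dataset: str
    event_date: dt.date


class ExtractionError(ValueError):
    pass


def _parse_dates(series: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = bad.idxmax()
        raise ExtractionError(
            f"unparseable {column} at row {row}: {series.loc[row]!r}"
        )
    if parsed.isna().any():
        row = parsed.isna().idxmax()
        raise ExtractionError(f"missing {column} at row {row}")
    return parsed


def extract_dated_flags(dataset: pd.DataFrame, catalog: CodeCatalog,
                        flag_name: str) -> pd.DataFrame:
    """Extract events for one dated flag from its source dataset.

    The hospital diagnosis flag matches the principal diagnosis code only;
    procedure flags match any entry of the procedure-code list; claim flags
    match the item code.  Duplicate (participant, date) events are collapsed.

    Returns a DataFrame with columns ``participant_id``, ``flag_name``,
    ``dataset``, ``event_date`` (datetime64).
    """
    entry = catalog[flag_name]
    date_col = DATE_COLUMN[entry.dataset]
    empty = pd.DataFrame({"participant_id": pd.Series(dtype="int64"),
                          "flag_name": pd.Series(dtype=object),
                          "dataset": pd.Series(dtype=object),
                          "event_date": pd.Series(dtype="datetime64[ns]")})
    if dataset.empty:
        return empty

    if entry.dataset in ("hospital_dx", "registry"):
        code_col = "principal_diagnosis_code" if entry.dataset == "hospital_dx" else "site_code"
        mask = dataset[code_col].map(lambda c: code_matches(c, flag_name, catalog))
    elif entry.dataset == "hospital_proc":
        def any_proc(codes) -> bool:
            if codes is None or (isinstance(codes, float) and pd.isna(codes)):
                return False
            if isinstance(codes, str):
                codes = [c for c in codes.split(";") if c.strip()]
            return any(code_matches(c, flag_name, catalog) for c in codes)

        mask = dataset["procedure_codes"].map(any_proc)
    else:
        mask = dataset["item_code"].map(lambda c: code_matches(c, flag_name, catalog))

    hits = dataset.loc[mask, ["participant_id", date_col]]
    if hits.empty:
        return empty
    out = pd.DataFrame({
        "participant_id": hits["participant_id"].astype("int64"),
        "flag_name": flag_name,
        "dataset": entry.dataset,
        "event_date": _parse_dates(hits[date_col], date_col),
    })
    out = out.drop_duplicates(["participant_id", "event_date"]).reset_index(drop=True)
    return out


def compute_proxy_diagnosis_window(completion_date: dt.date, age_years: int,
                                   age_months: int,
                                   reported_breast_cancer: bool,
                                   reported_age_at_diagnosis: Optional[int],
                                   ) -> Optional[MonthInterval]:
    """The 12-calendar-month window in which the respondent was the age she
    reported being at diagnosis.

    Month arithmetic ignores day-of-month: the birth month is the survey
    completion month minus the stated age in months; the window opens at the
    calendar month of the reported-age birthday and spans 12 months.
    Example: recruited August 2008 aged 72 years 4 months, diagnosis
    reported at age 68 -> April 2004 .. March 2005.

    Returns ``None`` when no diagnosis (or no age at diagnosis) was reported.
    """
    if not reported_breast_cancer:
        return None
    if reported_age_at_diagnosis is None or pd.isna(reported_age_at_diagnosis):
        return None
    if not 0 <= age_months <= 11:
        raise ValueError(f"age_months out of range: {age_months}")
    reported = int(reported_age_at_diagnosis)
    if reported > age_years:
        raise ValueError(
            f"reported age at diagnosis ({reported}) exceeds current age ({age_years})"
        )
    birth_month = month_index_of(completion_date) - (int(age_years) * 12 + int(age_months))
    start = birth_month + reported * 12
    return MonthInterval(start, start + 11)


def proxy_windows(survey: pd.DataFrame) -> pd.DataFrame:
    """Vectorised proxy windows for a survey table.

    Returns one row per participant with nullable ``window_start`` /
    ``window_end`` month indices (Int64; NA when nothing was reported).
    """
    completion = _parse_dates(survey["completion_date"], "completion_date")
    comp_idx = completion.dt.year * 12 + (completion.dt.month - 1)
    reported = survey["reported_breast_cancer"].map(_as_bool)
    age_years = survey["age_years"].astype("int64")
    age_months = survey["age_months"].astype("int64")
    if ((age_months < 0) | (age_months > 11)).any():
        raise ValueError("age_months out of range 0..11")
    dx_age = pd.to_numeric(survey["reported_age_at_diagnosis"], errors="coerce")
    has_window = reported & dx_age.notna()
    if (has_window & (dx_age > age_years)).any():
        raise ValueError("reported age at diagnosis exceeds current age")
    birth = comp_idx - (age_years * 12 + age_months)
    start = (birth + dx_age * 12).where(has_window).astype("Int64")
    return pd.DataFrame({
        "participant_id": survey["participant_id"].astype("int64"),
        "reported": reported,
        "window_start": start,
        "window_end": start + 11,
    })


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("yes", "true", "1", "y")
    return bool(value)
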