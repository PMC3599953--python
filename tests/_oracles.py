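"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's vectorised code paths and its
dateutil-based month arithmetic: month shifts are done with
``calendar.monthrange``, windows by explicit per-triple enumeration, and
proxy windows with pandas Period arithmetic.
"""

from __future__ import annotations

import calendar
import datetime as dt

import pandas as pd


def month_add(date: dt.date, months: int) -> dt.date:
    """Calendar-month shift with end-of-month clamping (monthrange-based)."""
    total = (date.year * 12 + date.month - 1) + months
    year, month = divmod(total, 12)
    month += 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def oracle_confusion(participant_ids, events, registry, window_months,
                     direction, study_period):
    """Enumerate every (participant, event, record) triple.

    ``events``: list of (participant_id, date); ``registry``: list of
    (participant_id, diagnosis_date).  Returns (tp, fp, tn, fn, n_flagged,
    n_cases, n_noncases) under the convention that a flagged case with no
    in-window event counts against both PPV and sensitivity.
    """
    lo, hi = study_period
    tp = fp = tn = fn = n_flagged = n_cases = 0
    for pid in participant_ids:
        my_events = [d for p, d in events if p == pid]
        my_records = [d for p, d in registry if p == pid and lo <= d <= hi]
        flagged = len(my_events) > 0
        is_case = len(my_records) > 0
        true_positive = False
        if flagged and is_case:
            anchor = min(my_records)
            lower = month_add(anchor, -window_months) if direction == "symmetric" else anchor
            upper = month_add(anchor, window_months)
            true_positive = any(lower <= d <= upper for d in my_events)
        n_flagged += flagged
        n_cases += is_case
        tp += true_positive
        fp += flagged and not true_positive
        fn += is_case and not true_positive
        tn += (not flagged) and (not is_case)
    n = len(participant_ids)
    return dict(tp=tp, fp=fp, tn=tn, fn=fn, n_flagged=n_flagged,
                n_cases=n_cases, n_noncases=n - n_cases)


def oracle_proxy_window(completion: dt.date, age_years: int, age_months: int,
                        reported_age: int) -> tuple[str, str]:
    """Proxy diagnosis year via pandas Period arithmetic; returns YYYY-MM pair."""
    birth = pd.Period(f"{completion.year}-{completion.month:02d}", freq="M") \
        - (age_years * 12 + age_months)
    start = birth + reported_age * 12
    end = start + 11
    return str(start), str(end)


def oracle_eval(expression_text: str, flags_present: set[str]) -> bool:
    """Evaluate an expression string via Python's own boolean operators."""
    tokens = expression_text.replace("(", " ( ").replace(")", " ) ").split()
    py = []
    for tok in tokens:
        if tok.upper() == "AND":
            py.append("and")
        elif tok.upper() == "OR":
            py.append("or")
        elif tok in "()":
            py.append(tok)
        else:
            py.append(repr(tok in flags_present))
    return bool(eval(" ".join(py)))  # noqa: S307 - test oracle on known tokens
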