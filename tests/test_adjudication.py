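"""Time-window adjudication against the registry gold standard."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from _oracles import month_add, oracle_confusion
from caseflag.adjudicate import (AdjudicationError, AdjudicationPolicy,
                                 adjudicate_dated_flag, adjudicate_expression,
                                 classify_self_report, misreport_audit,
                                 shift_months)
from caseflag.expressions import parse_expression
from caseflag.flags import proxy_windows
from caseflag.metrics import confusion

POLICY = AdjudicationPolicy()


def events_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "event_date"])


def registry_frame(rows):
    frame = pd.DataFrame(rows, columns=["participant_id", "diagnosis_date"])
    frame["site_code"] = "C50.9"
    return frame


def adjudicate(events, registry, flag="diagnosis", ids=(1,), policy=POLICY):
    return adjudicate_dated_flag(events_frame(events), registry_frame(registry),
                                 policy, flag, ids)


def test_event_on_diagnosis_date_is_true_positive():
    adj = adjudicate([(1, "2005-03-10")], [(1, "2005-03-10")])
    assert adj.loc[0, ["flagged", "is_case", "true_positive"]].all()


def test_event_four_calendar_months_out_is_flagged_but_not_tp():
    # diagnosis 2005-03-10, surgery 2005-07-20: outside the 3-month window,
    # so the participant hurts both PPV (false positive) and sensitivity
    adj = adjudicate([(1, "2005-07-20")], [(1, "2005-03-10")], flag="lumpectomy")
    row = adj.loc[0]
    assert row["flagged"] and row["is_case"] and not row["true_positive"]
    counts = confusion(adj)
    assert counts.fp == 1 and counts.fn == 1 and counts.tp == 0


def test_noncase_with_claim_is_false_positive():
    adj = adjudicate([(1, "2005-07-20")], [], flag="radiotherapy")
    row = adj.loc[0]
    assert row["flagged"] and not row["is_case"] and not row["true_positive"]


def test_symmetric_window_accepts_event_before_diagnosis():
    symmetric = adjudicate([(1, "2005-01-20")], [(1, "2005-03-10")])
    forward = adjudicate([(1, "2005-01-20")], [(1, "2005-03-10")],
                         policy=AdjudicationPolicy(window_direction="forward"))
    assert symmetric.loc[0, "true_positive"]
    assert not forward.loc[0, "true_positive"]


def test_end_of_month_clamping():
    # 2005-01-31 + 1 month clamps to 2005-02-28
    assert shift_months(dt.date(2005, 1, 31), 1) == dt.date(2005, 2, 28)
    policy = POLICY.with_window("diagnosis", 1)
    inside = adjudicate([(1, "2005-02-28")], [(1, "2005-01-31")], policy=policy)
    outside = adjudicate([(1, "2005-03-01")], [(1, "2005-01-31")], policy=policy)
    assert inside.loc[0, "true_positive"]
    assert not outside.loc[0, "true_positive"]


def test_earliest_registry_record_anchors_the_window():
    adj = adjudicate([(1, "2005-02-01")],
                     [(1, "2006-06-15"), (1, "2005-01-10")])
    assert adj.loc[0, "true_positive"]


def test_registry_record_outside_study_period_is_not_a_case():
    adj = adjudicate([(1, "2005-02-01")], [(1, "2003-01-10")])
    assert not adj.loc[0, "is_case"]


def test_event_for_unknown_participant_is_linkage_violation():
    with pytest.raises(AdjudicationError, match="linkage"):
        adjudicate([(99, "2005-02-01")], [])


# --- Figure-style self-report archetypes ---------------------------------

def survey_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "completion_date",
                                       "age_years", "age_months",
                                       "reported_breast_cancer",
                                       "reported_age_at_diagnosis"])


def test_self_report_archetypes_classify_exactly():
    """The eight archetype participants: reported windows overlapping or
    missing the comparison period, crossed with registry records inside or
    outside it, classify TP/TP/FP/FP/TN/TN/FN/FN."""
    # each participant aged exactly 60y0m at recruitment 2006-06; a reported
    # diagnosis age a yields window [2006-06 - (60-a) years, +11 months]
    def participant(pid, reported_age):
        reported = reported_age is not None
        return (pid, "2006-06-15", 60, 0, "yes" if reported else "no",
                reported_age)

    survey = survey_frame([
        participant(1, 58),    # A: window 2004-06..2005-05 overlaps, dx in period
        participant(2, 59),    # B: window 2005-06..2006-05 overlaps, dx in period
        participant(3, 58),    # C: overlap, no registry record at all
        participant(4, 59),    # D: overlap, record outside period only
        participant(5, None),  # E: no report, no record
        participant(6, 50),    # F: window 1996 does not overlap, no record
        participant(7, None),  # G: no report, record in period
        participant(8, 50),    # H: window misses period, record in period
    ])
    survey["reported_age_at_diagnosis"] = pd.array(
        survey["reported_age_at_diagnosis"], dtype="Int64")
    registry = registry_frame([
        (1, "2004-09-15"), (2, "2005-08-01"), (4, "2007-03-01"),
        (7, "2005-06-01"), (8, "2005-06-01"),
    ])
    adj = classify_self_report(proxy_windows(survey), registry, POLICY)
    adj = adj.set_index("participant_id")

    def cls(row):
        if row["true_positive"]:
            return "TP"
        if row["flagged"]:
            return "FP"
        return "FN" if row["is_case"] else "TN"

    assert [cls(adj.loc[p]) for p in range(1, 9)] == \
        ["TP", "TP", "FP", "FP", "TN", "TN", "FN", "FN"]


def test_reporter_with_nonoverlapping_window_and_record_is_false_negative():
    survey = survey_frame([(1, "2006-06-15", 60, 0, "yes", 40)])
    survey["reported_age_at_diagnosis"] = pd.array(
        survey["reported_age_at_diagnosis"], dtype="Int64")
    registry = registry_frame([(1, "2005-06-01")])
    adj = classify_self_report(proxy_windows(survey), registry, POLICY)
    row = adj.loc[0]
    assert not row["flagged"] and row["is_case"] and not row["true_positive"]


# --- combinations ---------------------------------------------------------

def _adj_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "flagged", "is_case",
                                       "true_positive"])


def test_expression_true_positive_requires_window_consistent_leaves():
    # participant 1: lumpectomy flagged but out-of-window, mastectomy absent
    per_flag = {
        "lumpectomy": _adj_frame([(1, True, True, False)]),
        "mastectomy": _adj_frame([(1, False, True, False)]),
    }
    registry = registry_frame([(1, "2005-06-01")])
    adj = adjudicate_expression(parse_expression("lumpectomy OR mastectomy"),
                                per_flag, registry, POLICY)
    row = adj.loc[0]
    assert row["flagged"] and row["is_case"] and not row["true_positive"]


def test_expression_monotone_in_leaf_true_positives():
    per_flag = {
        "lumpectomy": _adj_frame([(1, True, True, True)]),
        "diagnosis": _adj_frame([(1, True, True, True)]),
    }
    registry = registry_frame([(1, "2005-06-01")])
    adj = adjudicate_expression(parse_expression("lumpectomy AND diagnosis"),
                                per_flag, registry, POLICY)
    assert adj.loc[0, "true_positive"]


def test_expression_missing_leaf_adjudication_raises():
    with pytest.raises(AdjudicationError, match="missing adjudication"):
        adjudicate_expression(parse_expression("lumpectomy AND diagnosis"),
                              {"lumpectomy": _adj_frame([(1, True, True, True)])},
                              registry_frame([]), POLICY)


# --- misreport audit ------------------------------------------------------

def test_misreport_audit_hand_count():
    adj = _adj_frame([
        (1, True, False, False),   # FP with out-of-period record
        (2, True, False, False),   # FP with out-of-period record
        (3, True, False, False),   # FP, never on the registry
        (4, True, True, True),     # TP, not in the audit denominator
        (5, False, False, False),
    ])
    registry = registry_frame([(1, "2007-05-01"), (2, "2006-02-01"),
                               (4, "2005-03-01")])
    audit = misreport_audit(adj, registry, POLICY)
    assert (audit.n_false_positives, audit.n_with_out_of_period_record) == (3, 2)
    assert audit.proportion == pytest.approx(2 / 3)


def test_misreport_audit_with_no_false_positives_is_not_applicable():
    adj = _adj_frame([(1, False, False, False)])
    audit = misreport_audit(adj, registry_frame([]), POLICY)
    assert audit.proportion is None


# --- brute-force oracle equivalence & monotonicity ------------------------

def random_fixture(rng):
    n = int(rng.integers(3, 50))
    ids = list(range(1, n + 1))
    study = POLICY.study_period
    span = (study[1] - study[0]).days

    def random_date():
        return study[0] + dt.timedelta(days=int(rng.integers(-120, span + 120)))

    events = [(int(rng.integers(1, n + 1)), random_date())
              for _ in range(int(rng.integers(0, 2 * n)))]
    registry = [(int(rng.integers(1, n + 1)), random_date())
                for _ in range(int(rng.integers(0, n)))]
    return ids, events, registry


@pytest.mark.parametrize("direction", ["symmetric", "forward"])
def test_confusion_counts_match_enumeration_oracle(direction):
    rng = np.random.default_rng(20250926)
    policy = AdjudicationPolicy(window_direction=direction)
    for _ in range(100):
        ids, events, registry = random_fixture(rng)
        window = int(rng.integers(1, 13))
        policy_w = policy.with_window("diagnosis", window)
        adj = adjudicate_dated_flag(
            events_frame([(p, d.isoformat()) for p, d in events]),
            registry_frame([(p, d.isoformat()) for p, d in registry]),
            policy_w, "diagnosis", ids)
        counts = confusion(adj)
        expected = oracle_confusion(ids, events, registry, window, direction,
                                    policy.study_period)
        assert counts.tp == expected["tp"] and counts.fp == expected["fp"]
        assert counts.tn == expected["tn"] and counts.fn == expected["fn"]


def test_widening_the_window_never_loses_true_positives():
    rng = np.random.default_rng(77)
    for _ in range(30):
        ids, events, registry = random_fixture(rng)
        ev = events_frame([(p, d.isoformat()) for p, d in events])
        reg = registry_frame([(p, d.isoformat()) for p, d in registry])
        tps = []
        for window in (1, 2, 3, 6, 12, 24):
            adj = adjudicate_dated_flag(ev, reg, POLICY.with_window("diagnosis", window),
                                        "diagnosis", ids)
            tps.append(int(adj["true_positive"].sum()))
        assert tps == sorted(tps)


def test_month_shift_agrees_with_monthrange_oracle():
    rng = np.random.default_rng(5)
    for _ in range(300):
        date = dt.date(2004, 7, 1) + dt.timedelta(days=int(rng.integers(0, 1700)))
        k = int(rng.integers(-24, 25))
        assert shift_months(date, k) == month_add(date, k)
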