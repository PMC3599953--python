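"""Validity-table reports: run the full pipeline for a list of flag
expressions over one linked cohort and tabulate PPV / sensitivity /
specificity with raw counts and exact binomial CIs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .adjudicate import (AdjudicationPolicy, adjudicate_dated_flag,
                         adjudicate_expression, classify_self_report)
from .catalog import SELF_REPORT, CodeCatalog, load_catalog
from .cohort import Cohort
from .expressions import FlagExpression, Leaf, leaves, parse_expression, to_string
from .flags import extract_dated_flags, proxy_windows
from .metrics import confusion, metrics, percent

log = logging.getLogger(__name__)

#: which cohort table each flag is extracted from
FLAG_SOURCE = {
    "diagnosis": "hospital",
    "lumpectomy": "hospital",
    "mastectomy": "hospital",
    "radiotherapy": "mbs",
    "medicines": "pbs",
}


def adjudicate_flag_on_cohort(cohort: Cohort, flag_name: str,
                              policy: AdjudicationPolicy,
                              catalog: Optional[CodeCatalog] = None) -> pd.DataFrame:
    """Extract and adjudicate a single flag (dated or self-report)."""
    participant_ids = cohort.participants["participant_id"]
    if flag_name == SELF_REPORT:
        windows = proxy_windows(cohort.survey)
        return classify_self_report(windows, cohort.registry, policy)
    catalog = catalog or load_catalog()
    source = FLAG_SOURCE.get(flag_name)
    if source is None:
        raise KeyError(f"no source dataset mapped for flag {flag_name!r}")
    events = extract_dated_flags(getattr(cohort, source), catalog, flag_name)
    log.info("flag %s: %d events from %s", flag_name, len(events), source)
    return adjudicate_dated_flag(events, cohort.registry, policy, flag_name,
                                 participant_ids)


def adjudicate_expression_on_cohort(cohort: Cohort,
                                    expression: str | FlagExpression,
                                    policy: AdjudicationPolicy,
                                    catalog: Optional[CodeCatalog] = None,
                                    ) -> pd.DataFrame:
    """Adjudicate a flag expression end to end on one cohort.

    A bare single-flag expression keeps that flag's own adjudication
    semantics — in particular the standalone self-report row is judged
    against comparison-period cases only, while a self-report leaf inside a
    combination contributes its classification to a study-period judgment.
    """
    expr = parse_expression(expression) if isinstance(expression, str) else expression
    catalog = catalog or load_catalog()
    per_flag = {name: adjudicate_flag_on_cohort(cohort, name, policy, catalog)
                for name in sorted(leaves(expr))}
    if isinstance(expr, Leaf):
        return per_flag[expr.flag_name]
    return adjudicate_expression(expr, per_flag, cohort.registry, policy)


def build_report(expressions: Sequence[str | FlagExpression], cohort: Cohort,
                 policy: Optional[AdjudicationPolicy] = None,
                 catalog: Optional[CodeCatalog] = None,
                 labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One validity row per expression, in the given order.

    Percent columns are display values (half-up, one decimal); the raw
    counts allow every percentage to be re-derived exactly.
    """
    policy = policy or AdjudicationPolicy()
    catalog = catalog or load_catalog()
    rows = []
    for i, expression in enumerate(expressions):
        expr = parse_expression(expression) if isinstance(expression, str) else expression
        adj = adjudicate_expression_on_cohort(cohort, expr, policy, catalog)
        counts = confusion(adj)
        m = metrics(counts)
        log.info("row %d (%s): tp=%d fp=%d tn=%d fn=%d", i, to_string(expr),
                 counts.tp, counts.fp, counts.tn, counts.fn)
        rows.append({
            "label": labels[i] if labels is not None else to_string(expr),
            "expression": to_string(expr),
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
            "n_flagged": counts.n_flagged, "n_cases": counts.n_cases,
            "n_noncases": counts.n_noncases,
            "ppv": m.ppv, "sensitivity": m.sensitivity, "specificity": m.specificity,
            "ppv_pct": percent(m.ppv), "sensitivity_pct": percent(m.sensitivity),
            "specificity_pct": percent(m.specificity),
            "ppv_ci_low": m.ppv_ci[0] if m.ppv_ci else None,
            "ppv_ci_high": m.ppv_ci[1] if m.ppv_ci else None,
            "sensitivity_ci_low": m.sensitivity_ci[0] if m.sensitivity_ci else None,
            "sensitivity_ci_high": m.sensitivity_ci[1] if m.sensitivity_ci else None,
            "specificity_ci_low": m.specificity_ci[0] if m.specificity_ci else None,
            "specificity_ci_high": m.specificity_ci[1] if m.specificity_ci else None,
        })
    return pd.DataFrame(rows)


def select_flags(report: pd.DataFrame, ppv_floor: float) -> pd.DataFrame:
    """Rows with PPV at or above the floor, ranked by sensitivity.

    The selection rule of the validation study: require high PPV (the
    published analysis used >= 0.85), then prefer the most sensitive flag.
    Ties break by PPV, then by original row order.
    """
    if report.empty:
        raise ValueError("report is empty")
    eligible = report.loc[report["ppv"].notna() & (report["ppv"] >= ppv_floor)].copy()
    eligible["_order"] = range(len(eligible))
    ranked = eligible.sort_values(["sensitivity", "ppv", "_order"],
                                  ascending=[False, False, True], kind="stable")
    return ranked.drop(columns="_order").reset_index(drop=True)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of a report table.

    Exact binomial CIs are an extension over the published tables, which
    print percentages only.
    """
    cols = ["label", "ppv_pct", "sensitivity_pct", "specificity_pct",
            "tp", "fp", "tn", "fn"]
    body = report[cols].rename(columns={
        "label": "Flag", "ppv_pct": "PPV %", "sensitivity_pct": "Sensitivity %",
        "specificity_pct": "Specificity %",
    })
    text = body.to_string(index=False)
    return text + "\n\nCIs (not shown) are exact Clopper-Pearson 95% intervals; see CSV output."
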