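"""Validity metrics: confusion counts, PPV, sensitivity, specificity.

Conventions follow the adjudication design: a case flagged only outside the
window counts against both PPV (as a flagged non-true-positive) and
sensitivity (as a missed case); specificity's denominator is non-cases
only.  The four counts therefore refer to explicit denominators rather than
a strict 2x2 partition, and raw counts are always carried alongside the
proportions so every printed percentage can be re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Adjudicated counts with their denominators.

    ``tp`` / ``n_flagged`` -> PPV; ``tp`` / ``n_cases`` -> sensitivity;
    ``tn`` / ``n_noncases`` -> specificity.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_flagged: int
    n_cases: int
    n_noncases: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "n_flagged", "n_cases", "n_noncases"):
            if getattr(self, name) < 0:
                raise MetricsError(f"{name} must be non-negative")
        if self.tp > self.n_flagged or self.tp > self.n_cases or self.tn > self.n_noncases:
            raise MetricsError("counts exceed their denominators")

    @property
    def cohort_size(self) -> int:
        return self.n_cases + self.n_noncases


def confusion(adjudications: pd.DataFrame) -> ConfusionCounts:
    """Reduce per-participant adjudications to confusion counts.

    Expects one row per participant with boolean ``flagged``, ``is_case``,
    ``true_positive`` columns.
    """
    if adjudications.empty:
        raise MetricsError("empty cohort: no adjudications to count")
    if adjudications["participant_id"].duplicated().any():
        dup = adjudications.loc[adjudications["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise MetricsError(f"duplicate adjudication for participant {dup}")
    bad = adjudications["true_positive"] & ~(adjudications["flagged"] & adjudications["is_case"])
    if bad.any():
        raise MetricsError("true_positive participant that is not a flagged case")

    flagged = adjudications["flagged"]
    is_case = adjudications["is_case"]
    tp = int(adjudications["true_positive"].sum())
    n_flagged = int(flagged.sum())
    n_cases = int(is_case.sum())
    n_noncases = int((~is_case).sum())
    tn = int((~flagged & ~is_case).sum())
    return ConfusionCounts(
        tp=tp, fp=n_flagged - tp, tn=tn, fn=n_cases - tp,
        n_flagged=n_flagged, n_cases=n_cases, n_noncases=n_noncases,
    )


@dataclass(frozen=True)
class ValidityMetrics:
    """PPV, sensitivity and specificity with exact binomial 95% CIs.

    A metric whose denominator is zero is ``None`` (not applicable), never 0.
    """

    ppv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv_ci: Optional[tuple[float, float]] = None
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None


def _proportion(count: int, nobs: int, alpha: float,
                ) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    if nobs == 0:
        return None, None
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return count / nobs, (float(lo), float(hi))


def metrics(counts: ConfusionCounts, alpha: float = 0.05) -> ValidityMetrics:
    """Compute PPV / sensitivity / specificity with Clopper-Pearson CIs."""
    ppv, ppv_ci = _proportion(counts.tp, counts.n_flagged, alpha)
    se, se_ci = _proportion(counts.tp, counts.n_cases, alpha)
    sp, sp_ci = _proportion(counts.tn, counts.n_noncases, alpha)
    return ValidityMetrics(ppv=ppv, sensitivity=se, specificity=sp,
                           ppv_ci=ppv_ci, sensitivity_ci=se_ci, specificity_ci=sp_ci)


def percent(value: Optional[float], decimals: int = 1) -> Optional[float]:
    """Proportion -> percentage rounded half-up, display convention only."""
    if value is None:
        return None
    quantum = Decimal(1).scaleb(-decimals)
    return float((Decimal(str(value)) * 100).quantize(quantum, rounding=ROUND_HALF_UP))
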