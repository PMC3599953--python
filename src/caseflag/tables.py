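"""Published validity rows used as calibration targets and default report rows.

Each row pairs a flag expression with the PPV / sensitivity / specificity
reported for it in the source validation study (proportions, not percent).
The synthetic generator uses the single-flag rows as its default event-rate
calibration targets, and the parameter-recovery surface replays any row
through the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ValidityRow:
    label: str
    expression: str  # parseable flag expression; leaves are catalog flags or self_report
    ppv: float
    sensitivity: float
    specificity: float
    datasets: str


#: validity of flags within individual datasets (July 2004 - December 2008;
#: self-report compared over July 2004 - December 2005)
INDIVIDUAL_DATASET_ROWS: tuple[ValidityRow, ...] = (
    ValidityRow("Self-reported diagnosis of breast cancer",
                "self_report", 0.498, 0.847, 0.996, "survey"),
    ValidityRow("Diagnosis of invasive breast cancer",
                "diagnosis", 0.859, 0.861, 0.998, "hospital"),
    ValidityRow("Lumpectomy", "lumpectomy", 0.520, 0.607, 0.992, "hospital"),
    ValidityRow("Mastectomy", "mastectomy", 0.708, 0.326, 0.998, "hospital"),
    ValidityRow("Lumpectomy OR mastectomy",
                "lumpectomy OR mastectomy", 0.564, 0.844, 0.991, "hospital"),
    ValidityRow("Lumpectomy AND diagnosis",
                "lumpectomy AND diagnosis", 0.890, 0.591, 0.999, "hospital"),
    ValidityRow("Mastectomy AND diagnosis",
                "mastectomy AND diagnosis", 0.854, 0.318, 0.991, "hospital"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis",
                "(lumpectomy OR mastectomy) AND diagnosis", 0.877, 0.823, 0.998, "hospital"),
    ValidityRow("(Lumpectomy OR mastectomy) OR diagnosis",
                "(lumpectomy OR mastectomy) OR diagnosis", 0.565, 0.882, 0.990, "hospital"),
    ValidityRow("Mastectomy OR diagnosis",
                "mastectomy OR diagnosis", 0.797, 0.876, 0.997, "hospital"),
    ValidityRow("Lumpectomy OR diagnosis",
                "lumpectomy OR diagnosis", 0.582, 0.876, 0.991, "hospital"),
    ValidityRow("Breast radiotherapy", "radiotherapy", 0.728, 0.576, 0.997, "mbs"),
    ValidityRow("Dispensed medicine for breast cancer",
                "medicines", 0.455, 0.654, 0.989, "pbs"),
)

#: validity of combinations of flags across datasets
MULTI_DATASET_ROWS: tuple[ValidityRow, ...] = (
    ValidityRow("Radiotherapy AND medicine",
                "radiotherapy AND medicines", 0.801, 0.403, 0.999, "survey+mbs+pbs"),
    ValidityRow("Radiotherapy OR medicine",
                "radiotherapy OR medicines", 0.479, 0.827, 0.987, "survey+mbs+pbs"),
    ValidityRow("Radiotherapy AND self-report",
                "radiotherapy AND self_report", 0.693, 0.361, 0.999, "survey+mbs+pbs"),
    ValidityRow("Radiotherapy AND medicine AND self-report",
                "radiotherapy AND medicines AND self_report", 0.721, 0.239, 0.999, "survey+mbs+pbs"),
    ValidityRow("(Radiotherapy OR medicine) AND self-report",
                "(radiotherapy OR medicines) AND self_report", 0.586, 0.604, 0.998, "survey+mbs+pbs"),
    ValidityRow("Radiotherapy OR medicine OR self-report",
                "radiotherapy OR medicines OR self_report", 0.270, 0.953, 0.977, "survey+mbs+pbs"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis AND radiotherapy",
                "(lumpectomy OR mastectomy) AND diagnosis AND radiotherapy",
                0.901, 0.475, 0.999, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis AND radiotherapy AND medicine",
                "(lumpectomy OR mastectomy) AND diagnosis AND radiotherapy AND medicines",
                0.897, 0.337, 0.999, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis AND medicine",
                "(lumpectomy OR mastectomy) AND diagnosis AND medicines",
                0.878, 0.550, 0.999, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND (diagnosis OR radiotherapy)",
                "(lumpectomy OR mastectomy) AND (diagnosis OR radiotherapy)",
                0.830, 0.832, 0.998, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND (diagnosis OR medicine)",
                "(lumpectomy OR mastectomy) AND (diagnosis OR medicines)",
                0.841, 0.831, 0.998, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND (diagnosis OR radiotherapy OR medicine)",
                "(lumpectomy OR mastectomy) AND (diagnosis OR radiotherapy OR medicines)",
                0.805, 0.836, 0.997, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis AND self-report",
                "(lumpectomy OR mastectomy) AND diagnosis AND self_report",
                0.885, 0.711, 0.999, "all"),
    ValidityRow("(Lumpectomy OR mastectomy) AND diagnosis AND radiotherapy AND self-report",
                "(lumpectomy OR mastectomy) AND diagnosis AND radiotherapy AND self_report",
                0.873, 0.294, 0.999, "all"),
)


def row_by_expression(expression: str) -> ValidityRow:
    for row in INDIVIDUAL_DATASET_ROWS + MULTI_DATASET_ROWS:
        if row.expression.lower() == expression.lower():
            return row
    raise KeyError(f"no published row for expression {expression!r}")
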