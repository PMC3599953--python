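"""Code catalog: the versioned code lists that define each ascertainment flag.

The catalog maps a flag name (``diagnosis``, ``lumpectomy``, ``mastectomy``,
``radiotherapy``, ``medicines``, ``registry_diagnosis``) to the set of codes
that trigger it in its source dataset.  Codes are always handled as strings
(PBS items carry suffix letters, procedure codes leading zeros) and are
normalized before any comparison: whitespace trimmed, upper-cased, and
en-/em-dashes folded to ASCII hyphens, since typography in source documents
is not a data standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: datasets a flag may be extracted from
DATASETS = ("registry", "hospital_dx", "hospital_proc", "service_claim", "prescription_claim")

#: pseudo-flag handled by the self-report pathway; it has no code list
SELF_REPORT = "self_report"

_DASHES = str.maketrans({"‐": "-", "‑": "-", "‒": "-", "–": "-",
                         "—": "-", "−": "-"})


class CatalogError(ValueError):
    """Raised when a code-list file is malformed or a flag is unknown."""


def normalize_code(code: str) -> str:
    """Normalize a code string: trim, upper-case, unify dashes.

    Normalization is idempotent.
    """
    return str(code).strip().upper().translate(_DASHES)


@dataclass(frozen=True)
class FlagCodes:
    name: str
    dataset: str
    codes: frozenset[str]


@dataclass(frozen=True)
class CodeCatalog:
    """Immutable mapping of flag name to its code set and source dataset."""

    flags: Mapping[str, FlagCodes]

    def __contains__(self, flag_name: str) -> bool:
        return flag_name in self.flags

    def __getitem__(self, flag_name: str) -> FlagCodes:
        try:
            return self.flags[flag_name]
        except KeyError:
            raise CatalogError(f"unknown flag name: {flag_name!r}") from None

    def codes(self, flag_name: str) -> frozenset[str]:
        return self[flag_name].codes

    def dataset(self, flag_name: str) -> str:
        return self[flag_name].dataset

    def flag_names(self) -> tuple[str, ...]:
        return tuple(self.flags)


#: flags every shipped catalog must define
REQUIRED_FLAGS = ("registry_diagnosis", "diagnosis", "mastectomy", "lumpectomy",
                  "radiotherapy", "medicines")


def default_catalog_path() -> Path:
    return Path(str(resources.files("caseflag").joinpath("data/code_lists.yaml")))


def load_catalog(path: str | Path | None = None) -> CodeCatalog:
    """Load and validate a code catalog from a YAML code-list file.

    Validates that every required flag is present with a non-empty code set,
    that flag names are unique, and that code sets are disjoint within each
    dataset (the registry and hospital diagnosis flags intentionally share
    the C50.x site codes but live in different datasets).
    """
    path = Path(path) if path is not None else default_catalog_path()
    if not path.exists():
        raise CatalogError(f"code-list file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CatalogError(f"code-list file {path} must map flag names to entries")

    flags: dict[str, FlagCodes] = {}
    for name, entry in raw.items():
        if name in flags:  # pragma: no cover - yaml collapses dup keys first
            raise CatalogError(f"duplicate flag name: {name!r}")
        if not isinstance(entry, dict) or "dataset" not in entry or "codes" not in entry:
            raise CatalogError(f"flag {name!r}: entry needs 'dataset' and 'codes'")
        dataset = str(entry["dataset"])
        if dataset not in DATASETS:
            raise CatalogError(f"flag {name!r}: unknown dataset {dataset!r}")
        codes = entry["codes"]
        if not isinstance(codes, list) or not codes:
            raise CatalogError(f"flag {name!r}: empty code set")
        normalized = frozenset(normalize_code(c) for c in codes)
        if len(normalized) != len(codes):
            raise CatalogError(f"flag {name!r}: duplicate codes after normalization")
        flags[str(name)] = FlagCodes(str(name), dataset, normalized)

    for required in REQUIRED_FLAGS:
        if required not in flags:
            raise CatalogError(f"missing flag: {required!r}")

    _check_disjoint_within_dataset(flags.values())
    return CodeCatalog(flags=flags)


def _check_disjoint_within_dataset(entries: Iterable[FlagCodes]) -> None:
    seen: dict[str, dict[str, str]] = {}
    for entry in entries:
        per_ds = seen.setdefault(entry.dataset, {})
        for code in entry.codes:
            if code in per_ds:
                raise CatalogError(
                    f"code {code!r} appears in both {per_ds[code]!r} and "
                    f"{entry.name!r} within dataset {entry.dataset!r}"
                )
            per_ds[code] = entry.name


def _canonical_icd(code: str) -> str:
    # accept undotted ICD forms (C504 -> C50.4)
    if len(code) == 4 and code[0].isalpha() and code[1:].isdigit():
        return f"{code[:3]}.{code[3]}"
    return code


def code_matches(code: str, flag_name: str, catalog: CodeCatalog) -> bool:
    """True iff the normalized code belongs to the flag's code set.

    For the diagnosis flags, a bare 3-character ``C50`` is accepted (the
    source data may carry 3-character site codes), as is the undotted
    4-character form ``C504``.
    """
    entry = catalog[flag_name]
    norm = normalize_code(code)
    if entry.dataset in ("registry", "hospital_dx"):
        if norm == "C50":
            return True
        norm = _canonical_icd(norm)
    return norm in entry.codes
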