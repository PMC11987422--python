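"""Reading, validating, filtering and writing long-format claims records.

A claims file is delimited text (comma or tab, auto-detected from the header)
with one code occurrence per row::

    patient_id,admission_id,day_index,code_type,token

``day_index`` is 1-based with day 1 = admission day.  Tokens carry a
code-type prefix (``DX:``, ``RX:``, ``PR:``, ``SP:``, ``DM:``) so that
diagnosis and treatment codes sharing raw identifiers cannot collide in a
single vocabulary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed values of the ``code_type`` column.
CODE_TYPES = ("diagnosis", "medication", "procedure", "supply", "demographic")

#: Column order of a claims file.
CLAIMS_COLUMNS = ("patient_id", "admission_id", "day_index", "code_type", "token")

#: Columns every patient table must carry; measured-confounder columns are
#: free-form extras.
PATIENT_REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "admission_day_count",
    "treatment",
    "outcome_death",
    "outcome_adl_dependency",
    "outcome_readmit90",
    "length_of_stay",
)

_BINARY_PATIENT_COLUMNS = (
    "sex",
    "treatment",
    "outcome_death",
    "outcome_adl_dependency",
    "outcome_readmit90",
)


class ClaimsValidationError(ValueError):
    """A claims or patient table row violates an invariant."""


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def validate_claims(records: pd.DataFrame) -> None:
    """Raise :class:`ClaimsValidationError` naming the first offending line.

    Line numbers refer to the delimited file (header = line 1), i.e.
    ``dataframe row i`` -> ``line i + 2``.
    """
    missing = [c for c in CLAIMS_COLUMNS if c not in records.columns]
    if missing:
        raise ClaimsValidationError(f"claims table missing columns: {missing}")
    day = pd.to_numeric(records["day_index"], errors="coerce")
    bad = records.index[day.isna() | (day < 1) | (day != day.round())]
    if len(bad):
        raise ClaimsValidationError(
            f"invalid day_index (must be integer >= 1) at line {int(bad[0]) + 2}"
        )
    bad = records.index[~records["code_type"].isin(CODE_TYPES)]
    if len(bad):
        value = records.loc[bad[0], "code_type"]
        raise ClaimsValidationError(
            f"unknown code_type {value!r} at line {int(bad[0]) + 2}"
        )
    token = records["token"].astype(str)
    bad = records.index[token.isna() | (token.str.len() == 0) | (token == "nan")]
    if len(bad):
        raise ClaimsValidationError(f"empty token at line {int(bad[0]) + 2}")


def read_claims(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a claims file into a validated DataFrame, preserving row order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = _detect_sep(path)
    records = pd.read_csv(
        path,
        sep=sep,
        dtype={
            "patient_id": str,
            "admission_id": str,
            "code_type": str,
            "token": str,
        },
    )
    records = records.reset_index(drop=True)
    validate_claims(records)
    records["day_index"] = records["day_index"].astype(int)
    return records[list(CLAIMS_COLUMNS)]


def write_claims(records: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write claims records as delimited text readable by :func:`read_claims`."""
    validate_claims(records)
    records[list(CLAIMS_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_patient_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a patient-level table (one row per patient)."""
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    patients = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    validate_patient_table(patients)
    return patients


def validate_patient_table(patients: pd.DataFrame) -> None:
    missing = [c for c in PATIENT_REQUIRED_COLUMNS if c not in patients.columns]
    if missing:
        raise ClaimsValidationError(f"patient table missing columns: {missing}")
    if patients["patient_id"].duplicated().any():
        dup = patients["patient_id"][patients["patient_id"].duplicated()].iloc[0]
        raise ClaimsValidationError(f"duplicate patient_id {dup!r}")
    for col in _BINARY_PATIENT_COLUMNS:
        if not patients[col].isin([0, 1]).all():
            raise ClaimsValidationError(f"column {col!r} must be binary 0/1")
    if (patients["length_of_stay"] < 1).any():
        raise ClaimsValidationError("length_of_stay must be >= 1")
    if (patients["admission_day_count"] < 1).any():
        raise ClaimsValidationError("admission_day_count must be >= 1")


def write_patient_table(patients: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    validate_patient_table(patients)
    patients.to_csv(path, sep=sep, index=False)


@dataclass
class FilterResult:
    """Cohort after exclusion rules, with per-rule removal bookkeeping."""

    table: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_cohort(
    patients: pd.DataFrame, rules: Mapping[str, str] | Sequence[tuple[str, str]]
) -> FilterResult:
    """Apply declarative inclusion predicates sequentially.

    ``rules`` maps a rule name to a pandas ``query`` expression; rows failing
    a predicate are removed and counted under that rule's name.  Rules are
    applied in order, so counts are attributed to the first rule a row fails.
    An empty rule set is the identity.
    """
    items = list(rules.items()) if isinstance(rules, Mapping) else list(rules)
    table = patients
    removed: dict[str, int] = {}
    for name, expr in items:
        before = len(table)
        try:
            table = table.query(expr)
        except pd.errors.UndefinedVariableError as err:
            raise ClaimsValidationError(
                f"rule {name!r} references a missing field: {err}"
            ) from err
        removed[name] = before - len(table)
    return FilterResult(table=table.copy(), removed=removed)


@dataclass(frozen=True)
class Vocabulary:
    """Dense token index with occurrence counts.

    Tokens are ordered by descending corpus frequency (ties broken
    lexicographically) and indexed 0..V-1; every retained token occurred at
    least ``min_count`` times.
    """

    index: dict[str, int]
    counts: dict[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def tokens(self) -> list[str]:
        """Tokens in index order."""
        out = [""] * len(self.index)
        for tok, i in self.index.items():
            out[i] = tok
        return out


def build_vocabulary(records: pd.DataFrame, min_count: int = 1) -> Vocabulary:
    """Count tokens and retain those with corpus frequency >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if len(records) == 0:
        raise ValueError("cannot build a vocabulary from an empty record set")
    counts = Counter(records["token"].astype(str))
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda tok: (-counts[tok], tok),
    )
    if not kept:
        raise ValueError(f"no token reaches min_count={min_count}")
    return Vocabulary(
        index={tok: i for i, tok in enumerate(kept)},
        counts={tok: counts[tok] for tok in kept},
        min_count=min_count,
    )
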