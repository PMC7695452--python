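"""CSV round-trip for scoring tables.

Dialect: UTF-8, comma-delimited, mandatory header, booleans encoded 0/1,
days as plain numbers.  EdU columns may be absent (12-day tables are scored
without an EdU pulse); absent means "not scored", never zero.
"""

from __future__ import annotations

import math
from os import PathLike
from typing import Optional, Union

import pandas as pd

from .model import (
    SCORING_COLUMNS,
    Observation,
    SchemaError,
    ScoringTable,
    ValidationError,
)

__all__ = ["read_scoring_table", "write_scoring_table", "validate_table"]

_EDU_COLUMNS = ("edu_l1", "edu_l2", "edu_l3", "edu_ec")
_REQUIRED_COLUMNS = tuple(c for c in SCORING_COLUMNS if c not in _EDU_COLUMNS)
_BOOL_COLUMNS = ("immediate_fc_present", "any_fc_present")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_bool(value: object, column: str, row_id: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"{row_id}: cannot interpret {column}={value!r} as 0/1")


def _parse_optional_count(value: object) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "":
        return None
    return int(float(text))


def read_scoring_table(path: Union[str, PathLike]) -> ScoringTable:
    """Read and validate a scoring-table CSV.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If any record violates a count invariant; the message lists the
        offending germarium ids.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    known = set(SCORING_COLUMNS)
    extra = [c for c in frame.columns if c not in known]
    metadata: dict[str, str] = {}
    if extra:
        metadata["extra_columns"] = ",".join(extra)

    observations: list[Observation] = []
    for _, row in frame.iterrows():
        gid = str(row["germarium_id"])
        obs = Observation(
            germarium_id=gid,
            genotype=str(row["genotype"]),
            day=float(row["day"]),
            n_marked_l1=int(float(row["n_marked_l1"])),
            n_marked_l2=int(float(row["n_marked_l2"])),
            n_marked_l3=int(float(row["n_marked_l3"])),
            edu_l1=_parse_optional_count(row.get("edu_l1")),
            edu_l2=_parse_optional_count(row.get("edu_l2")),
            edu_l3=_parse_optional_count(row.get("edu_l3")),
            n_marked_ec=int(float(row["n_marked_ec"])),
            edu_ec=_parse_optional_count(row.get("edu_ec")),
            immediate_fc_present=_parse_bool(row["immediate_fc_present"], "immediate_fc_present", gid),
            any_fc_present=_parse_bool(row["any_fc_present"], "any_fc_present", gid),
        )
        observations.append(obs)

    table = ScoringTable(observations=observations, metadata=metadata)
    problems = table.violations()
    if problems:
        raise ValidationError("invalid scoring table: " + "; ".join(problems))
    return table


def _format_day(day: float) -> str:
    return str(int(day)) if float(day).is_integer() else repr(day)


def write_scoring_table(table: ScoringTable, path: Union[str, PathLike]) -> None:
    """Write a scoring table as canonical CSV (see module docstring).

    ``read_scoring_table(write_scoring_table(t))`` is the identity on every
    field value, including ``None`` EdU entries (written as empty cells).
    """
    rows = []
    for o in table.observations:
        rows.append(
            {
                "germarium_id": o.germarium_id,
                "genotype": o.genotype,
                "day": _format_day(o.day),
                "n_marked_l1": o.n_marked_l1,
                "n_marked_l2": o.n_marked_l2,
                "n_marked_l3": o.n_marked_l3,
                "edu_l1": "" if o.edu_l1 is None else o.edu_l1,
                "edu_l2": "" if o.edu_l2 is None else o.edu_l2,
                "edu_l3": "" if o.edu_l3 is None else o.edu_l3,
                "n_marked_ec": o.n_marked_ec,
                "edu_ec": "" if o.edu_ec is None else o.edu_ec,
                "immediate_fc_present": int(o.immediate_fc_present),
                "any_fc_present": int(o.any_fc_present),
            }
        )
    frame = pd.DataFrame(rows, columns=list(SCORING_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")


def validate_table(table: ScoringTable) -> list[str]:
    """Report all invariant violations; empty list iff the table is valid.

    Never raises: this is the reporting counterpart of the exceptions thrown
    by :func:`read_scoring_table`.
    """
    return table.violations()
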