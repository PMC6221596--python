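"""Record schemas and delimited-text I/O for ED visit and culture tables.

Two tables drive the whole analysis:

``visits``
    One row per ED encounter: ``visit_id, patient_id, arrival, departure,
    disposition``.  Visits are the denominator of the blood-culture
    ordering rate and the unit of 48-hour return-visit linkage.

``cultures``
    One row per ordered peripheral blood culture: ``culture_id, visit_id,
    patient_id, ordered_at, result, organism, exclusion_flags``.
    ``result`` is ``growth`` or ``no_growth``; ``organism`` is non-empty
    exactly when the culture grew; ``exclusion_flags`` is a
    semicolon-separated subset of the record-level exclusion reasons
    (central line, VP shunt, oncologic condition, neutropenia, transplant
    history).

Both files are RFC-4180 CSV with a header row, UTF-8, timezone-naive
ISO-8601 timestamps.  :func:`load_tables` validates rows against the
schema invariants; malformed rows go to a rejects report (one row per
reject, with a reason) rather than being silently dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DISPOSITIONS",
    "RESULTS",
    "EXCLUSION_FLAGS",
    "VISIT_COLUMNS",
    "CULTURE_COLUMNS",
    "TIMESTAMP_FORMAT",
    "load_tables",
    "write_tables",
]


class SchemaError(ValueError):
    """A required column is missing or a file does not match its schema."""


DISPOSITIONS = ("discharged", "admitted", "transferred", "other")
RESULTS = ("no_growth", "growth")
EXCLUSION_FLAGS = ("central_line", "vp_shunt", "oncologic", "neutropenia", "transplant")

VISIT_COLUMNS = ("visit_id", "patient_id", "arrival", "departure", "disposition")
CULTURE_COLUMNS = (
    "culture_id",
    "visit_id",
    "patient_id",
    "ordered_at",
    "result",
    "organism",
    "exclusion_flags",
)

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S.%f"

_REJECT_COLUMNS = ("table", "row", "record_id", "reason")


def _read_csv(path, required: tuple[str, ...], schema: Mapping[str, str] | None, table: str):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {src: dst for dst, src in schema.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} file {path} is missing required column(s): {', '.join(missing)}")
    return df.loc[:, list(required)]


def _parse_ts(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, errors="coerce", format="mixed")


def load_tables(
    visits_path,
    cultures_path,
    *,
    visits_schema: Mapping[str, str] | None = None,
    cultures_schema: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate the visit and culture tables.

    Parameters
    ----------
    visits_path, cultures_path :
        CSV files with the documented columns.
    visits_schema, cultures_schema :
        Optional mappings ``canonical name -> column name in the file`` for
        files whose headers differ from the canonical schema.

    Returns
    -------
    (visits, cultures, rejects) :
        Validated DataFrames plus a rejects report with columns
        ``table, row, record_id, reason`` (``row`` is the 0-based data row
        in the source file).  Rejected rows are excluded from the returned
        tables; an empty rejects frame means every row validated.

    Raises
    ------
    SchemaError
        If a required column is absent (this is a file-level defect, not a
        row-level one).
    """
    rejects: list[dict] = []

    visits = _read_csv(visits_path, VISIT_COLUMNS, visits_schema, "visits")
    visits["arrival"] = _parse_ts(visits["arrival"])
    visits["departure"] = _parse_ts(visits["departure"])

    bad = pd.Series(False, index=visits.index)

    def _reject_visits(mask, reason):
        nonlocal bad
        mask = mask & ~bad
        for i in visits.index[mask]:
            rejects.append(
                {"table": "visits", "row": int(i), "record_id": visits.at[i, "visit_id"], "reason": reason}
            )
        bad |= mask

    _reject_visits(visits["arrival"].isna(), "unparseable arrival timestamp")
    _reject_visits(visits["departure"].isna(), "unparseable departure timestamp")
    _reject_visits(visits["departure"] < visits["arrival"], "departure before arrival")
    _reject_visits(~visits["disposition"].isin(DISPOSITIONS), "unknown disposition")
    _reject_visits(visits["visit_id"].duplicated(keep="first"), "duplicate visit_id")
    visits = visits.loc[~bad].reset_index(drop=True)

    cultures = _read_csv(cultures_path, CULTURE_COLUMNS, cultures_schema, "cultures")
    cultures["ordered_at"] = _parse_ts(cultures["ordered_at"])

    cbad = pd.Series(False, index=cultures.index)

    def _reject_cultures(mask, reason):
        nonlocal cbad
        mask = mask & ~cbad
        for i in cultures.index[mask]:
            rejects.append(
                {"table": "cultures", "row": int(i), "record_id": cultures.at[i, "culture_id"], "reason": reason}
            )
        cbad |= mask

    _reject_cultures(cultures["ordered_at"].isna(), "unparseable ordered_at timestamp")
    _reject_cultures(~cultures["result"].isin(RESULTS), "unknown result")
    _reject_cultures(
        (cultures["result"] == "no_growth") & (cultures["organism"].str.strip() != ""),
        "organism present for no-growth result",
    )
    _reject_cultures(
        (cultures["result"] == "growth") & (cultures["organism"].str.strip() == ""),
        "missing organism for growth result",
    )
    flag_ok = cultures["exclusion_flags"].map(
        lambda s: all(tok in EXCLUSION_FLAGS for tok in s.split(";") if tok)
    )
    _reject_cultures(~flag_ok, "unknown exclusion flag")
    _reject_cultures(cultures["culture_id"].duplicated(keep="first"), "duplicate culture_id")

    # linkage: every culture must land inside its visit's stay
    vmap = visits.set_index("visit_id")
    known = cultures["visit_id"].isin(vmap.index)
    _reject_cultures(~known, "unknown visit_id")
    linked = cultures["visit_id"].where(known)
    arr = linked.map(vmap["arrival"])
    dep = linked.map(vmap["departure"])
    outside = known & ((cultures["ordered_at"] < arr) | (cultures["ordered_at"] > dep))
    _reject_cultures(outside, "culture outside visit window")

    cultures = cultures.loc[~cbad].reset_index(drop=True)
    cultures["exclusion_flags"] = cultures["exclusion_flags"].map(
        lambda s: ";".join(tok for tok in s.split(";") if tok)
    )
    cultures["organism"] = cultures["organism"].str.strip()

    rejects_df = pd.DataFrame(rejects, columns=_REJECT_COLUMNS)
    return visits, cultures, rejects_df


def write_tables(visits: pd.DataFrame, cultures: pd.DataFrame, visits_path, cultures_path) -> None:
    """Write the two tables in the exact dialect :func:`load_tables` reads.

    Timestamps are serialised at microsecond precision so a write/load
    round trip reproduces the in-memory records bit for bit.
    """
    v = visits.loc[:, list(VISIT_COLUMNS)].copy()
    for col in ("arrival", "departure"):
        v[col] = pd.to_datetime(v[col]).dt.strftime(TIMESTAMP_FORMAT)
    v.to_csv(visits_path, index=False, lineterminator="\n")

    c = cultures.loc[:, list(CULTURE_COLUMNS)].copy()
    c["ordered_at"] = pd.to_datetime(c["ordered_at"]).dt.strftime(TIMESTAMP_FORMAT)
    c.to_csv(cultures_path, index=False, lineterminator="\n")
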