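"""Clinical exposure-event records: model, validation, I/O and slicing.

A DR detector's statistics export yields one row per exposure event with the
acquisition date/time, body part and projection, technologist ID, exposure
index and reject information. kVp and mAs are optional because retrofit
detectors receive no generator information. Records are held in a pandas
DataFrame wrapped by :class:`ExposureDataset`, which also carries provenance:
where the rows came from and which input rows failed validation.

Vendor export column names are not standardized, so reading goes through a
:class:`Dialect` that names the delimiter, a header map onto the canonical
column names, and the date convention.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .ei import EI_SUSPECT_RANGE

__all__ = [
    "COLUMNS",
    "MANDATORY_COLUMNS",
    "Dialect",
    "ExposureRecord",
    "ExposureDataset",
    "read_records",
    "write_records",
    "filter_records",
    "monthly_partition",
]

#: Canonical column order of the in-memory table and the CSV writer.
COLUMNS = [
    "timestamp",
    "unit_id",
    "department",
    "body_part",
    "projection",
    "tech_id",
    "ei",
    "rejected",
    "reject_reason",
    "kvp",
    "mas",
]

MANDATORY_COLUMNS = ["timestamp", "unit_id", "body_part", "projection", "tech_id", "ei"]

_TRUE_STRINGS = {"true", "t", "yes", "y", "1", "rejected"}
_FALSE_STRINGS = {"false", "f", "no", "n", "0", "", "accepted"}


@dataclass(frozen=True)
class Dialect:
    """How a delimited export maps onto the canonical record columns.

    ``column_map`` maps source header names to canonical names; canonical
    headers pass through untouched. ``dayfirst`` selects day-first date
    parsing for exports using e.g. 31/01/2015.
    """

    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)
    dayfirst: bool = False


@dataclass(frozen=True)
class ExposureRecord:
    """One clinical exposure event."""

    timestamp: _dt.datetime
    unit_id: str
    body_part: str
    projection: str
    tech_id: str
    ei: int
    department: str = ""
    rejected: bool = False
    reject_reason: str | None = None
    kvp: float | None = None
    mas: float | None = None

    @property
    def suspect_ei(self) -> bool:
        lo, hi = EI_SUSPECT_RANGE
        return not lo <= self.ei <= hi


class ExposureDataset:
    """An ordered collection of exposure records with ingest provenance.

    Thin wrapper over a pandas DataFrame in canonical column order. The
    ``provenance`` dict records the source, the number of rows accepted and
    the per-row validation failures (``log``), so a monthly ingest can be
    audited. Slicing operations return new datasets that inherit provenance
    with a note appended.
    """

    def __init__(self, df: pd.DataFrame, provenance: dict | None = None):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        self._df = df.loc[:, COLUMNS].reset_index(drop=True)
        self.provenance = provenance or {"source": "<in-memory>", "log": []}

    # -- container protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[ExposureRecord]:
        for row in self._df.itertuples(index=False):
            yield ExposureRecord(
                timestamp=row.timestamp.to_pydatetime(),
                unit_id=row.unit_id,
                department=row.department if isinstance(row.department, str) else "",
                body_part=row.body_part,
                projection=row.projection,
                tech_id=row.tech_id,
                ei=int(row.ei),
                rejected=bool(row.rejected),
                reject_reason=row.reject_reason if isinstance(row.reject_reason, str) else None,
                kvp=None if pd.isna(row.kvp) else float(row.kvp),
                mas=None if pd.isna(row.mas) else float(row.mas),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExposureDataset):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying table (canonical columns; do not mutate)."""
        return self._df

    @property
    def n_suspect(self) -> int:
        lo, hi = EI_SUSPECT_RANGE
        return int((~self._df["ei"].between(lo, hi)).sum())

    def accepted(self) -> "ExposureDataset":
        """Records not flagged as rejects (the basis of all EI statistics)."""
        return filter_records(self, accepted_only=True)

    def eis(self, accepted_only: bool = True) -> np.ndarray:
        """EI values as an integer array, accepted records only by default."""
        df = self._df[~self._df["rejected"]] if accepted_only else self._df
        return df["ei"].to_numpy(dtype=np.int64)

    def _derive(self, df: pd.DataFrame, note: str) -> "ExposureDataset":
        prov = dict(self.provenance)
        prov["log"] = list(prov.get("log", [])) + [note]
        return ExposureDataset(df, prov)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "unit_id": pd.Series(dtype=object),
            "department": pd.Series(dtype=object),
            "body_part": pd.Series(dtype=object),
            "projection": pd.Series(dtype=object),
            "tech_id": pd.Series(dtype=object),
            "ei": pd.Series(dtype=np.int64),
            "rejected": pd.Series(dtype=bool),
            "reject_reason": pd.Series(dtype=object),
            "kvp": pd.Series(dtype=float),
            "mas": pd.Series(dtype=float),
        }
    )


def _parse_rejected(raw: pd.Series, log: list[str]) -> pd.Series:
    as_str = raw.astype(str).str.strip().str.lower()
    out = pd.Series(False, index=raw.index)
    out[as_str.isin(_TRUE_STRINGS)] = True
    unknown = ~as_str.isin(_TRUE_STRINGS | _FALSE_STRINGS) & raw.notna() & (as_str != "nan")
    for i in raw.index[unknown]:
        log.append(f"row {i}: unrecognized reject flag {raw[i]!r}, treated as accepted")
    return out


def read_records(path: str | Path, dialect: Dialect | None = None) -> ExposureDataset:
    """Read an exposure-event export into a validated dataset.

    Every input row either becomes a record or is dropped with a logged,
    counted validation failure (blank/unparseable EI or timestamp). Missing
    mandatory columns are fatal. The returned dataset's provenance carries
    ``n_rows``, ``n_accepted_rows``, ``n_invalid_rows`` and the failure log.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    df = df.rename(columns=dict(dialect.column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    log: list[str] = []
    n_rows = len(df)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = ""

    ts = pd.to_datetime(df["timestamp"], errors="coerce", dayfirst=dialect.dayfirst)
    ei = pd.to_numeric(df["ei"], errors="coerce")
    bad = ts.isna() | ei.isna()
    for i in df.index[bad]:
        reason = "timestamp" if pd.isna(ts[i]) else "ei"
        log.append(f"row {i + 2}: invalid {reason} ({df.loc[i, reason]!r}); row dropped")

    keep = ~bad
    out = pd.DataFrame(
        {
            "timestamp": ts[keep],
            "unit_id": df.loc[keep, "unit_id"].astype(str),
            "department": df.loc[keep, "department"].astype(str),
            "body_part": df.loc[keep, "body_part"].astype(str),
            "projection": df.loc[keep, "projection"].astype(str),
            "tech_id": df.loc[keep, "tech_id"].astype(str),
            "ei": ei[keep].round().astype(np.int64),
            "rejected": _parse_rejected(df.loc[keep, "rejected"], log),
            "reject_reason": df.loc[keep, "reject_reason"].mask(
                df.loc[keep, "reject_reason"] == "", None
            ),
            "kvp": pd.to_numeric(df.loc[keep, "kvp"], errors="coerce"),
            "mas": pd.to_numeric(df.loc[keep, "mas"], errors="coerce"),
        }
    )
    if out.empty:
        out = _empty_frame()
    provenance = {
        "source": str(path),
        "n_rows": n_rows,
        "n_accepted_rows": int(keep.sum()),
        "n_invalid_rows": int(bad.sum()),
        "log": log,
    }
    ds = ExposureDataset(out, provenance)
    lo, hi = EI_SUSPECT_RANGE
    n_suspect = ds.n_suspect
    if n_suspect:
        log.append(f"{n_suspect} records with EI outside [{lo:g}, {hi:g}] flagged suspect")
    return ds


def write_records(ds: ExposureDataset, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write a dataset as delimited text; round-trips with :func:`read_records`."""
    dialect = dialect or Dialect()
    out = ds.df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, sep=dialect.delimiter, index=False)


def filter_records(
    ds: ExposureDataset,
    unit: str | None = None,
    body_part: str | None = None,
    date_range: tuple | None = None,
    accepted_only: bool = False,
) -> ExposureDataset:
    """Subset a dataset; predicates compose and an empty result is legal.

    ``date_range`` is an inclusive (start, end) pair of anything
    ``pd.Timestamp`` accepts.
    """
    df = ds.df
    mask = pd.Series(True, index=df.index)
    if unit is not None:
        mask &= df["unit_id"] == unit
    if body_part is not None:
        mask &= df["body_part"] == body_part
    if date_range is not None:
        start, end = (pd.Timestamp(d) for d in date_range)
        mask &= df["timestamp"].between(start, end)
    if accepted_only:
        mask &= ~df["rejected"]
    note = f"filter(unit={unit!r}, body_part={body_part!r}, date_range={date_range!r}, accepted_only={accepted_only})"
    return ds._derive(df[mask], note)


def monthly_partition(ds: ExposureDataset) -> dict[pd.Period, ExposureDataset]:
    """Partition a dataset by calendar month (exhaustive and disjoint).

    Returns an ordered mapping from ``pd.Period('M')`` to the records of that
    month; months with no records do not appear.
    """
    df = ds.df
    if df["timestamp"].isna().any():
        raise ValueError("monthly_partition requires valid timestamps on every record")
    months = df["timestamp"].dt.to_period("M")
    return {
        month: ds._derive(sub, f"month={month}")
        for month, sub in sorted(df.groupby(months, sort=True), key=lambda kv: kv[0])
        if len(sub)
    }
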