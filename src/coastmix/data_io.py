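"""Core data model and CSV I/O for isotope tables.

Three tables drive the workflow:

* ``sources.csv`` — food-source measurements (one row per specimen/tissue),
* ``consumers.csv`` — consumer bone-collagen records,
* ``atmosphere.csv`` — yearly mean atmospheric CO2 d13C values.

All delta values are per mil (permil): d13C vs VPDB, d15N vs AIR. Reading is
strict: rows violating the physical-range invariants are rejected and reported
with their row numbers rather than silently dropped or kept.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

GROUPS = (
    "terrestrial_plant",
    "terrestrial_vertebrate",
    "marine_invertebrate",
    "marine_vertebrate",
)

GROUP_HABITAT = {
    "terrestrial_plant": "terrestrial",
    "terrestrial_vertebrate": "terrestrial",
    "marine_invertebrate": "marine",
    "marine_vertebrate": "marine",
}

#: Sentinel for samples of pre-industrial / archaeological age (no Suess correction).
ARCHAEOLOGICAL = "archaeological"

D13C_RANGE = (-40.0, 0.0)
D15N_RANGE = (-10.0, 30.0)


@dataclass
class IsotopeSample:
    """A single food-source isotope measurement."""

    sample_id: str
    taxon: str
    tissue: str
    group: str
    habitat: str
    d13C: float
    d15N: float
    pct_C: float | None = None
    pct_N: float | None = None  # may be unmeasured, e.g. for some plants
    collection_year: int | str = ARCHAEOLOGICAL


@dataclass
class ConsumerRecord:
    """One consumer's bone-collagen record.

    ``rank_by_d13C`` is assigned after load: 1..N in ascending d13C, ties broken
    by consumer_id so the ordering (used for plot/report IDs) is deterministic.
    """

    consumer_id: str
    sex: str  # M / F / unknown
    d13C: float
    d15N: float
    rank_by_d13C: int | None = None


@dataclass
class AtmosphericSeries:
    """Yearly mean atmospheric CO2 d13C (permil VPDB), one value per year."""

    years: np.ndarray
    mean_d13C_CO2: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean_d13C_CO2 = np.asarray(self.mean_d13C_CO2, dtype=float)
        if len(self.years) != len(self.mean_d13C_CO2):
            raise ValueError("years and values differ in length")
        if len(self.years) and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")

    def value(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not present in atmospheric series")
        return float(self.mean_d13C_CO2[idx])

    def __contains__(self, year: int) -> bool:
        idx = np.searchsorted(self.years, year)
        return idx < len(self.years) and self.years[idx] == year


@dataclass
class RowError:
    """A row-level validation failure with enough context to locate it."""

    row: int  # 1-based data-row number (header excluded)
    field: str
    message: str


SOURCE_COLUMNS = [
    "sample_id", "taxon", "tissue", "group", "habitat",
    "d13C", "d15N", "pct_C", "pct_N", "collection_year",
]
CONSUMER_COLUMNS = ["consumer_id", "sex", "d13C", "d15N"]
ATMOSPHERE_COLUMNS = ["year", "mean_d13C_CO2"]


class SchemaError(ValueError):
    """The table's header does not match the expected schema."""


def _check_delta(row_no: int, name: str, value, lo: float, hi: float,
                 errors: list[RowError]) -> float | None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        errors.append(RowError(row_no, name, f"not a number: {value!r}"))
        return None
    if np.isnan(v) or not (lo <= v <= hi):
        errors.append(RowError(row_no, name, f"{name}={value} outside [{lo}, {hi}]"))
        return None
    return v


def _parse_source_row(row_no: int, row: pd.Series, errors: list[RowError]) -> IsotopeSample | None:
    n_before = len(errors)
    group = str(row["group"])
    habitat = str(row["habitat"])
    if group not in GROUPS:
        errors.append(RowError(row_no, "group", f"unknown group {group!r}"))
    elif habitat != GROUP_HABITAT[group]:
        errors.append(RowError(
            row_no, "habitat",
            f"group {group} requires habitat {GROUP_HABITAT[group]}, got {habitat!r}"))
    d13C = _check_delta(row_no, "d13C", row["d13C"], *D13C_RANGE, errors=errors)
    d15N = _check_delta(row_no, "d15N", row["d15N"], *D15N_RANGE, errors=errors)

    def _pct(name: str) -> float | None:
        raw = row[name]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            return None
        v = float(raw)
        if not (0.0 < v <= 100.0):
            errors.append(RowError(row_no, name, f"{name}={v} outside (0, 100]"))
        return v

    pct_C = _pct("pct_C")
    pct_N = _pct("pct_N")
    year_raw = row["collection_year"]
    if isinstance(year_raw, str) and year_raw.strip().lower() == ARCHAEOLOGICAL:
        year: int | str = ARCHAEOLOGICAL
    else:
        try:
            year = int(float(year_raw))
        except (TypeError, ValueError):
            errors.append(RowError(row_no, "collection_year",
                                   f"expected a year or {ARCHAEOLOGICAL!r}: {year_raw!r}"))
            year = ARCHAEOLOGICAL
    if len(errors) > n_before:
        return None
    return IsotopeSample(
        sample_id=str(row["sample_id"]), taxon=str(row["taxon"]),
        tissue=str(row["tissue"]), group=group, habitat=habitat,
        d13C=d13C, d15N=d15N, pct_C=pct_C, pct_N=pct_N, collection_year=year,
    )


def _parse_consumer_row(row_no: int, row: pd.Series, errors: list[RowError]) -> ConsumerRecord | None:
    n_before = len(errors)
    sex = str(row["sex"])
    if sex not in ("M", "F", "unknown"):
        errors.append(RowError(row_no, "sex", f"sex must be M/F/unknown, got {sex!r}"))
    d13C = _check_delta(row_no, "d13C", row["d13C"], *D13C_RANGE, errors=errors)
    d15N = _check_delta(row_no, "d15N", row["d15N"], *D15N_RANGE, errors=errors)
    if len(errors) > n_before:
        return None
    return ConsumerRecord(consumer_id=str(row["consumer_id"]), sex=sex,
                          d13C=d13C, d15N=d15N)


def assign_ranks(consumers: Sequence[ConsumerRecord]) -> list[ConsumerRecord]:
    """Assign ``rank_by_d13C`` = 1..N by ascending d13C, ties by consumer_id."""
    ordered = sorted(consumers, key=lambda c: (c.d13C, c.consumer_id))
    for rank, rec in enumerate(ordered, start=1):
        rec.rank_by_d13C = rank
    return list(consumers)


def read_samples(path, schema: Literal["sources", "consumers", "atmosphere"]):
    """Read and validate a CSV table.

    Returns ``(records, errors)`` for ``sources``/``consumers`` (errors is a
    list of :class:`RowError`; only valid rows become records, and consumer
    ranks are assigned over the valid rows), or an :class:`AtmosphericSeries`
    for ``atmosphere``.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    """
    df = pd.read_csv(path, dtype={"collection_year": str} if schema == "sources" else None)
    required = {"sources": SOURCE_COLUMNS, "consumers": CONSUMER_COLUMNS,
                "atmosphere": ATMOSPHERE_COLUMNS}[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    if schema == "atmosphere":
        return AtmosphericSeries(df["year"].to_numpy(), df["mean_d13C_CO2"].to_numpy())

    errors: list[RowError] = []
    records = []
    parse = _parse_source_row if schema == "sources" else _parse_consumer_row
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        rec = parse(i, row, errors)
        if rec is not None:
            records.append(rec)
    if schema == "consumers":
        assign_ranks(records)
    return records, errors


def write_samples(records: Iterable[IsotopeSample | ConsumerRecord], path) -> None:
    """Write records back to CSV (canonical column order, UTF-8, '.' decimal)."""
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        raise ValueError("nothing to write")
    df = pd.DataFrame(rows)
    if "rank_by_d13C" in df.columns:
        df = df.drop(columns=["rank_by_d13C"])
    df.to_csv(path, index=False)


def summarize_range(records: Sequence, field_name: Literal["d13C", "d15N"]):
    """(min, max, width) of a delta field across records; width to 1 decimal.

    The width is the headline span statistic (e.g. consumer d13C spanning
    several permil indicates strongly contrasting diets in the group).
    """
    if not records:
        raise ValueError("empty collection")
    values = [getattr(r, field_name) for r in records]
    lo, hi = min(values), max(values)
    return lo, hi, round(hi - lo, 1)


def group_counts(samples: Sequence[IsotopeSample]) -> dict[str, int]:
    counts = {g: 0 for g in GROUPS}
    for s in samples:
        counts[s.group] += 1
    return counts
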