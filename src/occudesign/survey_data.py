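"""Ingestion, validation, daily binning and covariate standardisation.

Raw survey data arrive as long-format tables: one row per deployment unit
per day (cameras), per recording day (acoustic recorders), or per flight
(drones).  The analysis-ready object is a :class:`DetectionHistory` — one
row per site-occasion with a binary outcome and (optionally z-scored)
weather covariates.  Detections are collapsed into 24-h bins: a site-day
counts as a detection for cameras if any of the site's cameras produced a
validated photo, and for acoustic recorders if any call was validated that
day; each completed drone flight is its own occasion.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METHODS = ("acoustic", "drone", "camera")

#: covariate column -> short name used for z-scored columns
COVARIATES = ("temp_max", "rel_humidity", "rain")

DEFAULT_SCHEMA: dict[str, str] = {
    "site": "site",
    "method": "method",
    "date": "date",
    "detected": "detected",
    "unit": "unit",
    "temp_max": "temp_max",
    "rel_humidity": "rel_humidity",
    "rain": "rain",
}

REQUIRED_FIELDS = ("site", "method", "date", "detected")


class SurveyDataError(ValueError):
    """Base class for survey-table validation failures."""


class SchemaError(SurveyDataError):
    """A required column is missing from the input table."""


class RowParseError(SurveyDataError):
    """One or more rows could not be parsed; offending rows are listed."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__(
            "malformed rows in survey table:\n  " + "\n  ".join(self.messages)
        )


class ConstantCovariateError(SurveyDataError):
    """A covariate has no variation and cannot be z-scored."""


@dataclass(frozen=True)
class SurveyRecord:
    """One raw survey row: a unit-day (or flight) outcome with weather."""

    site_id: str
    method: str
    occasion_date: dt.date
    detected: int
    unit_id: str | None = None
    temp_max: float | None = None
    rel_humidity: float | None = None
    rain: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise SurveyDataError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        if self.detected not in (0, 1):
            raise SurveyDataError(
                f"detected must be 0 or 1, got {self.detected!r}"
            )


@dataclass
class CovariateScaler:
    """Per-covariate mean/sd used for z-scoring (sample sd, ddof=1)."""

    means: dict[str, float]
    sds: dict[str, float]
    ddof: int = 1

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not np.isfinite(sd) or sd <= 0:
                raise ConstantCovariateError(
                    f"covariate {name!r} has non-positive sd {sd}"
                )

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.means)

    def transform(self, values: Mapping[str, float] | pd.DataFrame):
        if isinstance(values, pd.DataFrame):
            out = values.copy()
            for name in self.covariates:
                if name in out:
                    out[name] = (out[name] - self.means[name]) / self.sds[name]
            return out
        return {
            name: (values[name] - self.means[name]) / self.sds[name]
            for name in self.covariates
            if name in values
        }

    def inverse(self, values: Mapping[str, float] | pd.DataFrame):
        if isinstance(values, pd.DataFrame):
            out = values.copy()
            for name in self.covariates:
                if name in out:
                    out[name] = out[name] * self.sds[name] + self.means[name]
            return out
        return {
            name: values[name] * self.sds[name] + self.means[name]
            for name in self.covariates
            if name in values
        }

    def to_json(self, path) -> None:
        payload = {"means": self.means, "sds": self.sds, "ddof": self.ddof}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CovariateScaler":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class DetectionHistory:
    """Binned site x occasion detection data.

    ``frame`` has one row per surveyed occasion with columns
    ``site, method, date, y`` plus raw covariate columns and, after
    :func:`zscore`, ``<cov>_z`` columns.  Occasions that were not surveyed
    simply have no row (the NA convention); rows with missing weather keep
    NaN covariates and are excluded from covariate-model fits only.
    """

    frame: pd.DataFrame
    scaler: CovariateScaler | None = None

    def __post_init__(self) -> None:
        required = {"site", "method", "date", "y"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SurveyDataError(f"history frame missing columns {sorted(missing)}")
        if not self.frame["y"].isin((0, 1)).all():
            raise SurveyDataError("history outcomes must be binary")

    @property
    def sites(self) -> np.ndarray:
        return self.frame["site"].unique()

    @property
    def n_sites(self) -> int:
        return int(self.frame["site"].nunique())

    @property
    def n_occasions(self) -> int:
        return len(self.frame)

    def occasions_per_method(self) -> pd.Series:
        return self.frame["method"].value_counts()

    def data_hash(self) -> int:
        cols = self.frame[["site", "method", "y"]]
        return int(pd.util.hash_pandas_object(cols, index=False).sum()) & 0x7FFFFFFF

    def to_records(self) -> list[SurveyRecord]:
        """Induced raw-record view (one record per occasion).

        Drone occasions on the same site-date are distinguished by a
        synthetic ``unit_id`` so that re-binning is the identity.
        """
        records = []
        flight_counter: dict[tuple, int] = {}
        for row in self.frame.itertuples(index=False):
            unit = None
            if row.method == "drone":
                key = (row.site, row.date)
                flight_counter[key] = flight_counter.get(key, 0) + 1
                unit = f"flight{flight_counter[key]}"
            records.append(
                SurveyRecord(
                    site_id=row.site,
                    method=row.method,
                    occasion_date=row.date,
                    detected=int(row.y),
                    unit_id=unit,
                    temp_max=_get(row, "temp_max"),
                    rel_humidity=_get(row, "rel_humidity"),
                    rain=_get(row, "rain"),
                )
            )
        return records

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, scaler: CovariateScaler | None = None) -> "DetectionHistory":
        frame = pd.read_csv(path, parse_dates=["date"])
        frame["date"] = frame["date"].dt.date
        return cls(frame=frame, scaler=scaler)


def _get(row, name):
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return float(val)


def read_survey_table(path, schema: Mapping[str, str] | None = None) -> list[SurveyRecord]:
    """Read a long-format survey CSV into validated :class:`SurveyRecord`\\ s.

    ``schema`` maps canonical field names (``site``, ``method``, ``date``,
    ``detected``, optionally ``unit``, ``temp_max``, ``rel_humidity``,
    ``rain``) to the column names actually present in the file.  Raises
    :class:`SchemaError` if a required column is absent and
    :class:`RowParseError` listing row numbers (1-based data rows) for
    malformed values.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name in REQUIRED_FIELDS:
        if colmap[name] not in raw.columns:
            raise SchemaError(
                f"required column {colmap[name]!r} (field {name!r}) not in "
                f"{sorted(raw.columns)}"
            )

    records: list[SurveyRecord] = []
    errors: list[str] = []
    for idx, row in enumerate(raw.itertuples(index=False), start=1):
        rowd = dict(zip(raw.columns, row))
        try:
            records.append(_parse_row(rowd, colmap))
        except SurveyDataError as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise RowParseError(errors)
    return records


def _parse_row(rowd: Mapping[str, str], colmap: Mapping[str, str]) -> SurveyRecord:
    def cell(name):
        col = colmap.get(name)
        if col is None or col not in rowd:
            return ""
        return str(rowd[col]).strip()

    date_text = cell("date")
    try:
        date = dt.date.fromisoformat(date_text)
    except ValueError:
        raise SurveyDataError(f"unparseable date {date_text!r}") from None

    det_text = cell("detected")
    if det_text not in ("0", "1"):
        raise SurveyDataError(f"detected must be 0 or 1, got {det_text!r}")

    def number(name):
        text = cell(name)
        if text == "" or text.upper() in ("NA", "NAN"):
            return None
        try:
            value = float(text)
        except ValueError:
            raise SurveyDataError(f"unparseable {name} value {text!r}") from None
        if not np.isfinite(value):
            raise SurveyDataError(f"non-finite {name} value {text!r}")
        return value

    unit = cell("unit") or None
    return SurveyRecord(
        site_id=cell("site"),
        method=cell("method"),
        occasion_date=date,
        detected=int(det_text),
        unit_id=unit,
        temp_max=number("temp_max"),
        rel_humidity=number("rel_humidity"),
        rain=number("rain"),
    )


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows)
    return frame.rename(
        columns={"site_id": "site", "occasion_date": "date", "unit_id": "unit",
                 "detected": "detected"}
    )


def bin_daily(records) -> DetectionHistory:
    """Collapse raw records into 24-h occasions.

    Camera and acoustic records on the same (site, date) collapse to one
    occasion whose outcome is the logical OR across units; every drone
    flight stays its own occasion.  Conflicting weather values for the same
    (site, date) raise an error.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        records = list(records)
        if not records:
            raise SurveyDataError("no records to bin")
        frame = records_to_frame(records)
    if frame.empty:
        raise SurveyDataError("no records to bin")

    covs = [c for c in COVARIATES if c in frame.columns]
    # weather is a site-day property: it may not differ between records
    if covs:
        per_day = frame.groupby(["site", "date"])[covs].nunique(dropna=True)
        bad = per_day[(per_day > 1).any(axis=1)]
        if len(bad):
            keys = ", ".join(f"{s}@{d}" for s, d in bad.index[:5])
            raise SurveyDataError(
                f"conflicting covariate values for site-dates: {keys}"
            )

    pooled = frame[frame["method"].isin(("acoustic", "camera"))]
    flights = frame[frame["method"] == "drone"]

    parts = []
    if len(pooled):
        agg = {"detected": "max", **{c: "first" for c in covs}}
        parts.append(
            pooled.groupby(["site", "method", "date"], as_index=False).agg(agg)
        )
    if len(flights):
        cols = ["site", "method", "date", "detected"] + covs
        parts.append(flights[cols].copy())
    binned = pd.concat(parts, ignore_index=True)
    binned = binned.rename(columns={"detected": "y"})
    binned["y"] = binned["y"].astype(int)
    binned = binned.sort_values(["site", "date", "method"], kind="stable")
    binned = binned.reset_index(drop=True)
    order = ["site", "method", "date", "y"] + covs
    return DetectionHistory(frame=binned[order])


def zscore(
    history: DetectionHistory, covariates: Sequence[str] | None = None
) -> tuple[DetectionHistory, CovariateScaler]:
    """Standardise covariates over all non-missing occasions (pooled across
    methods) and attach ``<cov>_z`` columns plus the fitted scaler."""
    frame = history.frame.copy()
    if covariates is None:
        covariates = [c for c in COVARIATES if c in frame.columns
                      and frame[c].notna().any()]
    means, sds = {}, {}
    for cov in covariates:
        values = frame[cov].astype(float)
        if values.dropna().nunique() < 2:
            raise ConstantCovariateError(
                f"covariate {cov!r} is constant; cannot z-score"
            )
        means[cov] = float(values.mean())
        sds[cov] = float(values.std(ddof=1))
    scaler = CovariateScaler(means=means, sds=sds)
    for cov in covariates:
        frame[f"{cov}_z"] = (frame[cov].astype(float) - means[cov]) / sds[cov]
    return DetectionHistory(frame=frame, scaler=scaler), scaler
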