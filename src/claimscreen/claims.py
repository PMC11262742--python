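"""Daily billing-claims data model, validation, delimited I/O and per-centre aggregation.

A claims dataset is a table with one row per centre-day:

    centre_id   opaque string identifier of the test centre
    category    one of ``pharmacy``, ``practice`` (doctor's/dentist's office),
                ``private`` (private test centre)
    date        calendar date of testing (ISO 8601)
    n_tests     number of antigen tests invoiced for that day
    n_positive  number of positive results among them

Days with ``n_tests == 0`` carry no positivity or digit information: they are
excluded from digit histograms, from the mean daily volume and from the
active-day count used for screen eligibility.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical test-centre categories (stratification variable for the volume
#: screen and fixed effect in the positivity model).
CATEGORIES = ("pharmacy", "practice", "private")

_CATEGORY_ALIASES = {
    "pharmacy": "pharmacy",
    "apotheke": "pharmacy",
    "practice": "practice",
    "doctor": "practice",
    "doctors": "practice",
    "doctor's or dentist's office": "practice",
    "doctors or dentists office": "practice",
    "dentist": "practice",
    "office": "practice",
    "private": "private",
    "private test centre": "private",
    "private test center": "private",
}

CLAIM_COLUMNS = ["centre_id", "category", "date", "n_tests", "n_positive"]

LEAD_COLUMNS = [f"lead_{d}" for d in range(1, 10)]
LAST_COLUMNS = [f"last_{d}" for d in range(10)]


class ClaimsValidationError(ValueError):
    """Raised when a claims table violates the data contract.

    ``errors`` is a list of human-readable messages, each naming the offending
    row (1-based, counting the header as row 1) and field.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} claims validation error(s): {preview}{more}")


@dataclasses.dataclass(frozen=True)
class StudyWindow:
    """Closed observation window with 1-based 7-day week indexing.

    Weeks are consecutive 7-day blocks anchored at ``start`` (not ISO weeks),
    so the pilot window 2021-04-08..2022-08-28 spans 508 days = 73 weeks.
    """

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def n_weeks(self) -> int:
        return (self.n_days + 6) // 7

    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]

    def week_index(self, dates) -> np.ndarray:
        """1-based week number of each date; raises if outside the window."""
        d = pd.to_datetime(pd.Series(dates)).dt.date
        offsets = np.array([(x - self.start).days for x in d])
        if (offsets < 0).any() or (offsets >= self.n_days).any():
            bad = d[(offsets < 0) | (offsets >= self.n_days)].iloc[0]
            raise ValueError(f"date {bad} outside study window {self.start}..{self.end}")
        return offsets // 7 + 1


#: Window of the original pilot (73 calendar weeks, 508 days).
DEFAULT_WINDOW = StudyWindow(dt.date(2021, 4, 8), dt.date(2022, 8, 28))


def normalise_category(value: str) -> str:
    key = str(value).strip().lower()
    if key in _CATEGORY_ALIASES:
        return _CATEGORY_ALIASES[key]
    raise ValueError(f"unknown category {value!r}")


def leading_digit(n):
    """First decimal digit of a positive integer (vectorised)."""
    arr = np.asarray(n)
    if (arr <= 0).any():
        raise ValueError("leading_digit requires n >= 1")
    p = np.floor(np.log10(arr)).astype(np.int64)
    # log10 of exact powers of 10 can land a hair below the integer
    p = np.where(10.0 ** (p + 1) <= arr, p + 1, p)
    out = (arr // 10**p).astype(np.int64)
    return out if out.ndim else int(out)


def last_digit(n):
    """Final decimal digit of a positive integer (vectorised)."""
    arr = np.asarray(n)
    if (arr <= 0).any():
        raise ValueError("last_digit requires n >= 1")
    out = (arr % 10).astype(np.int64)
    return out if out.ndim else int(out)


def validate_claims(df: pd.DataFrame, *, row_offset: int = 2) -> pd.DataFrame:
    """Validate and normalise an in-memory claims table.

    Returns a fresh DataFrame with canonical dtypes: string centre ids,
    canonical category labels, ``datetime.date`` dates, integer counts.
    ``row_offset`` is the file row number of the first data row (2 when the
    table came from a file with a header).
    """
    errors: list[str] = []
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsValidationError([f"missing column(s): {', '.join(missing)}"])

    out = df.loc[:, CLAIM_COLUMNS].copy().reset_index(drop=True)
    out["centre_id"] = out["centre_id"].astype(str)

    cats = []
    for i, v in enumerate(out["category"]):
        try:
            cats.append(normalise_category(v))
        except ValueError:
            errors.append(f"unknown category {v!r}, row {i + row_offset}")
            cats.append(None)
    out["category"] = cats

    dates = []
    for i, v in enumerate(out["date"]):
        if isinstance(v, dt.datetime):
            dates.append(v.date())
            continue
        if isinstance(v, dt.date):
            dates.append(v)
            continue
        try:
            dates.append(dt.date.fromisoformat(str(v).strip()))
        except ValueError:
            errors.append(f"malformed date {v!r}, row {i + row_offset}")
            dates.append(None)
    out["date"] = dates

    for col in ("n_tests", "n_positive"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(f"{col} must be a non-negative integer, row {i + row_offset}")
        out[col] = vals.fillna(0).astype(np.int64)

    if not errors:
        over = (out["n_positive"] > out["n_tests"]).to_numpy()
        for i in np.flatnonzero(over):
            errors.append(f"positives exceed tests, row {i + row_offset}")

        # duplicates are a hard error: repeated centre-day rows in billing
        # data are themselves a fraud signal and must surface, not be summed
        for i in np.flatnonzero(out.duplicated(subset=["centre_id", "date"]).to_numpy()):
            errors.append(
                f"duplicate (centre_id, date) = ({out['centre_id'][i]}, {out['date'][i]}), row {i + row_offset}"
            )

        ncat = out.groupby("centre_id")["category"].nunique()
        for cid in ncat.index[ncat > 1]:
            errors.append(f"centre {cid} appears under multiple categories")

    if errors:
        raise ClaimsValidationError(errors)
    return out


def read_claims(path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited claims file (header required, UTF-8)."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return validate_claims(raw, row_offset=2)


def write_claims(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    out = df.loc[:, CLAIM_COLUMNS].copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, sep=sep, index=False)


def read_labels(path, *, sep: str = ",") -> pd.DataFrame:
    """Read the optional per-centre label file.

    Columns: ``centre_id``, ``suspected_conventional`` (0/1/NA — NA means the
    supervising authority supplied no suspicion information, as for
    pharmacies in the pilot), ``corroborated`` (0/1/NA — NA = not
    investigated).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    need = ["centre_id", "suspected_conventional", "corroborated"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise ClaimsValidationError([f"labels file missing column(s): {', '.join(missing)}"])
    out = raw.loc[:, need].copy()
    out["centre_id"] = out["centre_id"].astype(str)
    for col in ("suspected_conventional", "corroborated"):
        vals = out[col].astype(str).str.strip().str.upper()
        mapped = vals.map({"0": 0, "1": 1, "NA": pd.NA, "": pd.NA})
        if mapped.isna().to_numpy().sum() != vals.isin(["NA", ""]).sum():
            bad = vals[~vals.isin(["0", "1", "NA", ""])].iloc[0]
            raise ClaimsValidationError([f"labels column {col}: invalid value {bad!r}"])
        out[col] = mapped.astype("Int64")
    if out["centre_id"].duplicated().any():
        dup = out["centre_id"][out["centre_id"].duplicated()].iloc[0]
        raise ClaimsValidationError([f"duplicate centre_id {dup!r} in labels file"])
    return out


def write_labels(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    out = df.loc[:, ["centre_id", "suspected_conventional", "corroborated"]].copy()
    for col in ("suspected_conventional", "corroborated"):
        out[col] = out[col].astype("Int64").astype(object)
        out[col] = out[col].where(out[col].notna(), "NA")
    out.to_csv(path, sep=sep, index=False)


def summarise_centres(records: pd.DataFrame) -> pd.DataFrame:
    """Per-centre aggregates feeding the volume and digit screens.

    Returns a DataFrame indexed by ``centre_id`` with columns ``category``,
    ``n_active_days`` (days with at least one invoiced test),
    ``mean_daily_tests`` (over active days), ``total_tests``,
    ``total_positive``, leading-digit counts ``lead_1..lead_9`` and
    last-digit counts ``last_0..last_9`` of the daily test numbers.
    Order of input rows is immaterial.
    """
    df = records
    centres = df.groupby("centre_id", sort=True)
    cat = centres["category"].first()
    total_tests = centres["n_tests"].sum()
    total_positive = centres["n_positive"].sum()

    active = df[df["n_tests"] >= 1]
    ag = active.groupby("centre_id", sort=True)
    n_active = ag.size().reindex(cat.index, fill_value=0)
    mean_daily = ag["n_tests"].mean().reindex(cat.index)

    out = pd.DataFrame(
        {
            "category": cat,
            "n_active_days": n_active.astype(np.int64),
            "mean_daily_tests": mean_daily,
            "total_tests": total_tests.astype(np.int64),
            "total_positive": total_positive.astype(np.int64),
        }
    )

    lead = pd.crosstab(active["centre_id"], leading_digit(active["n_tests"].to_numpy()))
    last = pd.crosstab(active["centre_id"], last_digit(active["n_tests"].to_numpy()))
    for d in range(1, 10):
        col = lead[d] if d in lead.columns else 0
        out[f"lead_{d}"] = pd.Series(col, index=lead.index).reindex(out.index, fill_value=0).astype(np.int64)
    for d in range(10):
        col = last[d] if d in last.columns else 0
        out[f"last_{d}"] = pd.Series(col, index=last.index).reindex(out.index, fill_value=0).astype(np.int64)
    out.index.name = "centre_id"
    return out
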