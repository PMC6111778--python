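"""GP prescription record model, validation and delimited-text I/O.

One record is one prescribed item (drug, laboratory test, referral, ...)
carrying an ICD-9-CM diagnosis code.  Files are UTF-8 CSV with the header

    patient_id,age,sex,date,rx_type,rx_code,icd9_code

dates in ISO 8601, ``sex`` in {M, F} and ``rx_type`` one of the six
prescription types.  The in-memory working representation is a pandas
DataFrame with those columns (``date`` as datetime64, ``age`` as integer);
:class:`PrescriptionRecord` offers a typed row-level view.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .icd9 import ICD9_RE

COLUMNS = ("patient_id", "age", "sex", "date", "rx_type", "rx_code", "icd9_code")

RX_TYPES = ("Drug", "Laboratory Test", "Procedures", "Rehab", "Referral", "Hospital")

SEXES = ("M", "F")

MIN_AGE = 15  # primary care below 15 is handled by paediatricians


class SchemaError(ValueError):
    """Input file lacks a required column."""


@dataclass(frozen=True)
class ObservationWindow:
    """Closed calendar interval within which records are considered valid."""

    start: dt.date = dt.date(2002, 1, 1)
    end: dt.date = dt.date(2013, 12, 31)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def years(self) -> float:
        return self.days / 365.25

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


DEFAULT_WINDOW = ObservationWindow()


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription event."""

    patient_id: str
    age: int
    sex: str
    date: dt.date
    rx_type: str
    rx_code: str
    icd9_code: str


@dataclass
class ValidationReport:
    """Accounting of input rows kept vs rejected, by reason."""

    n_input: int = 0
    n_rejected: int = 0
    rejection_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_rejected

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
            "rejection_reasons": dict(self.rejection_reasons),
        }


def validate_frame(
    df: pd.DataFrame, window: ObservationWindow = DEFAULT_WINDOW
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate a raw string-typed record frame.

    Returns the typed frame of rows passing every check and a
    :class:`ValidationReport` in which each rejected row is counted once,
    under the first failing check (checked in the order missing_field,
    bad_sex, bad_rx_type, bad_icd9, bad_age, bad_date, out_of_window).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].astype(str)
    n_input = len(df)

    age = pd.to_numeric(df["age"], errors="coerce")
    date = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")

    checks = [
        ("missing_field", df.isin(["", "nan", "None"]).any(axis=1)),
        ("bad_sex", ~df["sex"].isin(SEXES)),
        ("bad_rx_type", ~df["rx_type"].isin(RX_TYPES)),
        ("bad_icd9", ~df["icd9_code"].str.match(ICD9_RE)),
        ("bad_age", age.isna() | (age != age.round()) | (age < MIN_AGE)),
        ("bad_date", date.isna()),
        (
            "out_of_window",
            date.notna()
            & ((date < pd.Timestamp(window.start)) | (date > pd.Timestamp(window.end))),
        ),
    ]
    reason = pd.Series(pd.NA, index=df.index, dtype=object)
    for name, mask in checks:
        reason = reason.mask(reason.isna() & mask, name)

    rejected = reason.notna()
    report = ValidationReport(
        n_input=n_input,
        n_rejected=int(rejected.sum()),
        rejection_reasons=reason[rejected].value_counts().to_dict(),
    )
    kept = df[~rejected].copy()
    kept["age"] = age[~rejected].astype(int)
    kept["date"] = date[~rejected]
    return kept.reset_index(drop=True), report


def parse_records(
    path, window: ObservationWindow = DEFAULT_WINDOW
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a prescription CSV, returning (validated frame, report).

    Missing files and missing columns are fatal; malformed rows are dropped
    and accounted for in the report.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_frame(raw, window=window)


def write_records(df: pd.DataFrame, path) -> None:
    """Write a validated record frame as canonical CSV (ISO dates)."""
    out = df.loc[:, list(COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[PrescriptionRecord]:
    """Typed row-level view of a validated frame."""
    dates = pd.to_datetime(df["date"]).dt.date
    return [
        PrescriptionRecord(
            patient_id=str(r.patient_id),
            age=int(r.age),
            sex=str(r.sex),
            date=d,
            rx_type=str(r.rx_type),
            rx_code=str(r.rx_code),
            icd9_code=str(r.icd9_code),
        )
        for r, d in zip(df.itertuples(index=False), dates)
    ]


def records_to_frame(records: list[PrescriptionRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(COLUMNS))
    if len(df):
        df["date"] = pd.to_datetime(df["date"])
        df["age"] = df["age"].astype(int)
    return df
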