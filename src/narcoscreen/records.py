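"""Prescription-record data model, hospital attributes and safe-use rules.

The unit of observation is one dispensing event: a hospital issues one
prescription of a controlled drug (appetite suppressant, zolpidem or
propofol) to one patient on one date, at a daily dose for a number of days
supplied.  Korea's Ministry of Food and Drug Safety publishes per-drug
Standards for Safe Use of Medical Narcotics (SSUN) — dose, duration and
frequency limits — which downstream modules use to select the exceedance
subset that the network analysis operates on.

Hospitals carry two categorical attributes used for stratified reporting:
a size category (10 codes, clinics ``CL`` being by far the most common
institution type) and an administrative region (16 codes covering the
country's provinces and metropolitan cities).
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class NarcoscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(NarcoscreenError):
    """Invalid configuration: missing columns, unknown drugs, bad profiles."""


class ValidationError(NarcoscreenError):
    """Data violates a model invariant."""


class ConvergenceError(NarcoscreenError):
    """An iterative numerical routine failed to converge."""


# --------------------------------------------------------------------------
# Vocabularies
# --------------------------------------------------------------------------

class Drug(enum.Enum):
    """The three narcotic classes under SSUN-based surveillance."""

    APPETITE_SUPPRESSANT = "appetite_suppressant"
    ZOLPIDEM = "zolpidem"
    PROPOFOL = "propofol"

    @classmethod
    def from_token(cls, token: str) -> "Drug":
        t = str(token).strip().lower()
        for drug in cls:
            if t in (drug.value, drug.name.lower()):
                return drug
        raise ValidationError(
            f"unknown drug {token!r}; expected one of "
            f"{[d.value for d in cls]}"
        )


#: Hospital size-category codes: general hospital, psychiatric hospital,
#: oriental-medicine hospital, convalescent hospital, dental clinic, public
#: health center / clinic / unit, hospital, clinic.
SIZE_CATEGORIES: tuple[str, ...] = (
    "GH", "PH", "OMH", "CH", "DC", "PHCE", "PHCL", "PHU", "HO", "CL",
)

#: 16 region codes: Seoul, Pusan, Taegu, Inchon, Kwangju, Taejon, Ulsan,
#: Kyonggi, Kangwon, Chungbuk, Chungnam, Chonbuk, Chonnam, Kyongbuk,
#: Kyongnam, Cheju.
REGIONS: tuple[str, ...] = (
    "SEL", "PUS", "TAE", "INC", "KWJ", "TAJ", "USN", "KYG",
    "KAW", "CCB", "CCN", "CLB", "CLN", "KSB", "KSN", "CHJ",
)

#: Fallback category for hospitals missing from the attribute sidecar.
UNKNOWN: str = "UNKNOWN"

#: Study window of the source reporting system extraction (inclusive).
DEFAULT_STUDY_WINDOW: tuple[dt.date, dt.date] = (
    dt.date(2019, 7, 1),
    dt.date(2021, 6, 30),
)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event linking a patient to a hospital.

    Parameters
    ----------
    patient_id, hospital_id
        Opaque tokens in disjoint namespaces (canonical files use ``P-``
        and ``H-`` prefixes).
    drug
        One of the three surveilled drug classes.
    date
        Dispensing date.
    daily_dose_mg
        Prescribed daily dose in milligrams, strictly positive.
    days_supplied
        Number of days covered by the prescription, at least 1.
    """

    patient_id: str
    hospital_id: str
    drug: Drug
    date: dt.date
    daily_dose_mg: float
    days_supplied: int

    def __post_init__(self) -> None:
        if not self.patient_id or not self.hospital_id:
            raise ValidationError("patient_id and hospital_id must be nonempty")
        if not isinstance(self.drug, Drug):
            raise ValidationError(f"drug must be a Drug, got {self.drug!r}")
        if not isinstance(self.date, dt.date):
            raise ValidationError(f"date must be a datetime.date, got {self.date!r}")
        if not self.daily_dose_mg > 0:
            raise ValidationError(
                f"daily_dose_mg must be > 0, got {self.daily_dose_mg}"
            )
        if int(self.days_supplied) != self.days_supplied or self.days_supplied < 1:
            raise ValidationError(
                f"days_supplied must be an integer >= 1, got {self.days_supplied}"
            )


@dataclass(frozen=True)
class HospitalAttributes:
    """Sidecar attributes of one hospital: size category and region."""

    hospital_id: str
    size_category: str
    region: str

    def __post_init__(self) -> None:
        if not self.hospital_id:
            raise ValidationError("hospital_id must be nonempty")
        if self.size_category not in SIZE_CATEGORIES + (UNKNOWN,):
            raise ValidationError(
                f"unknown size_category {self.size_category!r}"
            )
        if self.region not in REGIONS + (UNKNOWN,):
            raise ValidationError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class SSUNRule:
    """Per-drug safe-use limits; ``None`` means the axis is unlimited.

    ``max_daily_dose_mg`` caps the dose of a single prescription,
    ``max_episode_days`` the total days supplied within one treatment
    episode, ``max_cumulative_days`` the days supplied within any rolling
    90-day window, and ``max_events_per_30_days`` the number of dispensing
    events within any rolling 30-day window.
    """

    drug: Drug
    max_daily_dose_mg: float | None = None
    max_episode_days: int | None = None
    max_cumulative_days: int | None = None
    max_events_per_30_days: int | None = None

    def __post_init__(self) -> None:
        for name in ("max_daily_dose_mg", "max_episode_days",
                     "max_cumulative_days", "max_events_per_30_days"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive or None, got {v}")


def default_ssun_rules() -> dict[Drug, SSUNRule]:
    """The published SSUN limits for the three drugs.

    Appetite suppressants: single treatment episode at most four weeks
    (28 days) and at most three months (90 days) cumulatively.  Zolpidem:
    at most 10 mg/day and an episode of at most four weeks.  Propofol: at
    most one administration per month (rolling 30-day window).
    """
    return {
        Drug.APPETITE_SUPPRESSANT: SSUNRule(
            Drug.APPETITE_SUPPRESSANT, max_episode_days=28, max_cumulative_days=90
        ),
        Drug.ZOLPIDEM: SSUNRule(
            Drug.ZOLPIDEM, max_daily_dose_mg=10.0, max_episode_days=28
        ),
        Drug.PROPOFOL: SSUNRule(Drug.PROPOFOL, max_events_per_30_days=1),
    }


# --------------------------------------------------------------------------
# Record I/O (delimited text, canonical dialect: comma, ISO dates)
# --------------------------------------------------------------------------

RECORD_FIELDS: tuple[str, ...] = (
    "patient_id", "hospital_id", "drug", "date", "daily_dose_mg", "days_supplied",
)

ATTRIBUTE_FIELDS: tuple[str, ...] = ("hospital_id", "size_category", "region")


@dataclass(frozen=True)
class RowError:
    """A row-level validation failure with its 1-based file line number."""

    line: int
    message: str


@dataclass
class LoadResult:
    """Outcome of :func:`load_records`.

    ``records`` preserves file order; ``errors`` lists malformed rows;
    ``n_outside_window`` counts well-formed rows dropped because their date
    fell outside the configured study window.
    """

    records: list[PrescriptionRecord]
    errors: list[RowError]
    n_outside_window: int = 0


def _guess_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _iter_data_lines(path: Path):
    """Yield (line_number, raw_line) skipping blank and ``#`` comment lines."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, line


def load_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    study_window: tuple[dt.date, dt.date] | None = DEFAULT_STUDY_WINDOW,
) -> LoadResult:
    """Load and validate prescription records from a delimited text file.

    Parameters
    ----------
    path
        UTF-8 delimited text with a header row; ``#`` lines are ignored.
    schema
        Optional mapping from canonical field names to the file's column
        names (identity by default).
    delimiter
        Field delimiter; guessed from the extension when omitted
        (``.tsv`` -> tab, else comma).
    study_window
        Inclusive ``(start, end)`` date window; well-formed rows outside
        it are dropped and counted, not errored.  ``None`` keeps all rows.

    Raises
    ------
    ConfigError
        If a required column is missing from the header.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"record file not found: {path}")
    delim = delimiter or _guess_delimiter(path)
    schema = dict(schema or {})
    colnames = {f: schema.get(f, f) for f in RECORD_FIELDS}

    lines = _iter_data_lines(path)
    try:
        header_lineno, header_line = next(lines)
    except StopIteration:
        raise ConfigError(f"{path}: empty file, no header row")
    header = next(csv.reader([header_line], delimiter=delim))
    positions: dict[str, int] = {}
    for field, col in colnames.items():
        if col not in header:
            raise ConfigError(
                f"{path}: missing column {col!r} (field {field!r}); header={header}"
            )
        positions[field] = header.index(col)

    records: list[PrescriptionRecord] = []
    errors: list[RowError] = []
    n_outside = 0
    for lineno, line in lines:
        row = next(csv.reader([line], delimiter=delim))
        try:
            if len(row) < len(header):
                raise ValidationError(
                    f"expected {len(header)} fields, got {len(row)}"
                )
            date = dt.date.fromisoformat(row[positions["date"]].strip())
            dose_text = row[positions["daily_dose_mg"]].strip()
            days_text = row[positions["days_supplied"]].strip()
            rec = PrescriptionRecord(
                patient_id=row[positions["patient_id"]].strip(),
                hospital_id=row[positions["hospital_id"]].strip(),
                drug=Drug.from_token(row[positions["drug"]]),
                date=date,
                daily_dose_mg=float(dose_text),
                days_supplied=int(days_text),
            )
        except (ValidationError, ValueError) as exc:
            errors.append(RowError(line=lineno, message=str(exc)))
            continue
        if study_window is not None and not (
            study_window[0] <= rec.date <= study_window[1]
        ):
            n_outside += 1
            continue
        records.append(rec)
    return LoadResult(records=records, errors=errors, n_outside_window=n_outside)


def write_records(
    records: Iterable[PrescriptionRecord],
    path: str | Path,
    delimiter: str = ",",
    header_comment: str | None = None,
) -> None:
    """Write records in the canonical dialect (ISO dates, ``%g`` doses).

    Loading a canonically written file and writing it again is
    byte-identical.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(RECORD_FIELDS)
        for rec in records:
            writer.writerow([
                rec.patient_id,
                rec.hospital_id,
                rec.drug.value,
                rec.date.isoformat(),
                format(rec.daily_dose_mg, "g"),
                str(rec.days_supplied),
            ])


def load_hospital_attributes(
    path: str | Path, delimiter: str | None = None
) -> dict[str, HospitalAttributes]:
    """Load the hospital attribute sidecar keyed by hospital_id."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"attribute file not found: {path}")
    delim = delimiter or _guess_delimiter(path)
    lines = _iter_data_lines(path)
    try:
        _, header_line = next(lines)
    except StopIteration:
        raise ConfigError(f"{path}: empty file, no header row")
    header = next(csv.reader([header_line], delimiter=delim))
    for col in ATTRIBUTE_FIELDS:
        if col not in header:
            raise ConfigError(f"{path}: missing column {col!r}")
    pos = {f: header.index(f) for f in ATTRIBUTE_FIELDS}
    out: dict[str, HospitalAttributes] = {}
    for lineno, line in lines:
        row = next(csv.reader([line], delimiter=delim))
        attr = HospitalAttributes(
            hospital_id=row[pos["hospital_id"]].strip(),
            size_category=row[pos["size_category"]].strip(),
            region=row[pos["region"]].strip(),
        )
        if attr.hospital_id in out:
            raise ValidationError(
                f"{path}:{lineno}: duplicate hospital_id {attr.hospital_id!r}"
            )
        out[attr.hospital_id] = attr
    return out


def write_hospital_attributes(
    attrs: Iterable[HospitalAttributes] | Mapping[str, HospitalAttributes],
    path: str | Path,
    delimiter: str = ",",
    header_comment: str | None = None,
) -> None:
    if isinstance(attrs, Mapping):
        attrs = list(attrs.values())
    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(ATTRIBUTE_FIELDS)
        for a in attrs:
            writer.writerow([a.hospital_id, a.size_category, a.region])


def get_attributes(
    attrs: Mapping[str, HospitalAttributes] | None, hospital_id: str
) -> HospitalAttributes:
    """Attribute lookup with an UNKNOWN fallback for missing hospitals."""
    if attrs is not None and hospital_id in attrs:
        return attrs[hospital_id]
    return HospitalAttributes(hospital_id, UNKNOWN, UNKNOWN)


def records_to_frame(records: Sequence[PrescriptionRecord]):
    """Records as a pandas DataFrame (reporting convenience)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "hospital_id": [r.hospital_id for r in records],
            "drug": [r.drug.value for r in records],
            "date": [r.date for r in records],
            "daily_dose_mg": [r.daily_dose_mg for r in records],
            "days_supplied": [r.days_supplied for r in records],
        }
    )
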