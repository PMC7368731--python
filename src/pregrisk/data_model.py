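"""Domain types and flat-table I/O for THIN-style primary-care data.

THIN-like databases store three flat tables: a patient registry (one row
per patient, year of birth only for adults), coded clinical events (Read-style
diagnosis/procedure codes) and coded prescriptions (Gemscript-style drug
codes).  Phenotyping algorithms query these tables through *codelists* —
curated sets of codes, each tagged with the clinical concept (category) it
ascertains.

All tables are comma-separated text with a mandatory header and ISO-8601
dates.  Readers are fail-fast: rows violating an invariant are collected into
row-indexed diagnostics and the whole read is rejected, because silently
dropped rows are silent misclassification.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Sex",
    "RegistrationStatus",
    "Category",
    "EventSource",
    "CONTRACEPTION_CATEGORIES",
    "PRESCRIPTION_CATEGORIES",
    "DATE_FLOOR",
    "PatientRecord",
    "CodedEvent",
    "CodelistBundle",
    "Lookback",
    "StudyConfig",
    "ProportionEstimate",
    "DataError",
    "pct",
    "read_registry",
    "write_registry",
    "read_events",
    "write_events",
    "read_codelist",
    "write_codelist",
    "write_report",
    "render_estimate",
]

#: Lower bound for "lifetime" lookback windows and plausible birth years.
DATE_FLOOR = date(1900, 1, 1)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class RegistrationStatus(str, enum.Enum):
    PERMANENT = "permanent"
    TEMPORARY = "temporary"
    TRANSFERRED_OUT = "transferred_out"


class Category(str, enum.Enum):
    """Exclusion-criterion categories for the at-risk-of-pregnancy phenotype."""

    INFERTILITY = "infertility"
    IATROGENIC_INFERTILITY = "iatrogenic_infertility"
    MENOPAUSE = "menopause"
    CONTRACEPTION_PRESCRIBED = "contraception_prescribed"
    LARC_IUD = "larc_iud"
    LARC_IMPLANT = "larc_implant"
    CONTRACEPTION_NONPRESCRIBED = "contraception_nonprescribed"
    VASECTOMY_PARTNER = "vasectomy_partner"
    PREGNANCY = "pregnancy"


class EventSource(str, enum.Enum):
    CLINICAL = "clinical"
    PRESCRIPTION = "prescription"


#: Categories that describe active contraception (as opposed to infertility,
#: menopause or current pregnancy).  Under-recording in the synthetic
#: generator applies to these by default: a woman may obtain contraception
#: outside her practice, leaving no coded trace.
CONTRACEPTION_CATEGORIES = frozenset(
    {
        Category.CONTRACEPTION_PRESCRIBED,
        Category.LARC_IUD,
        Category.LARC_IMPLANT,
        Category.CONTRACEPTION_NONPRESCRIBED,
        Category.VASECTOMY_PARTNER,
    }
)

#: Categories ascertained from the prescription (drug-dictionary) table.
PRESCRIPTION_CATEGORIES = frozenset(
    {Category.CONTRACEPTION_PRESCRIBED, Category.LARC_IUD, Category.LARC_IMPLANT}
)


class DataError(ValueError):
    """Invalid input table; carries row-indexed diagnostics."""

    def __init__(self, message: str, diagnostics: Sequence[str] = ()):
        self.diagnostics = list(diagnostics)
        if self.diagnostics:
            message = message + "\n  " + "\n  ".join(self.diagnostics)
        super().__init__(message)


def pct(numerator: float, denominator: float) -> float:
    """Percentage to one decimal place (round-half-even), the reporting
    precision used throughout."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class PatientRecord:
    """One woman's registry row.

    THIN stores year of birth rather than a full birth date for adults, so
    ages are always computed from ``birth_year``.
    """

    patient_id: str
    birth_year: int
    sex: Sex
    registration_date: date
    registration_status: RegistrationStatus

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not (DATE_FLOOR.year <= self.birth_year <= 2100):
            raise ValueError(f"implausible birth_year {self.birth_year}")
        if not isinstance(self.registration_date, date):
            raise TypeError("registration_date must be a datetime.date")


@dataclass(frozen=True)
class CodedEvent:
    """A dated diagnostic or prescription code attached to a patient."""

    patient_id: str
    code: str
    event_date: date
    source: EventSource

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        if not isinstance(self.event_date, date):
            raise TypeError("event_date must be a datetime.date")


@dataclass(frozen=True)
class CodelistBundle:
    """Per-category code sets for one version of the search list.

    A code mapping to two categories within one bundle is an input error:
    category membership must be unambiguous for the exclusion tally to be
    interpretable.
    """

    lists: Mapping[Category, frozenset[str]]
    version_label: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, Category] = {}
        for cat, codes in self.lists.items():
            if not isinstance(cat, Category):
                raise ValueError(f"unknown category {cat!r}")
            if not codes:
                raise ValueError(f"category {cat.value} has an empty code set")
            for code in codes:
                if not code:
                    raise ValueError("empty code string")
                if code in seen:
                    raise DataError(
                        f"code {code!r} assigned to two categories: "
                        f"{seen[code].value} and {cat.value}"
                    )
                seen[code] = cat

    def code_map(self) -> dict[str, Category]:
        """Flat code -> category lookup."""
        return {c: cat for cat, codes in self.lists.items() for c in codes}

    def codes(self, category: Category) -> frozenset[str]:
        return self.lists.get(category, frozenset())

    def all_codes(self) -> frozenset[str]:
        return frozenset().union(*self.lists.values()) if self.lists else frozenset()

    def covers(self, other: "CodelistBundle") -> bool:
        """True if every code of *other* is present under the same category."""
        return all(
            self.codes(cat) >= codes for cat, codes in other.lists.items()
        )


@dataclass(frozen=True)
class Lookback:
    """Lookback window specification for one exclusion category.

    ``lifetime`` searches any time prior to (and during) enrolment;
    ``fixed`` searches the given number of calendar months before
    enrolment start, plus the enrolment period itself.
    """

    mode: str  # "lifetime" | "fixed"
    months: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("lifetime", "fixed"):
            raise ValueError(f"unknown lookback mode {self.mode!r}")
        if self.mode == "fixed" and (self.months is None or self.months <= 0):
            raise ValueError("fixed lookback requires strictly positive months")
        if self.mode == "lifetime" and self.months is not None:
            raise ValueError("lifetime lookback takes no month length")


def default_windows() -> dict[Category, Lookback]:
    """Default lookbacks: 12 months for prescribed and non-prescribed
    contraception, the LARC natural life cycles (5 years Cu-IUD/LNG-IUS,
    3 years progestogen-only implant), 6 months for pregnancy, and lifetime
    for infertility, iatrogenic infertility, menopause and partner
    vasectomy."""
    return {
        Category.INFERTILITY: Lookback("lifetime"),
        Category.IATROGENIC_INFERTILITY: Lookback("lifetime"),
        Category.MENOPAUSE: Lookback("lifetime"),
        Category.CONTRACEPTION_PRESCRIBED: Lookback("fixed", 12),
        Category.LARC_IUD: Lookback("fixed", 60),
        Category.LARC_IMPLANT: Lookback("fixed", 36),
        Category.CONTRACEPTION_NONPRESCRIBED: Lookback("fixed", 12),
        Category.VASECTOMY_PARTNER: Lookback("lifetime"),
        Category.PREGNANCY: Lookback("fixed", 6),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Cross-sectional study design: enrolment window, eligibility bounds
    and per-category lookbacks.

    Defaults encode a September–December 2016 enrolment of women aged 15–45
    with permanent registration and at least one year of enrolment with
    their practice.
    """

    enrolment_start: date = date(2016, 9, 1)
    enrolment_end: date = date(2016, 12, 31)
    age_min: int = 15
    age_max: int = 45
    min_registration_days: int = 365
    window_by_category: Mapping[Category, Lookback] = field(
        default_factory=default_windows
    )

    def __post_init__(self) -> None:
        if self.enrolment_start >= self.enrolment_end:
            raise ValueError("enrolment_start must precede enrolment_end")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.min_registration_days < 0:
            raise ValueError("min_registration_days must be non-negative")


@dataclass(frozen=True)
class ProportionEstimate:
    """A validation proportion (PPV, NPV, agreement, response rate) with its
    binomial confidence interval."""

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str  # "wilson" | "clopper_pearson"
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")
        if self.denominator == 0:
            raise ValueError("denominator must be positive")
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError("interval must satisfy 0 <= low <= estimate <= high <= 1")
        if self.ci_method not in ("wilson", "clopper_pearson"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

    @property
    def percent(self) -> float:
        return pct(self.numerator, self.denominator)


# ---------------------------------------------------------------------------
# CSV I/O

_REGISTRY_HEADER = ["patient_id", "birth_year", "sex", "registration_date", "registration_status"]
_EVENTS_HEADER = ["patient_id", "code", "event_date", "source"]
_CODELIST_HEADER = ["code", "category"]


def _parse_date(text: str) -> date:
    return date.fromisoformat(text)


def _check_header(actual: Sequence[str] | None, expected: Sequence[str], path: Path) -> None:
    if actual is None:
        raise DataError(f"{path}: empty file")
    if list(actual) != list(expected):
        raise DataError(
            f"{path}: header {list(actual)!r} does not match expected {list(expected)!r}"
        )


def read_registry(path: str | Path) -> list[PatientRecord]:
    """Read a patient registry CSV, rejecting any invalid row.

    Raises :class:`DataError` listing every offending row (1-based data-row
    index) rather than failing on the first; a duplicated patient_id is
    reported by id.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    problems: list[str] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, _REGISTRY_HEADER, path)
        for i, row in enumerate(reader, start=1):
            try:
                pid, by, sex, rdate, status = row
                rec = PatientRecord(
                    patient_id=pid,
                    birth_year=int(by),
                    sex=Sex(sex),
                    registration_date=_parse_date(rdate),
                    registration_status=RegistrationStatus(status),
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"row {i}: {exc}")
                continue
            if rec.patient_id in seen:
                problems.append(f"row {i}: duplicate patient_id {rec.patient_id!r}")
                continue
            seen.add(rec.patient_id)
            records.append(rec)
    if problems:
        raise DataError(f"{path}: {len(problems)} invalid row(s)", problems)
    return records


def write_registry(records: Iterable[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REGISTRY_HEADER)
        for r in records:
            w.writerow(
                [r.patient_id, r.birth_year, r.sex.value,
                 r.registration_date.isoformat(), r.registration_status.value]
            )


def read_events(path: str | Path) -> list[CodedEvent]:
    """Read a coded-event CSV (clinical or prescription rows, tagged by the
    ``source`` column)."""
    path = Path(path)
    events: list[CodedEvent] = []
    problems: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, _EVENTS_HEADER, path)
        for i, row in enumerate(reader, start=1):
            try:
                pid, code, edate, source = row
                events.append(
                    CodedEvent(pid, code, _parse_date(edate), EventSource(source))
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"row {i}: {exc}")
    if problems:
        raise DataError(f"{path}: {len(problems)} invalid row(s)", problems)
    return events


def write_events(events: Iterable[CodedEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENTS_HEADER)
        for e in events:
            w.writerow([e.patient_id, e.code, e.event_date.isoformat(), e.source.value])


def read_codelist(path: str | Path, version_label: str | None = None) -> CodelistBundle:
    """Read a two-column (code, category) codelist CSV into a bundle.

    The version label defaults to the file stem.  A code listed under two
    categories or an unknown category label rejects the whole file.
    """
    path = Path(path)
    lists: dict[Category, set[str]] = {}
    problems: list[str] = []
    seen: dict[str, Category] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header, _CODELIST_HEADER, path)
        n_rows = 0
        for i, row in enumerate(reader, start=1):
            n_rows += 1
            try:
                code, cat_label = row
                cat = Category(cat_label)
            except ValueError as exc:
                problems.append(f"row {i}: {exc}")
                continue
            if not code:
                problems.append(f"row {i}: empty code")
                continue
            if code in seen and seen[code] != cat:
                problems.append(
                    f"row {i}: code {code!r} assigned to two categories: "
                    f"{seen[code].value} and {cat.value}"
                )
                continue
            seen[code] = cat
            lists.setdefault(cat, set()).add(code)
    if n_rows == 0:
        raise DataError(f"{path}: empty codelist")
    if problems:
        raise DataError(f"{path}: {len(problems)} invalid row(s)", problems)
    return CodelistBundle(
        lists={c: frozenset(s) for c, s in lists.items()},
        version_label=version_label if version_label is not None else path.stem,
    )


def write_codelist(bundle: CodelistBundle, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CODELIST_HEADER)
        for cat in sorted(bundle.lists, key=lambda c: c.value):
            for code in sorted(bundle.lists[cat]):
                w.writerow([code, cat.value])


def render_estimate(label: str, est: ProportionEstimate) -> str:
    """One-line report rendering, e.g. ``99.2% (95% CI: 95.5–99.9) [122/123]``."""
    level = round(100 * est.confidence_level)
    return (
        f"{label}: {est.percent:.1f}% ({level}% CI: "
        f"{round(100 * est.ci_low, 1):.1f}–{round(100 * est.ci_high, 1):.1f}) "
        f"[{est.numerator}/{est.denominator}, {est.ci_method}]"
    )


def write_report(rows, path: str | Path) -> None:
    """Write assessments or estimates as a CSV report.

    Accepts either a sequence of ``(label, ProportionEstimate)`` pairs or a
    sequence of dataclass instances (e.g. risk assessments); column order is
    the dataclass field order, percentages are rendered to one decimal.
    Empty input is an error — an empty report usually means a broken
    upstream stage.
    """
    rows = list(rows)
    if not rows:
        raise DataError("refusing to write an empty report")
    path = Path(path)
    first = rows[0]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if isinstance(first, tuple) and len(first) == 2 and isinstance(first[1], ProportionEstimate):
            w.writerow(
                ["label", "numerator", "denominator", "percent",
                 "ci_low_pct", "ci_high_pct", "ci_method", "confidence_level"]
            )
            for label, est in rows:
                w.writerow(
                    [label, est.numerator, est.denominator, f"{est.percent:.1f}",
                     f"{round(100 * est.ci_low, 1):.1f}",
                     f"{round(100 * est.ci_high, 1):.1f}",
                     est.ci_method, est.confidence_level]
                )
        else:
            names = [f.name for f in dc_fields(first)]
            w.writerow(names)
            for row in rows:
                out = []
                for name in names:
                    v = getattr(row, name)
                    if isinstance(v, enum.Enum):
                        v = v.value
                    elif isinstance(v, (frozenset, set)):
                        v = "|".join(sorted(str(x) for x in v))
                    elif isinstance(v, (list, tuple)):
                        v = "|".join(str(x) for x in v)
                    elif isinstance(v, date):
                        v = v.isoformat()
                    out.append(v)
                w.writerow(out)
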