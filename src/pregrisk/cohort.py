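"""At-risk-of-pregnancy phenotyping algorithm for THIN-style tables.

The algorithm screens a registry for eligible women (female, aged 15–45 at
enrolment start, permanently registered, at least one year with their
practice), then excludes every woman carrying at least one code from any
exclusion-category codelist inside that category's lookback window:
infertility, iatrogenic infertility, menopause and partner vasectomy over a
lifetime lookback; prescribed and non-prescribed contraception in the prior
12 months; LARC insertions within the device's natural life cycle (60 months
Cu-IUD/LNG-IUS, 36 months implant); and pregnancy in the prior 6 months.
Every window extends through the enrolment period itself, so the
classification is cross-sectional over the whole enrolment window.  A woman
free of all exclusion hits is classified as at risk of pregnancy not using
any contraception.

Window arithmetic uses calendar months anchored at enrolment start (six
months before 2016-09-01 is 2016-03-01), both bounds inclusive.  Age is
enrolment-start year minus birth year, because the registry stores year of
birth only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

from dateutil.relativedelta import relativedelta

from .data_model import (
    DATE_FLOOR,
    Category,
    CodedEvent,
    CodelistBundle,
    DataError,
    PatientRecord,
    RegistrationStatus,
    Sex,
    StudyConfig,
    pct,
)

__all__ = [
    "ExclusionHit",
    "RiskAssessment",
    "AttritionReport",
    "DeltaReport",
    "assess_eligibility",
    "resolve_window",
    "find_exclusions",
    "classify_cohort",
    "delta_run",
]


@dataclass(frozen=True)
class ExclusionHit:
    """One (event, category) match inside the category's lookback window."""

    category: Category
    code: str
    event_date: date
    window_start: date
    window_end: date

    def __post_init__(self) -> None:
        if not (self.window_start <= self.event_date <= self.window_end):
            raise ValueError("event_date outside [window_start, window_end]")


@dataclass(frozen=True)
class RiskAssessment:
    """Eligibility plus at-risk verdict for one woman.

    ``at_risk`` is true exactly when the woman is eligible and carries no
    exclusion hit; ineligible women are never tested for exclusions, keeping
    attrition categories disjoint.
    """

    patient_id: str
    eligible: bool
    ineligibility_reasons: frozenset[str]
    at_risk: bool
    hits: tuple[ExclusionHit, ...]

    def __post_init__(self) -> None:
        if self.eligible and self.ineligibility_reasons:
            raise ValueError("eligible woman cannot carry ineligibility reasons")
        if not self.eligible and self.at_risk:
            raise ValueError("ineligible woman cannot be at risk")
        if self.at_risk != (self.eligible and not self.hits):
            raise ValueError("at_risk must equal (eligible and no hits)")


@dataclass(frozen=True)
class AttritionReport:
    """Selection-funnel counts: screened → ineligible → excluded → at risk.

    A woman with hits in several categories appears in each per-category
    count but once in ``n_excluded``, so that
    ``n_screened == n_ineligible + n_excluded + n_at_risk``.
    """

    n_screened: int
    n_ineligible: int
    n_excluded: int
    n_excluded_by_category: Mapping[str, int]
    n_at_risk: int
    pass_label: str = ""
    orphan_patient_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_screened != self.n_ineligible + self.n_excluded + self.n_at_risk:
            raise ValueError("attrition counts do not sum to n_screened")

    def funnel_lines(self) -> list[str]:
        lines = [
            f"[{self.pass_label or 'cohort'}] screened: {self.n_screened}",
            f"  ineligible: {self.n_ineligible}",
            f"  excluded (>=1 criterion): {self.n_excluded}",
        ]
        for cat in sorted(self.n_excluded_by_category):
            lines.append(f"    {cat}: {self.n_excluded_by_category[cat]}")
        lines.append(f"  at risk of pregnancy: {self.n_at_risk}")
        if self.orphan_patient_ids:
            lines.append(f"  orphan event patient ids: {len(self.orphan_patient_ids)}")
        return lines


def assess_eligibility(
    patient: PatientRecord, config: StudyConfig
) -> tuple[bool, frozenset[str]]:
    """Eligibility screen; returns (eligible, reasons).

    Reasons are drawn from {"sex", "age", "registration_status",
    "registration_duration"}.  A registration date after enrolment (negative
    enrolment duration) is an ordinary registration_duration failure, not an
    error.
    """
    reasons: set[str] = set()
    if patient.sex is not Sex.FEMALE:
        reasons.add("sex")
    age = config.enrolment_start.year - patient.birth_year
    if not (config.age_min <= age <= config.age_max):
        reasons.add("age")
    if patient.registration_status is not RegistrationStatus.PERMANENT:
        reasons.add("registration_status")
    enrolled_days = (config.enrolment_start - patient.registration_date).days
    if enrolled_days < config.min_registration_days:
        reasons.add("registration_duration")
    return (not reasons, frozenset(reasons))


def resolve_window(category: Category, config: StudyConfig) -> tuple[date, date]:
    """Inclusive lookback window for one category.

    lifetime → (DATE_FLOOR, enrolment_end); fixed m months →
    (enrolment_start − m calendar months, enrolment_end).  Every window runs
    through enrolment_end because exclusion events during the enrolment
    period also disqualify.
    """
    try:
        lb = config.window_by_category[category]
    except KeyError:
        raise KeyError(f"no lookback configured for category {category.value!r}")
    if lb.mode == "lifetime":
        return (DATE_FLOOR, config.enrolment_end)
    start = config.enrolment_start - relativedelta(months=lb.months)
    return (start, config.enrolment_end)


def find_exclusions(
    patient: PatientRecord,
    events: Iterable[CodedEvent],
    codelists: CodelistBundle,
    config: StudyConfig,
) -> list[ExclusionHit]:
    """All windowed codelist matches for one woman.

    One hit per (event, category) pair whose code belongs to the category's
    codelist with the event date inside the category's window; sorted by
    date, then category, then code, for deterministic reports.  Window
    bounds are inclusive, so an event dated exactly at the window start
    counts.
    """
    code_map = codelists.code_map()
    windows = {cat: resolve_window(cat, config) for cat in codelists.lists}
    hits: list[ExclusionHit] = []
    for ev in events:
        if ev.patient_id != patient.patient_id:
            raise ValueError(
                f"event for {ev.patient_id!r} passed with patient {patient.patient_id!r}"
            )
        cat = code_map.get(ev.code)
        if cat is None:
            continue
        lo, hi = windows[cat]
        if lo <= ev.event_date <= hi:
            hits.append(ExclusionHit(cat, ev.code, ev.event_date, lo, hi))
    hits.sort(key=lambda h: (h.event_date, h.category.value, h.code))
    return hits


def classify_cohort(
    registry: Sequence[PatientRecord],
    events: Iterable[CodedEvent],
    codelists: CodelistBundle,
    config: StudyConfig,
    pass_label: str = "",
) -> tuple[list[RiskAssessment], AttritionReport]:
    """Classify every registered woman and tally the attrition funnel.

    Events whose patient_id is absent from the registry are collected into
    the report's ``orphan_patient_ids``, never silently dropped.
    Assessments are returned in registry order.
    """
    if not registry:
        raise DataError("empty registry")
    ids = [p.patient_id for p in registry]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate patient_id(s) in registry: {dupes}")

    code_map = codelists.code_map()
    windows = {cat: resolve_window(cat, config) for cat in codelists.lists}
    known = set(ids)

    # single pass over events, grouping in-window hits by patient
    hits_by_patient: dict[str, list[ExclusionHit]] = {}
    orphans: list[str] = []
    for ev in events:
        if ev.patient_id not in known:
            orphans.append(ev.patient_id)
            continue
        cat = code_map.get(ev.code)
        if cat is None:
            continue
        lo, hi = windows[cat]
        if lo <= ev.event_date <= hi:
            hits_by_patient.setdefault(ev.patient_id, []).append(
                ExclusionHit(cat, ev.code, ev.event_date, lo, hi)
            )

    assessments: list[RiskAssessment] = []
    n_inelig = n_excl = n_risk = 0
    by_cat: dict[str, int] = {}
    for patient in registry:
        eligible, reasons = assess_eligibility(patient, config)
        if not eligible:
            n_inelig += 1
            assessments.append(
                RiskAssessment(patient.patient_id, False, reasons, False, ())
            )
            continue
        hits = sorted(
            hits_by_patient.get(patient.patient_id, ()),
            key=lambda h: (h.event_date, h.category.value, h.code),
        )
        if hits:
            n_excl += 1
            for cat_value in {h.category.value for h in hits}:
                by_cat[cat_value] = by_cat.get(cat_value, 0) + 1
        else:
            n_risk += 1
        assessments.append(
            RiskAssessment(
                patient.patient_id, True, frozenset(), not hits, tuple(hits)
            )
        )

    report = AttritionReport(
        n_screened=len(registry),
        n_ineligible=n_inelig,
        n_excluded=n_excl,
        n_excluded_by_category=dict(sorted(by_cat.items())),
        n_at_risk=n_risk,
        pass_label=pass_label,
        orphan_patient_ids=tuple(sorted(set(orphans))),
    )
    return assessments, report


@dataclass(frozen=True)
class DeltaReport:
    """Reclassification after a codelist correction (v1 → v2 ⊇ v1).

    Enlarging a codelist can only add exclusion hits, so reclassification is
    one-way: at-risk under v1 → not at risk under v2.  ``newly_matching``
    maps each reclassified woman to the v2-only codes that caught her.
    """

    n_at_risk_v1: int
    n_at_risk_v2: int
    reclassified: tuple[str, ...]
    newly_matching: Mapping[str, tuple[str, ...]]
    attrition_v1: AttritionReport = field(repr=False, default=None)  # type: ignore[assignment]
    attrition_v2: AttritionReport = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_reclassified(self) -> int:
        return len(self.reclassified)

    @property
    def pct_of_v1_at_risk(self) -> float:
        """Reclassified women as a percentage of the v1 at-risk set."""
        return pct(self.n_reclassified, self.n_at_risk_v1)


def delta_run(
    registry: Sequence[PatientRecord],
    events: Iterable[CodedEvent],
    codelist_v1: CodelistBundle,
    codelist_v2: CodelistBundle,
    config: StudyConfig,
) -> DeltaReport:
    """Replay a two-pass codelist correction.

    Requires v2 to contain every v1 code under the same category (a missing
    category or code is an input error).  Classifies the cohort under both
    versions and reports every woman at risk under v1 but not under v2,
    together with the newly matching v2-only codes.  No woman can move the
    other way.
    """
    for cat in codelist_v1.lists:
        if cat not in codelist_v2.lists:
            raise DataError(f"codelist v2 missing category {cat.value!r} present in v1")
    if not codelist_v2.covers(codelist_v1):
        raise DataError("codelist v2 does not contain every v1 code")

    events = list(events)
    a1, rep1 = classify_cohort(registry, events, codelist_v1, config, pass_label="v1")
    a2, rep2 = classify_cohort(registry, events, codelist_v2, config, pass_label="v2")

    v1_by_id = {a.patient_id: a for a in a1}
    new_codes = codelist_v2.all_codes() - codelist_v1.all_codes()
    reclassified: list[str] = []
    newly: dict[str, tuple[str, ...]] = {}
    for a in a2:
        was = v1_by_id[a.patient_id]
        if a.at_risk and not was.at_risk:
            raise AssertionError(
                f"non-monotone reclassification for {a.patient_id!r}"
            )
        if was.at_risk and not a.at_risk:
            reclassified.append(a.patient_id)
            newly[a.patient_id] = tuple(
                sorted({h.code for h in a.hits if h.code in new_codes})
            )
    return DeltaReport(
        n_at_risk_v1=rep1.n_at_risk,
        n_at_risk_v2=rep2.n_at_risk,
        reclassified=tuple(reclassified),
        newly_matching=newly,
        attrition_v1=rep1,
        attrition_v2=rep2,
    )
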