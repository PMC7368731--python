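"""Synthetic THIN-like populations with planted ground truth.

Real UK primary-care extracts are access-restricted, so algorithm and
validation experiments run on generated populations that mimic the tables'
shape: a registry of women aged 15–45 at enrolment, coded clinical and
prescription events drawn from per-category codelists inside each category's
lookback window, and per-woman ground truth planted at generation time.

Ground truth is defined by the generator, not inferred afterwards: the
medical-record review and practitioner questionnaire are both *noisy
observations* of that truth (under-recording, "unknown" answers, recall
error), which is what makes PPV experiments exact — the planted label is the
oracle, the two gold standards are simulations of how the truth is observed.

Under-recording models a woman obtaining contraception outside her practice:
for each contraception category she truly carries, with probability
``unrecorded_contraception_rate`` her entire coded trace for that category is
withheld.  Non-contraception categories (infertility, menopause, pregnancy)
are always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import resolve_window
from .data_model import (
    CONTRACEPTION_CATEGORIES,
    PRESCRIPTION_CATEGORIES,
    Category,
    CodedEvent,
    CodelistBundle,
    EventSource,
    PatientRecord,
    RegistrationStatus,
    Sex,
    StudyConfig,
)

__all__ = [
    "QUESTIONNAIRE_ITEMS",
    "QuestionnaireModel",
    "GeneratorConfig",
    "GroundTruth",
    "Population",
    "toy_codelists",
    "generate_population",
    "generate_questionnaires",
    "plant_missing_codes",
]

#: Questionnaire items, in reporting order.  ``contraception_enrolment`` asks
#: about the enrolment period (retrospective — subject to recall error);
#: ``contraception_now`` asks about the time of filling in (no recall error).
QUESTIONNAIRE_ITEMS = (
    "contraception_enrolment",
    "contraception_now",
    "ever_use",
    "pregnant_now",
    "willing_to_conceive",
    "trying_to_conceive",
)

_RETROSPECTIVE_ITEMS = frozenset({"contraception_enrolment", "ever_use"})


def _default_unknown_rates() -> dict[str, float]:
    # anchored to the observed practitioner non-response per item:
    # 66/128, 60/128, 70/128, 27/128, 97/128, 96/128
    return {
        "contraception_enrolment": 0.516,
        "contraception_now": 0.469,
        "ever_use": 0.547,
        "pregnant_now": 0.211,
        "willing_to_conceive": 0.758,
        "trying_to_conceive": 0.750,
    }


def _default_empty_rates() -> dict[str, float]:
    return {item: 0.0 for item in QUESTIONNAIRE_ITEMS}


@dataclass(frozen=True)
class QuestionnaireModel:
    """Response model for practitioner questionnaires.

    Each item is answered informatively (the planted truth, possibly flipped
    by recall error for retrospective items), "unknown", or left empty, with
    per-item probabilities.  A whole questionnaire may not be returned at
    all, or be returned entirely empty.  ``attitude_yes_rate`` governs the
    two intention items (willingness / trying to conceive), which have no
    planted truth.
    """

    response_rate: float = 133 / 150
    blank_questionnaire_rate: float = 5 / 133
    unknown_rates: Mapping[str, float] = field(default_factory=_default_unknown_rates)
    empty_rates: Mapping[str, float] = field(default_factory=_default_empty_rates)
    recall_error: float = 0.05
    attitude_yes_rate: float = 0.15

    def __post_init__(self) -> None:
        for p in (self.response_rate, self.blank_questionnaire_rate,
                  self.recall_error, self.attitude_yes_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for item in QUESTIONNAIRE_ITEMS:
            u = self.unknown_rates.get(item, 0.0)
            e = self.empty_rates.get(item, 0.0)
            if not (0.0 <= u <= 1.0 and 0.0 <= e <= 1.0 and u + e <= 1.0):
                raise ValueError(f"invalid unknown/empty rates for item {item!r}")


def _default_prevalence() -> dict[Category, float]:
    # free parameters: per-category probabilities chosen so that roughly a
    # third of eligible women carry >=1 exclusion condition
    return {
        Category.INFERTILITY: 0.02,
        Category.IATROGENIC_INFERTILITY: 0.005,
        Category.MENOPAUSE: 0.03,
        Category.CONTRACEPTION_PRESCRIBED: 0.18,
        Category.LARC_IUD: 0.05,
        Category.LARC_IMPLANT: 0.03,
        Category.CONTRACEPTION_NONPRESCRIBED: 0.05,
        Category.VASECTOMY_PARTNER: 0.02,
        Category.PREGNANCY: 0.06,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic population.

    ``timing_by_category`` maps a category to a signed day-offset range
    (relative to enrolment start) from which event dates are drawn
    uniformly; categories without an entry default to the full extent of
    their lookback window, so that by construction every recorded true hit
    is visible to the algorithm.  Overriding a range lets tests plant events
    just outside a window boundary.
    """

    n_women: int = 5000
    age_weights: Mapping[int, float] | None = None  # per year of age 15..45
    prevalence_by_category: Mapping[Category, float] = field(
        default_factory=_default_prevalence
    )
    timing_by_category: Mapping[Category, tuple[int, int]] = field(
        default_factory=dict
    )
    events_per_hit: int = 1
    unrecorded_contraception_rate: float = 0.1
    ineligible_fraction: float = 0.0
    freetext_rate: float = 0.065
    questionnaire_model: QuestionnaireModel = field(default_factory=QuestionnaireModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        for cat, p in self.prevalence_by_category.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {cat.value} outside [0, 1]")
        for p in (self.unrecorded_contraception_rate, self.ineligible_fraction,
                  self.freetext_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.events_per_hit < 1:
            raise ValueError("events_per_hit must be >= 1")
        if self.age_weights is not None:
            w = np.asarray(list(self.age_weights.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("age weights must be non-negative, not all zero")


@dataclass(frozen=True)
class GroundTruth:
    """Planted oracle label for one woman.

    ``truly_at_risk`` is true exactly when she genuinely carries no
    exclusion condition — coded or not.
    """

    patient_id: str
    truly_at_risk: bool
    true_category_hits: frozenset[Category]

    def __post_init__(self) -> None:
        if self.truly_at_risk != (not self.true_category_hits):
            raise ValueError("truly_at_risk must equal (no true category hits)")

    @property
    def truly_contracepting(self) -> bool:
        return bool(self.true_category_hits & CONTRACEPTION_CATEGORIES)


@dataclass(frozen=True)
class Population:
    """One generated population: the three flat tables plus the oracle."""

    registry: tuple[PatientRecord, ...]
    clinical_events: tuple[CodedEvent, ...]
    prescription_events: tuple[CodedEvent, ...]
    ground_truth: tuple[GroundTruth, ...]
    freetext: Mapping[str, bool]

    @property
    def events(self) -> tuple[CodedEvent, ...]:
        return self.clinical_events + self.prescription_events

    def truth_by_id(self) -> dict[str, GroundTruth]:
        return {t.patient_id: t for t in self.ground_truth}


def toy_codelists(version_label: str = "toy-v2") -> CodelistBundle:
    """A small built-in codelist bundle with Read-style tokens for clinical
    categories and numeric drug-dictionary-style tokens for prescription
    categories.  These are synthetic stand-ins, not real dictionary codes."""
    lists = {
        Category.INFERTILITY: {"K5A0.", "K5A1.", "K5A2.", "K5A3.", "K5Ay."},
        Category.IATROGENIC_INFERTILITY: {"K5B0.", "K5B1.", "K5B2."},
        Category.MENOPAUSE: {"K5C0.", "K5C1.", "K5C2.", "K5Cz."},
        Category.CONTRACEPTION_PRESCRIBED: {
            "80110020", "80110021", "80110030", "80110031", "80110040",
            "80110041", "80110050", "80110051", "80110060", "80110061",
        },
        Category.LARC_IUD: {"81220010", "81220011", "81220020", "7E0A0", "7E0A1"},
        Category.LARC_IMPLANT: {"81330010", "81330011", "7E0B0", "7E0B1"},
        Category.CONTRACEPTION_NONPRESCRIBED: {"61A0.", "61A1.", "61A2.", "61Az."},
        Category.VASECTOMY_PARTNER: {"61B0.", "61B1.", "61B2."},
        Category.PREGNANCY: {"62A0.", "62A1.", "62A2.", "62A3.", "62Az."},
    }
    return CodelistBundle(
        lists={c: frozenset(s) for c, s in lists.items()},
        version_label=version_label,
    )


def _timing_range(
    cat: Category, config: GeneratorConfig, study: StudyConfig
) -> tuple[int, int]:
    if cat in config.timing_by_category:
        return config.timing_by_category[cat]
    lo, hi = resolve_window(cat, study)
    lo = max(lo, study.enrolment_start - timedelta(days=10 * 365))  # cap lifetime draw
    return ((lo - study.enrolment_start).days, (hi - study.enrolment_start).days)


def generate_population(
    config: GeneratorConfig,
    codelists: CodelistBundle | None = None,
    study: StudyConfig | None = None,
) -> Population:
    """Generate a registry, coded events and planted ground truth.

    Deterministic given ``config.seed``.  Every woman is aged 15–45 at
    enrolment start; a configurable fraction is made ineligible through a
    non-permanent registration status or a short registration.  For every
    true category hit that is *recorded*, ``events_per_hit`` dated events
    with codes from that category are emitted inside the category's timing
    range.
    """
    codelists = codelists if codelists is not None else toy_codelists()
    study = study if study is not None else StudyConfig()
    rng = np.random.default_rng(config.seed)

    cats = sorted(config.prevalence_by_category, key=lambda c: c.value)
    for cat in cats:
        if config.prevalence_by_category[cat] > 0 and not codelists.codes(cat):
            raise ValueError(
                f"category {cat.value!r} has nonzero prevalence but no codes"
            )

    n = config.n_women
    width = len(str(n))
    ids = [f"W{str(i + 1).zfill(width)}" for i in range(n)]

    ages_support = np.arange(study.age_min, study.age_max + 1)
    if config.age_weights is not None:
        w = np.array([config.age_weights.get(int(a), 0.0) for a in ages_support])
    else:
        w = np.ones_like(ages_support, dtype=float)
    ages = rng.choice(ages_support, size=n, p=w / w.sum())
    birth_years = study.enrolment_start.year - ages

    # registration 1..20 years before enrolment start keeps everyone eligible
    reg_offsets = rng.integers(study.min_registration_days, 20 * 365, size=n)
    statuses = np.full(n, "permanent", dtype=object)
    if config.ineligible_fraction > 0:
        bad = rng.random(n) < config.ineligible_fraction
        kind = rng.integers(0, 2, size=n)
        statuses[bad & (kind == 0)] = "temporary"
        reg_offsets = np.where(
            bad & (kind == 1), rng.integers(0, study.min_registration_days, size=n),
            reg_offsets,
        )

    registry = tuple(
        PatientRecord(
            patient_id=ids[i],
            birth_year=int(birth_years[i]),
            sex=Sex.FEMALE,
            registration_date=study.enrolment_start - timedelta(days=int(reg_offsets[i])),
            registration_status=RegistrationStatus(statuses[i]),
        )
        for i in range(n)
    )

    clinical: list[CodedEvent] = []
    prescriptions: list[CodedEvent] = []
    true_hits: list[set[Category]] = [set() for _ in range(n)]

    for cat in cats:
        p = config.prevalence_by_category[cat]
        if p == 0:
            continue
        has = rng.random(n) < p
        recorded = np.ones(n, dtype=bool)
        if cat in CONTRACEPTION_CATEGORIES and config.unrecorded_contraception_rate > 0:
            recorded = rng.random(n) >= config.unrecorded_contraception_rate
        codes = sorted(codelists.codes(cat))
        lo_off, hi_off = _timing_range(cat, config, study)
        source = (
            EventSource.PRESCRIPTION
            if cat in PRESCRIPTION_CATEGORIES
            else EventSource.CLINICAL
        )
        sink = prescriptions if source is EventSource.PRESCRIPTION else clinical
        idx = np.flatnonzero(has)
        offs = rng.integers(lo_off, hi_off + 1, size=(len(idx), config.events_per_hit))
        code_idx = rng.integers(0, len(codes), size=(len(idx), config.events_per_hit))
        for row, i in enumerate(idx):
            true_hits[i].add(cat)
            if not recorded[i]:
                continue
            for k in range(config.events_per_hit):
                sink.append(
                    CodedEvent(
                        patient_id=ids[i],
                        code=codes[int(code_idx[row, k])],
                        event_date=study.enrolment_start
                        + timedelta(days=int(offs[row, k])),
                        source=source,
                    )
                )

    truth = tuple(
        GroundTruth(ids[i], not true_hits[i], frozenset(true_hits[i]))
        for i in range(n)
    )
    freetext_flags = rng.random(n) < config.freetext_rate
    freetext = {ids[i]: bool(freetext_flags[i]) for i in range(n)}
    return Population(
        registry=registry,
        clinical_events=tuple(clinical),
        prescription_events=tuple(prescriptions),
        ground_truth=truth,
        freetext=freetext,
    )


def _informative_answer(
    item: str, truth: GroundTruth, rng: np.random.Generator, model: QuestionnaireModel
) -> str:
    if item in ("contraception_enrolment", "contraception_now", "ever_use"):
        ans = "yes" if truth.truly_contracepting else "no"
    elif item == "pregnant_now":
        ans = "yes" if Category.PREGNANCY in truth.true_category_hits else "no"
    else:  # intention items carry no planted truth
        ans = "yes" if rng.random() < model.attitude_yes_rate else "no"
    if item in _RETROSPECTIVE_ITEMS and rng.random() < model.recall_error:
        ans = "no" if ans == "yes" else "yes"
    return ans


def generate_questionnaires(
    sampled_ids: Sequence[str],
    ground_truth: Iterable[GroundTruth],
    model: QuestionnaireModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate practitioner questionnaires for a validation sample.

    Returns one row per sampled woman with a ``returned`` flag and the six
    items, each in {yes, no, unknown, empty}.  Non-returned and blank
    questionnaires have every item "empty".  The current-timeframe
    contraception item is generated without recall error; the enrolment item
    applies ``model.recall_error`` to informative answers.
    """
    truth_by_id = {t.patient_id: t for t in ground_truth}
    missing = [pid for pid in sampled_ids if pid not in truth_by_id]
    if missing:
        raise KeyError(f"sampled women absent from the population: {missing[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in sampled_ids:
        truth = truth_by_id[pid]
        returned = rng.random() < model.response_rate
        blank = returned and rng.random() < model.blank_questionnaire_rate
        row: dict[str, object] = {"patient_id": pid, "returned": returned}
        for item in QUESTIONNAIRE_ITEMS:
            if not returned or blank:
                row[item] = "empty"
                continue
            u = rng.random()
            if u < model.unknown_rates.get(item, 0.0):
                row[item] = "unknown"
            elif u < model.unknown_rates.get(item, 0.0) + model.empty_rates.get(item, 0.0):
                row[item] = "empty"
            else:
                row[item] = _informative_answer(item, truth, rng, model)
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "returned", *QUESTIONNAIRE_ITEMS])


def plant_missing_codes(
    codelists: CodelistBundle,
    fraction: float,
    seed: int,
    categories: Iterable[Category] = tuple(sorted(PRESCRIPTION_CATEGORIES, key=lambda c: c.value)),
) -> tuple[CodelistBundle, frozenset[str]]:
    """Withhold a fraction of drug codes from the search list, producing a
    deficient version-1 bundle.

    Codes are withheld from the *codelist*, not from the data, so the
    two-pass correction (classify with v1, discover the gap, re-classify
    with the full v2) can be replayed.  Returns the censored bundle and the
    withheld code set.  Withholding every code of a category drops the
    category from v1 entirely.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    withheld: set[str] = set()
    new_lists: dict[Category, frozenset[str]] = {}
    target = set(categories)
    for cat in sorted(codelists.lists, key=lambda c: c.value):
        codes = sorted(codelists.lists[cat])
        if cat in target and fraction > 0:
            k = int(round(fraction * len(codes)))
            drop = set(rng.choice(codes, size=k, replace=False)) if k else set()
            withheld |= drop
            keep = frozenset(c for c in codes if c not in drop)
            if keep:
                new_lists[cat] = keep
        else:
            new_lists[cat] = frozenset(codes)
    v1 = CodelistBundle(
        lists=new_lists, version_label=codelists.version_label + "+withheld"
    )
    return v1, frozenset(withheld)
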