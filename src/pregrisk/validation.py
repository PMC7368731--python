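"""Validation statistics: stratified sampling, PPV/NPV, agreement, intervals.

The phenotyping algorithm has no machine-readable gold standard, so its
positive predictive value is estimated on a stratified validation sample
against two noisy gold standards — manual record/free-text review and
practitioner questionnaires.  Questionnaires return "unknown" for many
women, and how unknowns are handled changes the conclusion, so unknown
handling is an explicit, never-defaulted parameter with the two named
definitions:

* ``as_noncase`` — an unknown counts as a non-confirmed case in the
  denominator (conservative);
* ``excluded`` — unknowns are removed from numerator and denominator
  (complete-case).

Two binomial interval methods ship: the Wilson score interval and the
"exact" Clopper–Pearson interval, because published validation studies use
either (sometimes both in one paper without saying which).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .data_model import DataError, ProportionEstimate, pct
from .synthetic import QUESTIONNAIRE_ITEMS

__all__ = [
    "UnknownHandling",
    "GoldSource",
    "GoldStatus",
    "GoldStandardRecord",
    "SamplingPlan",
    "CrosslinkTable",
    "CrosslinkResult",
    "wilson_interval",
    "clopper_pearson_interval",
    "make_estimate",
    "stratified_sample",
    "ppv",
    "crosslink",
    "crosslink_from_counts",
    "tabulate_questionnaires",
]


class UnknownHandling(str, enum.Enum):
    AS_NONCASE = "as_noncase"
    EXCLUDED = "excluded"


class GoldSource(str, enum.Enum):
    RECORD_REVIEW = "record_review"
    FREETEXT = "freetext"
    QUESTIONNAIRE_ENROLMENT = "questionnaire_enrolment"
    QUESTIONNAIRE_CURRENT = "questionnaire_current"


class GoldStatus(str, enum.Enum):
    CONFIRMED_CASE = "confirmed_case"
    NON_CASE = "non_case"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GoldStandardRecord:
    """One gold-standard verdict for one woman from one source."""

    patient_id: str
    source: GoldSource
    status: GoldStatus


def _default_bands() -> tuple[tuple[int, int], ...]:
    return ((18, 20), (20, 25), (25, 30), (30, 35), (35, 40), (40, 45))


@dataclass(frozen=True)
class SamplingPlan:
    """Equal-allocation stratified sampling plan over age bands.

    Bands are half-open ``[low, high)`` with the final band closed at its
    upper edge, so the conventional shared-endpoint listing 18–20, 20–25,
    …, 40–45 partitions ages without overlap.
    """

    bands: tuple[tuple[int, int], ...] = field(default_factory=_default_bands)
    per_band: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_band <= 0:
            raise ValueError("per_band must be positive")
        for lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"band ({lo}, {hi}) is empty")
        for (lo1, hi1), (lo2, hi2) in zip(self.bands, self.bands[1:]):
            if hi1 > lo2:
                raise ValueError("bands overlap under the half-open convention")

    def band_of(self, age: int) -> tuple[int, int] | None:
        for i, (lo, hi) in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if lo <= age < hi or (last and age == hi):
                return (lo, hi)
        return None


def stratified_sample(
    candidates: Iterable[tuple[str, int]],
    plan: SamplingPlan,
    allow_short: bool = False,
) -> list[str]:
    """Draw ``per_band`` patient ids per age band, reproducibly.

    ``candidates`` are ``(patient_id, age)`` pairs, normally the at-risk
    women of a classified cohort.  A band with fewer candidates than
    ``per_band`` is an error naming the band, unless ``allow_short`` is set
    (then the whole band is taken).
    """
    by_band: dict[tuple[int, int], list[str]] = {b: [] for b in plan.bands}
    for pid, age in candidates:
        band = plan.band_of(int(age))
        if band is not None:
            by_band[band].append(pid)
    rng = np.random.default_rng(plan.seed)
    sampled: list[str] = []
    for band in plan.bands:
        pool = sorted(by_band[band])
        if len(pool) < plan.per_band:
            if not allow_short:
                raise DataError(
                    f"band {band[0]}–{band[1]} has {len(pool)} candidates, "
                    f"fewer than per_band={plan.per_band}"
                )
            sampled.extend(pool)
        else:
            sampled.extend(sorted(rng.choice(pool, size=plan.per_band, replace=False)))
    return sampled


# ---------------------------------------------------------------------------
# Binomial intervals

def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    _check_counts(successes, n, level)
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return (float(lo), float(hi))


def clopper_pearson_interval(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided exact (Clopper–Pearson) interval from beta quantiles, with
    the conventions low = 0 at zero successes and high = 1 at n successes."""
    _check_counts(successes, n, level)
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return (lo, hi)


def _check_counts(successes: int, n: int, level: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError("need 0 <= successes <= n")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")


_METHODS = {
    "wilson": wilson_interval,
    "clopper_pearson": clopper_pearson_interval,
}


def make_estimate(
    numerator: int, denominator: int, ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> ProportionEstimate:
    """Bundle a count proportion with its confidence interval."""
    if ci_method not in _METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = _METHODS[ci_method](numerator, denominator, level)
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        estimate=numerator / denominator,
        ci_low=lo,
        ci_high=hi,
        ci_method=ci_method,
        confidence_level=level,
    )


# ---------------------------------------------------------------------------
# Predictive values and agreement

def ppv(
    gold: Iterable[GoldStandardRecord],
    algorithm_positives: Iterable[str],
    unknown_handling: UnknownHandling,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> ProportionEstimate:
    """Positive predictive value of the algorithm against one gold standard.

    Every algorithm-positive woman must have a gold record (possibly
    ``unknown``).  Under ``as_noncase`` unknowns stay in the denominator as
    non-confirmed; under ``excluded`` they are removed from both numerator
    and denominator (an empty denominator after exclusion is an error).
    """
    unknown_handling = UnknownHandling(unknown_handling)
    status_by_id = {g.patient_id: g.status for g in gold}
    positives = list(algorithm_positives)
    missing = [p for p in positives if p not in status_by_id]
    if missing:
        raise DataError(
            f"{len(missing)} algorithm-positive women lack a gold record",
            [f"patient {p}" for p in missing[:10]],
        )
    statuses = [status_by_id[p] for p in positives]
    confirmed = sum(s is GoldStatus.CONFIRMED_CASE for s in statuses)
    if unknown_handling is UnknownHandling.EXCLUDED:
        denominator = sum(s is not GoldStatus.UNKNOWN for s in statuses)
        if denominator == 0:
            raise DataError("empty denominator: every gold status is unknown")
    else:
        denominator = len(statuses)
        if denominator == 0:
            raise DataError("no algorithm-positive women")
    return make_estimate(confirmed, denominator, ci_method, level)


@dataclass(frozen=True)
class CrosslinkTable:
    """2×2 cross-classification: index method rows × gold method columns.

    ``confirmed_confirmed`` counts women confirmed by both, and so on; the
    chosen unknown handling has already been applied when the table is
    built.
    """

    confirmed_confirmed: int
    confirmed_nonconfirmed: int
    nonconfirmed_confirmed: int
    nonconfirmed_nonconfirmed: int
    unknown_handling: UnknownHandling

    def __post_init__(self) -> None:
        for v in (self.confirmed_confirmed, self.confirmed_nonconfirmed,
                  self.nonconfirmed_confirmed, self.nonconfirmed_nonconfirmed):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.confirmed_confirmed + self.confirmed_nonconfirmed
                + self.nonconfirmed_confirmed + self.nonconfirmed_nonconfirmed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gold_confirmed": [self.confirmed_confirmed, self.nonconfirmed_confirmed],
                "gold_nonconfirmed": [self.confirmed_nonconfirmed, self.nonconfirmed_nonconfirmed],
            },
            index=["index_confirmed", "index_nonconfirmed"],
        )


@dataclass(frozen=True)
class CrosslinkResult:
    table: CrosslinkTable
    ppv: ProportionEstimate
    npv: ProportionEstimate | None
    agreement: ProportionEstimate


def crosslink_from_counts(
    confirmed_confirmed: int,
    confirmed_nonconfirmed: int,
    nonconfirmed_confirmed: int,
    nonconfirmed_nonconfirmed: int,
    unknown_handling: UnknownHandling,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> CrosslinkResult:
    """Cross-link summary from a 2×2 count table (index rows, gold columns).

    PPV = confirmed-by-both / confirmed-by-index; NPV = non-confirmed-by-
    both / non-confirmed-by-index (None when the index never says
    non-confirmed); agreement = diagonal / total.
    """
    table = CrosslinkTable(
        confirmed_confirmed, confirmed_nonconfirmed,
        nonconfirmed_confirmed, nonconfirmed_nonconfirmed,
        UnknownHandling(unknown_handling),
    )
    if table.total == 0:
        raise DataError("empty cross-link table")
    n_index_pos = confirmed_confirmed + confirmed_nonconfirmed
    if n_index_pos == 0:
        raise DataError("index method confirmed no one; PPV undefined")
    ppv_est = make_estimate(confirmed_confirmed, n_index_pos, ci_method, level)
    n_index_neg = nonconfirmed_confirmed + nonconfirmed_nonconfirmed
    npv_est = (
        make_estimate(nonconfirmed_nonconfirmed, n_index_neg, ci_method, level)
        if n_index_neg > 0
        else None
    )
    agree = make_estimate(
        confirmed_confirmed + nonconfirmed_nonconfirmed, table.total, ci_method, level
    )
    return CrosslinkResult(table=table, ppv=ppv_est, npv=npv_est, agreement=agree)


def crosslink(
    index_records: Iterable[GoldStandardRecord],
    gold_records: Iterable[GoldStandardRecord],
    unknown_handling: UnknownHandling,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> CrosslinkResult:
    """Cross-link two per-woman gold standards over their overlap.

    The second source (typically the questionnaire) is the gold axis.
    Women unknown to the *index* contribute no information and are dropped;
    gold unknowns follow ``unknown_handling``.
    """
    unknown_handling = UnknownHandling(unknown_handling)
    index_by_id = {r.patient_id: r.status for r in index_records}
    gold_by_id = {r.patient_id: r.status for r in gold_records}
    overlap = sorted(set(index_by_id) & set(gold_by_id))
    if not overlap:
        raise DataError("no women present in both validation sources")
    counts = {"cc": 0, "cn": 0, "nc": 0, "nn": 0}
    for pid in overlap:
        idx, gold = index_by_id[pid], gold_by_id[pid]
        if idx is GoldStatus.UNKNOWN:
            continue
        if gold is GoldStatus.UNKNOWN:
            if unknown_handling is UnknownHandling.EXCLUDED:
                continue
            gold = GoldStatus.NON_CASE
        key = ("c" if idx is GoldStatus.CONFIRMED_CASE else "n") + (
            "c" if gold is GoldStatus.CONFIRMED_CASE else "n"
        )
        counts[key] += 1
    return crosslink_from_counts(
        counts["cc"], counts["cn"], counts["nc"], counts["nn"],
        unknown_handling, ci_method, level,
    )


# ---------------------------------------------------------------------------
# Questionnaire tabulation

def tabulate_questionnaires(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Item-level frequency table in the shape of a published summary.

    Returns rows (section, level, count, percent) where percent is to one
    decimal: response logistics against the number sent / returned, and
    item levels against the number of *valid* (returned, non-blank)
    questionnaires.  A questionnaire is blank when every item is empty.
    """
    required = {"patient_id", "returned", *QUESTIONNAIRE_ITEMS}
    missing = required - set(questionnaires.columns)
    if missing:
        raise DataError(f"questionnaire table missing columns: {sorted(missing)}")
    levels = {"yes", "no", "unknown", "empty"}
    for item in QUESTIONNAIRE_ITEMS:
        bad = set(questionnaires[item].unique()) - levels
        if bad:
            raise DataError(f"unknown level(s) {sorted(bad)} for item {item!r}")

    n_sent = len(questionnaires)
    returned = questionnaires[questionnaires["returned"].astype(bool)]
    n_returned = len(returned)
    blank_mask = (returned[list(QUESTIONNAIRE_ITEMS)] == "empty").all(axis=1)
    valid = returned[~blank_mask]
    n_blank, n_valid = int(blank_mask.sum()), len(valid)
    if n_valid == 0:
        raise DataError("no valid questionnaires: all returned forms are blank")

    rows = [
        ("logistics", "sent", n_sent, None),
        ("logistics", "returned", n_returned, pct(n_returned, n_sent)),
        ("logistics", "empty", n_blank, pct(n_blank, n_returned)),
        ("logistics", "valid", n_valid, pct(n_valid, n_returned)),
    ]
    for item in QUESTIONNAIRE_ITEMS:
        vc = valid[item].value_counts()
        for level in ("no", "unknown", "yes", "empty"):
            count = int(vc.get(level, 0))
            rows.append((item, level, count, pct(count, n_valid)))
    return pd.DataFrame(rows, columns=["section", "level", "count", "percent"])
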