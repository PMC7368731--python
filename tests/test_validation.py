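"""Interval methods against bisection oracles; PPV, cross-link, sampling."""

import numpy as np
import pytest

from pregrisk.data_model import DataError
from pregrisk.validation import (
    GoldSource,
    GoldStandardRecord,
    GoldStatus,
    SamplingPlan,
    UnknownHandling,
    clopper_pearson_interval,
    crosslink,
    crosslink_from_counts,
    make_estimate,
    ppv,
    stratified_sample,
    tabulate_questionnaires,
    wilson_interval,
)

from helpers import clopper_pearson_bisect, wilson_bisect


def _gold(n_confirmed, n_non, n_unknown, source=GoldSource.QUESTIONNAIRE_ENROLMENT):
    records, ids = [], []
    status_runs = (
        (GoldStatus.CONFIRMED_CASE, n_confirmed),
        (GoldStatus.NON_CASE, n_non),
        (GoldStatus.UNKNOWN, n_unknown),
    )
    i = 0
    for status, count in status_runs:
        for _ in range(count):
            pid = f"W{i:03d}"
            records.append(GoldStandardRecord(pid, source, status))
            ids.append(pid)
            i += 1
    return records, ids


class TestIntervals:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (122, 123, (0.955, 0.999)),
            (7, 8, (0.529, 0.978)),
        ],
    )
    def test_wilson_reproduces_published_bounds(self, x, n, expected):
        lo, hi = wilson_interval(x, n)
        assert (round(lo, 3), round(hi, 3)) == expected

    def test_wilson_zero_successes_has_zero_lower_bound(self):
        lo, _ = wilson_interval(0, 5)
        assert lo == 0.0

    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (33, 81, (0.299, 0.522)),
            (33, 39, (0.695, 0.941)),
            # complete-case questionnaire PPV: the exact interval to 3 dp
            (51, 62, (0.705, 0.908)),
        ],
    )
    def test_clopper_pearson_reproduces_exact_bounds(self, x, n, expected):
        lo, hi = clopper_pearson_interval(x, n)
        assert (round(lo, 3), round(hi, 3)) == expected

    def test_clopper_pearson_boundary_conventions(self):
        assert clopper_pearson_interval(0, 5)[0] == 0.0
        assert clopper_pearson_interval(5, 5)[1] == 1.0

    def test_both_methods_match_bisection_oracle_to_1e9(self):
        pairs = [(x, n) for n in range(1, 61) for x in range(n + 1)]
        xs = np.array([p[0] for p in pairs])
        ns = np.array([p[1] for p in pairs])
        got = np.array([wilson_interval(x, n) for x, n in pairs])
        lo, hi = wilson_bisect(xs, ns)
        np.testing.assert_allclose(got[:, 0], lo, atol=1e-9)
        np.testing.assert_allclose(got[:, 1], hi, atol=1e-9)
        got = np.array([clopper_pearson_interval(x, n) for x, n in pairs])
        lo, hi = clopper_pearson_bisect(xs, ns)
        np.testing.assert_allclose(got[:, 0], lo, atol=1e-9)
        np.testing.assert_allclose(got[:, 1], hi, atol=1e-9)

    def test_exact_interval_contains_point_estimate_and_shrinks_with_n(self):
        for x, n in [(1, 4), (3, 10), (9, 10)]:
            widths = []
            for scale in (1, 4, 16):
                lo, hi = clopper_pearson_interval(x * scale, n * scale)
                assert 0.0 <= lo <= x / n <= hi <= 1.0
                wl, wh = wilson_interval(x * scale, n * scale)
                assert 0.0 <= wl <= x / n <= wh <= 1.0
                widths.append(hi - lo)
            assert widths[0] > widths[1] > widths[2]

    def test_exact_coverage_is_at_least_nominal(self):
        # empirical coverage of the 95% exact interval at n = 30
        n, reps = 30, 20000
        rng = np.random.default_rng(0)
        intervals = np.array([clopper_pearson_interval(x, n) for x in range(n + 1)])
        for p in (0.1, 0.5, 0.9):
            draws = rng.binomial(n, p, size=reps)
            covered = (intervals[draws, 0] <= p) & (p <= intervals[draws, 1])
            assert covered.mean() >= 0.95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson_interval(5, 4)


class TestPpv:
    def test_record_review_ppv(self):
        gold, ids = _gold(122, 1, 0, source=GoldSource.RECORD_REVIEW)
        est = ppv(gold, ids, UnknownHandling.AS_NONCASE, ci_method="wilson")
        assert (est.numerator, est.denominator) == (122, 123)
        assert est.percent == 99.2

    def test_unknowns_excluded_gives_complete_case_ppv(self):
        gold, ids = _gold(51, 11, 66)
        est = ppv(gold, ids, UnknownHandling.EXCLUDED)
        assert (est.numerator, est.denominator) == (51, 62)
        assert est.percent == 82.3

    def test_unknowns_as_noncase_keep_full_denominator(self):
        gold, ids = _gold(51, 11, 66)
        est = ppv(gold, ids, UnknownHandling.AS_NONCASE)
        assert (est.numerator, est.denominator) == (51, 128)

    def test_zero_confirmed_gives_zero_estimate(self):
        gold, ids = _gold(0, 10, 0)
        assert ppv(gold, ids, UnknownHandling.AS_NONCASE).estimate == 0.0

    def test_all_unknown_gold_behaviour_by_handling(self):
        gold, ids = _gold(0, 0, 12)
        with pytest.raises(DataError):
            ppv(gold, ids, UnknownHandling.EXCLUDED)
        assert ppv(gold, ids, UnknownHandling.AS_NONCASE).estimate == 0.0

    def test_positive_without_gold_record_is_an_error(self):
        gold, ids = _gold(3, 0, 0)
        with pytest.raises(DataError, match="lack a gold record"):
            ppv(gold, ids + ["GHOST"], UnknownHandling.AS_NONCASE)


class TestCrosslink:
    def test_unknowns_as_noncase_table(self):
        res = crosslink_from_counts(33, 48, 0, 1, UnknownHandling.AS_NONCASE)
        assert res.ppv.percent == 40.7
        assert (round(res.ppv.ci_low, 3), round(res.ppv.ci_high, 3)) == (0.299, 0.522)
        assert res.npv.percent == 100.0
        assert res.agreement.percent == round(100 * 34 / 82, 1)

    def test_unknowns_excluded_table(self):
        res = crosslink_from_counts(33, 6, 0, 1, UnknownHandling.EXCLUDED)
        assert res.ppv.percent == 84.6
        assert (round(res.ppv.ci_low, 3), round(res.ppv.ci_high, 3)) == (0.695, 0.941)
        assert res.npv.percent == 100.0

    def test_per_woman_records_reduce_to_the_count_table(self):
        index, ids = _gold(34, 1, 0, source=GoldSource.RECORD_REVIEW)
        # questionnaire confirms the first 33 index-confirmed and the lone
        # index non-case; says unknown for one index-confirmed woman
        gold = (
            [GoldStandardRecord(i, GoldSource.QUESTIONNAIRE_ENROLMENT,
                                GoldStatus.CONFIRMED_CASE) for i in ids[:33]]
            + [GoldStandardRecord(ids[33], GoldSource.QUESTIONNAIRE_ENROLMENT,
                                  GoldStatus.UNKNOWN)]
            + [GoldStandardRecord(ids[34], GoldSource.QUESTIONNAIRE_ENROLMENT,
                                  GoldStatus.NON_CASE)]
        )
        res_a = crosslink(index, gold, UnknownHandling.AS_NONCASE)
        assert res_a.table.to_frame().values.tolist() == [[33, 1], [0, 1]]
        res_b = crosslink(index, gold, UnknownHandling.EXCLUDED)
        assert res_b.table.to_frame().values.tolist() == [[33, 0], [0, 1]]

    def test_perfect_concordance_gives_full_agreement(self):
        index, ids = _gold(20, 0, 0, source=GoldSource.RECORD_REVIEW)
        gold, _ = _gold(20, 0, 0)
        assert crosslink(index, gold, UnknownHandling.AS_NONCASE).agreement.estimate == 1.0

    def test_empty_overlap_is_an_error(self):
        index, _ = _gold(2, 0, 0, source=GoldSource.RECORD_REVIEW)
        gold = [GoldStandardRecord("Z9", GoldSource.QUESTIONNAIRE_ENROLMENT,
                                   GoldStatus.CONFIRMED_CASE)]
        with pytest.raises(DataError, match="both validation sources"):
            crosslink(index, gold, UnknownHandling.AS_NONCASE)


class TestStratifiedSample:
    @staticmethod
    def _candidates(per_age=30):
        return [
            (f"W{age}_{i}", age) for age in range(18, 46) for i in range(per_age)
        ]

    def test_six_bands_of_25_yield_150(self):
        plan = SamplingPlan(seed=1)
        sampled = stratified_sample(self._candidates(), plan)
        assert len(sampled) == 150
        assert len(set(sampled)) == 150

    def test_short_band_error_names_the_band(self):
        candidates = [c for c in self._candidates() if not 20 <= c[1] < 25]
        candidates += [(f"S{i}", 21) for i in range(10)]
        with pytest.raises(DataError, match="20–25"):
            stratified_sample(candidates, SamplingPlan(seed=1))
        short = stratified_sample(candidates, SamplingPlan(seed=1), allow_short=True)
        assert len(short) == 135

    def test_same_seed_reproduces_sample(self):
        plan = SamplingPlan(seed=99)
        assert stratified_sample(self._candidates(), plan) == stratified_sample(
            self._candidates(), plan
        )

    def test_final_band_closed_at_45(self):
        plan = SamplingPlan(seed=0)
        assert plan.band_of(45) == (40, 45)
        assert plan.band_of(40) == (40, 45)
        assert plan.band_of(20) == (20, 25)
        assert plan.band_of(17) is None

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SamplingPlan(bands=((18, 21), (20, 25)))


class TestTabulate:
    @staticmethod
    def _questionnaires(n_sent=150, n_returned=133, n_blank=5):
        import pandas as pd
        from pregrisk.synthetic import QUESTIONNAIRE_ITEMS

        rows = []
        # item levels for the 128 valid forms: 51 no / 66 unknown / 11 yes
        levels = ["no"] * 51 + ["unknown"] * 66 + ["yes"] * 11
        for i in range(n_sent):
            returned = i < n_returned
            blank = returned and i >= n_returned - n_blank
            row = {"patient_id": f"W{i:03d}", "returned": returned}
            for item in QUESTIONNAIRE_ITEMS:
                if not returned or blank:
                    row[item] = "empty"
                elif item == "contraception_enrolment":
                    row[item] = levels[i]
                else:
                    row[item] = "unknown"
            rows.append(row)
        return pd.DataFrame(rows)

    def test_logistics_and_item_percentages(self):
        table = tabulate_questionnaires(self._questionnaires())
        logistics = table[table.section == "logistics"].set_index("level")
        assert logistics.loc["returned", "count"] == 133
        assert logistics.loc["returned", "percent"] == 88.7
        assert logistics.loc["empty", "percent"] == 3.8
        assert logistics.loc["valid", "count"] == 128
        # 128/133 = 96.2 to one decimal; every percentage is the rounded ratio
        assert logistics.loc["valid", "percent"] == 96.2
        item = table[table.section == "contraception_enrolment"].set_index("level")
        assert item.loc["no", "percent"] == 39.8
        assert item.loc["unknown", "percent"] == 51.6
        assert item.loc["yes", "percent"] == 8.6

    def test_all_blank_input_is_an_error(self):
        q = self._questionnaires(n_sent=10, n_returned=10, n_blank=10)
        with pytest.raises(DataError, match="blank"):
            tabulate_questionnaires(q)

    def test_unknown_level_rejected(self):
        q = self._questionnaires()
        q.loc[0, "ever_use"] = "maybe"
        with pytest.raises(DataError, match="maybe"):
            tabulate_questionnaires(q)


def test_make_estimate_rejects_unknown_method():
    with pytest.raises(ValueError):
        make_estimate(1, 2, ci_method="jeffreys")
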