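"""Two-bowl palatability analytics and the digestibility formula.

The consumption ratios, split percentages and first-choice chi-square
p-values asserted here are the published worked examples of a 20-cat,
2-day, three-pair panel; every input (totals and counts) is printed data.
"""

import numpy as np
import pandas as pd
import pytest

from scfptrial.io import DigestibilityRecord, PalatabilityRecord, ValidationError
from scfptrial.palatability import (acceptance_model, attd, clear_preference,
                                    consumption_summary, daily_consumption_test,
                                    first_choice_test, intake_ratio_per_cat,
                                    intake_ratio_tests, palatability_report)


def _records_with_totals(total_a, total_b, diet_a="CD", diet_b="T150", n=20):
    """Distribute known totals over cats/days (summary only depends on totals)."""
    recs = []
    per_a, per_b = total_a / (2 * n), total_b / (2 * n)
    for i in range(n):
        for day in (1, 2):
            recs.append(PalatabilityRecord(f"c{i}", day, diet_a, diet_b,
                                           per_a, per_b, diet_b))
    return recs


class TestConsumptionSummary:
    @pytest.mark.parametrize("ta, tb, da, db, ratio, pct_first", [
        (988, 1699, "CD", "T150", 1.72, 63.2),
        (759, 1783, "CD", "T300", 2.35, 70.1),
        (1484, 1047, "T150", "T300", 1.42, 58.6),
    ])
    def test_published_panel_examples(self, ta, tb, da, db, ratio, pct_first):
        s = consumption_summary(_records_with_totals(ta, tb, da, db))
        assert s.ratio == pytest.approx(ratio, abs=0.005)
        assert s.percents[s.diet_order[0]] == pytest.approx(pct_first, abs=0.05)
        assert sum(s.percents.values()) == pytest.approx(100.0, abs=0.1)

    def test_equal_totals(self):
        s = consumption_summary(_records_with_totals(500, 500))
        assert s.ratio == pytest.approx(1.0)

    def test_scale_invariance(self):
        s1 = consumption_summary(_records_with_totals(988, 1699))
        s2 = consumption_summary(_records_with_totals(98.8, 169.9))
        assert s1.ratio == pytest.approx(s2.ratio)
        assert s1.percents == pytest.approx(s2.percents)

    def test_zero_consumption_rejected(self):
        with pytest.raises(ValidationError):
            consumption_summary(_records_with_totals(0, 0))


class TestIntakeRatio:
    def test_single_cat_split(self):
        recs = [PalatabilityRecord("c1", 1, "A", "B", 30, 10, "A")]
        table, means = intake_ratio_per_cat(recs)
        assert means["A"] == pytest.approx(0.75)
        assert means["B"] == pytest.approx(0.25)

    def test_per_cat_closure(self, small_bundle):
        recs = small_bundle.palatability_pair("CD", "T150")
        table, _ = intake_ratio_per_cat(recs)
        sums = table.filter(like="ir_").sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_mean_equals_hand_average(self):
        recs = [PalatabilityRecord(c, 1, "A", "B", a, b, "A")
                for c, a, b in (("c1", 10, 30), ("c2", 20, 20), ("c3", 30, 10))]
        _, means = intake_ratio_per_cat(recs)
        assert means["A"] == pytest.approx((0.25 + 0.5 + 0.75) / 3)

    def test_zero_total_cat_excluded(self):
        recs = [PalatabilityRecord("c1", 1, "A", "B", 30, 10, "A"),
                PalatabilityRecord("c2", 1, "A", "B", 0, 0, "none")]
        table, _ = intake_ratio_per_cat(recs)
        assert list(table["cat_id"]) == ["c1"]


class TestFirstChoice:
    @pytest.mark.parametrize("counts, n_days, x2, p", [
        # overall tests (20 cats x 2 days, expected 20 per diet)
        ((21, 19), 2, 0.1, 0.752),
        ((22, 17), 2, 0.65, 0.420),
        ((22, 16), 2, 1.0, 0.317),
        # daily tests (expected 10 per diet); abstentions do not shrink it
        ((9, 11), 1, 0.2, 0.655),
        ((14, 5), 1, 4.1, 0.043),
        ((13, 6), 1, 2.5, 0.114),
    ])
    def test_published_counts(self, counts, n_days, x2, p):
        stat, pval = first_choice_test(counts, n_cats=20, n_days=n_days)
        assert stat == pytest.approx(x2, abs=0.005)
        assert pval == pytest.approx(p, abs=0.0005)

    def test_even_split_null(self):
        stat, p = first_choice_test((10, 10), n_cats=20, n_days=1)
        assert stat == 0 and p == 1.0

    def test_symmetry(self):
        assert first_choice_test((14, 5), 20, 1) == first_choice_test((5, 14), 20, 1)

    def test_overflow_rejected(self):
        with pytest.raises(ValidationError):
            first_choice_test((15, 10), n_cats=20, n_days=1)


class TestClearPreference:
    @pytest.mark.parametrize("ratio, expected", [
        (2.35, True), (1.72, False), (2.0, True),
    ])
    def test_criterion(self, ratio, expected):
        assert clear_preference(ratio) is expected

    def test_sub_unit_ratio_rejected(self):
        with pytest.raises(ValidationError):
            clear_preference(0.9)


class TestDailyConsumption:
    def test_identical_columns(self):
        t, p = daily_consumption_test([10, 20, 30], [10, 20, 30])
        assert t == 0 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        t, p = daily_consumption_test([3, 4, 5], [1, 2, 3])
        assert np.isinf(t) and p == 0.0

    def test_null_type_i_error(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(30, 5, 20)
            b = rng.normal(30, 5, 20)
            _, p = daily_consumption_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            daily_consumption_test([1], [2])


class TestAcceptanceModel:
    def _panel(self, shift, n=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            treated = i % 2
            mu = 1 / (1 + np.exp(-(0.2 + shift * treated)))
            for period in (1, 2):
                frac = rng.beta(mu * 12, (1 - mu) * 12)
                rows.append({"cat_id": f"c{i}", "treated": treated,
                             "intake_g": frac * 100, "offered_g": 100.0})
        return pd.DataFrame(rows)

    def test_null_covers_unit_odds(self):
        covered = 0
        for seed in range(30):
            _, (lo, hi), _ = acceptance_model(self._panel(0.0, seed=seed))
            covered += lo <= 1.0 <= hi
        assert covered >= 27

    def test_planted_shift_recovered(self):
        ors = [acceptance_model(self._panel(0.5, seed=s))[0] for s in range(20)]
        assert np.mean(ors) == pytest.approx(np.exp(0.5), rel=0.2)

    def test_intake_above_offered_rejected(self):
        df = pd.DataFrame({"cat_id": ["c"], "treated": [1],
                           "intake_g": [120.0], "offered_g": [100.0]})
        with pytest.raises(ValidationError):
            acceptance_model(df)


class TestAttd:
    @pytest.mark.parametrize("intake, output, expected", [
        (10, 2, 80.0),
        (10, 0, 100.0),
        (16.55, 3.044, 81.61),  # direct formula: (16.55-3.044)/16.55*100
    ])
    def test_formula(self, intake, output, expected):
        r = attd(DigestibilityRecord("c", "dm", intake, output))
        assert r.digestibility_percent == pytest.approx(expected, abs=0.01)

    def test_monotone_in_output(self):
        vals = [attd(DigestibilityRecord("c", "dm", 10, o)).digestibility_percent
                for o in (0, 1, 2, 5)]
        assert vals == sorted(vals, reverse=True)

    def test_output_exceeding_intake_flagged(self):
        r = attd(DigestibilityRecord("c", "dm", 10, 12))
        assert r.flagged and r.digestibility_percent < 0

    def test_nonpositive_intake_rejected(self):
        with pytest.raises(ValidationError):
            DigestibilityRecord("c", "dm", 0, 1)


class TestReport:
    def test_full_report_on_synthetic_pair(self, small_bundle):
        recs = small_bundle.palatability_pair("CD", "T300")
        rep = palatability_report(recs)
        s = rep["summary"]
        assert s.diet_order[0] == "T300"  # planted preference direction
        assert set(rep["first_choice_daily"]) == {1, 2}
        assert 0 <= rep["first_choice_overall"]["p"] <= 1
        tests = rep["intake_ratio_tests"]
        assert {"wilcoxon_p", "anova_p"} <= set(tests)
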