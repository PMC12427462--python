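"""Two-bowl palatability analytics and apparent total tract digestibility.

A two-bowl test offers a cat ~100 g of each of two diets for four hours on
each of two days and records grams eaten per bowl and which bowl was
approached first. The summaries here follow standard palatability-panel
conventions: total consumption split and ratio (larger-consumed diet
first, 2:1 being the accepted "clear preference" criterion), per-cat
intake ratios, first-choice chi-square tests, and within-day paired
t-tests of daily consumption. First-choice chi-square expectations use
half the cat-days per diet, NOT half the recorded choices: a cat that
eats from neither bowl abstains, and abstentions do not shrink the null
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DigestibilityRecord, PalatabilityRecord, ValidationError

__all__ = [
    "ConsumptionSummary",
    "consumption_summary",
    "intake_ratio_per_cat",
    "first_choice_test",
    "clear_preference",
    "daily_consumption_test",
    "intake_ratio_tests",
    "acceptance_model",
    "attd",
    "AttdResult",
    "palatability_report",
]


@dataclass
class ConsumptionSummary:
    diet_order: tuple[str, str]        # larger-consumed diet first
    totals_g: dict
    percents: dict
    ratio: float

    @property
    def clear_preference(self) -> bool:
        return clear_preference(self.ratio)


def consumption_summary(records: list[PalatabilityRecord]) -> ConsumptionSummary:
    """Total grams per diet over all cats and days, split percents and the
    consumption ratio (larger total first)."""
    if not records:
        raise ValidationError("no palatability records")
    diets = (records[0].diet_a, records[0].diet_b)
    totals = {d: 0.0 for d in diets}
    for r in records:
        if (r.diet_a, r.diet_b) != diets and (r.diet_b, r.diet_a) != diets:
            raise ValidationError("records mix diet pairs")
        totals[r.diet_a] += r.grams_a
        totals[r.diet_b] += r.grams_b
    grand = sum(totals.values())
    if grand == 0:
        raise ValidationError("no consumption recorded for either diet")
    order = tuple(sorted(diets, key=lambda d: -totals[d]))
    percents = {d: 100.0 * totals[d] / grand for d in diets}
    ratio = totals[order[0]] / totals[order[1]] if totals[order[1]] > 0 else np.inf
    return ConsumptionSummary(diet_order=order, totals_g=totals,
                              percents=percents, ratio=ratio)


def intake_ratio_per_cat(records: list[PalatabilityRecord]):
    """Per-cat intake ratios (share of each diet in the cat's total,
    pooled over days) and their means across cats.

    Cats with zero total consumption are excluded.
    """
    if not records:
        raise ValidationError("no palatability records")
    diets = (records[0].diet_a, records[0].diet_b)
    per_cat: dict[str, dict[str, float]] = {}
    for r in records:
        acc = per_cat.setdefault(r.cat_id, {d: 0.0 for d in diets})
        acc[r.diet_a] += r.grams_a
        acc[r.diet_b] += r.grams_b
    rows = []
    for cat in sorted(per_cat):
        total = sum(per_cat[cat].values())
        if total == 0:
            continue  # excluded: nothing consumed on either day
        rows.append({"cat_id": cat,
                     **{f"ir_{d}": per_cat[cat][d] / total for d in diets}})
    if not rows:
        raise ValidationError("every cat had zero total consumption")
    table = pd.DataFrame(rows)
    means = {d: float(table[f"ir_{d}"].mean()) for d in diets}
    return table, means


def first_choice_test(counts, n_cats: int, n_days: int = 1):
    """Goodness-of-fit chi-square of first-choice counts against an even
    split of ALL cat-days (abstentions do not reduce the expectation).

    Returns (chi-square statistic, p) with df = 1, no continuity
    correction.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2,):
        raise ValidationError("expected first-choice counts for exactly two diets")
    if (obs < 0).any():
        raise ValidationError("negative counts")
    if obs.sum() > n_cats * n_days:
        raise ValidationError("more choices than cat-days")
    expected = n_cats * n_days / 2.0
    if expected < 1:
        raise ValidationError("expected count below 1; test invalid")
    x2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(x2, df=1))
    return x2, p


def clear_preference(ratio: float) -> bool:
    """The standard 2:1 consumption criterion (boundary inclusive)."""
    if ratio < 1:
        raise ValidationError("ratio must be reported larger-total-first (>= 1)")
    return ratio >= 2.0


def daily_consumption_test(grams_a, grams_b):
    """Two-sided paired t-test of per-cat daily consumption of two diets.

    Degenerate pairing (zero variance of the differences) returns t=0,
    p=1 when the diets were eaten identically, else an infinite statistic
    with p=0.
    """
    a = np.asarray(grams_a, dtype=float)
    b = np.asarray(grams_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if len(a) < 2:
        raise ValidationError("need at least two pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0
        return float(np.sign(diff[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def intake_ratio_tests(records: list[PalatabilityRecord]):
    """Wilcoxon signed-rank test of per-cat totals plus a two-way
    (diet + cat) ANOVA of consumption, validating the preference.

    Both tests are standard delegated procedures; this function assembles
    the paired/blocked data. Returns a dict with the Wilcoxon statistic
    and p, and the ANOVA F and p for the diet effect.
    """
    diets = (records[0].diet_a, records[0].diet_b)
    per_cat: dict[str, dict[str, float]] = {}
    for r in records:
        acc = per_cat.setdefault(r.cat_id, {d: 0.0 for d in diets})
        acc[r.diet_a] += r.grams_a
        acc[r.diet_b] += r.grams_b
    cats = sorted(per_cat)
    x = np.array([per_cat[c][diets[0]] for c in cats])
    y = np.array([per_cat[c][diets[1]] for c in cats])
    if np.ptp(x - y) == 0 and (x == y).all():
        wstat, wp = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(x, y)
        wstat, wp = float(res.statistic), float(res.pvalue)

    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    long = pd.DataFrame({
        "grams": np.concatenate([x, y]),
        "diet": [diets[0]] * len(cats) + [diets[1]] * len(cats),
        "cat": cats * 2,
    })
    fit = ols("grams ~ C(diet) + C(cat)", data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    f = float(anova.loc["C(diet)", "F"])
    p = float(anova.loc["C(diet)", "PR(>F)"])
    return {"wilcoxon_stat": wstat, "wilcoxon_p": wp, "anova_f": f, "anova_p": p}


def acceptance_model(data: pd.DataFrame, intake_col: str = "intake_g",
                     offered_col: str = "offered_g", treat_col: str = "treated",
                     cat_col: str = "cat_id"):
    """Odds ratio of diet acceptance, treated vs control.

    Acceptability is intake / offered; the proportion is modeled on the
    logit scale with a random intercept per cat (linear mixed model on
    empirical logits; proportions are clipped away from 0/1 by half an
    observation). Returns (odds ratio, (ci_low, ci_high), p).
    """
    from .contrasts import _fit_mixedlm
    prop = data[intake_col].to_numpy(dtype=float) / data[offered_col].to_numpy(dtype=float)
    if (prop > 1).any():
        raise ValidationError("intake exceeds the amount offered")
    if (data[offered_col] <= 0).any():
        raise ValidationError("offered amount must be positive")
    eps = 0.5 / float(np.max(data[offered_col]))
    prop = np.clip(prop, eps, 1 - eps)
    logit = np.log(prop / (1 - prop))
    x = np.column_stack([np.ones(len(prop)),
                         data[treat_col].to_numpy(dtype=float)])
    res = _fit_mixedlm(logit, x, data[cat_col].to_numpy())
    est = float(res.fe_params[1])
    se = float(np.sqrt(np.asarray(res.cov_params())[1, 1]))
    z = est / se if se > 0 else np.inf
    return (float(np.exp(est)),
            (float(np.exp(est - 1.96 * se)), float(np.exp(est + 1.96 * se))),
            float(2 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class AttdResult:
    nutrient: str
    digestibility_percent: float

    @property
    def flagged(self) -> bool:
        """Negative digestibility (output exceeded intake)."""
        return self.digestibility_percent < 0


def attd(record: DigestibilityRecord) -> AttdResult:
    """Apparent total tract digestibility:
    (intake - fecal output) / intake x 100%."""
    value = 100.0 * (record.intake_g_per_day - record.fecal_output_g_per_day) \
        / record.intake_g_per_day
    return AttdResult(nutrient=record.nutrient, digestibility_percent=value)


def palatability_report(records: list[PalatabilityRecord], n_cats: int | None = None) -> dict:
    """Full two-bowl report for one diet pair: consumption summary,
    intake ratios, overall and daily first-choice tests, daily paired
    t-tests, Wilcoxon/ANOVA validation."""
    summary = consumption_summary(records)
    ir_table, ir_means = intake_ratio_per_cat(records)
    diets = (records[0].diet_a, records[0].diet_b)
    cats = sorted({r.cat_id for r in records})
    if n_cats is None:
        n_cats = len(cats)
    days = sorted({r.day for r in records})

    overall_counts = [sum(r.first_choice == d for r in records) for d in diets]
    overall_x2, overall_p = first_choice_test(overall_counts, n_cats, n_days=len(days))

    daily = {}
    for day in days:
        day_recs = [r for r in records if r.day == day]
        counts = [sum(r.first_choice == d for r in day_recs) for d in diets]
        x2, p = first_choice_test(counts, n_cats, n_days=1)
        by_cat = {r.cat_id: r for r in day_recs}
        a = [by_cat[c].grams_a for c in sorted(by_cat)]
        b = [by_cat[c].grams_b for c in sorted(by_cat)]
        t, tp = daily_consumption_test(a, b)
        daily[day] = {"first_choice_counts": dict(zip(diets, counts)),
                      "chi2": x2, "chi2_p": p,
                      "mean_daily_g": {diets[0]: float(np.mean(a)),
                                       diets[1]: float(np.mean(b))},
                      "paired_t": t, "paired_t_p": tp}
    return {
        "diets": diets,
        "summary": summary,
        "intake_ratio_means": ir_means,
        "intake_ratio_table": ir_table,
        "intake_ratio_tests": intake_ratio_tests(records),
        "first_choice_overall": {"counts": dict(zip(diets, overall_counts)),
                                 "chi2": overall_x2, "p": overall_p},
        "first_choice_daily": daily,
        "clear_preference": summary.clear_preference,
    }
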