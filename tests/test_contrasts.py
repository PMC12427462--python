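"""Polynomial contrasts, per-feature mixed models, bias correction, FDR
and day-ratio contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from scfptrial.contrasts import (bh_adjust, bias_correct, differential_abundance,
                                 fit_feature_models, polynomial_contrasts,
                                 timepoint_ratio_contrast)
from scfptrial.io import TrialDesign, ValidationError


class TestPolynomialContrasts:
    def test_equally_spaced_three_levels(self):
        spec = polynomial_contrasts([0, 150, 300])
        assert np.allclose(spec.vectors["linear"],
                           np.array([-1, 0, 1]) / np.sqrt(2))
        assert np.allclose(spec.vectors["quadratic"],
                           np.array([1, -2, 1]) / np.sqrt(6))

    def test_orthonormal(self):
        spec = polynomial_contrasts([0, 150, 300])
        lin, quad = spec.vectors["linear"], spec.vectors["quadratic"]
        assert lin @ quad == pytest.approx(0, abs=1e-12)
        assert lin @ np.ones(3) == pytest.approx(0, abs=1e-12)
        assert quad @ np.ones(3) == pytest.approx(0, abs=1e-12)
        assert np.linalg.norm(lin) == pytest.approx(1)
        assert np.linalg.norm(quad) == pytest.approx(1)

    def test_affine_invariance(self):
        a = polynomial_contrasts([0, 21, 42])
        b = polynomial_contrasts([0, 150, 300])
        for name in ("linear", "quadratic"):
            assert np.allclose(a.vectors[name], b.vectors[name])

    def test_unequal_spacing_still_orthogonal(self):
        spec = polynomial_contrasts([0, 10, 100])
        lin, quad = spec.vectors["linear"], spec.vectors["quadratic"]
        assert lin @ quad == pytest.approx(0, abs=1e-10)
        assert lin @ np.ones(3) == pytest.approx(0, abs=1e-10)

    def test_two_levels_linear_only(self):
        spec = polynomial_contrasts([0, 42])
        assert set(spec.vectors) == {"linear"}


def _design(n_per_arm=7, days=(0, 21, 42), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    cats = []
    for a, (diet, dose) in enumerate([("CD", 0), ("T150", 150), ("T300", 300)]):
        for i in range(n_per_arm):
            cat = f"cat{a}{i:02d}"
            cats.append((cat, diet, dose))
    for cat, diet, dose in cats:
        sex = "F" if rng.random() < 0.6 else "M"
        for day in days:
            rows.append({"cat_id": cat, "sex": sex, "diet": diet,
                         "dose_mg_per_kg": dose, "timepoint_day": day,
                         "body_weight_kg": 4.4, "sample_id": f"{cat}_d{day:02d}"})
    return TrialDesign(pd.DataFrame(rows))


def _simulate_values(design, trend_features, slope, n_features=20, sigma=0.4,
                     cat_sd=0.3, arm="T300", seed=0):
    """Gaussian CLR-scale features with a planted per-step time trend in one arm."""
    rng = np.random.default_rng(seed)
    meta = design.to_frame()
    days = sorted(meta["timepoint_day"].unique())
    step = meta["timepoint_day"].map({d: i for i, d in enumerate(days)})
    in_arm = (meta["diet"] == arm).to_numpy().astype(float)
    cats = meta["cat_id"].to_numpy()
    cat_fx = {c: rng.normal(0, cat_sd) for c in np.unique(cats)}
    base = np.array([cat_fx[c] for c in cats])
    values = {}
    for f in range(n_features):
        y = base + rng.normal(0, sigma, len(meta))
        if f in trend_features:
            y = y + slope * step.to_numpy() * in_arm
        values[f"f{f:03d}"] = y
    return pd.DataFrame(values, index=meta.index).T


class TestFitFeatureModels:
    def test_planted_trend_recovered(self):
        design = _design(n_per_arm=10)
        planted = set(range(10))
        values = _simulate_values(design, planted, slope=0.3, n_features=12, seed=1)
        fits = fit_feature_models(values, design)
        trend = fits.time_linear_trend(300).set_index("feature")
        est = trend.loc[[f"f{i:03d}" for i in planted], "estimate"]
        assert (np.sign(est) > 0).sum() >= 9
        assert est.mean() == pytest.approx(0.3, abs=0.1)

    def test_constant_feature_skipped(self):
        design = _design(n_per_arm=3)
        values = _simulate_values(design, set(), 0.0, n_features=3, seed=2)
        values.loc["f000"] = 1.0
        fits = fit_feature_models(values, design)
        assert "f000" in fits.skipped
        assert "f000" not in fits.features

    def test_type_i_error_for_dose_contrast(self):
        # pure noise: the linear dose term should reject near the nominal rate
        design = _design(n_per_arm=7)
        ps = []
        for seed in range(8):
            values = _simulate_values(design, set(), 0.0, n_features=25, seed=seed)
            fits = fit_feature_models(values, design)
            ps.extend(fits.term_table("dose_linear")["p"].tolist())
        ps = np.asarray(ps)
        assert 0.01 <= (ps < 0.05).mean() <= 0.10

    def test_binary_coding_runs(self):
        design = _design(n_per_arm=4)
        values = _simulate_values(design, set(), 0.0, n_features=4, seed=3)
        fits = fit_feature_models(values, design, coding="binary", sex_adjust=True)
        assert "scfp" in fits.terms and "sex_M" in fits.terms

    def test_unknown_samples_rejected(self):
        design = _design(n_per_arm=3)
        values = _simulate_values(design, set(), 0.0, n_features=2, seed=4)
        values.columns = [f"x{i}" for i in range(values.shape[1])]
        with pytest.raises(ValidationError):
            fit_feature_models(values, design)


class TestBiasCorrect:
    def test_median_centering(self):
        corrected, offset = bias_correct([1, 1, 1, 5, 1])
        assert offset == 1
        assert np.allclose(corrected, [0, 0, 0, 4, 0])

    def test_all_equal_becomes_zero(self):
        corrected, offset = bias_correct([2.5] * 6)
        assert np.allclose(corrected, 0)
        assert offset == 2.5

    def test_too_few_features_warns_no_correction(self):
        with pytest.warns(UserWarning):
            corrected, offset = bias_correct([1, 2, 3])
        assert offset == 0 and np.allclose(corrected, [1, 2, 3])

    def test_planted_compositional_shift_removed(self, rng):
        # 90% nulls contaminated by a constant +0.4 shift
        true = np.zeros(200)
        true[:20] = rng.normal(1.5, 0.3, 20)
        observed = true + 0.4 + rng.normal(0, 0.02, 200)
        corrected, offset = bias_correct(observed)
        assert abs(corrected[20:].mean()) < 0.05
        assert offset == pytest.approx(0.4, abs=0.05)


def _bh_oracle(p):
    """Literal step-up definition: q_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p", [[1.0, 1.0, 1.0], [0.2], [0.5, 0.01, 0.04, 0.03]])
    def test_small_cases(self, p):
        assert np.allclose(bh_adjust(p), _bh_oracle(p))

    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_on_arbitrary_vectors(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p))
        # q preserves the ordering of p
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestDifferentialAbundance:
    def test_flags_planted_trends_in_bundle(self, small_bundle):
        from scfptrial.butyrate import classify_species, producer_subset
        calls = classify_species(small_bundle.annotations)
        sub = producer_subset(small_bundle.abundance, calls)
        res = differential_abundance(sub, small_bundle.design, arm_dose=300)
        res = res.set_index("feature")
        truth = small_bundle.truth["planted_trends"]
        for taxon, info in truth.items():
            assert np.sign(res.loc[taxon, "estimate"]) == np.sign(info["slope_per_step"])
            assert res.loc[taxon, "q"] < 0.05
        nulls = [f for f in res.index if f not in truth]
        assert (res.loc[nulls, "q"] < 0.05).mean() <= 0.2


class TestTimepointRatioContrast:
    def _data(self, ratios, n=12, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, (group, ratio) in enumerate(ratios.items()):
            for i in range(n):
                cat = f"{group}_c{i}"
                base = np.exp(rng.normal(np.log(100), 0.2))
                for day, mult in ((0, 1.0), (42, ratio)):
                    rows.append({"cat_id": cat, "diet": group, "timepoint_day": day,
                                 "count": base * mult * np.exp(rng.normal(0, sd))})
        return pd.DataFrame(rows)

    def test_identical_counts_give_unit_ratio(self):
        data = self._data({"CD": 1.0}, sd=0.0)
        ratios, _ = timepoint_ratio_contrast(data)
        assert ratios["CD"].ratio == pytest.approx(1.0, abs=1e-6)

    def test_planted_decline_recovered(self):
        est = []
        for seed in range(20):
            data = self._data({"CD": 0.8}, seed=seed)
            ratios, _ = timepoint_ratio_contrast(data)
            est.append(ratios["CD"].ratio)
        assert np.mean(est) == pytest.approx(0.8, abs=0.05)

    def test_pairwise_contrast_detects_group_difference(self):
        hits = 0
        for seed in range(10):
            data = self._data({"CD": 1.0, "T300": 0.8}, n=21, seed=seed)
            _, comp = timepoint_ratio_contrast(data)
            p = comp.loc[comp["kind"] == "pairwise", "p"].iloc[0]
            hits += p < 0.05
        assert hits >= 8

    def test_poisson_family_runs(self):
        rng = np.random.default_rng(5)
        rows = []
        for g, lam in (("CD", 40), ("T300", 30)):
            for i in range(10):
                for day in (0, 42):
                    rows.append({"cat_id": f"{g}{i}", "diet": g, "timepoint_day": day,
                                 "count": rng.poisson(lam)})
        ratios, comp = timepoint_ratio_contrast(pd.DataFrame(rows), family="poisson")
        assert set(ratios) == {"CD", "T300"}
        assert ratios["CD"].ci_low <= ratios["CD"].ratio <= ratios["CD"].ci_high

    def test_single_timepoint_rejected(self):
        data = pd.DataFrame({"cat_id": ["a", "b"], "diet": ["CD", "CD"],
                             "timepoint_day": [0, 0], "count": [1, 2]})
        with pytest.raises(ValidationError):
            timepoint_ratio_contrast(data)
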