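"""Dose/time polynomial contrasts, per-feature mixed models, compositional
bias correction and FDR — the longitudinal differential-abundance engine.

The model mirrors the trial's analysis plan: every feature (a CLR-scale
taxon abundance, a functional-potential value, or any continuous outcome)
is fitted with a linear mixed model with treatment, timepoint and their
interaction as fixed effects and cat as a random intercept. Treatment is
coded either as ordered dose levels (0/150/300 mg/kg, orthogonal linear
and quadratic polynomial contrasts) or as a binary control-vs-supplemented
variable. Post-hoc arm-specific time trends are linear combinations of
the fitted coefficients (emmeans-style). Compositional bias in CLR-scale
coefficients is removed by subtracting a location estimate (median by
default) across features, after which p-values are recomputed — a
LinDA-style correction. Multiplicity is handled by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, TrialDesign, ValidationError
from .diversity import clr_transform

__all__ = [
    "ContrastSpec",
    "polynomial_contrasts",
    "fit_feature_models",
    "FeatureModelResults",
    "bias_correct",
    "bh_adjust",
    "differential_abundance",
    "timepoint_ratio_contrast",
    "RatioContrast",
]


def _fit_mixedlm(y, x, groups, reml: bool = True):
    """MixedLM fit with an optimizer fallback chain (near-zero random-effect
    variance can make the default optimizer's score singular)."""
    last = None
    for method in ("lbfgs", "powell", "cg"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return MixedLM(y, x, groups=groups).fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
    raise last


@dataclass(frozen=True)
class ContrastSpec:
    """Orthonormal polynomial coding of an ordered factor."""

    factor: str
    levels: tuple[float, ...]
    vectors: dict  # name -> np.ndarray over levels
    binary: bool = False

    def coordinates(self, level: float, name: str) -> float:
        return float(self.vectors[name][self.levels.index(level)])


def polynomial_contrasts(levels, factor: str = "level") -> ContrastSpec:
    """Orthonormal linear/quadratic contrasts for ordered numeric levels.

    Built by QR on the centered Vandermonde matrix, so unequally spaced
    levels get the proper weights; for fewer than three levels only the
    linear contrast exists. Signs are fixed so the linear vector increases
    with the level.
    """
    x = np.asarray(sorted(levels), dtype=float)
    if len(np.unique(x)) != len(x):
        raise ValidationError("contrast levels must be distinct")
    k = len(x)
    if k < 2:
        raise ValidationError("need at least two levels")
    degree = min(k - 1, 2)
    vander = np.vander(x - x.mean(), degree + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    vectors = {}
    names = ["linear", "quadratic"]
    for d in range(1, degree + 1):
        v = q[:, d]
        # sign convention: positive projection on x**d
        if v @ (x ** d) < 0:
            v = -v
        vectors[names[d - 1]] = v
    return ContrastSpec(factor=factor, levels=tuple(x), vectors=vectors)


# ---------------------------------------------------------------------------
# fixed-effects design construction
# ---------------------------------------------------------------------------

def _build_design(meta: pd.DataFrame, coding: str, sex_adjust: bool):
    """Fixed-effect matrix with treatment/time polynomial coding.

    Returns (X DataFrame, time contrast spec, treatment contrast spec or
    None for binary coding).
    """
    doses = sorted(meta["dose_mg_per_kg"].unique())
    days = sorted(meta["timepoint_day"].unique())
    time_spec = polynomial_contrasts(days, factor="timepoint_day")
    cols = {"Intercept": np.ones(len(meta))}

    if coding == "ordered":
        if len(doses) < 3:
            raise ValidationError("ordered coding needs the three dose levels")
        dose_spec = polynomial_contrasts(doses, factor="dose_mg_per_kg")
        treat_cols = {
            f"dose_{name}": meta["dose_mg_per_kg"].map(
                dict(zip(dose_spec.levels, vec))).to_numpy()
            for name, vec in dose_spec.vectors.items()}
    elif coding == "binary":
        dose_spec = None
        treat_cols = {"scfp": (meta["dose_mg_per_kg"] > 0).astype(float).to_numpy()}
    else:
        raise ValidationError(f"unknown coding {coding!r}")

    time_cols = {
        f"time_{name}": meta["timepoint_day"].map(
            dict(zip(time_spec.levels, vec))).to_numpy()
        for name, vec in time_spec.vectors.items()}

    cols.update(treat_cols)
    cols.update(time_cols)
    for tname, tcol in treat_cols.items():
        for dname, dcol in time_cols.items():
            cols[f"{tname}:{dname}"] = tcol * dcol
    if sex_adjust:
        cols["sex_M"] = (meta["sex"] == "M").astype(float).to_numpy()

    x = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValidationError("rank-deficient fixed-effects design")
    return x, time_spec, dose_spec


@dataclass
class FeatureModelResults:
    """Per-feature mixed-model fits with contrast machinery.

    ``params``/``bse`` are feature x term frames; ``cov`` maps feature to
    the fixed-effects covariance matrix. P-values use a t reference with
    residual degrees of freedom (n_obs - fixed-effect rank).
    """

    params: pd.DataFrame
    bse: pd.DataFrame
    cov: dict
    terms: list[str]
    df_resid: int
    time_spec: ContrastSpec
    dose_spec: ContrastSpec | None
    coding: str
    skipped: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.params.index)

    def _pvalue(self, est, se):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, np.inf * np.sign(est))
        return 2 * stats.t.sf(np.abs(t), self.df_resid)

    def term_table(self, term: str) -> pd.DataFrame:
        est = self.params[term].to_numpy()
        se = self.bse[term].to_numpy()
        return pd.DataFrame({"feature": self.features, "estimate": est, "se": se,
                             "p": self._pvalue(est, se)})

    def contrast(self, weights: dict[str, float], label: str = "contrast") -> pd.DataFrame:
        """Linear combination of coefficients, per feature."""
        w = np.array([weights.get(t, 0.0) for t in self.terms])
        est, se = [], []
        for f in self.features:
            b = self.params.loc[f].to_numpy()
            v = self.cov[f]
            est.append(float(w @ b))
            se.append(float(np.sqrt(w @ v @ w)))
        est = np.asarray(est)
        se = np.asarray(se)
        return pd.DataFrame({"feature": self.features, "contrast": label,
                             "estimate": est, "se": se, "p": self._pvalue(est, se)})

    def time_linear_trend(self, arm_dose: float | None = None) -> pd.DataFrame:
        """Per-step linear time slope, optionally within one dose arm.

        The orthonormal time-linear contrast estimate is rescaled to
        change-per-timepoint-step so planted slopes compare directly.
        """
        steps = np.arange(len(self.time_spec.levels), dtype=float)
        scale = float(self.time_spec.vectors["linear"] @ steps)  # theta = slope*scale
        weights = {"time_linear": 1.0}
        if arm_dose is not None:
            if self.coding == "ordered":
                for name in self.dose_spec.vectors:
                    weights[f"dose_{name}:time_linear"] = \
                        self.dose_spec.coordinates(arm_dose, name)
            else:
                weights["scfp:time_linear"] = 1.0 if arm_dose > 0 else 0.0
        out = self.contrast(weights, label=f"time_linear@dose={arm_dose}")
        out["estimate"] = out["estimate"] / scale
        out["se"] = out["se"] / scale
        return out


def fit_feature_models(values: pd.DataFrame, design: TrialDesign,
                       coding: str = "ordered", sex_adjust: bool = False,
                       reml: bool = True) -> FeatureModelResults:
    """Fit a random-intercept LMM per feature.

    Parameters
    ----------
    values : DataFrame
        Features x samples matrix (CLR scale or continuous outcomes);
        columns must be sample ids present in the design.
    design : TrialDesign
    coding : "ordered" (dose polynomial) or "binary" (CD vs pooled SCFP)
    sex_adjust : include a sex fixed effect

    Constant (or all-zero) features are skipped with a recorded reason,
    not an error. Fitting is delegated to statsmodels MixedLM; design
    construction, contrast algebra and extraction live here.
    """
    meta = design.to_frame()
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples not in design: {missing[:5]}")
    meta = meta.loc[values.columns]
    x, time_spec, dose_spec = _build_design(meta, coding, sex_adjust)
    groups = meta["cat_id"].to_numpy()
    n, p = x.shape
    df_resid = n - p

    params, bses, covs, skipped, converged = {}, {}, {}, {}, {}
    xv = x.to_numpy()
    for feature in values.index:
        y = values.loc[feature].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            skipped[feature] = "constant feature"
            continue
        try:
            res = _fit_mixedlm(y, xv, groups, reml=reml)
        except Exception as exc:  # pragma: no cover - pathological inputs
            skipped[feature] = f"fit failed: {exc}"
            continue
        params[feature] = res.fe_params
        covmat = np.asarray(res.cov_params())[:p, :p]
        covs[feature] = covmat
        bses[feature] = np.sqrt(np.diag(covmat))
        converged[feature] = bool(res.converged)
    if not params:
        raise ValidationError("no fittable features")
    terms = list(x.columns)
    return FeatureModelResults(
        params=pd.DataFrame(params, index=terms).T,
        bse=pd.DataFrame(bses, index=terms).T,
        cov=covs, terms=terms, df_resid=df_resid,
        time_spec=time_spec, dose_spec=dose_spec, coding=coding,
        skipped=skipped, converged=converged)


# ---------------------------------------------------------------------------
# bias correction and FDR
# ---------------------------------------------------------------------------

def bias_correct(coefficients, mode: str = "median"):
    """Remove a shared compositional offset from per-feature coefficients.

    Subtracts the median (or a histogram-mode estimate) of the
    coefficients; returns (corrected array, offset). With fewer than five
    features no correction is applied (offset 0) and a warning is issued.
    """
    coefs = np.asarray(coefficients, dtype=float)
    if coefs.size < 5:
        warnings.warn("fewer than 5 features: skipping bias correction")
        return coefs.copy(), 0.0
    if mode == "median":
        offset = float(np.median(coefs))
    elif mode == "mode":
        # kernel-smoothed mode of the coefficient distribution
        kde = stats.gaussian_kde(coefs)
        grid = np.linspace(coefs.min(), coefs.max(), 512)
        offset = float(grid[np.argmax(kde(grid))])
    else:
        raise ValidationError(f"unknown bias-correction mode {mode!r}")
    return coefs - offset, offset


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(table: AbundanceTable, design: TrialDesign,
                           arm_dose: float | None = 300,
                           pseudocount: float = 0.5,
                           coding: str = "ordered",
                           bias_mode: str = "median",
                           sex_adjust: bool = False,
                           values: pd.DataFrame | None = None) -> pd.DataFrame:
    """LinDA-style differential abundance of the linear time trend.

    CLR-transforms the table (or takes precomputed CLR-scale ``values``,
    features x samples), fits the per-feature mixed models, extracts the
    per-step linear time trend within ``arm_dose`` (or the overall trend
    when None), removes the compositional bias offset, recomputes p-values
    and BH-adjusts them.
    """
    if values is None:
        values = clr_transform(table, pseudocount).T
    fits = fit_feature_models(values, design, coding=coding, sex_adjust=sex_adjust)
    raw = fits.time_linear_trend(arm_dose)
    corrected, offset = bias_correct(raw["estimate"].to_numpy(), mode=bias_mode)
    se = raw["se"].to_numpy()
    p = fits._pvalue(corrected, se)
    out = pd.DataFrame({
        "feature": raw["feature"],
        "estimate_raw": raw["estimate"].to_numpy(),
        "estimate": corrected,
        "se": se,
        "bias_offset": offset,
        "p": p,
        "q": bh_adjust(p),
    })
    return out.sort_values("feature").reset_index(drop=True)


# ---------------------------------------------------------------------------
# day-ratio contrasts for count outcomes
# ---------------------------------------------------------------------------

@dataclass
class RatioContrast:
    """Group-level day-last : day-first ratio on the response scale.

    ratio < 1 means the outcome was higher at the first day; > 1 higher
    at the last day.
    """

    group: str
    ratio: float
    ci_low: float
    ci_high: float
    p: float


def timepoint_ratio_contrast(data: pd.DataFrame, family: str = "gaussian-log",
                             group_col: str = "diet", value_col: str = "count",
                             cat_col: str = "cat_id", time_col: str = "timepoint_day"):
    """Per-group end:start ratio from a log-link mixed model, plus
    pairwise and polynomial dose comparisons of the log-ratios.

    ``gaussian-log`` fits a random-intercept LMM on log counts;
    ``poisson`` fits a Poisson GEE with exchangeable correlation within
    cat. Both use cell-mean (group x timepoint) coding so each ratio is
    exp(cell[t_last] - cell[t_first]) and comparisons are linear
    contrasts of log-ratios.
    """
    df = data.copy()
    times = sorted(df[time_col].unique())
    if len(times) < 2:
        raise ValidationError("need at least two timepoints")
    t0, t1 = times[0], times[-1]
    groups = sorted(df[group_col].unique())
    if family == "poisson":
        zero_cells = df.groupby([group_col, time_col])[value_col].sum()
        if (zero_cells == 0).any():
            raise ValidationError("a group-timepoint cell has all-zero counts")

    cell = df[group_col].astype(str) + "|" + df[time_col].astype(str)
    dummies = pd.get_dummies(cell).astype(float)
    cells = list(dummies.columns)
    xv = dummies.to_numpy()

    if family == "gaussian-log":
        if (df[value_col] <= 0).any():
            raise ValidationError("gaussian-log needs positive outcomes")
        y = np.log(df[value_col].to_numpy(dtype=float))
        res = _fit_mixedlm(y, xv, df[cat_col].to_numpy())
        beta = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:len(cells), :len(cells)]
    elif family == "poisson":
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(df[value_col].to_numpy(dtype=float), xv,
                         groups=df[cat_col].to_numpy(),
                         family=sm.families.Poisson(),
                         cov_struct=sm.cov_struct.Exchangeable()).fit()
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
    else:
        raise ValidationError(f"unknown family {family!r}")

    def cell_index(g, t):
        return cells.index(f"{g}|{t}")

    ratios = {}
    logr = {}
    for g in groups:
        w = np.zeros(len(cells))
        w[cell_index(g, t1)] = 1.0
        w[cell_index(g, t0)] = -1.0
        est = float(w @ beta)
        se = float(np.sqrt(w @ cov @ w))
        z = est / se if se > 0 else np.inf
        ratios[g] = RatioContrast(
            group=str(g), ratio=float(np.exp(est)),
            ci_low=float(np.exp(est - 1.96 * se)),
            ci_high=float(np.exp(est + 1.96 * se)),
            p=float(2 * stats.norm.sf(abs(z))))
        logr[g] = (w, est)

    comparisons = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            w = logr[gi][0] - logr[gj][0]
            est = float(w @ beta)
            se = float(np.sqrt(w @ cov @ w))
            z = est / se if se > 0 else np.inf
            comparisons.append({"comparison": f"{gi} vs {gj}", "kind": "pairwise",
                                "log_ratio_diff": est, "se": se,
                                "p": float(2 * stats.norm.sf(abs(z)))})
    if len(groups) >= 3:
        doses = np.arange(len(groups), dtype=float)
        spec = polynomial_contrasts(doses, factor=group_col)
        for name, vec in spec.vectors.items():
            w = np.zeros(len(cells))
            for g, c in zip(groups, vec):
                w += c * logr[g][0]
            est = float(w @ beta)
            se = float(np.sqrt(w @ cov @ w))
            z = est / se if se > 0 else np.inf
            comparisons.append({"comparison": name, "kind": "polynomial",
                                "log_ratio_diff": est, "se": se,
                                "p": float(2 * stats.norm.sf(abs(z)))})
    return ratios, pd.DataFrame(comparisons)
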