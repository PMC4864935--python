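"""Joint mining of image features, gene expression, clinical data and survival.

The screening rules operate on an aligned per-sample table collection
(:class:`JointDataset`):

* feature-gene association: Pearson correlation test at alpha = 0.05 with the
  additional requirement |rho| >= 0.5; no multiple-testing adjustment is
  applied by default (screening is exploratory);
* feature vs dichotomized clinical variables (T: {T1,T2} vs {T3,T4};
  G: {G1,G2} vs G3) by two-sided Welch t-test;
* block association by canonical correlation analysis with Wilks' lambda;
* survival by Cox proportional hazards with likelihood-ratio tests, hazard
  ratios reported per interquartile range of the covariate, Kaplan-Meier
  curves and log-rank tests after a median split.

An image prognostic score is the mean of selected codeblock frequencies; a
genomic score (e.g. a proliferation signature) is consumed as a precomputed
input column.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.multivariate.cancorr import CanCorr

from .exceptions import DataError, DegenerateInputError, ParameterError

T_LOW, T_HIGH = {"T1", "T2"}, {"T3", "T4"}
G_LOW, G_HIGH = {"G1", "G2"}, {"G3"}

DEFAULT_SCORE_COMPONENTS = ("C.41", "C.56", "C.65", "C.67", "C.69")


@dataclasses.dataclass
class JointDataset:
    """Aligned per-sample tables for joint mining.

    All tables must share the same ordered sample index.  ``clinical`` holds
    categorical columns ``T`` (T1..T4) and ``G`` (G1..G3); ``survival`` holds
    ``time`` (> 0) and ``event`` (0/1); ``genomic_score`` is an optional
    precomputed prognostic scalar per sample.
    """

    features: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    survival: pd.DataFrame
    genomic_score: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.features.index
        for name, tab in [("expression", self.expression),
                          ("clinical", self.clinical),
                          ("survival", self.survival)]:
            if not tab.index.equals(idx):
                raise DataError(f"{name} index differs from features index")
        if self.genomic_score is not None and not self.genomic_score.index.equals(idx):
            raise DataError("genomic_score index differs from features index")
        if (self.survival["time"] <= 0).any():
            raise DataError("survival times must be positive")

    @property
    def n(self) -> int:
        return len(self.features)

    def column(self, name: str) -> pd.Series:
        """Resolve a variable by name across features / expression / scores.

        A bare codeblock name like ``C.41`` resolves to its frequency column
        ``freq_C.41``.
        """
        for tab in (self.features, self.expression):
            if name in tab.columns:
                return tab[name]
            if f"freq_{name}" in tab.columns:
                return tab[f"freq_{name}"]
        if name == "genomic_score" and self.genomic_score is not None:
            return self.genomic_score
        raise ParameterError(f"unknown variable {name!r}")


@dataclasses.dataclass
class SurvivalModelResult:
    """A fitted Cox model on IQR-standardized covariates."""

    coefficients: pd.Series          # per-IQR log hazard ratios
    hazard_ratios: pd.Series         # per-IQR HRs
    conf_int: pd.DataFrame           # 95 % CI of the HRs
    log_likelihood: float
    p_value: float                   # likelihood-ratio test vs the null model
    model: CoxPHFitter
    iqr: float = 1.0                 # raw-scale IQR used for standardization


def _pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of the Pearson correlation t-test."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlate_features_genes(
    ds: JointDataset,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    features: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All feature x gene Pearson correlations with the screening rule.

    A pair is kept when p < alpha AND |rho| >= rho_min.  Zero-variance
    columns make a pair untestable (``testable`` False, never kept).  No
    multiplicity adjustment is applied.
    """
    F = ds.features[list(features)] if features is not None else ds.features
    E = ds.expression[list(genes)] if genes is not None else ds.expression
    n = len(F)
    if n < 3:
        raise DegenerateInputError("need at least 3 samples for correlation")
    Fv, Ev = F.to_numpy(float), E.to_numpy(float)
    f_sd, e_sd = Fv.std(axis=0), Ev.std(axis=0)
    Fc = Fv - Fv.mean(axis=0)
    Ec = Ev - Ev.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Fc.T @ Ec) / n / np.outer(f_sd, e_sd)
    p = _pearson_pvalue(rho, n)
    testable = np.outer(f_sd > 0, e_sd > 0)
    rows = []
    for i, fname in enumerate(F.columns):
        for j, gname in enumerate(E.columns):
            ok = bool(testable[i, j])
            r = float(rho[i, j]) if ok else np.nan
            pv = float(p[i, j]) if ok else np.nan
            rows.append({
                "feature": fname, "gene": gname, "rho": r, "p_value": pv,
                "testable": ok,
                "kept": ok and pv < alpha and abs(r) >= rho_min,
            })
    return pd.DataFrame(rows)


def sum_correlated_features(
    ds: JointDataset, feature_group: Sequence[str], name: str | None = None
) -> pd.Series:
    """Row-wise sum of a group of (correlated) frequency features.

    Summing codeblock frequencies that individually correlate with the same
    gene pools their signal and averages out independent noise, typically
    raising the correlation above any single component's.
    """
    cols = [ds.column(f) for f in feature_group]
    out = pd.concat(cols, axis=1).sum(axis=1)
    out.name = name or "sum(" + "+".join(feature_group) + ")"
    return out


def dichotomize_clinical_test(
    ds: JointDataset, feature: str, variable: str = "T"
) -> dict:
    """Welch two-sided t-test of a feature between dichotomized clinical groups.

    T stage splits as {T1, T2} vs {T3, T4}; grade as {G1, G2} vs G3.
    """
    if variable == "T":
        low_set, high_set = T_LOW, T_HIGH
    elif variable == "G":
        low_set, high_set = G_LOW, G_HIGH
    else:
        raise ParameterError("variable must be 'T' or 'G'")
    x = ds.column(feature)
    labels = ds.clinical[variable].astype(str)
    low = x[labels.isin(low_set)]
    high = x[labels.isin(high_set)]
    if len(low) < 2 or len(high) < 2:
        return {"feature": feature, "variable": variable, "statistic": np.nan,
                "p_value": np.nan, "testable": False, "kept": False}
    t, p = stats.ttest_ind(low, high, equal_var=False)
    return {"feature": feature, "variable": variable, "statistic": float(t),
            "p_value": float(p), "testable": True, "kept": bool(p < 0.05)}


def cca_screen(
    feature_block: pd.DataFrame, expression_block: pd.DataFrame
) -> tuple[np.ndarray, float, float]:
    """Canonical correlation analysis between two variable blocks.

    Returns (canonical correlations, Wilks' lambda, p of Wilks' test for the
    full set of canonical dimensions).  Requires n > p + q and full-rank
    blocks.
    """
    F = np.asarray(feature_block, dtype=float)
    E = np.asarray(expression_block, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    if E.ndim == 1:
        E = E[:, None]
    n, p = F.shape
    q = E.shape[1]
    if n <= p + q:
        raise ParameterError(f"CCA needs n > p + q ({n} <= {p + q})")
    if np.linalg.matrix_rank(F - F.mean(0)) < p or \
            np.linalg.matrix_rank(E - E.mean(0)) < q:
        raise DegenerateInputError("rank-deficient block in CCA")
    if p == 1 and q == 1:
        # degenerate CCA: the single canonical correlation is |pearson r|
        # and Wilks' test reduces to the exact F test of that correlation
        r = float(np.corrcoef(F[:, 0], E[:, 0])[0, 1])
        lam = 1.0 - r * r
        fstat = (r * r / lam) * (n - 2)
        pval = float(stats.f.sf(fstat, 1, n - 2))
        return np.array([abs(r)]), lam, pval
    # statsmodels requires the endog block to have >= 2 columns
    cc = CanCorr(E, F) if q >= 2 else CanCorr(F, E)
    res = cc.corr_test().stats
    return (np.asarray(cc.cancorr),
            float(res["Wilks' lambda"].iloc[0]),
            float(res["Pr > F"].iloc[0]))


def _iqr(x: pd.Series) -> float:
    return float(x.quantile(0.75) - x.quantile(0.25))


def cox_univariate(ds: JointDataset, variable: str | pd.Series) -> SurvivalModelResult:
    """Univariate Cox PH fit of an IQR-standardized covariate.

    The covariate is divided by its interquartile range before fitting, so
    the reported hazard ratio is per IQR increment (invariant to any positive
    rescaling of the raw variable).  The p-value is the likelihood-ratio test
    against the null model.
    """
    x = ds.column(variable) if isinstance(variable, str) else variable
    name = x.name or "x"
    iqr = _iqr(x)
    if iqr <= 0:
        raise ParameterError(f"variable {name!r} has zero IQR; not testable")
    if ds.survival["event"].sum() < 1:
        raise DataError("no events in survival data")
    df = pd.DataFrame({"time": ds.survival["time"],
                       "event": ds.survival["event"],
                       name: x / iqr})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    ci = np.exp(cph.confidence_intervals_)
    ci.columns = ["hr_lower_95", "hr_upper_95"]
    return SurvivalModelResult(
        coefficients=cph.params_,
        hazard_ratios=cph.hazard_ratios_,
        conf_int=ci,
        log_likelihood=float(cph.log_likelihood_),
        p_value=float(cph.log_likelihood_ratio_test().p_value),
        model=cph,
        iqr=iqr,
    )


def image_score(
    ds: JointDataset, components: Sequence[str] = DEFAULT_SCORE_COMPONENTS
) -> pd.Series:
    """Image prognostic score: mean of the named codeblock frequencies."""
    cols = [ds.column(c) for c in components]
    score = pd.concat(cols, axis=1).mean(axis=1)
    score.name = "image_score"
    return score


@dataclasses.dataclass
class CombinedModelResult:
    """Bivariate Cox model with nested likelihood-ratio and interaction tests."""

    bivariate: SurvivalModelResult
    lrt_p_vs_univariate: dict[str, float]
    interaction_p: float


def _fit_cox(ds: JointDataset, covs: pd.DataFrame) -> CoxPHFitter:
    df = pd.concat([ds.survival[["time", "event"]], covs], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def combined_model_test(
    ds: JointDataset, image: pd.Series, genomic: pd.Series
) -> CombinedModelResult:
    """Joint Cox model of the image and genomic scores.

    Fits the bivariate model on IQR-standardized scores, tests it against
    each nested univariate model by likelihood ratio (chi^2, 1 df), and tests
    the image x genomic interaction term the same way.  Near-collinear scores
    (|rho| > 0.999) trigger a warning.
    """
    if ds.survival["event"].sum() < 2:
        raise DataError("need at least 2 events for the combined model")
    rho = float(np.corrcoef(image, genomic)[0, 1])
    if abs(rho) > 0.999:
        warnings.warn("image and genomic scores are near-collinear", stacklevel=2)
    zi = (image / _iqr(image)).rename("image_score")
    zg = (genomic / _iqr(genomic)).rename("genomic_score")
    both = _fit_cox(ds, pd.concat([zi, zg], axis=1))
    ci = np.exp(both.confidence_intervals_)
    ci.columns = ["hr_lower_95", "hr_upper_95"]
    biv = SurvivalModelResult(
        coefficients=both.params_, hazard_ratios=both.hazard_ratios_,
        conf_int=ci, log_likelihood=float(both.log_likelihood_),
        p_value=float(both.log_likelihood_ratio_test().p_value), model=both,
    )
    lrt = {}
    for sub_cols, label in [([zi], "vs_image_only"), ([zg], "vs_genomic_only")]:
        sub = _fit_cox(ds, pd.concat(sub_cols, axis=1))
        chi2 = 2.0 * (both.log_likelihood_ - sub.log_likelihood_)
        lrt[label] = float(stats.chi2.sf(max(chi2, 0.0), df=1))
    inter = (zi * zg).rename("image_x_genomic")
    full = _fit_cox(ds, pd.concat([zi, zg, inter], axis=1))
    chi2 = 2.0 * (full.log_likelihood_ - both.log_likelihood_)
    interaction_p = float(stats.chi2.sf(max(chi2, 0.0), df=1))
    return CombinedModelResult(biv, lrt, interaction_p)


def km_by_median(
    ds: JointDataset, score: pd.Series
) -> tuple[pd.Series, float, dict[str, KaplanMeierFitter]]:
    """Median split of a score with Kaplan-Meier curves and a log-rank test.

    Samples at or below the median go to the 'low' group (ties -> low).
    Returns (group labels, log-rank p, fitted KM estimators per group).
    """
    med = float(score.median())
    groups = pd.Series(np.where(score > med, "high", "low"), index=score.index,
                       name="group")
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise DegenerateInputError("score does not separate at its median")
    fitters = {}
    for g in ("low", "high"):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(ds.survival.loc[sel, "time"], ds.survival.loc[sel, "event"],
                label=g)
        fitters[g] = kmf
    lr = logrank_test(
        ds.survival.loc[groups == "low", "time"],
        ds.survival.loc[groups == "high", "time"],
        event_observed_A=ds.survival.loc[groups == "low", "event"],
        event_observed_B=ds.survival.loc[groups == "high", "event"],
    )
    return groups, float(lr.p_value), fitters


def survival_at_horizon(
    result: SurvivalModelResult, score_values: pd.Series | np.ndarray,
    t: float = 4.0,
) -> pd.Series:
    """Predicted event-free probability S(t | score) from a fitted Cox model.

    ``score_values`` are on the RAW scale of the covariate: the model was fit
    on the IQR-standardized version and the stored IQR is re-applied here.
    Warns when ``t`` exceeds the observed follow-up.
    """
    cph = result.model
    max_t = float(cph.durations.max())
    if t > max_t:
        warnings.warn(f"horizon {t} beyond observed follow-up {max_t:.3g}",
                      stacklevel=2)
    name = result.coefficients.index[0]
    values = np.atleast_1d(np.asarray(score_values, dtype=float)) / result.iqr
    X = pd.DataFrame({name: values})
    surv = cph.predict_survival_function(X, times=[t])
    return pd.Series(surv.iloc[0].to_numpy(), name=f"S({t})")
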