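"""Population structure of touch modulation: bias vs potentiation.

Per-unit fold modulations are derived from the fitted GLM coefficients,

    touch_mod  = exp(b_touch)                      (touch-only model)
    female_mod = exp(b_touch)                      (touch+sex model)
    male_mod   = exp(b_touch + b_sex)

and the population geometry of male vs female modulation is characterized by
the mixed-effects regression (fitted on the log2 fold-change scale)

    male_mod ~ 1 + female_mod + subject_sex + female_mod:subject_sex
               + (1 | subject)

A slope CI excluding 1 indicates potentiation (context-dependent scaling of
response magnitude); an intercept CI excluding 0 indicates an additive bias.
Units with more than a 32-fold increase or decrease on either axis
(|log2 mod| > 5) are excluded from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "touch_modulation",
    "sex_modulations",
    "filter_records",
    "PopulationModel",
    "PopulationFitResults",
    "fit_population_model",
    "contingency_analysis",
    "rank_correlation",
    "area_sex_comparison",
]

FOLD_LIMIT_LOG2 = 5.0  # 32-fold exclusion threshold


def touch_modulation(beta_touch) -> float:
    """Fold change of rate during touch, ``exp(b_touch)`` of the touch-only
    model."""
    return float(np.exp(beta_touch))


def sex_modulations(beta_touch, beta_sex):
    """(female_mod, male_mod) fold ratios from the touch+sex model."""
    return float(np.exp(beta_touch)), float(np.exp(beta_touch + beta_sex))


def filter_records(records: pd.DataFrame, limit_log2=FOLD_LIMIT_LOG2):
    """Drop units beyond the 32-fold filter on either modulation axis."""
    f = np.log2(records["female_mod"].to_numpy(dtype=float))
    m = np.log2(records["male_mod"].to_numpy(dtype=float))
    keep = (np.abs(f) <= limit_log2) & (np.abs(m) <= limit_log2)
    return records.loc[keep].reset_index(drop=True)


@dataclass
class PopulationFitResults:
    """Estimates, Wald CIs and p-values of the population response model."""

    params: pd.Series
    conf_int: pd.DataFrame      # columns lo, hi
    pvalues: pd.Series
    group_var: float | None     # random-intercept variance (per subject)
    scale: str
    n_units: int
    n_excluded: int
    method: str
    raw_result: object

    @property
    def slope(self) -> float:
        return float(self.params["female_mod"])

    @property
    def intercept(self) -> float:
        return float(self.params["Intercept"])

    def has_potentiation(self) -> bool:
        lo, hi = self.conf_int.loc["female_mod"]
        return not (lo <= 1.0 <= hi)

    def has_bias(self) -> bool:
        lo, hi = self.conf_int.loc["Intercept"]
        return not (lo <= 0.0 <= hi)

    def summary(self) -> str:
        lines = [
            f"Population response model ({self.method}, {self.scale} scale)",
            f"n_units: {self.n_units}  excluded by 32-fold filter: "
            f"{self.n_excluded}",
            f"{'term':>28} {'estimate':>9} {'ci_lo':>8} {'ci_hi':>8} {'p':>8}",
        ]
        for k in self.params.index:
            lines.append(
                f"{k:>28} {self.params[k]:>9.3f} "
                f"{self.conf_int.loc[k, 'lo']:>8.3f} "
                f"{self.conf_int.loc[k, 'hi']:>8.3f} {self.pvalues[k]:>8.4f}"
            )
        if self.group_var is not None:
            lines.append(f"random-intercept variance (subject): "
                         f"{self.group_var:.4f}")
        lines.append(
            f"potentiation (slope CI excludes 1): {self.has_potentiation()}  "
            f"bias (intercept CI excludes 0): {self.has_bias()}"
        )
        return "\n".join(lines)


class PopulationModel:
    """Mixed-effects model of male vs female touch modulation.

    Parameters
    ----------
    records : DataFrame
        Columns ``female_mod, male_mod`` (fold ratios), ``subject_id``,
        ``subject_sex`` ({"F","M"}).
    scale : {"log2", "ratio"}
        Scale on which the regression is fitted; log2 (the default) is
        symmetric for increases and decreases and matches the 32-fold
        filter geometry.
    """

    def __init__(self, records: pd.DataFrame, scale="log2",
                 limit_log2=FOLD_LIMIT_LOG2):
        if scale not in ("log2", "ratio"):
            raise ValueError("scale must be 'log2' or 'ratio'")
        self.records_all = records
        self.records = filter_records(records, limit_log2)
        self.scale = scale

    def fit(self, reml=True) -> PopulationFitResults:
        df = self.records.copy()
        if self.scale == "log2":
            df["male"] = np.log2(df["male_mod"])
            df["female_mod"] = np.log2(df["female_mod"])
        else:
            df["male"] = df["male_mod"]
        df["subject_sex_m"] = (df["subject_sex"] == "M").astype(float)
        n_subjects = df["subject_id"].nunique()
        two_sexes = df["subject_sex_m"].nunique() > 1
        rhs = "female_mod"
        if two_sexes:
            rhs += " + subject_sex_m + female_mod:subject_sex_m"
        formula = f"male ~ 1 + {rhs}"
        import statsmodels.formula.api as smf

        if n_subjects >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(
                    reml=reml
                )
            fe = fit.fe_params
            ci = fit.conf_int().loc[fe.index]
            pv = fit.pvalues.loc[fe.index]
            group_var = float(fit.cov_re.iloc[0, 0])
            method = "MixedLM-" + ("REML" if reml else "ML")
        else:
            warnings.warn(
                "single subject: random intercept unidentifiable; "
                "falling back to a fixed-effects fit"
            )
            fit = smf.ols(formula, df).fit()
            fe = fit.params
            ci = fit.conf_int()
            pv = fit.pvalues
            group_var = None
            method = "OLS"
        ci.columns = ["lo", "hi"]
        return PopulationFitResults(
            params=fe, conf_int=ci, pvalues=pv, group_var=group_var,
            scale=self.scale, n_units=len(df),
            n_excluded=len(self.records_all) - len(df),
            method=method, raw_result=fit,
        )


def fit_population_model(records, scale="log2", **kw) -> PopulationFitResults:
    return PopulationModel(records, scale=scale).fit(**kw)


def contingency_analysis(table):
    """Chi-square test of independence with standardized Pearson residuals.

    ``table`` is a 2-d array or DataFrame of counts (e.g. unit label x
    cortical area).  Residuals are

        r_ij = (O - E) / sqrt(E (1 - row_p) (1 - col_p))

    and cells with |r| > 1.96 (two-sided normal, p < 0.05) are flagged.
    Returns ``(p_value, chi2, residuals, flagged)`` with residuals shaped
    like the input.
    """
    df = pd.DataFrame(table).astype(float)
    O = df.to_numpy()
    chi2, p, dof, E = sstats.chi2_contingency(O, correction=False)
    row_p = O.sum(axis=1, keepdims=True) / O.sum()
    col_p = O.sum(axis=0, keepdims=True) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (O - E) / np.sqrt(E * (1 - row_p) * (1 - col_p))
    resid = pd.DataFrame(r, index=df.index, columns=df.columns)
    return float(p), float(chi2), resid, resid.abs() > 1.96


def rank_correlation(female_mod, male_mod):
    """Kendall's tau (tie-adjusted tau-b) between the two modulation axes."""
    res = sstats.kendalltau(female_mod, male_mod)
    return float(res.statistic), float(res.pvalue)


def area_sex_comparison(records: pd.DataFrame, value="beta_touch"):
    """Convenience per-area comparison of a modulation value between units
    recorded in male vs female subjects (normality-gated t / rank tests)."""
    out = []
    for area, g in records.groupby("area"):
        male = g.loc[g.subject_sex == "M", value].to_numpy()
        female = g.loc[g.subject_sex == "F", value].to_numpy()
        row = {"area": area, "n_male": male.size, "n_female": female.size}
        for name, x in (("male", male), ("female", female)):
            if x.size >= 3:
                normal = sstats.shapiro(x).pvalue > 0.05 if x.size <= 5000 else True
                row[f"p_{name}"] = float(
                    sstats.ttest_1samp(x, 0).pvalue if normal
                    else sstats.wilcoxon(x).pvalue
                )
        if male.size >= 3 and female.size >= 3:
            row["p_male_vs_female"] = float(
                sstats.mannwhitneyu(male, female).pvalue
            )
        out.append(row)
    return pd.DataFrame(out)
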