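"""Cohort-level statistical battery.

Implements the comparisons run on a cohort table: paired sulci-vs-gyri test
(paired t with a Wilcoxon signed-rank fallback gated by a Shapiro-Wilk
normality check, Cohen's d on the paired differences), one-way ANOVA with
Tukey HSD post-hocs for profile effects, a two-way mixed (repeated-measures)
ANOVA with profile as the between factor and brain region (sulci vs gyri) as
the within factor, Pearson correlations between the kinematic peaks and the
sulcal metrics (r² with Fisher-z confidence intervals), and a joint ordinary
least-squares regression of sulcal strain (or strain rate) on all four
kinematic peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "PairedTestResult",
    "AnovaResult",
    "RmAnovaResult",
    "CorrelationResult",
    "RegressionResult",
    "paired_compare",
    "one_way_anova",
    "rm_anova",
    "kinematics_correlations",
    "kinematics_regression",
    "cohort_report",
]

KINEMATIC_PREDICTORS = ["peak_lin_vel", "peak_lin_acc",
                        "peak_rot_vel", "peak_rot_acc"]


@dataclass
class PairedTestResult:
    test: str                 # "paired_t" | "wilcoxon"
    statistic: float          # t, or Wilcoxon V (sum of positive ranks)
    p: float
    cohens_d: float           # mean(diff) / sd(diff)
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_p: float          # normality check on the differences
    n: int


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_residual: int
    p: float
    posthoc: pd.DataFrame     # group_a, group_b, diff, p_unadjusted, p_tukey

    def format_line(self) -> str:
        return f"F({self.df_between}, {self.df_residual}) = {self.F:.3f}, p = {self.p:.4g}"


@dataclass
class RmAnovaResult:
    F_between: float
    p_between: float
    F_within: float
    p_within: float
    F_interaction: float
    p_interaction: float
    transform: str            # "sqrt" | "log" | "none"
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore


@dataclass
class CorrelationResult:
    response: str
    predictor: str
    r: float
    r2: float
    ci_low: float             # CI on r², Fisher z on r then squared/ordered
    ci_high: float
    p: float
    n: int


@dataclass
class RegressionResult:
    response: str
    params: pd.DataFrame      # beta, ci_low, ci_high, p per predictor
    r2: float
    n: int
    condition_number: float
    collinearity_warning: bool


# ---------------------------------------------------------------------------

def paired_compare(sulcal: np.ndarray, gyral: np.ndarray,
                   alpha: float = 0.05) -> PairedTestResult:
    """Two-tailed paired comparison of sulcal vs gyral per-impact means.

    Shapiro-Wilk on the paired differences selects the paired t-test
    (normality not rejected at ``alpha``) or the Wilcoxon signed-rank test.
    Cohen's d uses the paired variant mean(diff)/SD(diff).
    """
    a = np.asarray(sulcal, float)
    b = np.asarray(gyral, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    sd_diff = diff.std(ddof=1)
    base = dict(mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n=n)

    if sd_diff == 0.0:
        # degenerate: identical pairs — no effect, nothing to test
        return PairedTestResult(test="paired_t", statistic=0.0, p=1.0,
                                cohens_d=0.0, shapiro_p=1.0, **base)
    d = float(diff.mean() / sd_diff)
    shapiro_p = float(sps.shapiro(diff).pvalue)
    if shapiro_p >= alpha:
        t, p = sps.ttest_rel(a, b)
        return PairedTestResult(test="paired_t", statistic=float(t),
                                p=float(p), cohens_d=d,
                                shapiro_p=shapiro_p, **base)
    nz = diff[diff != 0.0]
    ranks = sps.rankdata(np.abs(nz))
    V = float(ranks[nz > 0].sum())  # R-style V: sum of positive ranks
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return PairedTestResult(test="wilcoxon", statistic=V, p=float(res.pvalue),
                            cohens_d=d, shapiro_p=shapiro_p, **base)


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Classical one-way ANOVA, dfs (k−1, N−k), with Tukey HSD post-hocs.

    The post-hoc table also carries the unadjusted pooled-variance pairwise
    t-test p-value for each comparison.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    F, p = sps.f_oneway(*samples)
    k = len(samples)
    N = values.size
    dfb, dfr = k - 1, N - k
    if not np.isfinite(F):  # all values identical in every group
        F, p = 0.0, 1.0

    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / dfr
    tk = sps.tukey_hsd(*samples) if mse > 0 else None
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = samples[i].mean() - samples[j].mean()
            if mse > 0:
                se = np.sqrt(mse * (1 / len(samples[i]) + 1 / len(samples[j])))
                t = diff / se
                p_un = 2 * sps.t.sf(abs(t), dfr)
            else:
                p_un = 1.0
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "diff": float(diff),
                "p_unadjusted": float(p_un),
                "p_tukey": float(tk.pvalue[i, j]) if tk is not None else 1.0,
            })
    return AnovaResult(F=float(F), df_between=dfb, df_residual=dfr,
                       p=float(p), posthoc=pd.DataFrame(rows))


def _choose_transform(values: np.ndarray, groups_key: np.ndarray,
                      alpha: float = 0.05) -> tuple[str, np.ndarray]:
    """Square-root transform by default; fall back to log if the transformed
    cell residuals still fail Shapiro-Wilk at ``alpha``."""
    v = np.asarray(values, float)
    if np.any(v < 0):
        return "none", v

    def residuals(tv: np.ndarray) -> np.ndarray:
        df = pd.DataFrame({"v": tv, "g": groups_key})
        return (df["v"] - df.groupby("g")["v"].transform("mean")).to_numpy()

    sq = np.sqrt(v)
    res = residuals(sq)
    if res.std() == 0 or sps.shapiro(res).pvalue >= alpha:
        return "sqrt", sq
    lg = np.log(v + 1e-12)
    return "log", lg


def rm_anova(values: np.ndarray, profile: np.ndarray, region: np.ndarray,
             subject: np.ndarray, transform: str | None = None) -> RmAnovaResult:
    """Two-way mixed ANOVA: between = profile, within = region (2 levels).

    Strain-like responses are variance-stabilized first (sqrt by default,
    log fallback chosen by a Shapiro-Wilk check); pass ``transform="none"``
    to disable.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "profile": np.asarray(profile),
                       "region": np.asarray(region),
                       "subject": np.asarray(subject)})
    counts = df.groupby("subject")["region"].nunique()
    if (counts != df["region"].nunique()).any():
        raise ValueError("every subject needs a value for every region level")

    key = df["profile"].astype(str) + "/" + df["region"].astype(str)
    if transform is None:
        tname, tv = _choose_transform(df["value"].to_numpy(), key.to_numpy())
    elif transform == "sqrt":
        tname, tv = "sqrt", np.sqrt(df["value"].to_numpy())
    elif transform == "log":
        tname, tv = "log", np.log(df["value"].to_numpy() + 1e-12)
    else:
        tname, tv = "none", df["value"].to_numpy()
    df["tvalue"] = tv
    if np.std(tv) == 0:  # all values identical: no effects to test
        return RmAnovaResult(F_between=0.0, p_between=1.0, F_within=0.0,
                             p_within=1.0, F_interaction=0.0,
                             p_interaction=1.0, transform=tname,
                             table=pd.DataFrame())

    import pingouin as pg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=df, dv="tvalue", within="region",
                             subject="subject", between="profile")
    aov = aov.set_index("Source")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    inter = [k for k in aov.index if k not in ("profile", "region")][0]
    return RmAnovaResult(
        F_between=float(aov.loc["profile", "F"]),
        p_between=float(aov.loc["profile", pcol]),
        F_within=float(aov.loc["region", "F"]),
        p_within=float(aov.loc["region", pcol]),
        F_interaction=float(aov.loc[inter, "F"]),
        p_interaction=float(aov.loc[inter, pcol]),
        transform=tname,
        table=aov.reset_index(),
    )


def _fisher_ci_r2(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """CI for r² via Fisher z on r, endpoints squared and ordered."""
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + conf / 2)
    lo_r, hi_r = np.tanh(z - zc * se), np.tanh(z + zc * se)
    ends = sorted([lo_r ** 2, hi_r ** 2])
    if lo_r < 0 < hi_r:  # interval straddles zero correlation
        ends[0] = 0.0
    return float(ends[0]), float(ends[1])


def kinematics_correlations(table: pd.DataFrame,
                            responses: tuple[str, ...] = (
                                "sulcal_mean_strain", "sulcal_mean_strain_rate"),
                            predictors: tuple[str, ...] | None = None,
                            ) -> list[CorrelationResult]:
    """Pearson r² (with 95% CI and p) for each kinematics/metric pair."""
    predictors = tuple(predictors or KINEMATIC_PREDICTORS)
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 complete rows")
    out = []
    for resp in responses:
        y = table[resp].to_numpy(float)
        if y.std() == 0:
            raise ValueError(f"zero-variance response column {resp!r}")
        for pred in predictors:
            x = table[pred].to_numpy(float)
            if x.std() == 0:
                raise ValueError(f"zero-variance predictor column {pred!r}")
            r, p = sps.pearsonr(x, y)
            lo, hi = _fisher_ci_r2(r, n)
            out.append(CorrelationResult(response=resp, predictor=pred,
                                         r=float(r), r2=float(r * r),
                                         ci_low=lo, ci_high=hi,
                                         p=float(p), n=n))
    return out


def kinematics_regression(table: pd.DataFrame, response: str,
                          predictors: tuple[str, ...] | None = None,
                          ) -> RegressionResult:
    """OLS of a sulcal metric on the four kinematic peaks: β, 95% CI, p, R²."""
    predictors = tuple(predictors or KINEMATIC_PREDICTORS)
    n = len(table)
    if n <= len(predictors) + 2:
        raise ValueError("need n > number of predictors + 2")
    X = sm.add_constant(table[list(predictors)].to_numpy(float))
    y = table[response].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, X).fit()
    names = ["const", *predictors]
    ci = fit.conf_int()
    params = pd.DataFrame({
        "predictor": names,
        "beta": fit.params,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
        "p": fit.pvalues,
    })
    cond = float(np.linalg.cond(X))
    return RegressionResult(response=response, params=params,
                            r2=float(fit.rsquared) if y.std() > 0 else 0.0,
                            n=n, condition_number=cond,
                            collinearity_warning=cond > 1e8)


# ---------------------------------------------------------------------------

def cohort_report(table: pd.DataFrame) -> dict:
    """Run the full battery on a cohort table.

    Returns a dict of result objects plus Markdown text summarizing profile
    effects, the sulci-vs-gyri comparison, the mixed ANOVA and the
    kinematics-to-strain correlations/regressions.  Degenerate (zero
    variance) strain columns are flagged instead of raising.
    """
    out: dict = {"degenerate": []}
    lines = ["# Cohort statistics report", ""]

    for col in ("p90_strain", "p90_strain_rate",
                "sulcal_mean_strain", "gyral_mean_strain"):
        if col in table and (table[col].std(ddof=0) == 0
                             or table[col].abs().max() < 1e-10):
            out["degenerate"].append(col)
    if out["degenerate"]:
        lines.append("**Degenerate (zero-variance) columns:** "
                     + ", ".join(out["degenerate"]))

    # profile effects on p90 metrics and kinematics
    out["anova"] = {}
    for col in ("p90_strain", "p90_strain_rate", *KINEMATIC_PREDICTORS):
        if col not in table or col in out["degenerate"]:
            continue
        try:
            res = one_way_anova(table[col].to_numpy(),
                                table["profile"].to_numpy())
        except ValueError:
            continue
        out["anova"][col] = res
        lines.append(f"- One-way ANOVA, profile effect on {col}: "
                     f"{res.format_line()}")

    # sulci vs gyri
    if ("sulcal_mean_strain" in table
            and "sulcal_mean_strain" not in out["degenerate"]):
        for metric in ("strain", "strain_rate"):
            s = table[f"sulcal_mean_{metric}"].to_numpy()
            g = table[f"gyral_mean_{metric}"].to_numpy()
            try:
                res = paired_compare(s, g)
            except ValueError:
                continue
            out[f"paired_{metric}"] = res
            lines.append(
                f"- Sulci vs gyri, {metric}: {res.mean_a:.3g} ± {res.sd_a:.3g}"
                f" vs {res.mean_b:.3g} ± {res.sd_b:.3g}, {res.test},"
                f" stat = {res.statistic:.3g}, p = {res.p:.3g},"
                f" d = {res.cohens_d:.3g}")

        # mixed ANOVA on the two region-level values per impact
        for metric in ("strain", "strain_rate"):
            long = pd.melt(
                table, id_vars=["event_id", "profile"],
                value_vars=[f"sulcal_mean_{metric}", f"gyral_mean_{metric}"],
                var_name="region", value_name="value")
            long["region"] = long["region"].str.split("_").str[0]
            if long["value"].std(ddof=0) == 0:
                continue
            res = rm_anova(long["value"], long["profile"], long["region"],
                           long["event_id"])
            out[f"rm_anova_{metric}"] = res
            lines.append(
                f"- Mixed ANOVA ({metric}, transform={res.transform}): "
                f"profile F = {res.F_between:.3g} (p = {res.p_between:.3g}), "
                f"region F = {res.F_within:.3g} (p = {res.p_within:.3g}), "
                f"interaction F = {res.F_interaction:.3g} "
                f"(p = {res.p_interaction:.3g})")

        try:
            out["correlations"] = kinematics_correlations(table)
            lines.append("")
            lines.append("| response | predictor | r² | 95% CI | p |")
            lines.append("|---|---|---|---|---|")
            for c in out["correlations"]:
                lines.append(f"| {c.response} | {c.predictor} | {c.r2:.2f} | "
                             f"({c.ci_low:.2f}–{c.ci_high:.2f}) | {c.p:.3g} |")
        except ValueError:
            pass

        out["regression"] = {}
        for resp in ("sulcal_mean_strain", "sulcal_mean_strain_rate"):
            try:
                out["regression"][resp] = kinematics_regression(table, resp)
            except ValueError:
                continue

    out["markdown"] = "\n".join(lines) + "\n"
    return out
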