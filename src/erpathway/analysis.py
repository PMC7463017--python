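"""Cohort statistics: scoring, grouping, group comparisons and survival.

Implements the statistical stages applied to pathway-activity scores:
one-way ANOVA with Tukey HSD for multi-group comparisons (Mann-Whitney U
and chi-square for two-group and categorical calls), IHC binning
(0-10 / 11-50 / 51-100 %, inclusive upper bounds, ER-low at <= 10 %),
activity quartiles, Kaplan-Meier curves with log-rank tests, and uni-/
multivariate Cox regression (Efron tie handling). All tests are two-sided
at alpha = 0.05; patients with residual disease are excluded from
disease-free-survival analyses by the caller-facing helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .evidence import IntensityMap, matrix_to_evidence
from .exceptions import ConfigurationError
from .io import ExpressionMatrix
from .pathway_model import PathwayModel, infer_log2_odds

ALPHA = 0.05

IHC_BINS = ("0-10", "11-50", "51-100")
ER_LOW_CUTOFF = 10.0


def score_cohort(
    model: PathwayModel,
    matrix: ExpressionMatrix,
    intensity_map: IntensityMap | None = None,
) -> pd.DataFrame:
    """Score every sample of an expression matrix.

    Composition of evidence mapping, factored inference and normalisation;
    deliberately blind to clinical data. Returns a DataFrame indexed by
    sample id with ``score``, ``log2_odds`` and ``n_genes_used``.
    """
    imap = intensity_map if intensity_map is not None else model.intensity_map
    if imap is None:
        raise ConfigurationError("no intensity map available for scoring")
    if matrix.platform != model.platform:
        raise ConfigurationError(
            f"platform mismatch: model is {model.platform!r}, "
            f"matrix is {matrix.platform!r}"
        )
    vectors = matrix_to_evidence(imap, matrix)
    rows = []
    for sample in matrix.sample_ids:
        res = infer_log2_odds(model, vectors.get(sample, {}))
        rows.append(
            {
                "sample_id": sample,
                "score": res.score,
                "log2_odds": res.log2_odds,
                "n_genes_used": res.n_genes_used,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def ihc_bin(percent) -> pd.Series:
    """Bin IHC percentages into 0-10 / 11-50 / 51-100 (upper-inclusive)."""
    percent = pd.Series(percent, dtype=float)
    out = pd.Series(pd.NA, index=percent.index, dtype=object)
    out[percent <= 10.0] = IHC_BINS[0]
    out[(percent > 10.0) & (percent <= 50.0)] = IHC_BINS[1]
    out[percent > 50.0] = IHC_BINS[2]
    return out


def activity_quartiles(scores: pd.Series) -> pd.Series:
    """Quartile labels 1 (lowest) .. 4 by sample-quantile cuts.

    Ties at a cut point fall into the lower quartile; deterministic for any
    input (eight equal scores all land in quartile 1).
    """
    scores = pd.Series(scores, dtype=float)
    cuts = np.quantile(scores.dropna(), [0.25, 0.5, 0.75])
    q = pd.Series(np.nan, index=scores.index, dtype=float)
    ok = scores.notna()
    vals = scores[ok].to_numpy()
    q[ok] = 1 + (vals > cuts[0]).astype(int) + (vals > cuts[1]) + (vals > cuts[2])
    return q.astype("Int64")


def assign_groups(clinical: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Join scores onto clinical records and derive the analysis groupings.

    Adds ``score``, ``er_ihc_bin``, ``pr_ihc_bin``, ``er_low`` (IHC <= 10 %),
    ``activity_quartile`` (sample quartiles of the provided scores) and
    ``combined_high_risk`` (ER-low AND first quartile). Records without IHC
    are excluded from the IHC groupings (logged via a warning).
    """
    df = clinical.copy()
    df["score"] = df["sample_id"].map(scores)
    n_missing = int(df["er_ihc_pct"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} record(s) without ER IHC excluded from IHC groupings",
            stacklevel=2,
        )
    df["er_ihc_bin"] = ihc_bin(df["er_ihc_pct"])
    df["pr_ihc_bin"] = ihc_bin(df["pr_ihc_pct"])
    df["er_low"] = pd.array(df["er_ihc_pct"] <= ER_LOW_CUTOFF, dtype="boolean")
    df.loc[df["er_ihc_pct"].isna(), "er_low"] = pd.NA
    df["activity_quartile"] = activity_quartiles(df["score"]).values
    df["combined_high_risk"] = (
        df["er_low"].astype("boolean") & (df["activity_quartile"] == 1)
    )
    return df


@dataclass
class GroupComparisonResult:
    group_stats: pd.DataFrame  # group, n, mean, sd
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    excluded_groups: list[str] = field(default_factory=list)


def group_comparison(values, groups, pairwise: bool = True) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise adjusted comparisons.

    ``pairwise=False`` skips the post-hoc stage (useful when only the
    omnibus test is needed, e.g. in simulation studies).
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    df = df.dropna()
    stats_tbl = (
        df.groupby("group")["value"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if len(stats_tbl) < 2 or (stats_tbl["n"] < 2).all():
        raise ValueError("need >= 2 groups with >= 2 members")
    excluded = stats_tbl.loc[stats_tbl["n"] < 2, "group"].tolist()
    if excluded:
        warnings.warn(
            f"singleton group(s) excluded from pairwise tests: {excluded}",
            stacklevel=2,
        )
    keep = df[~df["group"].isin(excluded)]
    samples = [g["value"].to_numpy() for _, g in keep.groupby("group")]
    f_stat, p = stats.f_oneway(*samples)
    if not pairwise:
        return GroupComparisonResult(
            group_stats=stats_tbl,
            anova_f=float(f_stat),
            anova_p=float(p),
            tukey=pd.DataFrame(
                columns=[
                    "group1",
                    "group2",
                    "meandiff",
                    "p_adj",
                    "lower",
                    "upper",
                    "reject",
                ]
            ),
            excluded_groups=excluded,
        )
    res = pairwise_tukeyhsd(keep["value"].to_numpy(), keep["group"].to_numpy())
    pairs = [
        (res.groupsunique[i], res.groupsunique[j])
        for i in range(len(res.groupsunique))
        for j in range(i + 1, len(res.groupsunique))
    ]
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "reject": res.reject,
        }
    )
    return GroupComparisonResult(
        group_stats=stats_tbl,
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
        excluded_groups=excluded,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for two-group continuous comparisons."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SurvivalResult:
    curves: dict  # group -> DataFrame(time, estimate, at_risk)
    logrank_stat: float
    logrank_p: float
    flags: list[str] = field(default_factory=list)


def km_logrank(times, events, groups) -> SurvivalResult:
    """Product-limit curves per group plus a two-sided log-rank test."""
    df = pd.DataFrame(
        {
            "time": np.asarray(times, float),
            "event": np.asarray(events, bool),
            "group": list(groups),
        }
    ).dropna()
    if (df["time"] < 0).any():
        raise ValueError("times must be >= 0")
    flags: list[str] = []
    curves = {}
    for name, sub in df.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {name} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "estimate"]
        at_risk = kmf.event_table["at_risk"].reindex(curve["time"]).to_numpy()
        curve["at_risk"] = at_risk
        curves[name] = curve
    if not df["event"].any():
        flags.append("no events: log-rank undefined")
        return SurvivalResult(curves, np.nan, np.nan, flags)
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return SurvivalResult(
        curves, float(lr.test_statistic), float(lr.p_value), flags
    )


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a KM curve at time t."""
    past = curve[curve["time"] <= t]
    return float(past["estimate"].iloc[-1]) if len(past) else 1.0


@dataclass
class CoxResult:
    univariate: pd.DataFrame
    multivariate: pd.DataFrame | None = None


def _fit_single_cox(
    df: pd.DataFrame, covariates: list[str], time_col: str, event_col: str
) -> pd.DataFrame | None:
    sub = df[[time_col, event_col, *covariates]].dropna().astype(float)
    if sub[event_col].sum() < 1:
        return None
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sub, duration_col=time_col, event_col=event_col)
    summ = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
            "n": len(sub),
            "n_events": int(sub[event_col].sum()),
            "estimable": True,
        }
    )
    return out


def cox_regression(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    mode: str = "univariate",
) -> CoxResult:
    """Cox proportional-hazards regression (Efron tie handling).

    ``univariate`` fits each covariate alone; ``multivariate`` additionally
    fits one joint model over the covariates with univariate p <= 0.05.
    Covariates that are constant or fail to converge are reported with
    ``estimable`` False rather than silently dropped.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    uni_rows = []
    for cov in covariates:
        sub = df[[time_col, event_col, cov]].dropna()
        not_estimable = pd.DataFrame(
            [
                {
                    "covariate": cov,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": len(sub),
                    "n_events": int(sub[event_col].sum()) if len(sub) else 0,
                    "estimable": False,
                }
            ]
        )
        if len(sub) == 0 or sub[cov].astype(float).nunique() <= 1:
            uni_rows.append(not_estimable)
            continue
        try:
            fitted = _fit_single_cox(df, [cov], time_col, event_col)
        except Exception:
            fitted = None
        uni_rows.append(fitted if fitted is not None else not_estimable)
    univariate = pd.concat(uni_rows, ignore_index=True)
    if mode == "univariate":
        return CoxResult(univariate=univariate)
    selected = univariate[
        univariate["estimable"] & (univariate["p"] <= ALPHA)
    ]["covariate"].tolist()
    multivariate = None
    if selected:
        try:
            multivariate = _fit_single_cox(df, selected, time_col, event_col)
        except Exception:
            multivariate = None
    return CoxResult(univariate=univariate, multivariate=multivariate)


def dfs_analysis_frame(clinical: pd.DataFrame) -> pd.DataFrame:
    """EC records eligible for DFS analyses (residual disease excluded)."""
    df = clinical[clinical["dfs_months"].notna()].copy()
    residual = (
        df["residual_disease"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    )
    return df[~residual]


def dss_analysis_frame(clinical: pd.DataFrame) -> pd.DataFrame:
    """EC records eligible for disease-specific-survival analyses."""
    return clinical[clinical["dss_months"].notna()].copy()
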