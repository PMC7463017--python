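"""Scoring composition, grouping rules and the statistical stages."""

import numpy as np
import pandas as pd
import pytest

from erpathway.analysis import (
    activity_quartiles,
    assign_groups,
    chi_square,
    cox_regression,
    dfs_analysis_frame,
    group_comparison,
    ihc_bin,
    km_logrank,
    mann_whitney,
    score_cohort,
    survival_at,
)
from erpathway.evidence import IntensityMapEntry
from erpathway.exceptions import ConfigurationError
from erpathway.io import ExpressionMatrix
from erpathway.pathway_model import TargetGeneSpec, build_model


@pytest.fixture
def scoring_setup():
    genes = [TargetGeneSpec(f"G{i}", 0.95, 0.05, 0.9, 0.1) for i in range(1, 3)]
    imap = {
        "G1": IntensityMapEntry(0.0, 1.0, 2.0, 1.0, 1),
        "G2": IntensityMapEntry(0.0, 1.0, 2.0, 1.0, 1),
    }
    model = build_model(genes, prior_active=0.5, intensity_map=imap)
    return model, imap


# -- scoring -------------------------------------------------------------------


def test_identical_samples_get_identical_scores(scoring_setup):
    model, _ = scoring_setup
    data = pd.DataFrame(
        {"S1": [1.5, 0.3], "S2": [1.5, 0.3], "S3": [0.0, 0.0]},
        index=["G1", "G2"],
    )
    scores = score_cohort(model, ExpressionMatrix(data))
    assert scores.at["S1", "score"] == scores.at["S2", "score"]
    assert scores.at["S1", "score"] != scores.at["S3", "score"]


def test_all_missing_sample_scores_at_symmetric_midpoint(scoring_setup):
    model, _ = scoring_setup
    data = pd.DataFrame({"S1": [np.nan, np.nan]}, index=["G1", "G2"])
    scores = score_cohort(model, ExpressionMatrix(data))
    assert scores.at["S1", "score"] == pytest.approx(50.0)
    assert scores.at["S1", "n_genes_used"] == 0


def test_platform_mismatch_refused(scoring_setup):
    model, _ = scoring_setup
    data = pd.DataFrame({"S1": [1.0, 1.0]}, index=["G1", "G2"])
    with pytest.raises(ConfigurationError, match="platform"):
        score_cohort(model, ExpressionMatrix(data, platform="qpcr"))


# -- grouping ------------------------------------------------------------------


def test_ihc_bins_have_inclusive_upper_bounds():
    bins = ihc_bin(pd.Series([0.0, 10.0, 10.5, 50.0, 51.0, 100.0, np.nan]))
    assert bins.tolist()[:6] == [
        "0-10",
        "0-10",
        "11-50",
        "11-50",
        "51-100",
        "51-100",
    ]
    assert pd.isna(bins.iloc[6])


def test_equal_scores_fall_deterministically_in_first_quartile():
    q = activity_quartiles(pd.Series([5.0] * 8))
    assert (q == 1).all()


def test_quartiles_are_balanced_on_continuous_scores(rng):
    scores = pd.Series(rng.normal(50, 10, 1000))
    counts = activity_quartiles(scores).value_counts()
    assert sorted(counts.index) == [1, 2, 3, 4]
    assert all(abs(c - 250) <= 1 for c in counts)


def test_assign_groups_combined_risk_and_exclusions():
    clinical = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(8)],
            "tissue": ["eec_stage_i"] * 8,
            "er_ihc_pct": [5.0, 8.0, 60.0, 80.0, 90.0, 20.0, np.nan, 30.0],
            "pr_ihc_pct": [5.0] * 8,
            "residual_disease": [False] * 7 + [True],
            "dfs_months": [10.0] * 8,
            "recurrence": [True] * 8,
        }
    )
    scores = pd.Series(
        [10.0, 90.0, 20.0, 80.0, 70.0, 60.0, 30.0, 40.0],
        index=clinical["sample_id"],
    )
    with pytest.warns(UserWarning, match="without ER IHC"):
        df = assign_groups(clinical, scores)
    by_id = df.set_index("sample_id")
    assert bool(by_id.at["S0", "er_low"]) and by_id.at["S0", "activity_quartile"] == 1
    assert bool(by_id.at["S0", "combined_high_risk"])
    # ER-low but not in the lowest quartile -> not combined high risk
    assert bool(by_id.at["S1", "er_low"])
    assert not bool(by_id.at["S1", "combined_high_risk"])
    assert pd.isna(by_id.at["S6", "er_low"])
    # residual disease drops out of the DFS frame
    assert "S7" not in set(dfs_analysis_frame(df)["sample_id"])


# -- group comparisons -----------------------------------------------------------


def test_separated_groups_give_tiny_tukey_p(rng):
    a = rng.normal(0.0, 1.0, 30)
    b = rng.normal(10.0, 1.0, 30)  # 10 SD apart
    res = group_comparison(
        np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30
    )
    assert res.anova_p < 1e-10
    assert float(res.tukey["p_adj"].iloc[0]) < 0.001


def test_singleton_group_excluded_with_warning(rng):
    values = np.concatenate([rng.normal(size=10), rng.normal(size=10), [1.0]])
    groups = ["a"] * 10 + ["b"] * 10 + ["c"]
    with pytest.warns(UserWarning, match="singleton"):
        res = group_comparison(values, groups)
    assert res.excluded_groups == ["c"]
    assert set(res.tukey["group1"]) | set(res.tukey["group2"]) == {"a", "b"}


def test_chi_square_matches_hand_computation():
    # recurrence yes/no per tissue group, computed by hand below
    table = np.array([[8, 49], [6, 5], [6, 4]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    hand_stat = float(((table - expected) ** 2 / expected).sum())
    stat, p = chi_square(table)
    assert stat == pytest.approx(hand_stat, rel=1e-12)
    assert 0.0 <= p <= 1.0


def test_mann_whitney_detects_shift(rng):
    x = rng.normal(0, 1, 40)
    y = rng.normal(2, 1, 40)
    _, p = mann_whitney(x, y)
    assert p < 1e-6


# -- survival ---------------------------------------------------------------------


def test_km_product_limit_hand_calculation():
    res = km_logrank(
        times=[10.0, 20.0, 30.0],
        events=[True, False, True],
        groups=["g", "g", "g"],
    )
    curve = res.curves["g"]
    assert survival_at(curve, 5.0) == pytest.approx(1.0)
    assert survival_at(curve, 10.0) == pytest.approx(2 / 3)
    assert survival_at(curve, 25.0) == pytest.approx(2 / 3)  # censoring at 20
    assert survival_at(curve, 30.0) == pytest.approx(0.0)


def test_no_events_flags_logrank_undefined():
    res = km_logrank(
        times=[5.0, 6.0, 7.0, 8.0],
        events=[False] * 4,
        groups=["a", "a", "b", "b"],
    )
    assert np.isnan(res.logrank_p)
    assert any("no events" in f for f in res.flags)
    for curve in res.curves.values():
        assert (curve["estimate"] == 1.0).all()


def test_logrank_null_pvalues_are_uniform(rng):
    pvals = []
    for _ in range(150):
        times = rng.exponential(10.0, 60)
        censor = rng.uniform(5, 25, 60)
        observed = np.minimum(times, censor)
        events = times <= censor
        groups = np.repeat(["a", "b"], 30)
        pvals.append(km_logrank(observed, events, groups).logrank_p)
    _, ks_p = __import__("scipy.stats", fromlist=["kstest"]).kstest(
        pvals, "uniform"
    )
    assert ks_p > 0.01


def test_cox_recovers_two_group_rate_ratio(rng):
    n = 2000
    group = rng.integers(0, 2, n)
    rate = np.where(group == 1, 0.2, 0.1)  # true hazard ratio 2
    times = rng.exponential(1.0 / rate)
    censor = rng.uniform(0, 30, n)
    df = pd.DataFrame(
        {
            "t": np.minimum(times, censor),
            "e": times <= censor,
            "g": group.astype(float),
        }
    )
    res = cox_regression(df, ["g"], "t", "e")
    hr = res.univariate.iloc[0]["hr"]
    assert abs(hr - 2.0) / 2.0 < 0.15


def test_constant_covariate_reported_non_estimable(rng):
    df = pd.DataFrame(
        {
            "t": rng.exponential(10, 50),
            "e": rng.uniform(size=50) < 0.7,
            "c": np.ones(50),
        }
    )
    res = cox_regression(df, ["c"], "t", "e")
    row = res.univariate.iloc[0]
    assert not row["estimable"]
    assert np.isnan(row["hr"])


def test_null_covariate_rarely_significant(rng):
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        n = 80
        df = pd.DataFrame(
            {
                "t": rng.exponential(10, n),
                "e": np.ones(n, dtype=bool),
                "x": rng.normal(size=n),
            }
        )
        res = cox_regression(df, ["x"], "t", "e")
        if res.univariate.iloc[0]["p"] <= 0.05:
            hits += 1
    assert hits <= 0.10 * n_sim  # p <= .05 in at most 10 % of null fits


def test_multivariate_includes_only_significant_covariates(rng):
    n = 600
    x = rng.normal(size=n)  # strong effect
    z = rng.normal(size=n)  # null
    times = rng.exponential(1.0 / (0.1 * np.exp(0.9 * x)))
    censor = rng.uniform(5, 40, n)
    df = pd.DataFrame(
        {
            "t": np.minimum(times, censor),
            "e": times <= censor,
            "x": x,
            "z": z,
        }
    )
    res = cox_regression(df, ["x", "z"], "t", "e", mode="multivariate")
    uni = res.univariate.set_index("covariate")
    assert uni.at["x", "p"] <= 0.05
    if uni.at["z", "p"] > 0.05:
        assert res.multivariate is not None
        assert res.multivariate["covariate"].tolist() == ["x"]
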