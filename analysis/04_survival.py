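#!/usr/bin/env python
"""Survival analyses: activity quartiles, ER IHC cut-off, combined risk.

Kaplan-Meier curves with log-rank tests for disease-free and disease-
specific survival by (i) ER IHC <= 10 % vs > 10 %, (ii) activity quartiles,
(iii) the combined ER-low + lowest-quartile group; plus univariate and
multivariate Cox regression over the standard prognostic covariates.
Patients with residual disease are excluded from DFS analyses.
"""

from pathlib import Path

import pandas as pd

from erpathway.analysis import (
    assign_groups,
    cox_regression,
    dfs_analysis_frame,
    dss_analysis_frame,
    km_logrank,
    survival_at,
)
from erpathway.io import EC_GROUPS, read_clinical

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "reports"
    out.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col="sample_id")["score"]
    clinical = read_clinical(ROOT / "sim" / "clinical.csv")
    ec = clinical[clinical["tissue"].isin(EC_GROUPS)].copy()
    df = assign_groups(ec, scores)

    km_rows, lr_rows = [], []
    for endpoint, frame, time_col, event_col in (
        ("dfs", dfs_analysis_frame(df), "dfs_months", "recurrence"),
        ("dss", dss_analysis_frame(df), "dss_months", "ec_death"),
    ):
        for grouping in ("er_low", "activity_quartile", "combined_high_risk"):
            sub = frame.dropna(subset=[grouping])
            if sub[grouping].nunique() < 2:
                continue
            res = km_logrank(sub[time_col], sub[event_col].astype(bool), sub[grouping])
            lr_rows.append(
                {
                    "endpoint": endpoint,
                    "grouping": grouping,
                    "logrank_p": res.logrank_p,
                }
            )
            print(f"{endpoint.upper()} by {grouping}: log-rank p = {res.logrank_p:.3g}")
            for grp, curve in res.curves.items():
                print(f"   {grouping}={grp}: S(60 mo) = {survival_at(curve, 60.0):.2f}")
                c = curve.copy()
                c.insert(0, "group", str(grp))
                c.insert(0, "grouping", grouping)
                c.insert(0, "endpoint", endpoint)
                km_rows.append(c)
    pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(lr_rows).to_csv(out / "logrank.tsv", sep="\t", index=False, float_format="%.6g")

    # Cox regression on DFS with the standard prognostic covariates
    frame = dfs_analysis_frame(df).copy()
    frame["grade_high"] = (frame["grade"] == "high").astype(float)
    frame["figo_advanced"] = frame["figo"].isin(["III", "IV"]).astype(float)
    for col in ("lvsi", "deep_mi"):
        frame[col] = frame[col].astype("boolean").astype("Float64")
    covariates = ["grade_high", "lvsi", "deep_mi", "figo_advanced", "er_ihc_pct", "score"]
    cox = cox_regression(frame, covariates, "dfs_months", "recurrence", mode="multivariate")
    cox.univariate.to_csv(out / "cox_univariate.tsv", sep="\t", index=False, float_format="%.6g")
    print("univariate Cox (DFS):")
    for _, row in cox.univariate.iterrows():
        if row["estimable"]:
            print(
                f"  {row['covariate']:14s} HR {row['hr']:.2f} "
                f"({row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.3g}"
            )
        else:
            print(f"  {row['covariate']:14s} non-estimable")
    if cox.multivariate is not None:
        cox.multivariate.to_csv(out / "cox_multivariate.tsv", sep="\t", index=False, float_format="%.6g")
        kept = ", ".join(cox.multivariate["covariate"])
        print(f"multivariate Cox over univariately significant covariates: {kept}")


if __name__ == "__main__":
    main()
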