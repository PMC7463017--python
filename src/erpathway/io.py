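"""Readers and writers for expression matrices, qPCR Cq tables and clinical
annotations, plus the packaged endometrial-cancer cohort summary table.

Expression matrices are tab-separated text, genes in rows (first column is
the gene identifier) and samples in columns, values on a log2 scale. qPCR
data arrive as long-format CSV with columns ``sample_id, gene_id, cq, role``
where ``role`` is ``target`` or ``reference``; relative expression is
computed by the standard delta-Cq convention against the arithmetic mean of
the reference-gene Cq values of the same sample (equivalently, the geometric
mean of reference expression).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError

PLATFORMS = ("array", "qpcr")

TISSUE_GROUPS = (
    "proliferative",
    "hyperplasia",
    "eec_stage_i",
    "eec_stage_ii_iv",
    "usc",
)
EC_GROUPS = ("eec_stage_i", "eec_stage_ii_iv", "usc")

#: Clinical annotation columns, in file order. Booleans are stored as 0/1,
#: missing values as empty cells.
CLINICAL_COLUMNS = (
    "sample_id",
    "tissue",
    "grade",
    "figo",
    "er_ihc_pct",
    "pr_ihc_pct",
    "lvsi",
    "deep_mi",
    "residual_disease",
    "recurrence",
    "ec_death",
    "dfs_months",
    "dss_months",
    "activity_true",
)

_CLINICAL_BOOL = ("lvsi", "deep_mi", "residual_disease", "recurrence", "ec_death")
_CLINICAL_FLOAT = (
    "er_ihc_pct",
    "pr_ihc_pct",
    "dfs_months",
    "dss_months",
    "activity_true",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a platform tag.

    ``data`` is a float DataFrame indexed by gene id with sample-id columns;
    missing values are NaN.
    """

    data: pd.DataFrame
    platform: str = "array"

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression_matrix(path, platform: str = "array") -> ExpressionMatrix:
    """Parse a TSV expression matrix.

    Duplicate gene rows are collapsed by their mean (with a warning);
    non-numeric cells become missing. Ragged rows raise :class:`ParseError`
    with the offending line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file", line=1)
    header = lines[0].split("\t")
    ncol = len(header)
    gene_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}",
                line=lineno,
            )
        gene_ids.append(fields[0])
        rows.append(fields[1:])
    sample_ids = header[1:]
    raw = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        warnings.warn(
            f"{path}: collapsing duplicate gene ids by mean: {dups}", stacklevel=2
        )
        values = values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("sample_id", "gene_id", "cq", "role")


def read_qpcr(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    return validate_qpcr(records)


def validate_qpcr(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(QPCR_COLUMNS) - set(records.columns)
    if missing:
        raise ParseError(f"qPCR table lacks columns: {sorted(missing)}")
    records = records.loc[:, list(QPCR_COLUMNS)].copy()
    records["cq"] = pd.to_numeric(records["cq"], errors="raise")
    bad = records[(records["cq"] <= 0) | (records["cq"] > 45)]
    if not bad.empty:
        raise ParseError(
            f"Cq values outside (0, 45] for rows: {bad.index.tolist()[:10]}"
        )
    unknown_roles = set(records["role"]) - {"target", "reference"}
    if unknown_roles:
        raise ParseError(f"unknown qPCR roles: {sorted(unknown_roles)}")
    return records


@dataclass
class QPCRNormalizationResult:
    matrix: ExpressionMatrix
    dropped_samples: list[str] = field(default_factory=list)


def normalize_qpcr(
    records: pd.DataFrame, reference_genes: Sequence[str] | None = None
) -> QPCRNormalizationResult:
    """Reference-gene delta-Cq normalisation.

    Technical replicates are averaged on the Cq scale; then per sample
    ``dCq_g = Cq_g - mean(Cq over reference genes)`` and the log2 relative
    expression is ``-dCq``. Samples lacking every reference gene are dropped
    and reported in ``dropped_samples``.
    """
    records = validate_qpcr(records)
    # replicate averaging on the Cq scale
    agg = (
        records.groupby(["sample_id", "gene_id"], sort=False)
        .agg(cq=("cq", "mean"), role=("role", "first"))
        .reset_index()
    )
    if reference_genes is not None:
        is_ref = agg["gene_id"].isin(set(reference_genes))
    else:
        is_ref = agg["role"] == "reference"
    ref_mean = agg[is_ref].groupby("sample_id")["cq"].mean()
    targets = agg[~is_ref]
    dropped = sorted(set(agg["sample_id"]) - set(ref_mean.index))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) without reference Cq: {dropped}",
            stacklevel=2,
        )
    targets = targets[targets["sample_id"].isin(ref_mean.index)].copy()
    targets["log2_expr"] = -(targets["cq"] - ref_mean.loc[targets["sample_id"]].values)
    wide = targets.pivot(index="gene_id", columns="sample_id", values="log2_expr")
    # keep first-appearance order for both axes
    gene_order = targets["gene_id"].drop_duplicates().tolist()
    sample_order = [s for s in agg["sample_id"].drop_duplicates() if s in wide.columns]
    wide = wide.loc[gene_order, sample_order]
    wide.columns.name = None
    wide.index.name = None
    return QPCRNormalizationResult(
        ExpressionMatrix(wide, platform="qpcr"), dropped_samples=dropped
    )


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "tissue"} - set(df.columns)
    if missing:
        raise ParseError(f"clinical table lacks columns: {sorted(missing)}")
    for col in _CLINICAL_BOOL:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: bool(int(v)) if pd.notna(v) and v != "" else pd.NA
            )
    for col in _CLINICAL_FLOAT:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    unknown = set(df["tissue"].dropna()) - set(TISSUE_GROUPS)
    if unknown:
        raise ParseError(f"unknown tissue groups: {sorted(unknown)}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _CLINICAL_BOOL:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Packaged cohort summary (clinicopathological characteristics)
# ---------------------------------------------------------------------------

#: Rows whose denominator excludes residual-disease patients.
RECURRENCE_METRICS = ("recurrence_yes", "recurrence_distant", "recurrence_no")


@dataclass
class CohortSummary:
    """Aggregate clinicopathological counts per tissue group.

    ``groups`` maps group name to a dict with keys ``n``,
    ``residual_excluded``, ``counts`` (metric -> count) and
    ``printed_percent`` (metric -> percentage as printed in the source
    table, kept verbatim even where internally inconsistent).
    """

    groups: dict
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        for name, grp in self.groups.items():
            counts = grp["counts"]
            analysable = grp["n"] - grp["residual_excluded"]
            if counts["recurrence_yes"] + counts["recurrence_no"] != analysable:
                raise ValueError(
                    f"{name}: recurrence yes+no must equal n minus residual exclusions"
                )

    @property
    def total_n(self) -> int:
        return sum(grp["n"] for grp in self.groups.values())


def load_cohort_summary() -> CohortSummary:
    """Load the packaged per-group clinicopathological counts."""
    with resources.files("erpathway.data").joinpath("cohort_summary.json").open() as fh:
        payload = json.load(fh)
    return CohortSummary(groups=payload["groups"], notes=payload.get("notes", []))


def summary_rates(summary: CohortSummary) -> pd.DataFrame:
    """Percentages per group/metric.

    The denominator is the group size, except recurrence rows which use the
    number of analysable patients (group size minus residual-disease
    exclusions). Returns exact and integer-rounded percentages; a zero
    denominator yields NaN with ``defined`` False.
    """
    rows = []
    for group, grp in summary.groups.items():
        n = grp["n"]
        analysable = n - grp["residual_excluded"]
        for metric, count in grp["counts"].items():
            denom = analysable if metric in RECURRENCE_METRICS else n
            if denom == 0:
                exact = np.nan
            else:
                exact = 100.0 * count / denom
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "count": count,
                    "denominator": denom,
                    "percent_exact": exact,
                    "percent": int(round(exact)) if denom else np.nan,
                    "defined": denom > 0,
                }
            )
    return pd.DataFrame(rows)
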