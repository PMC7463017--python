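"""Build a pathway model from ground-truth active/inactive samples.

The workflow mirrors how such tests are calibrated in practice: expression
of candidate target genes is measured in samples of known pathway state
(e.g. oestradiol-stimulated versus hormone-deprived cell lines), the
best-discriminating genes are selected by Mann-Whitney AUC, per-gene
intensity distributions and conditional probability tables are estimated,
and the attainable score range is computed so scores land on 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evidence import SIGMA_FLOOR, IntensityMap, evidence_frame, fit_intensity_map
from .exceptions import CalibrationError, ConfigurationError
from .io import ExpressionMatrix
from .pathway_model import PathwayModel, TargetGeneSpec, build_model, infer_log2_odds


@dataclass
class CalibrationSet:
    """Expression matrix plus per-sample ground-truth labels."""

    matrix: ExpressionMatrix
    labels: pd.Series  # sample_id -> "active" | "inactive"

    def __post_init__(self):
        self.labels = pd.Series(self.labels)
        missing = set(self.matrix.sample_ids) - set(self.labels.index)
        if missing:
            raise ConfigurationError(f"samples without labels: {sorted(missing)[:5]}")
        unknown = set(self.labels.unique()) - {"active", "inactive"}
        if unknown:
            raise ConfigurationError(f"unknown labels: {sorted(unknown)}")
        counts = self.labels.loc[self.matrix.sample_ids].value_counts()
        for cls in ("active", "inactive"):
            if counts.get(cls, 0) < 3:
                raise ConfigurationError(
                    f"need >= 3 {cls} samples, got {counts.get(cls, 0)}"
                )

    def class_columns(self, cls: str) -> list[str]:
        return [s for s in self.matrix.sample_ids if self.labels[s] == cls]


@dataclass
class GeneSelectionReport:
    """Per-candidate AUC ranking with the selection outcome.

    ``table`` columns: gene_id, auc (P(active value > inactive value) plus
    half ties), directional_auc = max(auc, 1 - auc), direction (+1/-1/0) and
    selected.
    """

    table: pd.DataFrame
    min_auc: float
    max_genes: int

    @property
    def selected_genes(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return sel["gene_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class CalibrationConfig:
    """Tunables of the calibration stage (defaults documented in the
    methods note)."""

    min_auc: float = 0.8
    max_genes: int = 20
    pseudocount: float = 1.0
    regulation_fidelity: float = 0.95
    prior_active: float = 0.5
    sigma_floor: float = SIGMA_FLOOR
    forced_include: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not (0.5 < self.min_auc <= 1.0):
            raise ConfigurationError("min_auc must lie in (0.5, 1]")
        if self.max_genes < 1:
            raise ConfigurationError("max_genes must be >= 1")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")


@dataclass
class CalibrationResult:
    model: PathwayModel
    intensity_map: IntensityMap
    report: GeneSelectionReport


def rank_auc(values_active, values_inactive) -> float:
    """Mann-Whitney AUC: P(active > inactive) + 0.5 P(tie).

    Computed from midranks, which is exactly the pair-counting definition
    including tie halving.
    """
    a = np.asarray(values_active, dtype=float)
    b = np.asarray(values_inactive, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def select_target_genes(
    calib: CalibrationSet,
    min_auc: float = 0.8,
    max_genes: int = 20,
    forced_include: Sequence[str] = (),
) -> GeneSelectionReport:
    """Rank candidate genes by directional AUC and keep the best.

    Genes pass when max(auc, 1 - auc) >= ``min_auc`` (or are in
    ``forced_include``); the top ``max_genes`` by directional AUC are
    selected, ties broken lexicographically by gene id.
    """
    active_cols = calib.class_columns("active")
    inactive_cols = calib.class_columns("inactive")
    data = calib.matrix.data
    rows = []
    for gene in data.index:
        act = data.loc[gene, active_cols].dropna().to_numpy(float)
        inact = data.loc[gene, inactive_cols].dropna().to_numpy(float)
        auc = rank_auc(act, inact)
        directional = max(auc, 1.0 - auc)
        if np.isclose(auc, 0.5, atol=1e-12):
            direction = 0
        else:
            direction = 1 if auc > 0.5 else -1
        rows.append(
            {
                "gene_id": gene,
                "auc": auc,
                "directional_auc": directional,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows)
    forced = set(forced_include)
    passing = table[
        (table["directional_auc"] >= min_auc) | table["gene_id"].isin(forced)
    ]
    ordered = passing.sort_values(
        ["directional_auc", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    chosen = set(ordered["gene_id"].head(max_genes))
    table["selected"] = table["gene_id"].isin(chosen)
    report = GeneSelectionReport(table=table, min_auc=min_auc, max_genes=max_genes)
    if not chosen:
        raise CalibrationError(
            f"no gene reached directional AUC {min_auc}", report=report
        )
    return report


def estimate_cpts(
    evidence_by_sample: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    pseudocount: float = 1.0,
    regulation_fidelity: float = 0.95,
) -> list[TargetGeneSpec]:
    """Estimate per-gene CPTs from calibration evidence.

    ``evidence_by_sample`` is genes x samples soft evidence (already
    oriented towards the activity-associated state, so no flipping is
    needed for repressed genes). P(I=high | R=up) is the pseudocount-
    smoothed mean evidence in the active class and P(I=high | R=down) in
    the inactive class; the regulation layer is a fixed near-deterministic
    link P(R=up | TF=active) = ``regulation_fidelity``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not (0.5 < regulation_fidelity < 1.0):
        raise ValueError("regulation_fidelity must lie in (0.5, 1)")
    labels = pd.Series(labels)
    active_cols = [s for s in evidence_by_sample.columns if labels[s] == "active"]
    inactive_cols = [s for s in evidence_by_sample.columns if labels[s] == "inactive"]
    genes = []
    for gene, row in evidence_by_sample.iterrows():
        act = row[active_cols].dropna().to_numpy(float)
        inact = row[inactive_cols].dropna().to_numpy(float)
        p_high_up = (act.sum() + pseudocount) / (act.size + 2.0 * pseudocount)
        p_high_down = (inact.sum() + pseudocount) / (inact.size + 2.0 * pseudocount)
        genes.append(
            TargetGeneSpec(
                gene_id=gene,
                p_up_given_active=regulation_fidelity,
                p_up_given_inactive=1.0 - regulation_fidelity,
                p_high_given_up=float(p_high_up),
                p_high_given_down=float(p_high_down),
            )
        )
    return genes


def calibrate_model(
    calib: CalibrationSet, config: CalibrationConfig | None = None
) -> CalibrationResult:
    """Full calibration: intensity maps -> gene selection -> CPTs -> range.

    The returned model carries the intensity-map entries of its selected
    genes. Fails if the calibrated model does not separate the ground-truth
    classes (mean active score must exceed mean inactive score).
    """
    config = config or CalibrationConfig()
    imap_all = fit_intensity_map(
        calib.matrix, calib.labels, sigma_floor=config.sigma_floor
    )
    report = select_target_genes(
        calib,
        min_auc=config.min_auc,
        max_genes=config.max_genes,
        forced_include=config.forced_include,
    )
    selected = report.selected_genes
    imap = {g: imap_all[g] for g in selected}
    sub = ExpressionMatrix(
        calib.matrix.data.loc[selected], platform=calib.matrix.platform
    )
    ev = evidence_frame(imap, sub)
    genes = estimate_cpts(
        ev,
        calib.labels,
        pseudocount=config.pseudocount,
        regulation_fidelity=config.regulation_fidelity,
    )
    # deterministic gene order: by gene id
    genes = sorted(genes, key=lambda g: g.gene_id)
    try:
        model = build_model(
            genes,
            prior_active=config.prior_active,
            platform=calib.matrix.platform,
            intensity_map=imap,
        )
    except Exception as exc:  # uninformative range etc.
        raise CalibrationError(f"model construction failed: {exc}", report=report)
    # sanity: scores must separate the calibration classes
    scores = {}
    for sample, vec in _evidence_vectors(ev).items():
        scores[sample] = infer_log2_odds(model, vec).score
    act = [scores[s] for s in calib.class_columns("active")]
    inact = [scores[s] for s in calib.class_columns("inactive")]
    if np.mean(act) <= np.mean(inact):
        raise CalibrationError(
            "calibrated model does not separate classes "
            f"(mean active {np.mean(act):.2f} <= mean inactive {np.mean(inact):.2f})",
            report=report,
        )
    return CalibrationResult(model=model, intensity_map=imap, report=report)


def _evidence_vectors(frame: pd.DataFrame) -> dict[str, dict[str, float]]:
    out = {}
    for sample in frame.columns:
        col = frame[sample]
        out[sample] = {g: float(v) for g, v in col.items() if not np.isnan(v)}
    return out
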