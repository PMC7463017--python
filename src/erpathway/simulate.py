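"""Synthetic-data generator for the whole pipeline.

A single latent pathway activity ``a`` on the 0-100 scale drives everything
(shared-latent design): informative genes shift linearly with ``a`` around a
per-gene baseline, ER/PR IHC percentages are a noisy linear function of
``a``, and recurrence/death hazards rise log-linearly as ``a`` falls. The
ground-truth calibration classes sit at the activity extremes (a = 100
active, a = 0 inactive), i.e. informative genes are shifted by
+/- effect_size/2 between classes.

Tissue-group activity distributions default to the published group means and
SDs: proliferative endometrium 41 (SD 8), hyperplasia 43 (SD 4), EEC stage I
36 (SD 11), EEC stage II-IV 31 (SD 9), USC 28 (SD 13).

All randomness flows from ``config.seed`` through named substreams, so the
same config yields byte-identical outputs while calibration, validation and
cohort draws stay independent.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .calibration import CalibrationSet
from .exceptions import ConfigurationError
from .io import EC_GROUPS, TISSUE_GROUPS, ExpressionMatrix

DEFAULT_GROUP_PARAMS: dict[str, tuple[float, float]] = {
    "proliferative": (41.0, 8.0),
    "hyperplasia": (43.0, 4.0),
    "eec_stage_i": (36.0, 11.0),
    "eec_stage_ii_iv": (31.0, 9.0),
    "usc": (28.0, 13.0),
}

#: Published cohort composition: 57 EEC I / 12 EEC II-IV / 14 USC plus 4
#: proliferative and 20 hyperplasia samples.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "proliferative": 4,
    "hyperplasia": 20,
    "eec_stage_i": 57,
    "eec_stage_ii_iv": 12,
    "usc": 14,
}

# per-group clinicopathological rates used for covariates not driven by the
# latent activity (from the packaged cohort summary)
_GRADE3_RATE = {"eec_stage_i": 6 / 57, "eec_stage_ii_iv": 5 / 12, "usc": 1.0}
_LVSI_RATE = {"eec_stage_i": 11 / 57, "eec_stage_ii_iv": 9 / 12, "usc": 8 / 14}
_DEEP_MI_RATE = {"eec_stage_i": 15 / 57, "eec_stage_ii_iv": 9 / 12, "usc": 8 / 14}
_FIGO_DIST = {
    "eec_stage_i": (("I",), (1.0,)),
    "eec_stage_ii_iv": (("II", "III", "IV"), (4 / 12, 5 / 12, 3 / 12)),
    "usc": (("I", "III", "IV"), (4 / 14, 3 / 14, 7 / 14)),
}

_STREAMS = {
    "meta": 101,
    "calibration": 1,
    "validation": 2,
    "cohort": 3,
    "qpcr": 4,
}


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``effect_size`` is the log2 expression shift of an informative gene
    between the activity extremes; ``hazard_coef`` is the log hazard ratio
    per 10-point decrease of activity below 50; ``baseline_hazard`` is the
    monthly event rate at activity 50.
    """

    n_genes: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    fraction_informative: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    group_params: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GROUP_PARAMS.items()}
    )
    hazard_coef: float = 0.9
    baseline_hazard: float = 0.0006
    dss_hazard_ratio: float = 0.5
    censor_window_months: tuple[float, float] = (36.0, 120.0)
    ihc_slope: float = 1.6
    ihc_intercept: float = -20.0
    ihc_noise_sd: float = 15.0
    pr_ihc_intercept: float = -10.0
    pr_ihc_noise_sd: float = 18.0
    residual_counts: dict = field(
        default_factory=lambda: {"usc": 4, "eec_stage_ii_iv": 1}
    )
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ConfigurationError("SDs must be > 0")
        if not (0.0 <= self.fraction_informative <= 1.0):
            raise ConfigurationError("fraction_informative must lie in [0, 1]")
        for group, (mu, sd) in dict(self.group_params).items():
            if sd <= 0:
                raise ConfigurationError(f"group {group}: SD must be > 0")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["censor_window_months"] = list(self.censor_window_months)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        doc = dict(doc)
        if "censor_window_months" in doc:
            doc["censor_window_months"] = tuple(doc["censor_window_months"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class _GeneMeta:
    gene_ids: tuple[str, ...]
    informative: np.ndarray  # bool per gene
    direction: np.ndarray  # +1 / -1 per gene (0 for uninformative)
    baseline: np.ndarray


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def gene_metadata(config: GeneratorConfig) -> _GeneMeta:
    """Deterministic per-gene identity shared by all generated datasets."""
    rng = _rng(config, "meta")
    n = config.n_genes
    n_inf = int(round(config.fraction_informative * n))
    informative = np.zeros(n, dtype=bool)
    informative[:n_inf] = True
    direction = np.zeros(n, dtype=int)
    direction[:n_inf] = rng.choice([-1, 1], size=n_inf)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    width = len(str(max(n, 1)))
    gene_ids = tuple(f"G{i + 1:0{width}d}" for i in range(n))
    return _GeneMeta(gene_ids, informative, direction, baseline)


def _expression_for_activity(
    config: GeneratorConfig,
    meta: _GeneMeta,
    activity: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Linear latent -> expression link plus iid normal noise."""
    shift = np.outer(
        meta.direction * config.effect_size, (activity - 50.0) / 100.0
    )
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(activity)))
    values = meta.baseline[:, None] + shift + noise
    frame = pd.DataFrame(values, index=list(meta.gene_ids), columns=sample_ids)
    return ExpressionMatrix(frame, platform="array")


def generate_calibration_set(
    config: GeneratorConfig, n_per_class: int = 25, stream: str = "calibration"
) -> CalibrationSet:
    """Ground-truth samples at the activity extremes.

    Informative genes differ by +/- effect_size/2 between classes (sign per
    gene fixed by the seed); uninformative genes are distributed identically
    in both classes. ``stream`` may be ``"validation"`` for an independent
    hold-out set under the same gene identity.
    """
    if n_per_class < 3:
        raise ConfigurationError("n_per_class must be >= 3")
    meta = gene_metadata(config)
    rng = _rng(config, stream)
    prefix = "VAL" if stream == "validation" else "CAL"
    ids = [f"{prefix}_ACT{i + 1:03d}" for i in range(n_per_class)] + [
        f"{prefix}_INACT{i + 1:03d}" for i in range(n_per_class)
    ]
    activity = np.concatenate(
        [np.full(n_per_class, 100.0), np.full(n_per_class, 0.0)]
    )
    matrix = _expression_for_activity(config, meta, activity, ids, rng)
    labels = pd.Series(
        ["active"] * n_per_class + ["inactive"] * n_per_class, index=ids
    )
    return CalibrationSet(matrix=matrix, labels=labels)


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: GeneratorConfig,
    group_sizes: Mapping[str, int] | None = None,
    stream: str = "cohort",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix plus clinical annotations for a tissue cohort.

    Latent activity is truncated-normal per tissue group; expression, IHC
    and survival all derive from it. Event times are exponential with rate
    ``baseline_hazard * exp(hazard_coef * (50 - a) / 10)`` (disease-specific
    death at ``dss_hazard_ratio`` times that rate), administratively
    censored uniformly over ``censor_window_months``. Residual-disease flags
    are assigned per group to match the published exclusion counts. The
    returned clinical table includes the latent ``activity_true`` for
    generator diagnostics; the scoring stage never sees it.
    """
    sizes = dict(group_sizes) if group_sizes is not None else dict(DEFAULT_GROUP_SIZES)
    unknown = set(sizes) - set(TISSUE_GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown tissue groups: {sorted(unknown)}")
    if any(n < 1 for n in sizes.values()):
        raise ConfigurationError("group sizes must be >= 1")
    meta = gene_metadata(config)
    rng = _rng(config, stream)

    records = []
    activities = []
    sample_ids = []
    for group in TISSUE_GROUPS:  # fixed order for determinism
        if group not in sizes:
            continue
        n = sizes[group]
        mu, sd = config.group_params[group]
        a = _truncated_normal(rng, float(mu), float(sd), n)
        ids = [f"{group.upper()}_{i + 1:04d}" for i in range(n)]
        is_ec = group in EC_GROUPS

        er_ihc = np.clip(
            config.ihc_slope * a
            + config.ihc_intercept
            + rng.normal(0.0, config.ihc_noise_sd, n),
            0.0,
            100.0,
        )
        pr_ihc = np.clip(
            config.ihc_slope * a
            + config.pr_ihc_intercept
            + rng.normal(0.0, config.pr_ihc_noise_sd, n),
            0.0,
            100.0,
        )

        if is_ec:
            # grade tracks low activity within the group; USC is always high
            k_high = int(round(_GRADE3_RATE[group] * n))
            order = np.argsort(a, kind="stable")
            grade = np.array(["low"] * n, dtype=object)
            grade[order[:k_high]] = "high"
            figo_states, figo_p = _FIGO_DIST[group]
            figo = rng.choice(figo_states, size=n, p=figo_p)
            lvsi = rng.random(n) < _LVSI_RATE[group]
            deep_mi = rng.random(n) < _DEEP_MI_RATE[group]
            residual = np.zeros(n, dtype=bool)
            k_res = min(int(config.residual_counts.get(group, 0)), n)
            if k_res:
                residual[rng.choice(n, size=k_res, replace=False)] = True

            u = (50.0 - a) / 10.0
            rate_dfs = config.baseline_hazard * np.exp(config.hazard_coef * u)
            rate_dss = config.dss_hazard_ratio * rate_dfs
            t_rec = rng.exponential(1.0 / rate_dfs)
            t_death = rng.exponential(1.0 / rate_dss)
            censor = rng.uniform(*config.censor_window_months, size=n)
            recurrence = t_rec <= censor
            ec_death = t_death <= censor
            dfs = np.minimum(t_rec, censor)
            dss = np.minimum(t_death, censor)
        else:
            grade = np.array([None] * n, dtype=object)
            figo = np.array([None] * n, dtype=object)
            lvsi = deep_mi = residual = recurrence = ec_death = None
            dfs = dss = None

        for i in range(n):
            records.append(
                {
                    "sample_id": ids[i],
                    "tissue": group,
                    "grade": grade[i],
                    "figo": figo[i],
                    "er_ihc_pct": er_ihc[i],
                    "pr_ihc_pct": pr_ihc[i],
                    "lvsi": bool(lvsi[i]) if is_ec else pd.NA,
                    "deep_mi": bool(deep_mi[i]) if is_ec else pd.NA,
                    "residual_disease": bool(residual[i]) if is_ec else pd.NA,
                    "recurrence": bool(recurrence[i]) if is_ec else pd.NA,
                    "ec_death": bool(ec_death[i]) if is_ec else pd.NA,
                    "dfs_months": float(dfs[i]) if is_ec else np.nan,
                    "dss_months": float(dss[i]) if is_ec else np.nan,
                    "activity_true": float(a[i]),
                }
            )
        activities.append(a)
        sample_ids.extend(ids)

    activity = np.concatenate(activities)
    matrix = _expression_for_activity(config, meta, activity, sample_ids, rng)
    clinical = pd.DataFrame(records)
    return matrix, clinical


def to_qpcr_records(
    matrix: ExpressionMatrix,
    config: GeneratorConfig,
    n_reference: int = 3,
    technical_sd: float = 0.15,
    reference_level: float = 21.0,
    stream: str = "qpcr",
) -> pd.DataFrame:
    """Emulate qPCR measurement of an expression matrix.

    Target Cq values are ``reference_level - log2 expression`` plus
    technical noise; reference genes sit near ``reference_level`` so that
    delta-Cq normalisation recovers the log2 expression up to noise.
    """
    rng = _rng(config, stream)
    rows = []
    ref_ids = [f"REF{i + 1}" for i in range(n_reference)]
    ref_offsets = rng.normal(0.0, 0.5, size=n_reference)
    # centre reference offsets so their mean Cq equals reference_level
    ref_offsets -= ref_offsets.mean()
    for sample in matrix.sample_ids:
        for i, ref in enumerate(ref_ids):
            cq = reference_level + ref_offsets[i] + rng.normal(0.0, technical_sd)
            rows.append(
                {"sample_id": sample, "gene_id": ref, "cq": cq, "role": "reference"}
            )
        for gene in matrix.gene_ids:
            x = matrix.data.at[gene, sample]
            if math.isnan(x):
                continue
            cq = reference_level - x + rng.normal(0.0, technical_sd)
            rows.append(
                {"sample_id": sample, "gene_id": gene, "cq": cq, "role": "target"}
            )
    return pd.DataFrame(rows)
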