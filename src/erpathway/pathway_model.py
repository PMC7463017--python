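"""Exact inference in the two-layer pathway-activity Bayesian network.

The network has one binary transcription-complex activation node TF
(active/inactive) and, per target gene, a regulation node R (up/down) whose
distribution depends on TF, and an intensity node I (high/low) whose
distribution depends on R. Conditioned on TF the genes are independent, so
the posterior odds factorise into the prior odds times one likelihood ratio
per gene:

    odds(TF = active | evidence) = prior_odds * prod_g LR_g(e_g)

with soft (virtual) evidence e_g in [0, 1] weighting the "high" state of
gene g's intensity node. The log2 of these odds, mapped affinely from the
model's attainable [min, max] range onto [0, 100], is the pathway-activity
score: 0 is the lowest odds the model can produce, 100 the highest.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .evidence import IntensityMap, IntensityMapEntry
from .exceptions import ConfigurationError, UninformativeModelError

MODEL_FORMAT = "erpathway-model/1"

#: Tolerance beyond which clamping a score to [0, 100] triggers a warning;
#: drift below this is ordinary floating-point noise.
CLAMP_WARN_TOL = 1e-9


def _check_prob(name: str, p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")


@dataclass(frozen=True)
class TargetGeneSpec:
    """Conditional probability tables for one target gene.

    ``p_up_given_active``/``p_up_given_inactive`` parameterise P(R = up | TF)
    and ``p_high_given_up``/``p_high_given_down`` parameterise P(I = high | R).
    All four must be strictly inside (0, 1) (pseudocount smoothing upstream
    guarantees this for estimated tables).
    """

    gene_id: str
    p_up_given_active: float
    p_up_given_inactive: float
    p_high_given_up: float
    p_high_given_down: float

    def __post_init__(self):
        for name in (
            "p_up_given_active",
            "p_up_given_inactive",
            "p_high_given_up",
            "p_high_given_down",
        ):
            _check_prob(f"{self.gene_id}: {name}", getattr(self, name))

    def p_high_given_tf(self, active: bool) -> float:
        p_up = self.p_up_given_active if active else self.p_up_given_inactive
        return p_up * self.p_high_given_up + (1.0 - p_up) * self.p_high_given_down

    def likelihood_ratio(self, evidence_high: float) -> float:
        return gene_likelihood_ratio(self, evidence_high)

    def log2_lr_bounds(self) -> tuple[float, float]:
        """(min, max) of log2 LR over evidence; extremes sit at e = 0 or 1
        since the LR is a monotone Moebius function of e."""
        l0 = math.log2(self.likelihood_ratio(0.0))
        l1 = math.log2(self.likelihood_ratio(1.0))
        return (min(l0, l1), max(l0, l1))

    @property
    def is_informative(self) -> bool:
        return not math.isclose(
            self.likelihood_ratio(0.0), self.likelihood_ratio(1.0), rel_tol=1e-12
        )

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "p_up_given_active": float(self.p_up_given_active),
            "p_up_given_inactive": float(self.p_up_given_inactive),
            "p_high_given_up": float(self.p_high_given_up),
            "p_high_given_down": float(self.p_high_given_down),
        }


def gene_likelihood_ratio(gene: TargetGeneSpec, evidence_high: float) -> float:
    """Per-gene factor of the posterior odds for soft evidence ``e``.

    Returns P(evidence | TF=active) / P(evidence | TF=inactive) where the
    evidence likelihood for each TF state is
    ``sum_r P(r | TF) * (e * P(high | r) + (1 - e) * P(low | r))``.
    """
    e = float(evidence_high)
    if not (0.0 <= e <= 1.0):
        raise ValueError(f"evidence_high must be in [0, 1], got {e}")
    p_hi_act = gene.p_high_given_tf(active=True)
    p_hi_inact = gene.p_high_given_tf(active=False)
    num = e * p_hi_act + (1.0 - e) * (1.0 - p_hi_act)
    den = e * p_hi_inact + (1.0 - e) * (1.0 - p_hi_inact)
    return num / den


@dataclass(frozen=True)
class ActivityResult:
    log2_odds: float
    score: float
    n_genes_used: int


@dataclass(frozen=True)
class PathwayModel:
    """Calibrated pathway-activity model: gene CPTs, prior and score range.

    ``log2_odds_min``/``log2_odds_max`` are the totals reached when every
    gene's evidence sits at its per-gene minimising/maximising extreme,
    including the prior term; they anchor the 0 and 100 ends of the score.
    """

    genes: tuple[TargetGeneSpec, ...]
    prior_active: float
    log2_odds_min: float
    log2_odds_max: float
    platform: str = "array"
    intensity_map: IntensityMap | None = field(default=None, compare=False)

    def __post_init__(self):
        _check_prob("prior_active", self.prior_active)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate gene ids in model")
        if not (self.log2_odds_min < self.log2_odds_max):
            raise UninformativeModelError(
                "log2_odds_min must be < log2_odds_max; model is uninformative"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def prior_log2_odds(self) -> float:
        return math.log2(self.prior_active / (1.0 - self.prior_active))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        doc = {
            "format": MODEL_FORMAT,
            "platform": self.platform,
            "prior_active": float(self.prior_active),
            "log2_odds_min": float(self.log2_odds_min),
            "log2_odds_max": float(self.log2_odds_max),
            "genes": [g.to_dict() for g in self.genes],
        }
        if self.intensity_map is not None:
            for gene_doc in doc["genes"]:
                entry = self.intensity_map.get(gene_doc["gene_id"])
                if entry is not None:
                    gene_doc["intensity"] = entry.to_dict()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "PathwayModel":
        if doc.get("format") != MODEL_FORMAT:
            raise ConfigurationError(f"unsupported model format {doc.get('format')!r}")
        genes = []
        imap: IntensityMap = {}
        for gd in doc["genes"]:
            gd = dict(gd)
            intensity = gd.pop("intensity", None)
            genes.append(TargetGeneSpec(**gd))
            if intensity is not None:
                imap[gd["gene_id"]] = IntensityMapEntry(**intensity)
        return cls(
            genes=tuple(genes),
            prior_active=doc["prior_active"],
            log2_odds_min=doc["log2_odds_min"],
            log2_odds_max=doc["log2_odds_max"],
            platform=doc["platform"],
            intensity_map=imap or None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PathwayModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_score_range(
    genes: Sequence[TargetGeneSpec], prior_active: float
) -> tuple[float, float]:
    """Attainable [min, max] of the total log2 odds, prior included.

    Each gene's LR is monotone in its evidence, so per-gene extremes occur at
    e = 0 or e = 1; the totals accumulate the smaller/larger log2 LR per
    gene. Raises if no gene is informative (the range would collapse).
    """
    _check_prob("prior_active", prior_active)
    if not any(g.is_informative for g in genes):
        raise UninformativeModelError("all genes are uninformative")
    prior_term = math.log2(prior_active / (1.0 - prior_active))
    lo = prior_term
    hi = prior_term
    for g in genes:
        gmin, gmax = g.log2_lr_bounds()
        lo += gmin
        hi += gmax
    return lo, hi


def build_model(
    genes: Sequence[TargetGeneSpec],
    prior_active: float = 0.5,
    platform: str = "array",
    intensity_map: IntensityMap | None = None,
) -> PathwayModel:
    """Assemble a model, computing its score range from the gene CPTs."""
    lo, hi = compute_score_range(genes, prior_active)
    return PathwayModel(
        genes=tuple(genes),
        prior_active=prior_active,
        log2_odds_min=lo,
        log2_odds_max=hi,
        platform=platform,
        intensity_map=intensity_map,
    )


def normalize_score(model: PathwayModel, log2_odds: float) -> float:
    """Affine map of log2 odds from [min, max] onto [0, 100], clamped."""
    span = model.log2_odds_max - model.log2_odds_min
    if span <= 0:
        raise UninformativeModelError("degenerate score range")
    # ratio first: evidence at the extremes then yields exactly 0.0 / 100.0
    score = ((log2_odds - model.log2_odds_min) / span) * 100.0
    if score < 0.0 or score > 100.0:
        drift = max(-score, score - 100.0) * span / 100.0
        if drift > CLAMP_WARN_TOL:
            warnings.warn(
                f"log2 odds {log2_odds} outside model range "
                f"[{model.log2_odds_min}, {model.log2_odds_max}]; clamping",
                stacklevel=2,
            )
        score = min(max(score, 0.0), 100.0)
    return score


def infer_log2_odds(
    model: PathwayModel, evidence: Mapping[str, float]
) -> ActivityResult:
    """Factored exact inference of the posterior log2 odds and score.

    Genes without evidence contribute a likelihood ratio of 1 (they are
    marginalised out); ``n_genes_used`` counts the genes present.
    """
    if not model.genes:
        raise ConfigurationError("model has no genes")
    unknown = set(evidence) - set(model.gene_ids)
    if unknown:
        raise ConfigurationError(f"evidence for unknown genes: {sorted(unknown)}")
    total = model.prior_log2_odds
    n_used = 0
    for gene in model.genes:
        if gene.gene_id in evidence:
            total += math.log2(gene_likelihood_ratio(gene, evidence[gene.gene_id]))
            n_used += 1
    return ActivityResult(
        log2_odds=total,
        score=normalize_score(model, total),
        n_genes_used=n_used,
    )


def extreme_evidence(model: PathwayModel, which: str = "max") -> dict[str, float]:
    """Evidence vector placing every gene at its score-extreme endpoint."""
    if which not in ("max", "min"):
        raise ValueError("which must be 'max' or 'min'")
    ev = {}
    for g in model.genes:
        lr0, lr1 = g.likelihood_ratio(0.0), g.likelihood_ratio(1.0)
        if which == "max":
            ev[g.gene_id] = 1.0 if lr1 >= lr0 else 0.0
        else:
            ev[g.gene_id] = 1.0 if lr1 < lr0 else 0.0
    return ev


# ---------------------------------------------------------------------------
# Independent oracle: full joint enumeration
# ---------------------------------------------------------------------------

BRUTE_FORCE_MAX_GENES = 12


def brute_force_posterior(
    model: PathwayModel, evidence: Mapping[str, float]
) -> float:
    """P(TF = active | evidence) by summation over every joint network state.

    Test oracle only: enumerates all (R_g, I_g) assignments (4 states per
    gene) for both TF states, weighting each intensity state by the soft
    evidence (e for "high", 1-e for "low"; both weights 1 for missing
    genes). Refuses models with more than 12 genes.
    """
    n = len(model.genes)
    if n > BRUTE_FORCE_MAX_GENES:
        raise ValueError(f"brute force refuses models with > {BRUTE_FORCE_MAX_GENES} genes")
    unknown = set(evidence) - set(model.gene_ids)
    if unknown:
        raise ConfigurationError(f"evidence for unknown genes: {sorted(unknown)}")
    if n == 0:
        return model.prior_active

    # per-gene tables over joint (R, I) states indexed 2*r + i
    def gene_table(g: TargetGeneSpec, active: bool) -> np.ndarray:
        p_up = g.p_up_given_active if active else g.p_up_given_inactive
        p_r = np.array([1.0 - p_up, p_up])  # r = 0 (down), 1 (up)
        p_i = np.array(
            [
                [1.0 - g.p_high_given_down, g.p_high_given_down],
                [1.0 - g.p_high_given_up, g.p_high_given_up],
            ]
        )  # [r, i]
        if g.gene_id in evidence:
            e = float(evidence[g.gene_id])
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"evidence for {g.gene_id} outside [0, 1]")
            w = np.array([1.0 - e, e])
        else:
            w = np.array([1.0, 1.0])
        return (p_r[:, None] * p_i * w[None, :]).reshape(4)

    def joint_sum(active: bool) -> float:
        tables = [gene_table(g, active) for g in model.genes]
        # enumerate the last <= 8 genes as a dense state grid; loop any
        # remaining leading genes in Python (memory bound, n <= 12)
        tail = tables[-8:] if n > 8 else tables
        head = tables[: max(n - 8, 0)]
        m = len(tail)
        combos = np.stack(
            np.meshgrid(*([np.arange(4)] * m), indexing="ij"), axis=-1
        ).reshape(-1, m)
        tail_arr = np.stack(tail)  # (m, 4)
        tail_prods = tail_arr[np.arange(m)[None, :], combos].prod(axis=1)
        if not head:
            return float(tail_prods.sum())
        total = 0.0
        for head_state in itertools.product(range(4), repeat=len(head)):
            head_prod = 1.0
            for tbl, s in zip(head, head_state):
                head_prod *= tbl[s]
            total += float((head_prod * tail_prods).sum())
        return total

    pa = model.prior_active * joint_sum(active=True)
    pi = (1.0 - model.prior_active) * joint_sum(active=False)
    return pa / (pa + pi)
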