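"""Map continuous log2 expression to per-gene soft evidence.

The discrete network has a binary intensity node per target gene. Continuous
expression enters as the posterior responsibility of the "high" intensity
component under a two-component normal model with equal class priors,

    e(x) = phi_high(x) / (phi_high(x) + phi_low(x)),

where the "high" component is fitted on ground-truth active samples and the
"low" component on inactive samples. For a repressed target the active-class
mean lies below the inactive-class mean, so e(x) decreases with x; the
direction flag records this but no explicit flipping is needed — evidence is
always oriented towards the activity-associated intensity state. With equal
class standard deviations the map reduces to a logistic function of x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import CalibrationError, ConfigurationError
from .io import ExpressionMatrix

#: Lower bound on fitted class standard deviations (log2 units). Prevents a
#: zero-variance calibration class from producing degenerate 0/1 evidence.
SIGMA_FLOOR = 0.05


@dataclass(frozen=True)
class IntensityMapEntry:
    """Per-gene low/high intensity distributions on the log2 scale.

    ``mu_high``/``sigma_high`` describe the ground-truth *active* class and
    ``mu_low``/``sigma_low`` the inactive class. ``direction`` is +1 when the
    active class sits above the inactive class (activated target), -1 when
    below (repressed target) and 0 when indistinguishable (uninformative).
    """

    mu_low: float
    sigma_low: float
    mu_high: float
    sigma_high: float
    direction: int

    def __post_init__(self):
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("sigmas must be positive")

    def to_dict(self) -> dict:
        return {
            "mu_low": float(self.mu_low),
            "sigma_low": float(self.sigma_low),
            "mu_high": float(self.mu_high),
            "sigma_high": float(self.sigma_high),
            "direction": int(self.direction),
        }


IntensityMap = dict[str, IntensityMapEntry]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.data
    return matrix


def fit_intensity_map(
    matrix,
    labels: Mapping[str, str] | pd.Series,
    sigma_floor: float = SIGMA_FLOOR,
    min_per_class: int = 3,
) -> IntensityMap:
    """Fit per-gene class location/scale from ground-truth samples.

    ``labels`` maps sample id to ``"active"`` or ``"inactive"``. Standard
    deviations below ``sigma_floor`` are floored (with a warning when a class
    has zero variance). Genes whose class means coincide are flagged with
    ``direction`` 0.
    """
    data = _as_frame(matrix)
    labels = pd.Series(labels)
    unknown = set(labels.unique()) - {"active", "inactive"}
    if unknown:
        raise ConfigurationError(f"unknown calibration labels: {sorted(unknown)}")
    active_cols = labels.index[labels == "active"]
    inactive_cols = labels.index[labels == "inactive"]
    imap: IntensityMap = {}
    floored: list[str] = []
    for gene, row in data.iterrows():
        act = row[active_cols].dropna().to_numpy(float)
        inact = row[inactive_cols].dropna().to_numpy(float)
        if len(act) < min_per_class or len(inact) < min_per_class:
            raise CalibrationError(
                f"gene {gene}: need >= {min_per_class} samples per class "
                f"(got {len(act)} active / {len(inact)} inactive)"
            )
        mu_high, mu_low = float(np.mean(act)), float(np.mean(inact))
        sd_high, sd_low = float(np.std(act, ddof=1)), float(np.std(inact, ddof=1))
        if sd_high < sigma_floor or sd_low < sigma_floor:
            if sd_high == 0.0 or sd_low == 0.0:
                floored.append(gene)
            sd_high = max(sd_high, sigma_floor)
            sd_low = max(sd_low, sigma_floor)
        if np.isclose(mu_high, mu_low, atol=1e-12, rtol=0.0):
            direction = 0
        else:
            direction = 1 if mu_high > mu_low else -1
        imap[gene] = IntensityMapEntry(mu_low, sd_low, mu_high, sd_high, direction)
    if floored:
        warnings.warn(
            f"zero-variance calibration class; sigma floored at {sigma_floor} "
            f"for {len(floored)} gene(s)",
            stacklevel=2,
        )
    return imap


def expression_to_evidence(entry: IntensityMapEntry, x):
    """Soft evidence for the activity-associated intensity state.

    Vectorised over ``x``; defined for every real x and numerically stable
    far in the tails (computed on the log-density scale).
    """
    x = np.asarray(x, dtype=float)
    log_high = -np.log(entry.sigma_high) - 0.5 * ((x - entry.mu_high) / entry.sigma_high) ** 2
    log_low = -np.log(entry.sigma_low) - 0.5 * ((x - entry.mu_low) / entry.sigma_low) ** 2
    out = expit(log_high - log_low)
    if out.ndim == 0:
        return float(out)
    return out


def evidence_frame(imap: IntensityMap, matrix) -> pd.DataFrame:
    """Per-gene evidence for every sample, as a genes x samples DataFrame.

    Only genes present in both the map and the matrix appear; missing
    expression values yield missing evidence.
    """
    data = _as_frame(matrix)
    overlap = [g for g in data.index if g in imap]
    if not overlap:
        raise ConfigurationError("no overlap between intensity map and matrix genes")
    rows = {}
    for gene in overlap:
        vals = data.loc[gene].to_numpy(float)
        ev = np.full_like(vals, np.nan)
        ok = ~np.isnan(vals)
        ev[ok] = expression_to_evidence(imap[gene], vals[ok])
        rows[gene] = ev
    return pd.DataFrame(rows, index=data.columns).T


def matrix_to_evidence(imap: IntensityMap, matrix) -> dict[str, dict[str, float]]:
    """One evidence vector (gene -> weight on the high state) per sample.

    Genes absent from the matrix — or with missing expression in a sample —
    are simply absent from that sample's vector.
    """
    frame = evidence_frame(imap, matrix)
    out: dict[str, dict[str, float]] = {}
    for sample in frame.columns:
        col = frame[sample]
        out[sample] = {g: float(v) for g, v in col.items() if not np.isnan(v)}
    return out
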