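"""DX-score feature ranking and perturbation sensitivity of the risk model.

The DX score of feature j is the squared difference of its class means over
the sum of its class variances — a univariate separability measure used to
rank the 18 model inputs.  Sensitivity perturbs selected features of each
patient over a symmetric relative grid and reports the largest relative
change of the predicted risk.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .model import RiskModel

__all__ = ["FeatureRanking", "SensitivityReport", "dx_score", "sensitivity", "top_k"]

_VARIANCE_GUARD = 1e-12


@dataclasses.dataclass
class FeatureRanking:
    """Per-feature DX scores with a deterministic descending order."""

    scores: np.ndarray
    order: np.ndarray  #: feature indices, best first; ties broken by index
    names: tuple[str, ...] | None = None

    def impact_percentage(self, subset: Sequence[int]) -> float:
        """Share of the total DX score carried by ``subset``, in percent."""
        subset = np.asarray(subset, dtype=int)
        total = self.scores.sum()
        if total == 0:
            return 0.0
        return float(self.scores[subset].sum() / total * 100.0)


def dx_score(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> FeatureRanking:
    """DX_j = (mean_1j - mean_0j)^2 / (var_1j + var_0j), sample variances.

    A tiny guard term in the denominator keeps zero-variance features
    finite (their score is then ~0 unless the means differ).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 samples for a class variance")
    num = (pos.mean(axis=0) - neg.mean(axis=0)) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1) + _VARIANCE_GUARD
    scores = num / den
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return FeatureRanking(scores=scores, order=order,
                          names=None if names is None else tuple(names))


def top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """Indices of the k highest-scoring features (ties by feature order)."""
    if not 0 < k <= len(ranking.scores):
        raise ValueError(f"k must lie in [1, {len(ranking.scores)}], got {k}")
    return ranking.order[:k].copy()


@dataclasses.dataclass
class SensitivityReport:
    """Output-change statistics for perturbed features.

    ``statistic_pct[f]`` is the maximum relative change of the predicted
    risk (percent) over all patients and grid perturbations of feature
    ``feature_indices[f]``; ``per_patient`` holds the per-patient maxima.
    """

    feature_indices: np.ndarray
    statistic_pct: np.ndarray
    per_patient: np.ndarray  #: (n_features, n_patients)
    range_pct: float
    additive_features: list[int]  #: features perturbed additively (zero values)


def sensitivity(
    model: RiskModel,
    X: np.ndarray,
    subset: Sequence[int],
    range_pct: float = 5.0,
    n_grid: int = 11,
) -> SensitivityReport:
    """Perturb each selected feature over ±``range_pct`` % and track the risk.

    Perturbations are multiplicative, ``x_j * (1 + delta)``; entries that are
    exactly zero are instead shifted additively by ``delta`` times the
    feature's cohort standard deviation (recorded in ``additive_features``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    deltas = np.linspace(-range_pct / 100.0, range_pct / 100.0, n_grid)
    base = model.predict(X)
    cohort_sd = X.std(axis=0)
    per_patient = np.zeros((subset.size, X.shape[0]))
    additive: list[int] = []
    for f, j in enumerate(subset):
        used_additive = False
        for delta in deltas:
            Xp = X.copy()
            zero = Xp[:, j] == 0.0
            Xp[~zero, j] *= 1.0 + delta
            if zero.any():
                Xp[zero, j] += delta * cohort_sd[j]
                used_additive = True
            rel = np.abs(model.predict(Xp) - base) / base * 100.0
            per_patient[f] = np.maximum(per_patient[f], rel)
        if used_additive:
            additive.append(int(j))
    return SensitivityReport(
        feature_indices=subset,
        statistic_pct=per_patient.max(axis=1),
        per_patient=per_patient,
        range_pct=range_pct,
        additive_features=additive,
    )
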