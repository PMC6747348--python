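"""Maximum-relevance filtering: mutual information between probe and label.

Each probe is scored by the plug-in mutual information (in bits) between the
subtype label and the probe's beta values discretized into three states at
mean ± w·σ (the mRMR convention, w = 1 by default).  Probes scoring strictly
above a threshold (0.2 bits by default) are retained for the Monte Carlo
feature-selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import BetaMatrix

__all__ = [
    "DiscretizedFeature",
    "RelevanceResult",
    "RelevanceFilter",
    "discretize",
    "mutual_information",
    "mr_filter",
]


@dataclass
class DiscretizedFeature:
    """Three-state discretization of a continuous feature.

    ``states[i]`` is 0 below the lower edge, 2 above the upper edge and 1
    between (inclusive); edges sit at mean ± w·σ.
    """

    states: np.ndarray
    bin_edges: tuple[float, float]


def discretize(values, width_multiplier: float = 1.0) -> DiscretizedFeature:
    """Bin a real vector into states {0, 1, 2} at mean ± w·std.

    A constant vector has σ = 0 and both edges at the mean, so every sample
    lands in state 1 and contributes zero mutual information downstream.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mu = values.mean()
    sigma = values.std()
    lo, hi = mu - width_multiplier * sigma, mu + width_multiplier * sigma
    states = np.ones(values.shape, dtype=np.int8)
    states[values < lo] = 0
    states[values > hi] = 2
    return DiscretizedFeature(states, (float(lo), float(hi)))


def _codes(x) -> np.ndarray:
    x = np.asarray(x)
    _, inv = np.unique(x, return_inverse=True)
    return inv


def mutual_information(x, y) -> float:
    """Plug-in mutual information, in bits, between two discrete vectors.

    ``y`` may be a :class:`DiscretizedFeature` or any discrete vector.  Uses
    the empirical joint distribution with the convention 0·log 0 = 0; the
    plug-in estimate is always ≥ 0.
    """
    ystates = y.states if isinstance(y, DiscretizedFeature) else np.asarray(y)
    x = np.asarray(x)
    if len(x) != len(ystates):
        raise ValueError(f"length mismatch: {len(x)} labels vs {len(ystates)} values")
    xi = _codes(x)
    yi = _codes(ystates)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


@dataclass
class RelevanceResult:
    """Per-probe MI scores plus the retained (score > threshold) probe list,
    sorted by score descending with probe-id lexicographic tie-break."""

    scores: pd.Series
    retained: list[str]
    threshold: float


class RelevanceFilter(SelectorMixin, BaseEstimator):
    """Univariate feature selector keeping features with MI(label, feature)
    strictly above ``threshold`` bits.

    Parameters
    ----------
    threshold : float, default 0.2
        Retention cut in bits (strict inequality).
    width_multiplier : float, default 1.0
        Discretization half-width in units of the feature's σ.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        MI of each feature with the label, in bits.
    """

    def __init__(self, threshold: float = 0.2, width_multiplier: float = 1.0):
        self.threshold = threshold
        self.width_multiplier = width_multiplier

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        yi = _codes(y)
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            feat = discretize(X[:, j], self.width_multiplier)
            scores[j] = mutual_information(yi, feat)
        self.scores_ = scores
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "scores_")
        return self.scores_ > self.threshold

    def _more_tags(self):
        return {"requires_y": True}


def mr_filter(
    matrix: BetaMatrix, threshold: float = 0.2, width_multiplier: float = 1.0
) -> RelevanceResult:
    """Score every probe of a labeled BetaMatrix and keep score > threshold."""
    selector = RelevanceFilter(threshold, width_multiplier).fit(
        matrix.values, matrix.labels.astype(str)
    )
    scores = pd.Series(selector.scores_, index=matrix.probe_ids, name="mi_bits")
    kept = [p for p in matrix.probe_ids if scores[p] > threshold]
    kept.sort(key=lambda p: (-scores[p], p))
    return RelevanceResult(scores, kept, threshold)
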