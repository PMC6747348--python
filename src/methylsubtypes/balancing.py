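"""SMOTE class balancing for beta-value matrices.

Every class below the target size (default: the majority class size) is
topped up with synthetic samples: pick a class member x, one of its k
nearest same-class neighbors y (Euclidean distance, within-class only), and
emit z = x + r·(y − x) with r ~ U[0, 1].  Because z is a convex combination
of two points in [0, 1]^d, synthetic beta values always stay in range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .io import BetaMatrix

__all__ = ["SmoteConfig", "SmoteBalancer", "synthesize_sample", "balance"]


@dataclass
class SmoteConfig:
    """k: neighbor count (capped at class size − 1); target_size: per-class
    size after balancing (None → majority class size)."""

    k: int = 5
    target_size: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be ≥ 1")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("target_size must be ≥ 1")


def synthesize_sample(x, neighbors, rng: np.random.Generator) -> np.ndarray:
    """One synthetic point on the segment between x and a random neighbor."""
    x = np.asarray(x, dtype=float)
    neighbors = np.asarray(neighbors, dtype=float)
    if neighbors.ndim != 2 or neighbors.shape[0] == 0:
        raise ValueError("neighbors must be a non-empty 2-D array")
    y = neighbors[int(rng.integers(0, neighbors.shape[0]))]
    r = rng.random()
    return x + r * (y - x)


class SmoteBalancer(BaseEstimator):
    """SMOTE resampler with the imbalanced-learn ``fit_resample`` calling
    convention.

    Parameters
    ----------
    k : int, default 5
        Nearest-neighbor count (within class, Euclidean).
    target_size : int or None
        Per-class size after resampling; None uses the majority class size.
    seed : int
        RNG seed.

    Attributes
    ----------
    synthetic_mask_ : bool ndarray over the resampled rows, True for
        synthesized samples (originals come first, unmodified).
    """

    def __init__(self, k: int = 5, target_size: int | None = None, seed: int = 0):
        self.k = k
        self.target_size = target_size
        self.seed = seed

    def fit_resample(self, X, y):
        SmoteConfig(self.k, self.target_size, self.seed).validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
        target = self.target_size or max(counts.values())
        if target < max(counts.values()):
            raise ValueError(
                f"target_size {target} is below the majority class size "
                f"{max(counts.values())}"
            )
        new_X: list[np.ndarray] = []
        new_y: list = []
        rng = np.random.default_rng(self.seed)
        for c in sorted(counts):
            deficit = target - counts[c]
            if deficit == 0:
                continue
            members = np.flatnonzero(y == c)
            if members.size < 2:
                raise ValueError(
                    f"class {c!r} has {members.size} sample(s); SMOTE needs ≥ 2"
                )
            k_eff = min(self.k, members.size - 1)
            block = X[members]
            nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(block)
            # drop each point's self-match in column 0
            neigh_idx = nn.kneighbors(block, return_distance=False)[:, 1:]
            for _ in range(deficit):
                i = int(rng.integers(0, members.size))
                z = synthesize_sample(block[i], block[neigh_idx[i]], rng)
                new_X.append(z)
                new_y.append(c)
        n_orig = X.shape[0]
        if new_X:
            X_res = np.vstack([X, np.asarray(new_X)])
            y_res = np.concatenate([y, np.asarray(new_y, dtype=object)])
        else:
            X_res, y_res = X.copy(), y.copy()
        self.synthetic_mask_ = np.concatenate(
            [np.zeros(n_orig, dtype=bool), np.ones(len(new_X), dtype=bool)]
        )
        return X_res, y_res


def balance(matrix: BetaMatrix, config: SmoteConfig | None = None) -> BetaMatrix:
    """Balance a BetaMatrix so every class reaches the target size.

    Original samples are kept unmodified (and keep their ids); synthetic
    samples are appended with ids ``synth_<class>_<i>`` and flagged in the
    result's ``synthetic`` vector.
    """
    config = config or SmoteConfig()
    balancer = SmoteBalancer(config.k, config.target_size, config.seed)
    X_res, y_res = balancer.fit_resample(matrix.values, matrix.labels)
    n_orig = matrix.n_samples
    n_new = X_res.shape[0] - n_orig
    counters: dict[str, int] = {}
    new_ids = []
    for lab in y_res[n_orig:]:
        counters[lab] = counters.get(lab, 0) + 1
        new_ids.append(f"synth_{lab}_{counters[lab]:04d}")
    synthetic = np.concatenate([matrix.synthetic, np.ones(n_new, dtype=bool)])
    return BetaMatrix(
        np.clip(X_res, 0.0, 1.0),
        list(matrix.sample_ids) + new_ids,
        matrix.probe_ids,
        y_res,
        synthetic,
    )
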