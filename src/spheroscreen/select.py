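"""Mutual-information feature ranking against the viability class.

Each continuous feature is discretized into equal-frequency bins and its
mutual information with the class label estimated in bits with the plug-in
(maximum-likelihood) entropy estimator.  Plug-in MI is positively biased at
finite n, so a permutation baseline (mean MI over label shuffles) is
subtracted and the result floored at zero; features that carry no signal
then score ~0 bits instead of the O(bins/n) bias floor.  The top-k features
by MI form the training subset for the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankedFeatures", "mutual_information", "rank_and_select"]


@dataclass
class RankedFeatures:
    """Features ordered by mutual information with the class, plus the top-k."""

    ranking: list[tuple[str, float]]  # (feature name, MI in bits), descending
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranking, columns=["feature", "mi_bits"])
        df["selected"] = df["feature"].isin(self.selected)
        return df


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign equal-frequency bin indices; duplicate quantile edges collapse."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def _plugin_mi_bits(xb: np.ndarray, yb: np.ndarray) -> float:
    """Maximum-likelihood mutual information, in bits, of two discrete arrays."""
    n = xb.size
    xi, xinv = np.unique(xb, return_inverse=True)
    yi, yinv = np.unique(yb, return_inverse=True)
    joint = np.zeros((xi.size, yi.size))
    np.add.at(joint, (xinv, yinv), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def mutual_information(
    feature,
    labels,
    n_bins: int | None = None,
    n_permutations: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mutual information between a feature and class labels, in bits.

    The feature is discretized into ``n_bins`` equal-frequency bins (default
    ``ceil(sqrt(n/5))`` capped at 16; already-discrete features with fewer
    distinct values keep their own categories).  The permutation bias
    baseline — the mean plug-in MI over ``n_permutations`` label shuffles —
    is subtracted and the result floored at 0.

    A constant feature scores 0 bits; fewer than two distinct labels is an
    error (MI with a constant class is undefined as a ranking signal).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size:
        raise ValueError("feature and labels must align")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain at least two classes")
    if np.unique(x).size < 2:
        return 0.0
    n = x.size
    if n_bins is None:
        n_bins = min(math.ceil(math.sqrt(n / 5)), 16)
    if np.unique(x).size <= n_bins:
        xb = np.unique(x, return_inverse=True)[1]
    else:
        xb = _equal_frequency_bins(x, n_bins)
    mi = _plugin_mi_bits(xb, y)
    if n_permutations > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        baseline = 0.0
        yp = y.copy()
        for _ in range(n_permutations):
            rng.shuffle(yp)
            baseline += _plugin_mi_bits(xb, yp)
        mi -= baseline / n_permutations
    return max(mi, 0.0)


def rank_and_select(
    features: pd.DataFrame,
    labels,
    k: int = 15,
    feature_columns: list[str] | None = None,
    n_permutations: int = 100,
    rng: np.random.Generator | int | None = None,
) -> RankedFeatures:
    """Rank features by MI with the class and keep the top ``k``.

    Ties are broken alphabetically by feature name.  If ``k`` exceeds the
    number of features, all are selected (with a logged warning).
    """
    import logging

    if k < 1:
        raise ValueError("k must be >= 1")
    if feature_columns is None:
        feature_columns = [
            c
            for c in features.columns
            if c not in ("spheroid_id", "experiment_id", "concentration_um", "label")
        ]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scores = {
        name: mutual_information(
            features[name].to_numpy(), labels, n_permutations=n_permutations, rng=rng
        )
        for name in feature_columns
    }
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranking):
        logging.getLogger(__name__).warning(
            "k=%d exceeds the %d available features; selecting all", k, len(ranking)
        )
        k = len(ranking)
    return RankedFeatures(ranking, [name for name, _ in ranking[:k]])
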