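"""Minimum-redundancy maximum-relevance (MRMR) ranking for a continuous target.

Relevance of a feature is the absolute Pearson correlation with the target;
redundancy is the mean absolute Pearson correlation with the already-selected
features. Ranking is greedy forward selection: the first pick maximizes
relevance, each later pick maximizes the MRMR criterion against the selected
set. The difference scheme (relevance - redundancy) is the default; the
quotient scheme (relevance / redundancy) is available as an option. Ties are
broken toward the lower feature index, so the ranking is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FeatureRanking:
    """Greedy MRMR ordering of all features.

    ``order`` is a permutation of feature indices; ``scores[t]`` is the MRMR
    criterion value of ``order[t]`` at the step it was selected (relevance
    itself for the first pick). ``k`` is the selection size: the model uses
    ``order[:k]``.
    """

    order: np.ndarray
    scores: np.ndarray = field(repr=False)
    k: int = 15

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order must be a permutation of feature indices")
        if not 1 <= self.k <= len(order):
            raise ValueError("k must lie in [1, n_features]")

    @property
    def selected(self) -> np.ndarray:
        return np.asarray(self.order)[: self.k]


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r|, with 0 (and a warning) for constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant vector in correlation; treated as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def relevance(feature: np.ndarray, target: np.ndarray) -> float:
    """Relevance of one feature: |Pearson r(feature, target)|."""
    feature = np.asarray(feature, dtype=float)
    if len(feature) < 3:
        raise ValueError("relevance needs at least 3 subjects")
    return _abs_corr(feature, target)


def redundancy(feature: np.ndarray, selected_set: np.ndarray | list) -> float:
    """Mean |Pearson r| of a feature with an already-selected set (0 if empty)."""
    selected = [np.asarray(s, dtype=float) for s in selected_set]
    if not selected:
        return 0.0
    return float(np.mean([_abs_corr(feature, s) for s in selected]))


def mrmr_rank(
    features: np.ndarray,
    target: np.ndarray,
    k: int = 15,
    scheme: str = "difference",
) -> FeatureRanking:
    """Greedy MRMR ranking of a subjects x features matrix.

    Parameters
    ----------
    features:
        (n_subjects, n_features) matrix.
    target:
        Continuous outcome, length n_subjects.
    k:
        Selection size recorded in the ranking (default 15).
    scheme:
        ``"difference"`` (relevance - redundancy) or ``"quotient"``
        (relevance / redundancy, with a small floor on the denominator).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, p = x.shape
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features p={p}")
    if scheme not in ("difference", "quotient"):
        raise ValueError(f"unknown MRMR scheme: {scheme}")
    if n < 3:
        raise ValueError("mrmr_rank needs at least 3 subjects")

    sd = x.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s); relevance/redundancy set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    z = np.zeros_like(x)
    z[:, ~const] = (x[:, ~const] - x[:, ~const].mean(axis=0)) / sd[~const]
    if y.std() == 0:
        warnings.warn("constant target; all relevances are 0", RuntimeWarning, stacklevel=2)
        rel = np.zeros(p)
    else:
        zy = (y - y.mean()) / y.std()
        rel = np.abs(z.T @ zy) / n
    abs_corr = np.abs(z.T @ z) / n  # constant features -> zero rows/cols

    order = np.empty(p, dtype=int)
    scores = np.empty(p)
    remaining = np.ones(p, dtype=bool)
    red_sum = np.zeros(p)
    for t in range(p):
        if t == 0:
            crit = rel.copy()
        else:
            red = red_sum / t
            if scheme == "difference":
                crit = rel - red
            else:
                crit = rel / np.maximum(red, 1e-12)
        crit = np.where(remaining, crit, -np.inf)
        pick = int(np.argmax(crit))  # argmax takes the lowest index on ties
        order[t] = pick
        scores[t] = crit[pick]
        remaining[pick] = False
        red_sum += abs_corr[:, pick]
    return FeatureRanking(order=order, scores=scores, k=k)


def variance_explained_check(features: np.ndarray, k: int) -> float:
    """Cumulative variance fraction of the top-k principal components.

    A diagnostic companion to the fixed selection size (the study's 15
    features corresponded to ~80% PCA variance); it never gates selection.
    """
    x = np.asarray(features, dtype=float)
    if not 1 <= k <= x.shape[1]:
        raise ValueError("k must lie in [1, n_features]")
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        raise ValueError("feature matrix has zero total variance")
    return float(var[:k].sum() / total)
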