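"""Shapley attributions and dimension-normalized modality importance.

Per-sample per-feature Shapley values are estimated for any probability
function: exact subset enumeration when the feature count is at most 10,
permutation sampling otherwise (missing features imputed from background
reference rows). Per-feature values are then collapsed to per-modality
scores: within each modality feature set the absolute values are averaged
(dividing by the modality's dimension so high-dimensional sets do not
dominate) and normalized across modalities so every sample's scores sum to
one; the global modality contribution is the mean over samples and also
sums to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModalityRegistry",
    "ShapAttribution",
    "ModalityImportance",
    "shapley_values",
    "mm_shap_per_sample",
    "mm_shap_global",
]

logger = logging.getLogger(__name__)

EXACT_MAX_FEATURES = 10


@dataclass
class ModalityRegistry:
    """Ordered modality feature sets partitioning a fused feature space."""

    index_sets: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.index_sets:
            raise ValueError("registry needs at least one modality")
        self.index_sets = {
            k: np.asarray(v, dtype=int) for k, v in self.index_sets.items()
        }

    @classmethod
    def from_dims(cls, dims: Mapping[str, int]) -> "ModalityRegistry":
        """Contiguous blocks in the given order."""
        sets, start = {}, 0
        for name, d in dims.items():
            sets[name] = np.arange(start, start + d)
            start += d
        return cls(sets)

    @property
    def names(self) -> list[str]:
        return list(self.index_sets)

    @property
    def n_features(self) -> int:
        return sum(len(v) for v in self.index_sets.values())

    def check_partition(self, n_features: int) -> None:
        all_idx = np.concatenate(list(self.index_sets.values()))
        if sorted(all_idx.tolist()) != list(range(n_features)):
            raise ValueError("modality index sets must partition the feature space")


@dataclass
class ShapAttribution:
    """phi[i, j] is feature j's Shapley value for sample i."""

    phi: np.ndarray
    baseline: float
    predictions: np.ndarray


@dataclass
class ModalityImportance:
    s_per_sample: np.ndarray  # (samples, M); excluded samples are NaN rows
    s_global: np.ndarray  # (M,)
    names: list[str]
    excluded_samples: list[int] = field(default_factory=list)


def _value_function(model: Callable, x: np.ndarray, background: np.ndarray):
    """v(S) = mean over background rows of f(x on S, background elsewhere)."""
    k, d = background.shape

    def v(masks: np.ndarray) -> np.ndarray:
        # masks: (m, d) booleans; evaluate all masks x background rows at once
        m = masks.shape[0]
        tiled_bg = np.tile(background, (m, 1))
        tiled_mask = np.repeat(masks, k, axis=0)
        X = np.where(tiled_mask, np.tile(x, (m * k, 1)), tiled_bg)
        out = np.asarray(model(X), dtype=float).reshape(m, k)
        return out.mean(axis=1)

    return v


def _exact_shapley(model, x, background) -> np.ndarray:
    d = x.shape[0]
    masks = np.zeros((2**d, d), dtype=bool)
    subsets = []
    for size in range(d + 1):
        for comb in combinations(range(d), size):
            subsets.append(frozenset(comb))
    for i, s in enumerate(subsets):
        masks[i, list(s)] = True
    v = _value_function(model, x, background)
    values = dict(zip(subsets, v(masks)))
    phi = np.zeros(d)
    for j in range(d):
        for s in subsets:
            if j in s:
                continue
            w = factorial(len(s)) * factorial(d - len(s) - 1) / factorial(d)
            phi[j] += w * (values[s | {j}] - values[s])
    return phi


def _sampled_shapley(model, x, background, n_perm, rng) -> np.ndarray:
    d = x.shape[0]
    v = _value_function(model, x, background)
    phi = np.zeros(d)
    # all prefix masks of all permutations evaluated in one model call
    masks = np.zeros((n_perm * (d + 1), d), dtype=bool)
    orders = np.empty((n_perm, d), dtype=int)
    for p in range(n_perm):
        order = rng.permutation(d)
        orders[p] = order
        row = p * (d + 1)
        for step in range(d):
            masks[row + step + 1] = masks[row + step]
            masks[row + step + 1, order[step]] = True
    vals = v(masks).reshape(n_perm, d + 1)
    deltas = np.diff(vals, axis=1)  # (n_perm, d) marginal contributions
    for p in range(n_perm):
        phi[orders[p]] += deltas[p]
    return phi / n_perm


def shapley_values(
    model: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> ShapAttribution:
    """Shapley attribution of ``model`` over the samples in ``X``.

    ``model`` maps an (n, d) matrix to n real outputs (e.g. positive-class
    probabilities). Exact enumeration is used automatically for d <= 10;
    otherwise ``n_perm`` sampled permutations per sample. Both estimators
    satisfy local accuracy: each row of phi sums to f(x) - E_b[f(b)].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background reference is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    baseline = float(np.mean(np.asarray(model(background), dtype=float)))
    preds = np.asarray(model(X), dtype=float)
    phi = np.empty((n, d))
    for i in range(n):
        if d <= EXACT_MAX_FEATURES:
            phi[i] = _exact_shapley(model, X[i], background)
        else:
            phi[i] = _sampled_shapley(model, X[i], background, n_perm, rng)
    return ShapAttribution(phi=phi, baseline=baseline, predictions=preds)


def mm_shap_per_sample(
    phi: ShapAttribution | np.ndarray,
    registry: ModalityRegistry,
) -> ModalityImportance:
    """Dimension-normalized per-sample modality scores.

    s_m(x_i) = (mean_{j in F_m} |phi_j(x_i)|) / sum_m' (mean |phi|);
    every valid row sums to one. A sample whose attributions are all zero
    has an undefined ratio: its row is NaN, it is excluded from the global
    mean, and the exclusion is logged.
    """
    mat = phi.phi if isinstance(phi, ShapAttribution) else np.asarray(phi, float)
    registry.check_partition(mat.shape[1])
    names = registry.names
    per_mod = np.column_stack(
        [np.abs(mat[:, registry.index_sets[m]]).mean(axis=1) for m in names]
    )
    totals = per_mod.sum(axis=1)
    excluded = np.flatnonzero(totals == 0)
    if excluded.size:
        logger.warning("MM-SHAP: %d sample(s) with all-zero attributions "
                       "excluded from the global mean", excluded.size)
    s = np.full_like(per_mod, np.nan)
    ok = totals > 0
    s[ok] = per_mod[ok] / totals[ok, None]
    if not ok.any():
        raise ValueError("no sample has nonzero attributions")
    s_global = s[ok].mean(axis=0)
    return ModalityImportance(
        s_per_sample=s, s_global=s_global, names=names,
        excluded_samples=excluded.tolist(),
    )


def mm_shap_global(per_sample: ModalityImportance) -> np.ndarray:
    """Global modality contributions: mean of the retained sample rows."""
    s = per_sample.s_per_sample
    ok = ~np.isnan(s).any(axis=1)
    if not ok.any():
        raise ValueError("no valid samples")
    return s[ok].mean(axis=0)
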