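"""Late fusion of per-feature-set classifier outputs.

Three deterministic aggregation rules combine the per-modality
classifiers' test-fold outputs into one decision per participant:

* majority voting over hard class predictions (ties broken toward the
  class with the larger mean probability among voters),
* average-probability fusion (mean positive-class probability, class 1
  iff the mean exceeds 0.5; an exact 0.5 goes positive and is logged),
* selective voting: only feature sets whose validation AUROC strictly
  exceeded 0.5 vote; if none qualify, all sets vote (logged fallback).

Fusion presets mirror the published analyses: audio+language(+demo),
facial+cardio(+demo), and all modalities(+demo); demographics joins every
multimodal fusion as one voter.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "majority_vote",
    "average_probability",
    "selective_vote",
    "FUSION_PRESETS",
    "fuse_fold",
]

logger = logging.getLogger(__name__)

FUSION_PRESETS = {
    "audio_language_demo": [
        "acoustic", "acoustic_hmm", "speech_embedding",
        "sentiment", "sentiment_hmm", "text_embedding", "demographics",
    ],
    "facial_cardio_demo": [
        "emotion_aus", "emotion_aus_hmm", "facial_embedding",
        "bpm", "bpm_hmm", "demographics",
    ],
    "all_demo": [
        "emotion_aus", "emotion_aus_hmm", "facial_embedding",
        "acoustic", "acoustic_hmm", "speech_embedding",
        "sentiment", "sentiment_hmm", "text_embedding",
        "bpm", "bpm_hmm", "demographics",
    ],
}


def majority_vote(
    hard_predictions: Sequence[int],
    probabilities: Sequence[float] | None = None,
) -> int:
    """Modal class of the voters; a tie goes to the class with the larger
    mean positive-class probability (positive class if no probabilities)."""
    preds = list(hard_predictions)
    if not preds:
        raise ValueError("no voters")
    if any(p not in (0, 1) for p in preds):
        raise ValueError("hard predictions must be 0 or 1")
    ones = sum(preds)
    zeros = len(preds) - ones
    if ones != zeros:
        return int(ones > zeros)
    if probabilities is None:
        return 1
    return int(float(np.mean(probabilities)) >= 0.5)


def average_probability(probabilities: Sequence[float]) -> tuple[int, float]:
    """Mean positive-class probability and the implied class."""
    probs = np.asarray(list(probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("no voters")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    fused = float(probs.mean())
    if fused == 0.5:
        logger.info("average-probability tie at 0.5 resolved to positive class")
    return int(fused >= 0.5), fused


def selective_vote(
    per_feature_val_auc: Mapping[str, float],
    hard_predictions: Mapping[str, int],
    probabilities: Mapping[str, float] | None = None,
) -> int:
    """Majority vote restricted to feature sets with validation AUROC > 0.5.

    Feature sets whose validation AUROC is undefined (NaN) do not qualify.
    When no set qualifies the vote falls back to all sets.
    """
    if set(per_feature_val_auc) != set(hard_predictions):
        raise KeyError("validation AUCs and predictions keyed by different sets")
    qualified = [k for k, a in per_feature_val_auc.items()
                 if np.isfinite(a) and a > 0.5]
    if not qualified:
        logger.info("selective voting: no feature set exceeded 0.5; "
                    "falling back to all voters")
        qualified = list(hard_predictions)
    probs = ([probabilities[k] for k in qualified]
             if probabilities is not None else None)
    return majority_vote([hard_predictions[k] for k in qualified], probs)


def fuse_fold(
    per_set_proba: Mapping[str, Mapping[str, float]],
    per_set_val_auc: Mapping[str, float],
    rule: str,
) -> dict[str, tuple[int, float]]:
    """Fuse one fold: per participant, (class, fused score) under a rule.

    ``per_set_proba`` maps feature set -> participant id -> positive-class
    probability. The fused score reported for the vote rules is the mean
    probability of the participating voters (useful for AUROC of the fused
    pipeline).
    """
    sets = list(per_set_proba)
    if not sets:
        raise ValueError("no voters")
    pids = set.intersection(*[set(per_set_proba[s]) for s in sets])
    out = {}
    for pid in sorted(pids):
        probs = {s: per_set_proba[s][pid] for s in sets}
        hards = {s: int(probs[s] > 0.5) for s in sets}
        if rule == "majority":
            cls = majority_vote(list(hards.values()), list(probs.values()))
            score = float(np.mean(list(probs.values())))
        elif rule == "average_probability":
            cls, score = average_probability(list(probs.values()))
        elif rule == "selective":
            cls = selective_vote(per_set_val_auc, hards, probs)
            qualified = [s for s in sets
                         if np.isfinite(per_set_val_auc[s])
                         and per_set_val_auc[s] > 0.5] or sets
            score = float(np.mean([probs[s] for s in qualified]))
        else:
            raise ValueError(f"unknown fusion rule {rule!r}")
        out[pid] = (cls, score)
    return out
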