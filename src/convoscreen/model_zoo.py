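"""Per-feature-set classifiers and the model-to-feature pairing policy.

Four shallow families (logistic regression, gradient-boosted trees, RBF
SVM, random forest) handle aggregated feature vectors; an LSTM and an
encoder-only transformer handle uniformly resampled sequences; an MLP
handles static vectors (demographics, document embeddings). Hyperparameters
follow the published protocol: LR L2 / max_iter 1000; GBDT 100 trees,
learning rate 1.0, depth 3; SVM RBF with probability outputs; RF 100
trees; LSTM hidden 128, one layer; transformer embed 128, 4 heads, 2
layers, MLP hidden 32, dropout 0.1, CLS token; MLP one 64-unit ReLU layer
with dropout 0.3; neural nets train 10 epochs of Adam (lr 1e-3, batch 8)
on cross-entropy. Run r of the evaluation protocol seeds every model with
42 + r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import LSTMClassifier, MLPClassifier, TransformerClassifier

__all__ = [
    "SHALLOW_FAMILIES",
    "ModelSpec",
    "PairingPolicy",
    "SingleClassFoldError",
    "assign_model",
    "train_shallow",
    "train_sequence_model",
    "train_static_mlp",
]

SHALLOW_FAMILIES = ("LR", "GBDT", "SVM", "RF")
SEED_BASE = 42

#: Explicit published pairing of shallow families to feature sets; feature
#: sets outside the table fall back to the dimension rule (<100 -> LR,
#: >=100 -> GBDT). SVM and RF apply to every set.
TABLE_PAIRING = {
    "LR": {
        "emotion_aus", "demographics", "sentiment", "acoustic",
        "emotion_aus_hmm", "sentiment_hmm", "acoustic_hmm",
    },
    "GBDT": {
        "facial_embedding", "bpm", "text_embedding", "speech_embedding",
        "bpm_hmm",
    },
}


@dataclass(frozen=True)
class PairingPolicy:
    explicit: dict = field(default_factory=lambda: {k: set(v) for k, v in TABLE_PAIRING.items()})
    dim_threshold: int = 100


@dataclass
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed_base: int = SEED_BASE

    def seed_for_run(self, run: int) -> int:
        return self.seed_base + run


class SingleClassFoldError(ValueError):
    """Training fold contains a single class; the fold must be skipped."""


def assign_model(feature_set: str, dim: int, policy: PairingPolicy | None = None) -> str:
    """Shallow family for a feature set: explicit table first, then the
    low-/high-dimensional rule."""
    policy = policy or PairingPolicy()
    for family, sets in policy.explicit.items():
        if feature_set in sets:
            return family
    if dim is None:
        raise KeyError(f"unregistered feature set {feature_set!r} without dimension")
    return "LR" if dim < policy.dim_threshold else "GBDT"


def _make_shallow(family: str, seed: int):
    if family == "LR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                # L2 penalty is the library default; naming it explicitly is
                # deprecated in current scikit-learn
                ("clf", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    if family == "GBDT":
        return GradientBoostingClassifier(
            n_estimators=100, learning_rate=1.0, max_depth=3, random_state=seed
        )
    if family == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]
        )
    if family == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown shallow family {family!r}")


def train_shallow(family: str, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit one shallow classifier; raises SingleClassFoldError when the
    fold has one class (callers skip the fold and log it)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassFoldError("training fold contains a single class")
    model = _make_shallow(family, int(seed))
    model.fit(X, y)
    return model


def train_sequence_model(family: str, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit the LSTM or transformer on (participants, frames, dim) input.

    Sequences must already be uniformly resampled to the feature set's
    fixed length; a ragged input is a caller error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("sequence models need (n, frames, dim) input")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassFoldError("training fold contains a single class")
    n, t, d = X.shape
    if family == "LSTM":
        model = LSTMClassifier(n_features=d, hidden=128, seed=int(seed))
    elif family == "TRANSFORMER":
        model = TransformerClassifier(n_features=d, seq_len=t, seed=int(seed))
    else:
        raise ValueError(f"unknown sequence family {family!r}")
    model.fit(X, y)
    return model


def train_static_mlp(X: np.ndarray, y: np.ndarray, seed: int):
    """Fit the 64-unit MLP on static vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassFoldError("training fold contains a single class")
    model = MLPClassifier(n_features=X.shape[1], hidden=64, dropout_p=0.3,
                          seed=int(seed))
    model.fit(X, y)
    return model
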