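"""Binary classification targets from continuous assessments.

Eight outcomes are screened: CDR (0 vs 0.5), MoCA (>24 high vs <=24 low),
clinical diagnosis (1 = normal cognition, 0 = MCI), LSNS-6 social
isolation (<=12), neuroticism, and the three NIH Toolbox emotional
battery composites (negative affect, social satisfaction, psychological
well-being) split at instrument medians. The boundary convention is a
single consistent rule: "cutoff c" means score <= c maps to the low
class, score > c to the high class.

Also provides the one-hot + z-score demographics encoder (sex, years of
education, and age treated as categorical over unique training values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .synthetic_cohort import AssessmentScores, ParticipantRecord, SensitiveAttributes

__all__ = [
    "OUTCOMES",
    "CutoffPolicy",
    "OutcomeLabels",
    "dichotomize",
    "labels_for_cohort",
    "recompute_cutoffs",
    "DemographicsEncoder",
]

OUTCOMES = (
    "CDR",
    "MoCA",
    "DiagnosisMCI",
    "LSNS",
    "Neuroticism",
    "NegativeAffect",
    "SocialSatisfaction",
    "PsychWellbeing",
)

#: Published fixed cutoffs: MoCA 24, LSNS-6 12, neuroticism median 16 and
#: NIH Toolbox composite medians 44.10 / 48.66 / 53.70.
PAPER_CUTOFFS = {
    "MoCA": 24.0,
    "LSNS": 12.0,
    "Neuroticism": 16.0,
    "NegativeAffect": 44.10,
    "SocialSatisfaction": 48.66,
    "PsychWellbeing": 53.70,
}

_SCORE_RANGES = {
    "moca": (0, 30),
    "cdr": (0.0, 0.5),
    "lsns6": (0, 30),
    "neuroticism": (0, 48),
}


@dataclass(frozen=True)
class CutoffPolicy:
    """Where the dichotomization thresholds come from.

    mode "fixed" uses the published values; mode "recompute" replaces the
    median-based cutoffs (MoCA, neuroticism, the three composites) with
    medians of the supplied training scores — CDR, diagnosis, and the
    LSNS-6 isolation threshold of 12 are instrument-defined and never
    recomputed.
    """

    mode: str = "fixed"
    cutoffs: Mapping[str, float] = field(default_factory=lambda: dict(PAPER_CUTOFFS))

    def __post_init__(self):
        if self.mode not in {"fixed", "recompute"}:
            raise ValueError(f"unknown cutoff mode {self.mode!r}")


@dataclass
class OutcomeLabels:
    """Binary label and the cutoff actually used, per outcome."""

    labels: dict[str, int]
    cutoffs: dict[str, float]

    def __getitem__(self, outcome: str) -> int:
        return self.labels[outcome]


def _check_ranges(s: AssessmentScores) -> None:
    for attr, (lo, hi) in _SCORE_RANGES.items():
        v = getattr(s, attr)
        if not (lo <= v <= hi):
            raise ValueError(f"{attr}={v} outside instrument range [{lo}, {hi}]")
    if s.cdr not in (0.0, 0.5):
        raise ValueError(f"CDR must be 0 or 0.5, got {s.cdr}")


def dichotomize(
    scores: AssessmentScores,
    cutoffs: CutoffPolicy | None = None,
    diagnosis: str | None = None,
) -> OutcomeLabels:
    """Map one participant's assessments to the eight binary targets.

    Label 1 means: high MoCA (>24), questionable dementia (CDR 0.5),
    normal cognition (vs MCI), socially isolated (LSNS-6 <= 12), and
    above-cutoff neuroticism / composite scores. The cutoff used for each
    outcome is recorded for audit.
    """
    policy = cutoffs or CutoffPolicy()
    _check_ranges(scores)
    c = dict(PAPER_CUTOFFS)
    c.update(policy.cutoffs)
    labels = {
        "CDR": int(scores.cdr == 0.5),
        "MoCA": int(scores.moca > c["MoCA"]),
        "LSNS": int(scores.lsns6 <= c["LSNS"]),  # isolated = positive
        "Neuroticism": int(scores.neuroticism > c["Neuroticism"]),
        "NegativeAffect": int(scores.negative_affect > c["NegativeAffect"]),
        "SocialSatisfaction": int(scores.social_satisfaction > c["SocialSatisfaction"]),
        "PsychWellbeing": int(scores.psych_wellbeing > c["PsychWellbeing"]),
    }
    if diagnosis is not None:
        if diagnosis not in {"NC", "MCI"}:
            raise ValueError(f"unknown diagnosis {diagnosis!r}")
        labels["DiagnosisMCI"] = int(diagnosis == "NC")  # 1 = normal cognition
    used = {k: c.get(k, float("nan")) for k in labels}
    used["CDR"] = 0.5
    used["DiagnosisMCI"] = float("nan")
    return OutcomeLabels(labels=labels, cutoffs=used)


def recompute_cutoffs(
    training_records: Iterable[ParticipantRecord],
    base: CutoffPolicy | None = None,
) -> CutoffPolicy:
    """Median-based cutoffs recomputed on training participants only."""
    recs = list(training_records)
    meds = {
        "MoCA": float(np.median([r.scores.moca for r in recs])),
        "Neuroticism": float(np.median([r.scores.neuroticism for r in recs])),
        "NegativeAffect": float(np.median([r.scores.negative_affect for r in recs])),
        "SocialSatisfaction": float(
            np.median([r.scores.social_satisfaction for r in recs])
        ),
        "PsychWellbeing": float(np.median([r.scores.psych_wellbeing for r in recs])),
    }
    cutoffs = dict((base or CutoffPolicy()).cutoffs)
    cutoffs.update(meds)
    return replace(base or CutoffPolicy(), mode="recompute", cutoffs=cutoffs)


def labels_for_cohort(
    records: Iterable[ParticipantRecord],
    cutoffs: CutoffPolicy | None = None,
) -> dict[str, OutcomeLabels]:
    """Participant-id keyed labels for a whole cohort."""
    return {
        r.participant_id: dichotomize(r.scores, cutoffs, diagnosis=r.attrs.diagnosis)
        for r in records
    }


class DemographicsEncoder:
    """One-hot + z-score encoding of sex, years of education, and age.

    Age and YOE are treated as categorical: one indicator per unique
    value seen in the training fold. Columns are standardized with
    training-fold statistics (a zero-variance column keeps denominator 1,
    so it encodes as constant 0). Test-time categories unseen in training
    map to an all-zero block for their variable.
    """

    def __init__(self) -> None:
        self._fitted = False

    def fit(self, attrs: Iterable[SensitiveAttributes]) -> "DemographicsEncoder":
        attrs = list(attrs)
        if not attrs:
            raise ValueError("no training attributes")
        self.sex_levels_ = sorted({a.sex for a in attrs})
        self.yoe_levels_ = sorted({a.yoe for a in attrs})
        self.age_levels_ = sorted({a.age_years for a in attrs})
        raw = np.array([self._onehot(a) for a in attrs], dtype=float)
        self.mean_ = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self._fitted = True
        return self

    def _onehot(self, a: SensitiveAttributes) -> np.ndarray:
        for f in ("sex", "age_years", "yoe"):
            if getattr(a, f, None) is None:
                raise ValueError(f"missing attribute {f}")
        sex = [float(a.sex == lvl) for lvl in self.sex_levels_]
        yoe = [float(a.yoe == lvl) for lvl in self.yoe_levels_]
        age = [float(a.age_years == lvl) for lvl in self.age_levels_]
        return np.array(sex + yoe + age)

    def transform(self, attrs: Iterable[SensitiveAttributes]) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("encoder not fitted")
        raw = np.array([self._onehot(a) for a in attrs], dtype=float)
        return (raw - self.mean_) / self.scale_

    def fit_transform(self, attrs: Iterable[SensitiveAttributes]) -> np.ndarray:
        attrs = list(attrs)
        return self.fit(attrs).transform(attrs)

    @property
    def age_block_width(self) -> int:
        return len(self.age_levels_)
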