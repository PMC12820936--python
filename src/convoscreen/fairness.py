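"""Group-fairness audit and equalized-odds threshold post-processing.

For each sensitive attribute (sex, age group split at 78.9 years, years
of education in three bands, NC vs MCI diagnosis) the audit computes
per-group selection rates, true-positive rates and false-positive rates,
summarizes disparity as the demographic parity ratio (min/max selection
rate) and the equalized odds ratio (the worse of the min/max TPR and
min/max FPR ratios), and flags a pipeline under the four-fifths rule when
either ratio falls below 0.8.

Mitigation follows the equalized-odds post-processing recipe: on a
fitting (validation) set, each group's achievable (FPR, TPR) region is the
convex hull of its empirical ROC curve; the common operating point
maximizing balanced accuracy inside the intersection of all groups'
regions is selected, and each group realizes it with a randomized decision
rule (a mixture of two thresholds, plus a coin that matches the common
point exactly). The utility cost is reported as subgroup-averaged F1
before and after mitigation.

Rate-ratio conventions: a 0/0 ratio is 1 (two identically degenerate
groups are not a disparity); a defined-vs-zero ratio is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

__all__ = [
    "GroupRates",
    "FairnessReport",
    "ThresholdPolicy",
    "group_rates",
    "demographic_parity_ratio",
    "equalized_odds_ratio",
    "fit_eo_thresholds",
    "apply_thresholds",
    "subgroup_f1_tradeoff",
    "audit",
]

logger = logging.getLogger(__name__)

FOUR_FIFTHS = 0.8


@dataclass
class GroupRates:
    """Per-group selection / error rates; undefined rates are NaN."""

    selection_rate: dict[str, float]
    tpr: dict[str, float]
    fpr: dict[str, float]
    support: dict[str, int]

    @property
    def groups(self) -> list[str]:
        return list(self.selection_rate)


@dataclass
class FairnessReport:
    attribute: str
    dpr: float
    eor: float
    four_fifths_flag: bool
    rates: GroupRates
    f1_before: float = float("nan")
    f1_after: float = float("nan")
    ci95: dict = field(default_factory=dict)


@dataclass
class ThresholdPolicy:
    """Randomized group-specific decision rules hitting one operating point.

    For each group: predict positive when score > t_hi, and when the score
    falls between the two thresholds randomize with probability ``alpha``
    of using the lower threshold; with probability ``1 - beta`` the rule is
    replaced by a coin of rate ``coin_p`` (= target FPR), which pulls the
    group's TPR down to the common point without moving its FPR.
    """

    target_fpr: float
    target_tpr: float
    group_rules: dict[str, dict]

    def describe(self) -> dict:
        return {
            "target": {"fpr": self.target_fpr, "tpr": self.target_tpr},
            "groups": self.group_rules,
        }


def _as_arrays(y_true, y_pred, groups):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    groups = np.asarray(groups)
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise ValueError("y_true, y_pred and groups must have equal length")
    return y_true, y_pred, groups


def group_rates(y_true, y_pred, groups) -> GroupRates:
    """Selection rate, TPR and FPR per group by direct counting.

    Groups without positives (TPR) or negatives (FPR) get NaN for the
    undefined rate, with a logged warning.
    """
    y_true, y_pred, groups = _as_arrays(y_true, y_pred, groups)
    if len(y_true) == 0:
        raise ValueError("empty inputs")
    sr, tpr, fpr, support = {}, {}, {}, {}
    for g in np.unique(groups):
        m = groups == g
        key = str(g)
        support[key] = int(m.sum())
        sr[key] = float(y_pred[m].mean())
        pos = m & (y_true == 1)
        neg = m & (y_true == 0)
        if pos.any():
            tpr[key] = float(y_pred[pos].mean())
        else:
            tpr[key] = float("nan")
            logger.warning("group %s has no positives; TPR undefined", key)
        if neg.any():
            fpr[key] = float(y_pred[neg].mean())
        else:
            fpr[key] = float("nan")
            logger.warning("group %s has no negatives; FPR undefined", key)
    return GroupRates(sr, tpr, fpr, support)


def _min_max_ratio(values: list[float]) -> float:
    """min/max over defined (non-NaN) rates; 0/0 -> 1, x/0 with x>0 -> 0."""
    vals = [v for v in values if np.isfinite(v)]
    if len(vals) < 2:
        raise ValueError("need at least two groups with defined rates")
    lo, hi = min(vals), max(vals)
    if hi == 0.0:
        return 1.0
    return lo / hi


def demographic_parity_ratio(rates: GroupRates) -> float:
    """Least-favored selection rate over most-favored selection rate."""
    if max(rates.selection_rate.values()) == 0.0:
        logger.info("no selections in any group; DPR defined as 1")
    return _min_max_ratio(list(rates.selection_rate.values()))


def equalized_odds_ratio(rates: GroupRates) -> float:
    """min(min/max TPR, min/max FPR) across groups with defined rates."""
    defined = [g for g in rates.groups
               if np.isfinite(rates.tpr[g]) and np.isfinite(rates.fpr[g])]
    dropped = set(rates.groups) - set(defined)
    if dropped:
        logger.warning("EOR: excluding groups with undefined rates: %s",
                       sorted(dropped))
    if len(defined) < 2:
        raise ValueError("fewer than two groups with defined TPR and FPR")
    tpr_ratio = _min_max_ratio([rates.tpr[g] for g in defined])
    fpr_ratio = _min_max_ratio([rates.fpr[g] for g in defined])
    return min(tpr_ratio, fpr_ratio)


# ---------------------------------------------------------------------------
# equalized-odds post-processing
# ---------------------------------------------------------------------------

def _roc_envelope(scores: np.ndarray, y: np.ndarray):
    """Upper concave envelope of the empirical ROC, as threshold points.

    Returns (fpr, tpr, thresholds) for the vertices of the convex hull of
    the achievable region, ordered by increasing FPR, always including
    (0, 0) at threshold +inf and (1, 1) at threshold -inf.
    """
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    tp = np.concatenate([[0], np.cumsum(ys == 1)])
    fp = np.concatenate([[0], np.cumsum(ys == 0)])
    # candidate thresholds between distinct consecutive scores
    sorted_scores = scores[order]
    thresholds = np.concatenate([[np.inf], sorted_scores])
    keep = np.ones(len(thresholds), dtype=bool)
    keep[1:-1] = sorted_scores[:-1] != sorted_scores[1:]
    fpr = fp[keep] / n_neg
    tpr = tp[keep] / n_pos
    thr = thresholds[keep]
    # upper concave envelope (monotone chain over ROC points)
    hull = []
    for i in range(len(fpr)):
        while len(hull) >= 2:
            (x1, y1, _), (x2, y2, _) = hull[-2], hull[-1]
            cross = (x2 - x1) * (tpr[i] - y1) - (y2 - y1) * (fpr[i] - x1)
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append((fpr[i], tpr[i], thr[i]))
    # for duplicate FPR keep the highest-TPR vertex so interpolation is
    # well defined
    dedup: dict[float, tuple[float, float]] = {}
    for a, b, c in hull:
        if a not in dedup or b > dedup[a][0]:
            dedup[a] = (b, c)
    xs = np.array(sorted(dedup))
    ys = np.array([dedup[x][0] for x in xs])
    ts = np.array([dedup[x][1] for x in xs])
    return xs, ys, ts


def _envelope_tpr_at(fpr_env, tpr_env, target_fpr: float) -> float:
    return float(np.interp(target_fpr, fpr_env, tpr_env))


def fit_eo_thresholds(
    scores,
    y_true,
    groups,
    grid: int = 501,
) -> ThresholdPolicy:
    """Group-specific randomized thresholds aligning TPR and FPR.

    On the fitting set the achievable (FPR, TPR) region of each group is
    the convex hull of its empirical ROC; the intersection over groups is
    scanned along an FPR grid for the point maximizing balanced accuracy
    (TPR + 1 - FPR) / 2, where the common TPR at each FPR is the minimum
    of the group envelopes. Each group realizes the chosen point exactly
    (on the fitting set) by mixing two adjacent thresholds and, if its
    envelope lies above the common point, a coin of rate FPR*.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    groups = np.asarray(groups)
    envelopes = {}
    for g in np.unique(groups):
        m = groups == g
        if (y_true[m] == 1).sum() == 0 or (y_true[m] == 0).sum() == 0:
            raise ValueError(f"group {g!s} lacks positives or negatives")
        envelopes[str(g)] = _roc_envelope(scores[m], y_true[m])
    fpr_grid = np.linspace(0.0, 1.0, grid)
    common_tpr = np.min(
        [np.interp(fpr_grid, e[0], e[1]) for e in envelopes.values()], axis=0
    )
    common_tpr = np.maximum(common_tpr, fpr_grid)  # diagonal always feasible
    bal_acc = (common_tpr + 1.0 - fpr_grid) / 2.0
    best = int(np.argmax(bal_acc))
    fpr_star, tpr_star = float(fpr_grid[best]), float(common_tpr[best])

    rules = {}
    for g, (fe, te, th) in envelopes.items():
        # two adjacent envelope vertices straddling fpr_star
        j = int(np.searchsorted(fe, fpr_star, side="right"))
        j = min(max(j, 1), len(fe) - 1)
        f1_, f2_ = fe[j - 1], fe[j]
        alpha = 0.0 if f2_ == f1_ else (fpr_star - f1_) / (f2_ - f1_)
        alpha = float(np.clip(alpha, 0.0, 1.0))
        env_tpr = (1 - alpha) * te[j - 1] + alpha * te[j]
        if env_tpr > tpr_star and env_tpr > fpr_star:
            beta = (tpr_star - fpr_star) / (env_tpr - fpr_star)
        else:
            beta = 1.0
        rules[g] = {
            "t_lo": float(th[j]),      # lower threshold (higher FPR vertex)
            "t_hi": float(th[j - 1]),  # higher threshold (lower FPR vertex)
            "alpha": alpha,            # P(use t_lo) in the envelope mixture
            "beta": float(np.clip(beta, 0.0, 1.0)),  # P(use envelope rule)
            "coin_p": fpr_star,        # rate of the flattening coin
        }
    return ThresholdPolicy(fpr_star, tpr_star, rules)


def apply_thresholds(policy: ThresholdPolicy, scores, groups, seed: int) -> np.ndarray:
    """Randomized group-specific thresholding, seeded for reproducibility.

    Groups absent from the policy fall back to a pooled 0.5 threshold
    with a logged warning.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    pred = np.zeros(len(scores), dtype=int)
    for i, (s, g) in enumerate(zip(scores, groups)):
        rule = policy.group_rules.get(str(g))
        if rule is None:
            logger.warning("group %s unseen by the policy; pooled threshold", g)
            pred[i] = int(s > 0.5)
            continue
        if rng.random() >= rule["beta"]:
            pred[i] = int(rng.random() < rule["coin_p"])
            continue
        t = rule["t_lo"] if rng.random() < rule["alpha"] else rule["t_hi"]
        pred[i] = int(s >= t)  # >= matches the empirical ROC vertex counts
    return pred


def policy_expected_rates(policy: ThresholdPolicy, scores, y_true, groups) -> GroupRates:
    """Expected per-group rates of the randomized policy (no coin flips).

    For a randomized decision rule the realized rates on a finite sample
    fluctuate around the rule's expectation; this computes the exact
    expected selection/TPR/FPR per group, which on the fitting set equals
    the chosen operating point by construction.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    groups = np.asarray(groups)
    p_pos = np.zeros(len(scores))
    for i, (s, g) in enumerate(zip(scores, groups)):
        rule = policy.group_rules.get(str(g))
        if rule is None:
            p_pos[i] = float(s > 0.5)
            continue
        env = (rule["alpha"] * float(s >= rule["t_lo"])
               + (1 - rule["alpha"]) * float(s >= rule["t_hi"]))
        p_pos[i] = rule["beta"] * env + (1 - rule["beta"]) * rule["coin_p"]
    sr, tpr, fpr, support = {}, {}, {}, {}
    for g in np.unique(groups):
        m = groups == g
        key = str(g)
        support[key] = int(m.sum())
        sr[key] = float(p_pos[m].mean())
        pos, neg = m & (y_true == 1), m & (y_true == 0)
        tpr[key] = float(p_pos[pos].mean()) if pos.any() else float("nan")
        fpr[key] = float(p_pos[neg].mean()) if neg.any() else float("nan")
    return GroupRates(sr, tpr, fpr, support)


def subgroup_f1_tradeoff(y_true, pred_before, pred_after, groups) -> tuple[float, float]:
    """Unweighted mean of per-subgroup positive-class F1, before and after
    mitigation. A subgroup with no positives and no positive predictions
    contributes F1 = 0 (logged)."""
    y_true, pred_before, groups = _as_arrays(y_true, pred_before, groups)
    pred_after = np.asarray(pred_after, dtype=int)
    if len(pred_after) != len(y_true):
        raise ValueError("inconsistent lengths")

    def mean_f1(pred):
        vals = []
        for g in np.unique(groups):
            m = groups == g
            if y_true[m].sum() == 0 and pred[m].sum() == 0:
                logger.info("group %s has no positives nor positive "
                            "predictions; F1 defined 0", g)
                vals.append(0.0)
                continue
            vals.append(f1_score(y_true[m], pred[m], zero_division=0))
        return float(np.mean(vals))

    return mean_f1(pred_before), mean_f1(pred_after)


def audit(y_true, y_pred, groups, attribute: str = "") -> FairnessReport:
    """One-attribute fairness report: rates, DPR, EOR, four-fifths flag."""
    rates = group_rates(y_true, y_pred, groups)
    dpr = demographic_parity_ratio(rates)
    eor = equalized_odds_ratio(rates)
    return FairnessReport(
        attribute=attribute,
        dpr=dpr,
        eor=eor,
        four_fifths_flag=bool(min(dpr, eor) < FOUR_FIFTHS),
        rates=rates,
    )
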