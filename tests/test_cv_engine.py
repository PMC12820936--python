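import itertools

import numpy as np
import pytest

from convoscreen import cv_engine
from convoscreen.cv_engine import (
    AuditEntry,
    FoldPlan,
    FoldPredictions,
    assert_no_leakage,
    evaluate,
    make_fold_plans,
)


def brute_force_auroc(y, p):
    """Pair-counting definition; ties count 0.5."""
    pos = [s for s, t in zip(p, y) if t == 1]
    neg = [s for s, t in zip(p, y) if t == 0]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _fold_preds(run, fold, ids, proba, val_auc=0.7):
    plan = FoldPlan(run, fold, tuple(f"tr{i}" for i in range(3)),
                    ("v0",), tuple(ids))
    proba = np.asarray(proba, dtype=float)
    return FoldPredictions(plan, tuple(ids), proba,
                           (proba > 0.5).astype(int), val_auc)


class TestFoldPlans:
    def test_split_fractions_at_39(self):
        ids = [f"p{i}" for i in range(39)]
        plans = make_fold_plans(ids, n_runs=3)
        for p in plans:
            assert len(p.test_ids) in (7, 8)          # ~20%
            assert len(p.val_ids) == 6                # ~16%
            assert len(p.train_ids) in (25, 26)       # ~64%
            union = set(p.train_ids) | set(p.val_ids) | set(p.test_ids)
            assert union == set(ids)
        for r in range(3):
            covered = [pid for p in plans if p.run_index == r
                       for pid in p.test_ids]
            assert sorted(covered) == sorted(ids)  # each id tested once

    def test_plans_deterministic_in_seed_base(self):
        ids = [f"p{i}" for i in range(17)]
        assert make_fold_plans(ids, 2, seed_base=42) == make_fold_plans(
            ids, 2, seed_base=42
        )
        assert make_fold_plans(ids, 1, seed_base=42) != make_fold_plans(
            ids, 1, seed_base=43
        )

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plans(["a", "b", "c", "d"])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(0, 0, ("a", "b"), ("b",), ("c",))


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = {f"t{i}": i % 2 for i in range(8)}
        ids = list(labels)
        fp = _fold_preds(0, 0, ids, [labels[i] * 0.8 + 0.1 for i in ids])
        out = evaluate([fp], labels)
        assert out["AUROC"].mean == 1.0
        assert out["macroF1"].mean == 1.0
        assert out["accuracy"].mean == 1.0

    def test_auroc_matches_pair_counting_oracle(self):
        y = [0, 0, 1, 1]
        p = [0.1, 0.4, 0.35, 0.8]
        assert brute_force_auroc(y, p) == pytest.approx(0.75)
        labels = dict(zip("abcd", y))
        fp = _fold_preds(0, 0, list("abcd"), p)
        assert evaluate([fp], labels)["AUROC"].mean == pytest.approx(0.75)

    def test_auroc_oracle_on_random_instances_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.choice([0.2, 0.5, 0.7, 0.9], size=n)  # force ties
            ids = [f"x{i}" for i in range(n)]
            fp = _fold_preds(0, 0, ids, p)
            got = evaluate([fp], dict(zip(ids, y)))["AUROC"].mean
            assert got == pytest.approx(brute_force_auroc(y, p))

    def test_label_independent_scores_average_half(self, rng):
        labels = {f"t{i}": int(rng.integers(0, 2)) for i in range(10)}
        ids = list(labels)
        preds = [_fold_preds(r, 0, ids, rng.random(len(ids)))
                 for r in range(300)]
        s = evaluate(preds, labels)["AUROC"]
        se = s.per_run.std(ddof=1) / np.sqrt(s.n_runs)
        assert abs(s.mean - 0.5) <= 1.96 * se

    def test_ci_shrinks_with_runs(self, rng):
        labels = {f"t{i}": i % 2 for i in range(10)}
        ids = list(labels)
        preds = [_fold_preds(r, 0, ids, rng.random(len(ids)))
                 for r in range(400)]
        s100 = evaluate(preds[:100], labels)["AUROC"]
        s400 = evaluate(preds, labels)["AUROC"]
        assert s400.ci95_halfwidth < s100.ci95_halfwidth

    def test_no_completed_runs_rejected(self):
        fp = _fold_preds(0, 0, ["a"], [0.5])
        fp.skipped = True
        with pytest.raises(ValueError):
            evaluate([fp], {"a": 1})


class TestLeakageAudit:
    def test_cv_runner_fits_only_on_training_folds(self, small_cohort,
                                                   small_labels):
        labels = small_labels["MoCA"]
        ids = [r.participant_id for r in small_cohort]
        plans = make_fold_plans(ids, n_runs=1)
        audit: list[AuditEntry] = []
        preds = cv_engine.run_feature_set_cv(
            small_cohort, labels, "emotion_aus_hmm", "LR", plans, audit=audit
        )
        assert_no_leakage(audit, plans)
        hmm_entries = [a for a in audit if a.object_kind.startswith("hmm")]
        assert len(hmm_entries) == 5  # one group HMM per outer fold
        done = [p for p in preds if not p.skipped]
        assert all(len(p.proba) == len(p.test_ids) for p in done)

    def test_leaky_entry_detected(self):
        ids = [f"p{i}" for i in range(10)]
        plans = make_fold_plans(ids, n_runs=1)
        bad = AuditEntry(0, 0, "model", tuple(plans[0].test_ids))
        with pytest.raises(AssertionError):
            assert_no_leakage([bad], plans)
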