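"""Participant-wise nested cross-validation protocol.

The evaluation protocol is 100 repetitions of participant-wise 5-fold
nested cross-validation: each run shuffles the cohort into five outer test
folds, and within each outer training set one fifth of the participants is
held out for validation, giving 64% / 16% / 20% train / validation / test
splits. Run r is seeded with ``seed_base + r`` (default base 42) so every
model family sees the exact same splits. Metrics (AUROC, accuracy,
macro-F1) are computed per run as the mean over its test folds' metrics
and summarized as mean +/- 1.96 standard errors across runs.

This module also hosts the per-feature-set CV runner, which re-fits every
training-fold-dependent object (HMMs, scalers, demographics encoders,
median cutoffs, classifiers) inside each fold, and a fold-audit trail that
fingerprints which participants each fitted object saw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from . import model_zoo, outcomes, temporal_features
from .model_zoo import SingleClassFoldError
from .synthetic_cohort import ParticipantRecord

__all__ = [
    "FoldPlan",
    "FoldPredictions",
    "MetricSummary",
    "make_fold_plans",
    "evaluate",
    "run_feature_set_cv",
    "FeatureCache",
    "assert_no_leakage",
]


@dataclass(frozen=True)
class FoldPlan:
    run_index: int
    outer_fold: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test sets overlap")


@dataclass
class FoldPredictions:
    """Test-fold outputs of one fitted pipeline."""

    plan: FoldPlan
    test_ids: tuple[str, ...]
    proba: np.ndarray  # positive-class probability per test participant
    pred: np.ndarray
    val_auc: float
    skipped: bool = False
    skip_reason: str = ""
    val_ids: tuple[str, ...] = ()
    val_proba: np.ndarray | None = None


@dataclass
class MetricSummary:
    metric: str
    mean: float
    ci95_halfwidth: float
    per_run: np.ndarray
    ci_mode: str = "normal"

    @property
    def n_runs(self) -> int:
        return len(self.per_run)


@dataclass
class AuditEntry:
    run_index: int
    outer_fold: int
    object_kind: str
    seen_ids: tuple[str, ...]


def make_fold_plans(
    participant_ids,
    n_runs: int = 100,
    seed_base: int = 42,
    n_folds: int = 5,
) -> list[FoldPlan]:
    """Fold plans for every (run, outer fold) pair.

    Each run shuffles the cohort and cuts it into ``n_folds`` test folds;
    within each outer training set a further 1/``n_folds`` of participants
    becomes validation (0.8 * 0.8 = 64% training overall).
    """
    ids = list(participant_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} participants")
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    plans = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed_base + r)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        folds = np.array_split(np.arange(len(ids)), n_folds)
        for k, test_idx in enumerate(folds):
            test = tuple(perm[i] for i in test_idx)
            rest = [p for p in perm if p not in set(test)]
            rest = [rest[i] for i in rng.permutation(len(rest))]
            n_val = max(1, int(round(len(rest) / n_folds)))
            val = tuple(rest[:n_val])
            train = tuple(rest[n_val:])
            plans.append(FoldPlan(r, k, train, val, test))
    return plans


def _safe_auc(y, p) -> float:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, p))


def evaluate(
    fold_predictions: list[FoldPredictions],
    labels: dict[str, int],
    ci_mode: str = "normal",
    per_run: str = "fold_mean",
) -> dict[str, MetricSummary]:
    """Per-run metrics, aggregated across runs.

    Each run's AUROC / accuracy / macro-F1 is by default the mean over
    its five test folds' metrics (folds where a metric is undefined are
    dropped with their count reflected in the run value). Pooling the
    five folds' predictions first is available as ``per_run="pooled"``
    but is systematically pessimistic on label-independent data: the
    classifier's score scale shifts with each training fold's class
    prior, and ranking scores across unstratified folds turns those
    shifts into inversions. The summary across runs is the mean with a
    95% CI (normal approximation by default, percentile optional).
    """
    if per_run not in {"fold_mean", "pooled"}:
        raise ValueError(f"unknown per-run mode {per_run!r}")
    by_run: dict[int, list[FoldPredictions]] = {}
    for fp in fold_predictions:
        if not fp.skipped:
            by_run.setdefault(fp.plan.run_index, []).append(fp)
    if not by_run:
        raise ValueError("no completed runs to evaluate")
    rows = {"AUROC": [], "accuracy": [], "macroF1": []}
    for r in sorted(by_run):
        if per_run == "pooled":
            y, p, c = [], [], []
            for fp in by_run[r]:
                for pid, prob, pred in zip(fp.test_ids, fp.proba, fp.pred):
                    y.append(labels[pid])
                    p.append(prob)
                    c.append(pred)
            rows["AUROC"].append(_safe_auc(y, p))
            rows["accuracy"].append(accuracy_score(y, c))
            rows["macroF1"].append(
                f1_score(y, c, average="macro", zero_division=0)
            )
            continue
        aucs, accs, f1s = [], [], []
        for fp in by_run[r]:
            y = [labels[pid] for pid in fp.test_ids]
            aucs.append(_safe_auc(y, fp.proba))
            accs.append(accuracy_score(y, fp.pred))
            f1s.append(f1_score(y, fp.pred, average="macro", zero_division=0))
        rows["AUROC"].append(float(np.nanmean(aucs)) if np.isfinite(aucs).any()
                             else float("nan"))
        rows["accuracy"].append(float(np.mean(accs)))
        rows["macroF1"].append(float(np.mean(f1s)))
    out = {}
    for metric, vals in rows.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"metric {metric} undefined in every run")
        mean = float(vals.mean())
        if ci_mode == "normal":
            half = float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        elif ci_mode == "percentile":
            lo, hi = np.percentile(vals, [2.5, 97.5])
            half = float((hi - lo) / 2.0)
        else:
            raise ValueError(f"unknown ci mode {ci_mode!r}")
        out[metric] = MetricSummary(metric, mean, half, vals, ci_mode)
    return out


# ---------------------------------------------------------------------------
# per-feature-set CV runner
# ---------------------------------------------------------------------------

class FeatureCache:
    """Memoizes fold-dependent participant feature vectors so several
    tasks and families can share one HMM fit per (feature set, run, fold)."""

    def __init__(self) -> None:
        self._store: dict = {}

    def get_or_build(self, key, builder):
        if key not in self._store:
            self._store[key] = builder()
        return self._store[key]


def _hmm_features(
    records_by_id: dict[str, ParticipantRecord],
    base_set: str,
    plan: FoldPlan,
    seed: int,
    audit: list[AuditEntry] | None,
    pad_to_tmax: bool = False,
    posterior: bool = False,
) -> dict[str, np.ndarray]:
    train_series = [records_by_id[pid].streams[base_set] for pid in plan.train_ids]
    hmm = temporal_features.fit_group_hmm(
        train_series, seed=seed, pad_to_tmax=pad_to_tmax
    )
    hmm.train_fingerprint = tuple(sorted(plan.train_ids))
    if audit is not None:
        audit.append(AuditEntry(plan.run_index, plan.outer_fold,
                                f"hmm:{base_set}", hmm.train_fingerprint))
    return {
        pid: temporal_features.hmm_state_summary(
            hmm, rec.streams[base_set], posterior=posterior
        ).as_vector()
        for pid, rec in records_by_id.items()
    }


def _static_features(
    records_by_id: dict[str, ParticipantRecord],
    feature_set: str,
    plan: FoldPlan,
    audit: list[AuditEntry] | None,
) -> dict[str, np.ndarray]:
    if feature_set == "demographics":
        enc = outcomes.DemographicsEncoder()
        enc.fit([records_by_id[pid].attrs for pid in plan.train_ids])
        if audit is not None:
            audit.append(AuditEntry(plan.run_index, plan.outer_fold,
                                    "demographics_encoder",
                                    tuple(sorted(plan.train_ids))))
        ids = list(records_by_id)
        mat = enc.transform([records_by_id[pid].attrs for pid in ids])
        return dict(zip(ids, mat))
    if feature_set in next(iter(records_by_id.values())).static_vectors:
        return {pid: np.asarray(rec.static_vectors[feature_set], dtype=float)
                for pid, rec in records_by_id.items()}
    raise KeyError(f"unknown static feature set {feature_set!r}")


def participant_features(
    records_by_id: dict[str, ParticipantRecord],
    feature_set: str,
    plan: FoldPlan,
    seed: int,
    audit: list[AuditEntry] | None = None,
    cache: FeatureCache | None = None,
    pad_to_tmax: bool = False,
    posterior: bool = False,
) -> dict[str, np.ndarray]:
    """Fixed-length vectors for one feature set under one fold plan.

    Fold-dependent featurizers (group HMM, demographics encoder) fit on
    the fold's training participants only; fold-independent ones
    (statistical aggregation, BPM quantiles) are computed once and cached.
    """
    sample = next(iter(records_by_id.values()))
    if feature_set.endswith("_hmm"):
        base = feature_set[: -len("_hmm")]
        key = ("hmm", feature_set, plan.run_index, plan.outer_fold,
               pad_to_tmax, posterior)

        def build():
            return _hmm_features(records_by_id, base, plan, seed, audit,
                                 pad_to_tmax, posterior)

        return cache.get_or_build(key, build) if cache else build()
    if feature_set == "demographics" or feature_set in sample.static_vectors:
        if feature_set == "demographics":
            return _static_features(records_by_id, feature_set, plan, audit)
        key = ("static", feature_set)

        def build_static():
            return _static_features(records_by_id, feature_set, plan, None)

        return cache.get_or_build(key, build_static) if cache else build_static()
    if feature_set == "bpm":
        key = ("bpm_quantiles",)

        def build_bpm():
            return {
                pid: temporal_features.hrv_quantile_features(
                    rec.streams["bpm"].values[:, 0]
                )
                for pid, rec in records_by_id.items()
            }

        return cache.get_or_build(key, build_bpm) if cache else build_bpm()
    # default: per-dimension mean / std aggregation of the raw stream
    key = ("stats", feature_set)

    def build_stats():
        return {
            pid: temporal_features.aggregate_stats(rec.streams[feature_set])
            for pid, rec in records_by_id.items()
        }

    return cache.get_or_build(key, build_stats) if cache else build_stats()


def run_feature_set_cv(
    records: list[ParticipantRecord],
    labels: dict[str, int],
    feature_set: str,
    family: str,
    plans: list[FoldPlan],
    seed_base: int = 42,
    audit: list[AuditEntry] | None = None,
    cache: FeatureCache | None = None,
    recompute_cutoffs_outcome: str | None = None,
    pad_to_tmax: bool = False,
    posterior: bool = False,
) -> list[FoldPredictions]:
    """Train and evaluate one (feature set, family) pipeline over all folds.

    For every fold: featurize with training-fold-fitted objects, fit the
    classifier on training participants (seed ``seed_base + run``), record
    the validation AUROC, and predict the test fold. Single-class training
    folds are skipped with a logged reason. When
    ``recompute_cutoffs_outcome`` names an outcome, its median-based
    cutoff is recomputed on each fold's training participants and the
    fold's labels are re-derived from it.
    """
    records_by_id = {r.participant_id: r for r in records}
    results = []
    for plan in plans:
        seed = seed_base + plan.run_index
        fold_labels = labels
        if recompute_cutoffs_outcome is not None:
            policy = outcomes.recompute_cutoffs(
                [records_by_id[pid] for pid in plan.train_ids]
            )
            fold_labels = {
                pid: outcomes.dichotomize(
                    rec.scores, policy, diagnosis=rec.attrs.diagnosis
                )[recompute_cutoffs_outcome]
                for pid, rec in records_by_id.items()
            }
        feats = participant_features(
            records_by_id, feature_set, plan, seed, audit, cache,
            pad_to_tmax, posterior,
        )
        X_tr = np.array([feats[p] for p in plan.train_ids])
        y_tr = np.array([fold_labels[p] for p in plan.train_ids])
        try:
            if family in model_zoo.SHALLOW_FAMILIES:
                model = model_zoo.train_shallow(family, X_tr, y_tr, seed)
            elif family == "MLP":
                model = model_zoo.train_static_mlp(X_tr, y_tr, seed)
            else:
                raise ValueError(
                    f"family {family!r} is not valid for aggregated features; "
                    "use run_sequence_cv for LSTM/TRANSFORMER"
                )
        except SingleClassFoldError as err:
            results.append(
                FoldPredictions(plan, plan.test_ids, np.array([]), np.array([]),
                                float("nan"), skipped=True, skip_reason=str(err))
            )
            continue
        if audit is not None:
            audit.append(AuditEntry(plan.run_index, plan.outer_fold,
                                    f"model:{family}:{feature_set}",
                                    tuple(sorted(plan.train_ids))))
        X_val = np.array([feats[p] for p in plan.val_ids])
        y_val = np.array([fold_labels[p] for p in plan.val_ids])
        val_proba = model.predict_proba(X_val)[:, 1]
        val_auc = _safe_auc(y_val, val_proba)
        X_te = np.array([feats[p] for p in plan.test_ids])
        proba = model.predict_proba(X_te)[:, 1]
        results.append(
            FoldPredictions(
                plan, plan.test_ids, proba, (proba > 0.5).astype(int), val_auc,
                val_ids=plan.val_ids, val_proba=val_proba,
            )
        )
    return results


def run_sequence_cv(
    records: list[ParticipantRecord],
    labels: dict[str, int],
    feature_set: str,
    family: str,
    plans: list[FoldPlan],
    seed_base: int = 42,
    target_len: int | None = None,
    audit: list[AuditEntry] | None = None,
) -> list[FoldPredictions]:
    """Sequence-model CV: streams uniformly resampled to the cohort's
    minimum native length (or ``target_len``), then LSTM/transformer."""
    records_by_id = {r.participant_id: r for r in records}
    n_min = min(r.streams[feature_set].n_frames for r in records)
    t_len = target_len or n_min
    seqs = {
        pid: temporal_features.uniform_resample(rec.streams[feature_set], t_len).values
        for pid, rec in records_by_id.items()
    }
    results = []
    for plan in plans:
        seed = seed_base + plan.run_index
        X_tr = np.stack([seqs[p] for p in plan.train_ids])
        y_tr = np.array([labels[p] for p in plan.train_ids])
        try:
            model = model_zoo.train_sequence_model(family, X_tr, y_tr, seed)
        except SingleClassFoldError as err:
            results.append(
                FoldPredictions(plan, plan.test_ids, np.array([]), np.array([]),
                                float("nan"), skipped=True, skip_reason=str(err))
            )
            continue
        if audit is not None:
            audit.append(AuditEntry(plan.run_index, plan.outer_fold,
                                    f"model:{family}:{feature_set}",
                                    tuple(sorted(plan.train_ids))))
        val_proba = model.predict_proba(
            np.stack([seqs[p] for p in plan.val_ids])
        )[:, 1]
        val_auc = _safe_auc([labels[p] for p in plan.val_ids], val_proba)
        proba = model.predict_proba(np.stack([seqs[p] for p in plan.test_ids]))[:, 1]
        results.append(
            FoldPredictions(plan, plan.test_ids, proba,
                            (proba > 0.5).astype(int), val_auc,
                            val_ids=plan.val_ids, val_proba=val_proba)
        )
    return results


def assert_no_leakage(audit: list[AuditEntry], plans: list[FoldPlan]) -> None:
    """Every fitted object must have seen only its fold's training ids."""
    by_fold = {(p.run_index, p.outer_fold): set(p.train_ids) for p in plans}
    for entry in audit:
        allowed = by_fold[(entry.run_index, entry.outer_fold)]
        leaked = set(entry.seen_ids) - allowed
        if leaked:
            raise AssertionError(
                f"{entry.object_kind} in run {entry.run_index} fold "
                f"{entry.outer_fold} saw non-training participants {sorted(leaked)}"
            )
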