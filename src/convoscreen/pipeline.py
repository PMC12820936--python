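"""End-to-end orchestration: cohort -> features -> CV -> fusion ->
modality importance -> fairness audit -> report tables.

``run_pipeline`` consumes a YAML configuration and writes a results
directory with five tables (per-pipeline metrics, task x feature-set
heatmap, modality importance, fairness report, and a manifest echoing
every toggle), all reproducible from the seeds it records.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv_engine, explain, fairness, fusion, model_zoo, outcomes
from .cv_engine import FeatureCache, FoldPlan, FoldPredictions
from .synthetic_cohort import CohortConfig, ParticipantRecord, generate_cohort, load_cohort

__all__ = [
    "run_pipeline",
    "per_set_results",
    "fused_results",
    "mmshap_for_pipeline",
    "fairness_for_predictions",
    "group_labels",
]

logger = logging.getLogger(__name__)

FAIRNESS_ATTRIBUTES = ("sex", "age", "yoe", "diagnosis")


def group_labels(records: list[ParticipantRecord], attribute: str) -> dict[str, str]:
    """Participant-id -> subgroup label for one sensitive attribute."""
    out = {}
    for r in records:
        if attribute == "sex":
            out[r.participant_id] = r.attrs.sex
        elif attribute == "age":
            out[r.participant_id] = r.attrs.age_group
        elif attribute == "yoe":
            out[r.participant_id] = r.attrs.yoe_group
        elif attribute == "diagnosis":
            out[r.participant_id] = r.attrs.diagnosis
        else:
            raise ValueError(f"unknown sensitive attribute {attribute!r}")
    return out


def per_set_results(
    records: list[ParticipantRecord],
    labels: dict[str, int],
    feature_sets: list[str],
    plans: list[FoldPlan],
    seed_base: int = 42,
    families: dict[str, str] | None = None,
    cache: FeatureCache | None = None,
    audit: list | None = None,
) -> dict[str, tuple[str, list[FoldPredictions]]]:
    """Per feature set: assigned shallow family and its fold predictions."""
    cache = cache if cache is not None else FeatureCache()
    out = {}
    records_by_id = {r.participant_id: r for r in records}
    for fs in feature_sets:
        if families and fs in families:
            family = families[fs]
        else:
            dim = _feature_dim(records_by_id, fs)
            family = model_zoo.assign_model(fs, dim)
        preds = cv_engine.run_feature_set_cv(
            records, labels, fs, family, plans,
            seed_base=seed_base, cache=cache, audit=audit,
        )
        out[fs] = (family, preds)
    return out


def _feature_dim(records_by_id, fs: str) -> int:
    sample = next(iter(records_by_id.values()))
    if fs.endswith("_hmm"):
        return 8
    if fs == "bpm":
        return 5
    if fs == "demographics":
        return 10  # order of magnitude only; pairing needs < / >= 100
    if fs in sample.static_vectors:
        return len(sample.static_vectors[fs])
    return 2 * sample.streams[fs].dim


def fused_results(
    per_set: dict[str, tuple[str, list[FoldPredictions]]],
    preset_sets: list[str],
    rule: str,
) -> list[FoldPredictions]:
    """Late-fused fold predictions for one preset and fusion rule."""
    sets = [s for s in preset_sets if s in per_set]
    if not sets:
        raise ValueError("preset selects no available feature sets")
    by_fold: dict[tuple[int, int], dict[str, FoldPredictions]] = {}
    for s in sets:
        for fp in per_set[s][1]:
            by_fold.setdefault((fp.plan.run_index, fp.plan.outer_fold), {})[s] = fp
    fused = []
    for key in sorted(by_fold):
        votes = {s: fp for s, fp in by_fold[key].items() if not fp.skipped}
        if not votes:
            any_fp = next(iter(by_fold[key].values()))
            fused.append(FoldPredictions(any_fp.plan, any_fp.plan.test_ids,
                                         np.array([]), np.array([]), float("nan"),
                                         skipped=True,
                                         skip_reason="all voters skipped"))
            continue
        plan = next(iter(votes.values())).plan
        proba_maps = {s: dict(zip(fp.test_ids, fp.proba)) for s, fp in votes.items()}
        val_aucs = {s: fp.val_auc for s, fp in votes.items()}
        fused_map = fusion.fuse_fold(proba_maps, val_aucs, rule)
        ids = tuple(sorted(fused_map))
        pred = np.array([fused_map[p][0] for p in ids])
        score = np.array([fused_map[p][1] for p in ids])
        # fused validation score: mean of voter validation AUCs
        finite = [a for a in val_aucs.values() if np.isfinite(a)]
        val = float(np.mean(finite)) if finite else float("nan")
        fused.append(FoldPredictions(plan, ids, score, pred, val))
    return fused


# ---------------------------------------------------------------------------
# modality importance for a fused pipeline
# ---------------------------------------------------------------------------

def mmshap_for_pipeline(
    records: list[ParticipantRecord],
    labels: dict[str, int],
    preset_sets: list[str],
    plans: list[FoldPlan],
    seed_base: int = 42,
    n_perm: int = 64,
    cache: FeatureCache | None = None,
    families: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    """Global modality importance of a late-fused pipeline.

    Per fold: per-set models are fitted on the training participants, the
    fused probability (average of per-set probabilities over their
    feature blocks) is explained on the concatenated test-fold features
    with the training-fold means as background, and the per-sample
    modality scores are averaged. Returns the overall mean, the modality
    names, and one per-plan mean for run-level stability checks.
    """
    cache = cache if cache is not None else FeatureCache()
    records_by_id = {r.participant_id: r for r in records}
    per_plan_means = []
    all_rows = []
    names = list(preset_sets)
    for plan in plans:
        seed = seed_base + plan.run_index
        feats = {
            fs: cv_engine.participant_features(
                records_by_id, fs, plan, seed, cache=cache
            )
            for fs in names
        }
        dims = {fs: len(next(iter(feats[fs].values()))) for fs in names}
        registry = explain.ModalityRegistry.from_dims(dims)
        y_tr = np.array([labels[p] for p in plan.train_ids])
        models, blocks = {}, registry.index_sets
        try:
            for fs in names:
                if families and fs in families:
                    family = families[fs]
                else:
                    family = model_zoo.assign_model(fs, dims[fs])
                X_tr = np.array([feats[fs][p] for p in plan.train_ids])
                models[fs] = model_zoo.train_shallow(family, X_tr, y_tr, seed)
        except model_zoo.SingleClassFoldError:
            continue

        def fused_proba(Xc, _models=models, _blocks=blocks):
            probs = [
                _models[fs].predict_proba(Xc[:, _blocks[fs]])[:, 1]
                for fs in _models
            ]
            return np.mean(probs, axis=0)

        concat = {
            pid: np.concatenate([feats[fs][pid] for fs in names])
            for pid in records_by_id
        }
        X_te = np.array([concat[p] for p in plan.test_ids])
        background = np.array([concat[p] for p in plan.train_ids]).mean(
            axis=0, keepdims=True
        )
        attribution = explain.shapley_values(
            fused_proba, X_te, background, n_perm=n_perm, seed=seed
        )
        imp = explain.mm_shap_per_sample(attribution, registry)
        rows = imp.s_per_sample[~np.isnan(imp.s_per_sample).any(axis=1)]
        if rows.size:
            per_plan_means.append(rows.mean(axis=0))
            all_rows.append(rows)
    if not all_rows:
        raise ValueError("modality importance undefined on every fold")
    overall = np.vstack(all_rows).mean(axis=0)
    return overall, names, per_plan_means


# ---------------------------------------------------------------------------
# fairness audit of a prediction set
# ---------------------------------------------------------------------------

def fairness_for_predictions(
    records: list[ParticipantRecord],
    fold_preds: list[FoldPredictions],
    labels: dict[str, int],
    attribute: str,
    mitigate: bool = True,
    seed_base: int = 42,
) -> fairness.FairnessReport:
    """Run-aggregated DPR/EOR (mean +/- 95% CI) for one attribute, with
    optional equalized-odds mitigation fitted per fold on the validation
    split and applied to the test fold."""
    groups = group_labels(records, attribute)
    by_run: dict[int, list[FoldPredictions]] = {}
    for fp in fold_preds:
        if not fp.skipped:
            by_run.setdefault(fp.plan.run_index, []).append(fp)
    dprs, eors, dprs_after, eors_after, f1b, f1a = [], [], [], [], [], []
    for r, fps in sorted(by_run.items()):
        y, pred, grp, score, pred_m = [], [], [], [], []
        for fp in fps:
            mitigated = None
            if mitigate and fp.val_proba is not None and len(fp.val_ids):
                try:
                    policy = fairness.fit_eo_thresholds(
                        fp.val_proba,
                        [labels[p] for p in fp.val_ids],
                        [groups[p] for p in fp.val_ids],
                    )
                    mitigated = fairness.apply_thresholds(
                        policy, fp.proba, [groups[p] for p in fp.test_ids],
                        seed=seed_base + r,
                    )
                except ValueError as err:
                    logger.info("mitigation skipped for run %d fold %d: %s",
                                r, fp.plan.outer_fold, err)
            for i, pid in enumerate(fp.test_ids):
                y.append(labels[pid])
                pred.append(int(fp.pred[i]))
                score.append(float(fp.proba[i]))
                grp.append(groups[pid])
                pred_m.append(int(mitigated[i]) if mitigated is not None
                              else int(fp.pred[i]))
        try:
            rates = fairness.group_rates(y, pred, grp)
            dpr_val = fairness.demographic_parity_ratio(rates)
            eor_val = fairness.equalized_odds_ratio(rates)
            dprs.append(dpr_val)
            eors.append(eor_val)
            if mitigate:
                rates_m = fairness.group_rates(y, pred_m, grp)
                dprs_after.append(fairness.demographic_parity_ratio(rates_m))
                eors_after.append(fairness.equalized_odds_ratio(rates_m))
                before, after = fairness.subgroup_f1_tradeoff(y, pred, pred_m, grp)
                f1b.append(before)
                f1a.append(after)
        except ValueError as err:
            logger.info("fairness run %d skipped: %s", r, err)
    if not dprs:
        raise ValueError(f"no run produced defined fairness ratios for {attribute}")

    def ci(vals):
        vals = np.asarray(vals)
        if len(vals) < 2:
            return 0.0
        return float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))

    report = fairness.FairnessReport(
        attribute=attribute,
        dpr=float(np.mean(dprs)),
        eor=float(np.mean(eors)),
        four_fifths_flag=bool(min(np.mean(dprs), np.mean(eors)) < fairness.FOUR_FIFTHS),
        rates=fairness.group_rates(
            [labels[p] for fp in fold_preds if not fp.skipped for p in fp.test_ids],
            [int(v) for fp in fold_preds if not fp.skipped for v in fp.pred],
            [groups[p] for fp in fold_preds if not fp.skipped for p in fp.test_ids],
        ),
        f1_before=float(np.mean(f1b)) if f1b else float("nan"),
        f1_after=float(np.mean(f1a)) if f1a else float("nan"),
        ci95={"dpr": ci(dprs), "eor": ci(eors)},
    )
    if dprs_after:
        report.ci95["dpr_after"] = ci(dprs_after)
        report.ci95["eor_after"] = ci(eors_after)
        report.ci95["dpr_after_mean"] = float(np.mean(dprs_after))
        report.ci95["eor_after_mean"] = float(np.mean(eors_after))
    return report


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def _load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run every configured stage and write the result tables.

    The config names the cohort (inline parameters or a directory), the
    outcome tasks, feature sets, fusion presets, fairness attributes,
    number of CV runs and base seed. Partial failures in one task are
    logged and the run continues.
    """
    t0 = time.time()
    cfg = _load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    if "cohort_dir" in cfg:
        records = load_cohort(cfg["cohort_dir"])
        cohort_cfg = None
    else:
        cc = dict(cfg.get("cohort", {}))
        if "length_range_min" in cc:
            cc["length_range_min"] = tuple(cc["length_range_min"])
        cohort_cfg = CohortConfig(**cc)
        records = generate_cohort(cohort_cfg)
    ids = [r.participant_id for r in records]

    tasks = cfg.get("tasks", ["CDR"])
    feature_sets = cfg.get("feature_sets")
    if feature_sets is None:
        sample = records[0]
        feature_sets = sorted(sample.streams) + sorted(sample.static_vectors)
        feature_sets += ["demographics"]
    n_runs = int(cfg.get("n_runs", 3))
    seed_base = int(cfg.get("seed_base", 42))
    presets = cfg.get("fusion_presets", {})
    if isinstance(presets, list):
        presets = {name: fusion.FUSION_PRESETS[name] for name in presets}
    rules = cfg.get("fusion_rules", ["majority", "average_probability", "selective"])
    attributes = cfg.get("fairness_attributes", list(FAIRNESS_ATTRIBUTES))
    mm_cfg = cfg.get("mmshap", {})
    families_override = cfg.get("families", {})

    plans = cv_engine.make_fold_plans(ids, n_runs=n_runs, seed_base=seed_base)
    all_labels = outcomes.labels_for_cohort(records)

    metric_rows, heat_rows, mm_rows, fair_rows = [], [], [], []
    for task in tasks:
        labels = {pid: lab[task] for pid, lab in all_labels.items()}
        cache = FeatureCache()
        try:
            per_set = per_set_results(
                records, labels, feature_sets, plans,
                seed_base=seed_base, families=families_override, cache=cache,
            )
        except Exception as err:  # keep other tasks running
            logger.error("task %s failed: %s", task, err)
            continue
        pipelines: dict[str, list[FoldPredictions]] = {}
        for fs, (family, preds) in per_set.items():
            pipelines[f"{fs}[{family}]"] = preds
            summaries = cv_engine.evaluate(preds, labels)
            for m, s in summaries.items():
                metric_rows.append(
                    dict(task=task, pipeline=fs, family=family, metric=m,
                         mean=s.mean, ci95=s.ci95_halfwidth, n_runs=s.n_runs)
                )
            heat_rows.append(
                dict(task=task, feature_set=fs, family=family,
                     auroc=summaries["AUROC"].mean)
            )
        for pname, sets in presets.items():
            for rule in rules:
                try:
                    fused = fused_results(per_set, sets, rule)
                    summaries = cv_engine.evaluate(fused, labels)
                except ValueError as err:
                    logger.error("fusion %s/%s on %s failed: %s",
                                 pname, rule, task, err)
                    continue
                label = f"fusion:{pname}:{rule}"
                pipelines[label] = fused
                for m, s in summaries.items():
                    metric_rows.append(
                        dict(task=task, pipeline=label, family="fusion",
                             metric=m, mean=s.mean, ci95=s.ci95_halfwidth,
                             n_runs=s.n_runs)
                    )
        if mm_cfg.get("enabled", bool(presets)):
            mm_sets = mm_cfg.get("feature_sets")
            targets = ([(n, s) for n, s in presets.items()]
                       if mm_sets is None else [("custom", mm_sets)])
            for pname, sets in targets:
                try:
                    overall, names, _ = mmshap_for_pipeline(
                        records, labels, sets,
                        plans[: int(mm_cfg.get("max_folds", 5))],
                        seed_base=seed_base,
                        n_perm=int(mm_cfg.get("n_perm", 64)),
                        cache=cache, families=families_override,
                    )
                    for name, val in zip(names, overall):
                        mm_rows.append(dict(task=task, pipeline=pname,
                                            modality=name, s_global=float(val)))
                except ValueError as err:
                    logger.error("MM-SHAP for %s on %s failed: %s",
                                 pname, task, err)
        audit_target = cfg.get("fairness_pipeline")
        if audit_target is None and presets:
            audit_target = f"fusion:{next(iter(presets))}:average_probability"
        if audit_target and audit_target in pipelines:
            for attribute in attributes:
                try:
                    rep = fairness_for_predictions(
                        records, pipelines[audit_target], labels, attribute,
                        mitigate=bool(cfg.get("mitigate", True)),
                        seed_base=seed_base,
                    )
                except ValueError as err:
                    logger.info("fairness audit %s/%s skipped: %s",
                                task, attribute, err)
                    continue
                fair_rows.append(
                    dict(task=task, pipeline=audit_target, attribute=attribute,
                         dpr=rep.dpr, eor=rep.eor,
                         four_fifths_flag=rep.four_fifths_flag,
                         dpr_ci95=rep.ci95.get("dpr", 0.0),
                         eor_ci95=rep.ci95.get("eor", 0.0),
                         dpr_after=rep.ci95.get("dpr_after_mean", float("nan")),
                         eor_after=rep.ci95.get("eor_after_mean", float("nan")),
                         f1_before=rep.f1_before, f1_after=rep.f1_after)
                )

    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    heat = pd.DataFrame(heat_rows)
    if not heat.empty:
        heat = heat.pivot_table(index="task", columns="feature_set",
                                values="auroc")
    heat.to_csv(out / "heatmap.csv")
    pd.DataFrame(mm_rows).to_csv(out / "mmshap.csv", index=False)
    pd.DataFrame(fair_rows).to_csv(out / "fairness_report.csv", index=False)
    manifest = {
        "config": cfg,
        "n_participants": len(ids),
        "n_runs": n_runs,
        "seed_base": seed_base,
        "tasks": list(tasks),
        "feature_sets": list(feature_sets),
        "decisions": {
            "hmm_fit": "native-length sequences (pad_to_tmax off)",
            "hmm_state_inference": "most-likely joint path",
            "hmm_frequency_unit": "state entries per 100 native frames",
            "quantile_interpolation": "linear",
            "bpm_band_hz": [0.65, 4.0],
            "per_run_metric": "mean over the five test folds' metrics "
                              "(pooled mode available)",
            "ci": "normal approximation, mean +/- 1.96 SE across runs",
            "auroc_ties": "counted 0.5 (rank definition)",
            "fusion_tie_break": "larger mean probability, then positive class",
            "selective_fallback": "all voters when none exceed 0.5",
            "eor_dpr_degenerate": "0/0 ratio = 1; defined-vs-zero = 0",
            "subgroup_f1": "positive-class F1 per subgroup, unweighted mean",
            "shap_background": "training-fold feature means",
            "scaling": "z-score inside LR/SVM pipelines, train-fold fitted",
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    if cohort_cfg is not None:
        manifest["cohort_seed"] = cohort_cfg.seed
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
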