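# convoscreen

Screening cognitive impairment and psychological well-being from
multimodal features of remote conversations.

Semi-structured video interviews with older adults carry behavioral
signal in several channels at once: facial expression and action-unit
dynamics, vocal acoustics, speech content and sentiment, and the heart
rate visible to remote photoplethysmography. `convoscreen` implements a
complete, testable analysis chain for per-participant multimodal feature
streams of this kind, aimed at methodologists who want to study the
*protocol* — temporal featurization, small-cohort evaluation, late
fusion, modality attribution, and fairness auditing — without access to
identifiable recordings. A synthetic cohort generator stands in for the
extracted features of a real cohort, with label-dependent temporal
structure so every downstream stage has recoverable ground truth.

## What it computes

- **Outcomes.** Eight binary targets from clinical and psychosocial
  assessments: CDR (0 vs 0.5), MoCA (>24 vs ⩽24), clinical diagnosis
  (1 = normal cognition, 0 = MCI), LSNS-6 social isolation (⩽12),
  neuroticism (median 16), and NIH Toolbox negative affect / social
  satisfaction / psychological well-being (medians 44.10 / 48.66 /
  53.70).
- **Temporal features.** Per-dimension mean and population SD; a
  four-state Gaussian HMM fitted jointly to all training participants
  (K-means init, 20 EM iterations), summarized per participant as state
  *durations* (occupancy fractions, summing to 1) and *frequencies*
  (state entries per 100 frames); heart-rate quantiles (5/25/50/75/95)
  from a windowed spectral BPM estimator (6-s windows, 1-s hop,
  0.65–4 Hz band); uniform resampling for sequence models.
- **Classifiers.** Logistic regression, gradient-boosted trees, RBF SVM,
  random forest with the published hyperparameters, plus an LSTM
  (hidden 128), a ViT-style transformer encoder (embed 128, 4 heads,
  2 layers, CLS token), and a 64-unit MLP — trained 10 epochs with
  cross-entropy. The table-based model–feature pairing (<100-dim → LR,
  ⩾100-dim → GBDT, with explicit overrides) is built in.
- **Evaluation.** 100-run participant-wise nested 5-fold
  cross-validation (64% / 16% / 20% train/val/test, run *r* seeded
  42 + *r*), AUROC / accuracy / macro-F1 with 95% CIs across runs.
- **Late fusion.** Majority voting, average-probability fusion, and
  selective voting (validation-AUROC > 0.5 gate).
- **MM-SHAP.** Per-sample Shapley values (exact enumeration ⩽10
  features, permutation sampling otherwise) collapsed to
  dimension-normalized modality scores
  s_m(x_i) = (|𝓕_m|⁻¹ Σ_{j∈𝓕_m} |φ_j(x_i)|) / Σ_{m′} (|𝓕_{m′}|⁻¹ Σ_j |φ_j(x_i)|),
  which sum to one per sample; global scores s̄_m average over samples.
- **Fairness.** Per-attribute selection/TPR/FPR rates, demographic
  parity ratio (min/max selection rate), equalized odds ratio (worse of
  the min/max TPR and FPR ratios), the four-fifths rule (0.8), and
  equalized-odds post-processing via group-specific randomized
  thresholds fitted on validation folds, with subgroup-averaged F1
  before/after.

## Worked example

```python
import numpy as np
from convoscreen import (CohortConfig, generate_cohort, outcomes,
                         cv_engine)

cfg = CohortConfig(n_participants=39, seed=0,
                   effect_size={"emotion_aus": 1.5},
                   modality_dims={"emotion_aus": 24})
records = generate_cohort(cfg)
labels = {pid: lab["MoCA"]
          for pid, lab in outcomes.labels_for_cohort(records).items()}
plans = cv_engine.make_fold_plans([r.participant_id for r in records],
                                  n_runs=5)
preds = cv_engine.run_feature_set_cv(records, labels, "emotion_aus_hmm",
                                     "LR", plans)
auroc = cv_engine.evaluate(preds, labels)["AUROC"]
print(f"AUROC {auroc.mean:.3f} +/- {auroc.ci95_halfwidth:.3f}")
```

```
AUROC 0.889 +/- 0.016
```

A severity effect of 1.5 on the facial emotion/AU stream is recovered by
the HMM-dynamics pathway well above chance even at N = 39; the CI is the
normal-approximation 95% interval across the five CV runs. The same
pipeline at N = 200 reaches AUROC ≈ 0.96, and with `effect_size=0.0`
the mean AUROC across independent cohorts is statistically
indistinguishable from 0.5.

The end-to-end pipeline is driven by a YAML config:

```bash
convoscreen simulate --config cohort.yaml --out cohort_dir
convoscreen run --config pipeline.yaml --out results/
```

`results/` then contains `metrics.csv` (task × pipeline × metric ± CI),
`heatmap.csv` (task × feature set AUROC), `mmshap.csv` (global modality
contributions), `fairness_report.csv` (DPR/EOR/flags and the F1
trade-off), and `manifest.yaml` recording every design toggle and seed.

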