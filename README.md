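# connectrl

Average controllability of resting-state functional brain networks: a
pipeline for turning ROI time series into per-region network-control
biomarkers, comparing two cohorts region by region, and evaluating the
discriminating regions with a cross-validated neural-network classifier.

## Who this is for

Researchers analyzing case/control resting-state fMRI studies at the
region-of-interest level (e.g. AAL-90 parcellations) who want to go beyond
network topology and ask a control-theoretic question: *how easily can
activity injected at each region steer the whole network between states,
and does that capacity differ between groups?* Because clinical cohorts
are rarely shareable, the package also ships a seeded synthetic-cohort
generator that emulates a two-group study design end to end, so every
stage is testable without patient data.

## The model

Each subject's brain is modeled as a discrete-time linear system
`x(t+1) = A x(t) + B u(t)`, where `A` is the subject's functional
connectivity (Pearson correlations between ROI time series, diagonal
zeroed) normalized to Schur stability by `A ← A / (1 + σ_max(A))`. For a
control input at region κ the controllability Gramian

    W_κ = Σ_{τ≥0} A^τ b_κ b_κᵀ (Aᵀ)^τ   (solves  W = A W Aᵀ + b_κ b_κᵀ)

is finite, and **average controllability** is `trace(W_κ)` — always ≥ 1,
larger for regions whose input spreads at low energy through the network.
Cohorts are compared per region with pooled-variance t-tests and
Mann–Whitney U, corrected across regions with Benjamini–Hochberg FDR; the
significant regions feed a six-hidden-layer ReLU/dropout(0.25)/sigmoid MLP
evaluated under stratified ten-fold cross-validation (confusion matrix,
sensitivity/specificity, ROC/AUC). See `docs/methods.md` for the full
account.

## Worked example

```python
from connectrl import (CohortConfig, generate_cohort, fc_for_cohort,
                       compare_groups, top_k, select_features, cross_validate)
from connectrl.pipeline import profiles_for_cohort

cfg = CohortConfig(seed=7)              # 130 + 156 subjects, 90 regions,
cohort = generate_cohort(cfg)           # 950 timepoints, 8 effect regions
profiles = profiles_for_cohort(fc_for_cohort(cohort))
table = compare_groups(profiles)

print(table.to_frame()[table.to_frame().ID.isin([33, 78, 90])])
print("top 5 decreased in group B:", top_k(table, 5, "decreased-in-B"))

cv = cross_validate(select_features(profiles, table), k=10, seed=7)
print(f"accuracy={cv.overall_accuracy:.3f} mean_auc={cv.mean_auc:.3f}")
```

prints (abridged):

```
 ID            Name  Ave_control_HC  Ave_control_MDD  HC-MDD     T
 33  Cingulum_Mid_L          1.0485           1.0381  0.0104  10.48
 78      Thalamus_R          1.0500           1.0379  0.0121  10.97
 90  Temporal_Inf_R          1.0538           1.0409  0.0128  11.76
top 5 decreased in group B: ['Paracentral_Lobule_R', 'Paracentral_Lobule_L',
                             'Temporal_Inf_R', 'Thalamus_R', 'Cingulum_Mid_L']
accuracy=0.962 mean_auc=0.992
```

Reading the output: `Ave_control_HC` / `Ave_control_MDD` are the group
means of average controllability per region (dimensionless, just above 1);
`HC-MDD` their difference — positive values mean the region's capacity to
steer network dynamics is *reduced* in the case-like group, exactly where
the generator injected dampened couplings (atlas IDs 33, 40, 59, 69, 70,
77, 78, 90). The classifier separates the synthetic groups far more
cleanly than real clinical data would; the generator's effect is noise-free
by comparison (see the methods note).

## Command line

Every stage is also a subcommand over plain TSV/JSON artifacts:

```bash
connectrl run-all  --config configs/default.yaml --output-dir run1 --seed 42
connectrl simulate --config configs/default.yaml   # cohort TSVs + manifest
connectrl fc       --manifest run1/cohort/cohort_manifest.tsv
connectrl control  --manifest run1/cohort/cohort_manifest.tsv
connectrl compare  --profiles run1/controllability_profiles.tsv
connectrl classify --profiles run1/controllability_profiles.tsv \
                   --table run1/comparison_table.tsv
```

Real data enter through the same manifest format (TSV with `subject_id`,
`group_label`, `path`), pointing either at timepoints × regions series or
at precomputed labeled correlation matrices. A single master seed makes
reruns byte-identical.

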