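# longconn

Longitudinal functional-connectivity classification for resting-state fMRI.

Cross-sectional classifiers see one snapshot of a subject's brain network
and are limited by between-subject variability — a globally low-connectivity
healthy brain looks like a progressed patient. Neurodegeneration, however,
is a trajectory: connectivity declines over time. `longconn` implements a
pipeline that exploits this, for researchers studying Alzheimer's disease
(AD) diagnosis and prediction of conversion from mild cognitive impairment
(MCI): it builds whole-brain functional connectomes per visit, augments
scarce labelled data with a GAN, and classifies each subject's
(baseline, 12-month, 24-month) sequence of connectomes with a residual
1D-CNN + three-layer LSTM, compared against single-visit CNN and linear SVM
baselines under subject-level 5-fold cross-validation.

## The model

Per visit, the connectome is the R x R matrix of Pearson correlations
between ROI-averaged BOLD signals,

    rho_ij = Cov(X_i, X_j) / (sigma_i sigma_j),

with unit diagonal, entries in [-1, 1], and motion QC excluding scans with
more than 50 frames of framewise displacement above 0.5 mm. The strict upper
triangle (length R(R-1)/2) is the feature vector. A convolutional encoder
with two short-connection (residual) links — shared across visits — maps
each vector to an embedding; a three-layer LSTM

    f_k = sigma(W_f [h_{k-1}, x_k] + b_f)        c_k = f_k o c_{k-1} + i_k o c~_k
    i_k = sigma(W_i [h_{k-1}, x_k] + b_i)        o_k = sigma(W_o [h_{k-1}, x_k] + b_o)
    c~_k = tanh(W_c [h_{k-1}, x_k] + b_c)        h_k = o_k o tanh(c_k)

fuses the three embeddings, and a sigmoid head yields the disease
probability. Per-class GANs on the same edge vectors enlarge training
folds; synthetic matrices are projected to validity and never leave the
fold that produced them. Metrics are pooled over folds: accuracy
(TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN), plus
ROC/AUC. Because multi-visit clinical cohorts are access-restricted, the
package includes a cohort simulator with known group structure (stable
controls, static disease effects, progressive per-visit connectivity loss,
subject-level confounds) so the whole pipeline is testable; see
`docs/methods.md` for the generative model and design choices.

## Worked example

Simulate a small strong-effect cohort and compare the three methods at the
24-month scope:

```python
from longconn.cohort import CohortSpec, simulate_cohort
from longconn.evaluate import run_comparison
from longconn.model import TrainConfig

spec = CohortSpec(roi_count=12, frames_per_scan=60,
                  group_sizes={"NC": 10, "AD": 10}, edge_effect=0.8,
                  affected_edge_fraction=0.5, subject_noise_sd=0.0, seed=7)
cohort = simulate_cohort(spec)
result = run_comparison(cohort, task="nc-ad", scope="24m", seed=1,
                        train_config=TrainConfig(epochs=20))
print(result.table[["method", "timepoint", "accuracy_pct",
                    "precision_pct", "recall_pct", "auc"]].to_string(index=False))
```

prints

```
    method timepoint  accuracy_pct  precision_pct  recall_pct  auc
svm-linear       24m         100.0          100.0       100.0  1.0
  cnn-only       24m         100.0          100.0       100.0  1.0
  cnn-lstm       24m          80.0          100.0        60.0  1.0
```

With 80% of the correlation removed on half the edges the problem is easy:
the SVM and the single-visit CNN separate the 20 subjects perfectly, and the
sequence model ranks perfectly (AUC 1.0) but, with only 16 training subjects
per fold and 20 epochs, its decision threshold is conservative (recall 60%).
At realistic cohort sizes (50–100 per group) the sequence model trains to
match and then beat the single-visit methods — that comparison is exactly
what `run_comparison` and the acceptance script measure.

The same pipeline runs from the shell:

```bash
longconn simulate --roi-count 20 --subjects-per-group 50 --seed 1 --out runs/cohort
longconn evaluate --manifest runs/cohort/manifest.tsv --task nc-ad --scope all \
    --out runs/eval
longconn run-all --config config.yaml        # everything from one document
```

`longconn fc` builds a connectome from a 4D NIfTI + label atlas (or a
pre-extracted series TSV) with motion QC; `longconn augment` and
`longconn train` expose the GAN and the classifier separately.

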