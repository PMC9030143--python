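# Methods

## Problem setting

`longconn` implements a longitudinal classification pipeline for resting-state
fMRI functional connectivity. Each subject contributes three scans — baseline
(BL), 12 months, 24 months. A scan is reduced upstream (slice timing,
realignment, normalisation, detrending, filtering, nuisance regression are
assumed done) to a T x R matrix of ROI-averaged BOLD signal; the pipeline
turns each scan into an R x R Pearson correlation matrix (the functional
connectome), augments scarce labelled training data with a per-class GAN, and
classifies the three-matrix sequence with a residual 1D-CNN spatial encoder
fused across visits by a three-layer LSTM. Two binary tasks are supported:
normal controls vs Alzheimer's disease (NC vs AD) and stable vs progressive
mild cognitive impairment (sMCI vs pMCI); the more-diseased label is the
positive class, so recall reads as sensitivity to disease.

## Connectome construction

Functional connectivity between regions i and j is the Pearson correlation
rho_ij = Cov(X_i, X_j) / (sigma_i sigma_j), computed with population
(divide-by-T) moments; the ratio is insensitive to the convention but
intermediate covariances follow it. The diagonal is assigned the constant 1
(never computed, avoiding 0/0 for constant signals); off-diagonal entries are
clamped to [-1, 1] after floating-point rounding; zero-variance columns yield
zero correlations with a warning rather than NaN propagation. Correlations
are fed to the classifier raw — no Fisher z-transform and no thresholding,
matching the choice to model the connectome as it is estimated.

Motion quality control follows the framewise-displacement rule: a scan is
excluded when more than `max_bad_frames` (default 50, i.e. 2.5 minutes at a
3 s frame period) frames exceed `fd_threshold` (default 0.5 mm). Both
inequalities are strict; both knobs are CLI-tunable because the underlying
convention is a reading of an ambiguous rule. When starting from raw 4D
images the first 10 frames are dropped (scanner equilibration); pre-cleaned
series default to dropping none.

## Synthetic cohort generator

Real multi-visit clinical imaging cohorts are access-restricted, so the
package ships a generator whose output has the statistical structure the
analysis assumes, making every downstream stage testable end to end.

Frames are drawn i.i.d. from a zero-mean multivariate normal whose covariance
is a valid correlation matrix; under a Gaussian model the Pearson connectome
is a sufficient description of dependence, so group structure enters only
through these generating matrices. Temporal autocorrelation is deliberately
absent: every stage of the pipeline treats frames exchangeably, so adding
BOLD-like smoothness would change effective sample size per scan but no
qualitative behaviour.

The base connectome is a low-rank factor model: Sigma = (s/k) Lambda Lambda'
+ (1-s) I with k = 4 random factors and shared variance s = 0.65, normalised
to unit diagonal. This yields mean absolute off-diagonal correlations around
0.2–0.25, the magnitude typical of ROI-level resting connectomes dominated by
a few large-scale networks — large enough that multiplicative disease effects
are visible.

Disease enters as shrinkage toward zero on a fixed random subset of edges
(`affected_edge_fraction` of all R(R-1)/2 edges, one subset per cohort so the
signal is learnable): affected groups (sMCI, pMCI, AD) lose `edge_effect` of
those correlations at every visit, and progressive groups (pMCI, AD)
additionally lose `t * progression_rate` at visit index t. The affected-edge
subset is shared by all affected groups, so within the MCI pair the static
effect cancels and separation is purely longitudinal — mirroring why
conversion prediction is the harder task. Perturbed matrices are projected
back to the nearest valid correlation matrix (eigenvalue clipping, diagonal
renormalisation, symmetrisation, clamping).

Each subject carries a stable "connectome fingerprint", drawn once and
applied identically at all three visits, with two components:

- an elementwise symmetric jitter of scale `subject_noise_sd`;
- a global connectivity scale: every edge is multiplied by (1 - c) with
  c ~ N(0, `subject_scale_sd`) clipped to ±0.6, emulating between-subject
  differences in global signal amplitude / vigilance.

The global scale is the scientifically important one: at a single visit a
globally low-connectivity healthy subject is indistinguishable from a
progressed patient, so cross-sectional classifiers are confound-limited,
whereas a model that sees the subject's own baseline can cancel the
fingerprint exactly. This is precisely the argument for longitudinal
modelling, built into the generator so the pipeline's comparison can measure
it.

`trajectory_only=True` removes the static disease effect, so all groups share
identical BL distributions and diverge only at 12/24 months through
`progression_rate` — the control condition for demonstrating that the
sequence model uses longitudinal information rather than a better
cross-sectional representation.

Defaults are desk-scale: R = 20 regions, T = 130 frames (a 140-frame scan
minus 10 dropped), 50 subjects per group — small enough that full 5-fold
comparisons train in minutes on one CPU while keeping the shape of the
original study design. Determinism: all draws derive from one seed via
spawned per-subject streams; identical spec, byte-identical output.

### Frozen study conditions used by the acceptance checks

- Null control: `edge_effect = 0`, R = 20, T = 130, 50/group — label
  exchangeability by construction; every method must stay inside the 95%
  binomial band around 50%.
- Strong effect: `edge_effect = 0.5`, `affected_edge_fraction = 0.3`,
  100/group (200 subjects).
- Trajectory-only: `progression_rate = 0.125`, `affected_edge_fraction = 1.0`
  (diffuse progressive loss), `subject_noise_sd = 0.05`,
  `subject_scale_sd = 0.3`, 50/group. Calibration pilots showed a linear-SVM
  oracle reaches ~0.70 cross-sectionally (confound-limited) vs ~0.90 with
  baseline reference, leaving the sequence model genuine longitudinal
  headroom; a large i.i.d. per-edge fingerprint was rejected during design
  because it degrades deep-model training wholesale rather than separating
  cross-sectional from longitudinal information.

What passing these checks shows — and does not show: the pipeline recovers
the kinds of structure the generator encodes (mean connectivity differences,
progressive diffuse loss, a low-rank between-subject confound) at desk scale.
Real rs-fMRI adds temporal autocorrelation, site and scanner effects,
registration error, heavy-tailed motion artifacts and heterogeneous disease
topography, none of which are emulated; synthetic performance numbers are
properties of the generator, not estimates of performance on clinical data.

## Classifier

Input representation. Each FC matrix is vectorised to its strict upper
triangle, row-major (length R(R-1)/2; 4005 at R = 90, 190 at R = 20),
dropping the redundant lower triangle and the constant diagonal.

Spatial encoder. A 1D CNN over the edge vector: three blocks of
(convolution, ReLU, max-pool), default channels (16, 32, 64), kernel 5
(same-length, zero-padded), pool 2, followed by global average pooling and a
linear map to a `feature_dim` = 64 embedding. Two short-connection modules
fuse early and late features: block 1's activation is 1x1-projected and
pooled onto block 3's input, and block 2's onto the final block output. The
two-link count is fixed by the architecture being reproduced; everything
else is configuration. The same encoder parameters are applied at every
visit (weight sharing), so per-visit embeddings live in one space and the
recurrent stage can compare them.

Temporal fuser. The three embeddings pass through a three-layer LSTM
(hidden size 64 per layer, dropout 0.2 between layers during training). The
cell is the standard gated recurrence

    f_k = sigma(W_f [h_{k-1}, x_k] + b_f)
    i_k = sigma(W_i [h_{k-1}, x_k] + b_i)
    c~_k = tanh(W_c [h_{k-1}, x_k] + b_c)
    c_k = f_k o c_{k-1} + i_k o c~_k
    o_k = sigma(W_o [h_{k-1}, x_k] + b_o)
    h_k = o_k o tanh(c_k)

and the top layer's final hidden state maps through a linear head and
sigmoid to one disease probability, thresholded at 0.5. Missing visits are
an error, not imputed — the design targets complete three-visit subjects.
A CNN-only comparator reuses the same encoder with the head attached
directly (no recurrence), consuming a single visit.

Training. Binary cross-entropy (numerically stable log-sum-exp form),
Adam (learning rate 1e-3, batch 16), global gradient-norm clipping at 5,
forget-gate biases initialised to 1, orthogonal initialisation of the
recurrent blocks and Glorot elsewhere — standard conditioning for stacked
LSTMs. The checkpoint kept is the epoch with the highest validation
accuracy, ties broken by lower validation loss: with the small validation
sets this pipeline sees (tens of subjects), the loss of an overconfident
model rises even while its decisions improve, so raw loss is a poor
selection criterion. Inputs are consumed as raw correlations; per-edge
standardisation was evaluated and rejected (it erases the informative
magnitude structure of the connectome and slowed learning measurably).
Everything is deterministic given the seed: initialisation, batch order and
dropout masks derive from it.

All tensor computation runs on a small reverse-mode automatic
differentiation engine written for this package (numpy arrays, float64),
covering dense affine maps, same-length 1D convolution (im2col), max
pooling, the gate nonlinearities, concatenation, dropout and the loss.
Analytic gradients of the composed model agree with central finite
differences to better than 1e-4 relative error on a small configuration;
the check randomises parameters first because with zero-initialised biases
whole pooling windows of ReLU zeros sit exactly on the kink, where one-sided
derivatives legitimately disagree with central differences.

## GAN augmentation

One generator/discriminator pair per class, operating on the upper-triangle
vector. The generator maps 32-dimensional Gaussian noise through two
64-unit ReLU layers to a tanh output (samples are born in [-1, 1]); the
discriminator is a 64/32-unit ReLU net with a logistic output. Training
uses the standard non-saturating losses, Adam with learning rate 2e-4 and
betas (0.5, 0.999), alternating one discriminator and one generator step per
minibatch. Generated vectors are rebuilt into matrices and projected to
validity (symmetrise, clip, unit diagonal); positive semi-definiteness is
deliberately not enforced because the classifier consumes raw entries and no
downstream step requires it. A non-finite loss aborts with the last stable
generator attached to the error.

For sequence training, one generator per (class, visit) is trained and the
three generators of a class are sampled with a shared noise stream, so the
k-th synthetic subject's visits align loosely; synthetic sequences lack the
true cross-visit fingerprint coupling and are used only to enlarge the
training set (default ratio 1:1, tunable). Every synthetic sample carries a
provenance tag; cross-validation asserts that synthetic data never leaves
the training fold that produced it.

## Evaluation

Stratified 5-fold cross-validation split by subject (all visits of a subject
share a fold), deterministic per seed. Within each training fold, 20% per
class is held out as the validation set for checkpoint selection. Headline
metrics are pooled (micro): confusion counts are summed over the five test
folds before computing accuracy, precision and recall (each x100 for
display); per-fold mean ± sd is reported alongside. Precision and recall are
reported as absent (with a warning) when their denominators vanish, never
as 0. ROC curves come from a threshold sweep over distinct scores (tied
scores grouped, so ties contribute diagonal segments); AUC is the trapezoid
integral and equals the Mann–Whitney pair-counting statistic with half
credit for ties.

The comparison harness runs linear SVM (C = 1.0, on the same edge vector),
CNN-only and CNN+LSTM. Single-visit methods consume the scope's latest
visit; the sequence model consumes the sequence up to the scope, truncating
the LSTM unroll to 1 or 2 steps for BL/12m scopes so the comparison table
has every visit row. Scope "all" produces one row per visit per method.

## Pipeline and reproducibility

`run_pipeline` executes simulate → FC → split/augment/train → evaluate from
one strictly validated config document (unknown keys rejected before any
stage runs). Per-stage seeds derive from the global seed by hashing the
stage name, so stages are individually reproducible; every artifact carries
the config hash. The run directory contains the cohort (manifest + series
TSVs + spec sidecar), the metrics table, per-epoch loss curves and ROC
points as delimited text, and a JSON run record with the fold assignment —
enough to re-create every curve without recomputation. Identical config and
seed reproduce byte-identical metrics tables.

## Known limitations

- The generator's frames are temporally white; estimated FC noise scales as
  1/sqrt(T) exactly, slightly optimistic for autocorrelated BOLD.
- Synthetic sequences from the GAN lack true cross-visit coupling.
- The desk-scale network (R = 20) is far smaller than a 90-region atlas;
  nothing in the code fixes R, but runtimes quoted here are for desk scale.
- The 3-layer LSTM needs moderate signal-to-noise to train from random
  initialisation at n = 100–200 subjects; with very weak or very confounded
  signals it degrades toward chance rather than recovering the linear-oracle
  solution, which is a property of the method at this scale, not a defect of
  the implementation.
- Sequence classification requires all three visits; subjects with missing
  visits must be excluded upstream.
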