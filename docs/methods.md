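# Methods

## Problem and scope

`deeppsy` implements a multimodal behavioral screening pipeline for
flagging boarding-school students at elevated mental-disorder (MD) risk
from routinely logged behavior: canteen consumption events, internet
session logs, course grades and insomnia-night indicators. The package
covers the whole chain — cohort simulation, preprocessing, feature
engineering, a five-algorithm tabular classifier bench, and the DeepPsy
CNN+LSTM+FCNN fusion model — together with paired experiment drivers
(baseline comparison, feature ablation, robustness sweeps).

Because no real cohort of this kind is publicly deposited, the package
ships a seeded synthetic-cohort simulator as a first-class, tested
component. Everything downstream is exercised on simulated cohorts; see
"What the simulator does and does not show" below.

## The synthetic cohort

The standard design is 210 students — 70 each in primary, junior and
senior levels, alternating gender — observed for 60 days. Each student
is independently MD with probability `md_prevalence` (default 0.3);
MD students receive an ordinal severity label (mild/moderate/severe,
default mix 0.5/0.3/0.2) that scales their channel shifts by 0.75/1.0/
1.25. Four channels carry planted signal, each controlled by a
standardized effect size `e` (default 1.0 per channel; `e = 0` makes MD
and non-MD students exchangeable on that channel):

| channel | generative form | MD shift |
|---|---|---|
| meals | Gaussian jitter around 07:30 / 12:00 / 18:00, SD 25 min; skip prob 0.05; uniform "stray" visit prob 0.03/day | SD ×(1+0.6e), skip +0.05e, stray +0.04e |
| internet sessions | Poisson(2)/day; start-time mixture of evening N(19:00, 150 min) and night N(02:00, 60 min) components; exponential durations ~55 min | night-component weight 0.04 + 0.10e |
| grades | 8 fixed courses; integer scores ~ N(75, 8) clipped to [50, 100] | mean −4e |
| insomnia | nights with net activity in 00:00–06:00, plus extra Binomial nights at rate 0.04 | extra-night rate +0.08e |

These forms were chosen for controllability: every downstream feature
responds monotonically to its effect size, which the test suite verifies
at n = 1000 over 10 seeds. All draws flow from one integer seed;
identical configurations are byte-identical. A corruption helper injects
duplicate/impossible consumption rows and blanks course credits at
chosen rates, recording ground truth so preprocessing can be tested
exactly.

The "strong planted effects" condition used by the signal-recovery and
direction-of-effect checks sets all four effect sizes to 2.0 — two
standard generative shifts per channel, i.e. a cohort where behavioral
signal is unambiguous — while the null condition sets all four to 0.

## Features

* **Grade point** `F = (score − 50)/10`; **course quality**
  `Q = credit × F`; **aggregate GPA** `F_avg = ΣQ / Σscore`. The
  score-sum denominator is implemented as the method's printed form;
  the conventional credit-sum denominator is available via
  `gpa_average(..., denominator="credit")`. With integer scores and
  credits the pipeline is exact to 1e-12 against rational arithmetic.
* **Dining distribution and entropy**: meal events are binned into
  breakfast 06:00–09:00, lunch 11:00–14:00, dinner 17:00–20:00 and a
  catch-all "other" bin; entropy is Shannon entropy in natural log
  (base only rescales; downstream models standardize inputs). A student
  with no events yields an empty-profile sentinel handled as entropy 0
  with median imputation downstream.
* **Dining clustering and anomaly score**: per-student descriptors
  (entropy, meals/day, fraction of canonical windows used) are
  standardized and clustered with k-means, k = 3 (good / poor / few
  dining regularity), Lloyd iterations with 10 restarts. The anomaly
  score is `M = D(x, c) × (1 − n_c/N)` with Euclidean distance in the
  standardized space: far-from-centroid students in small clusters
  score highest. `M` is scale-covariant (scaling coordinates by α scales
  M by α) and zero for a whole-cohort cluster.
* **Insomnia probability** `P = t/T`, insomnia nights over observed
  days. In simulation an insomnia night is any night with network
  activity intersecting 00:00–06:00 plus extra generated nights — the
  only behavioral operationalization the logged channels support.
* **Preprocessing**: duplicate and out-of-range consumption rows are
  dropped (first occurrence kept); missing credits are imputed with the
  cohort median for the course, which fails loudly if a course has no
  observed credit anywhere.

The assembled table has fixed column order: `gpa_avg, dining_entropy,
anomaly_score, insomnia_prob, sessions_per_day, night_session_frac`,
plus the binary label (MD = label ≠ none). The binary task is the
primary one — the screening claim is recall on the MD class — while a
4-class severity mode exists in the fusion model.

## The base CNN

Internet behavior is represented as weekly 7×24 day-by-hour grids of
fraction-of-hour online (minutes/60, clipped to [0, 1]). The base
feature extractor is a five-layer CNN: conv (4 kernels 3×3, valid) —
pool — conv (32 kernels 3×3, valid) — pool — fully connected (16).
Pooling is 2×2 mean pooling followed by a learnable per-channel scalar
scale and bias (the downsampling step is an affine map of the pooled
values passed through the activation); max pooling is available by
flag. Hidden activations are ReLU; the embedding output is linear.
Odd spatial dims are padded on the right/bottom, and mean pooling
averages only genuine cells. Kernel counts for this base network are
not externally constrained, so they default to the 4/32 used in the
fusion model. Initialization is uniform fan-in scaling from a fixed
seed.

The whole stack is implemented in numpy with manual backpropagation;
analytic gradients of every layer (conv valid/same, mean/max pool,
batchnorm in train mode, dense, LSTM, weighted softmax cross-entropy)
are validated against central finite differences at 1e-4.

## DeepPsy

The fusion model has two branches trained jointly:

* trajectory branch, applied to each weekly grid: conv(4, 3×3, same) →
  batchnorm → pool(2×2) → conv(32, 3×3, same) → batchnorm → pool(2×2)
  → fc(16) → dropout(0.5); the per-week 16-vectors are linearly
  projected to width 64 and consumed as a sequence (one timestep per
  simulated week, 8 weeks for the 60-day design) by a 4-unit LSTM.
  The projection reconciles the stated fc width (16) with the stated
  LSTM input width (64).
* basic branch: fc(8) → fc(4) on the standardized tabular features.

The branch outputs are concatenated (width 8), passed through a
4-neuron fusion layer (ReLU) and a final dense softmax head. With the
default binary output the head maps 4 → 2; in the 4-class severity mode
it maps 4 → 4. Same-padding keeps spatial dims unchanged through the
convolutions, batch normalization uses per-batch statistics in training
and running averages (momentum 0.9) at inference, and dropout is active
in training only.

Training: 60 epochs, Adam at learning rate 1e-3, batch size 4,
cross-entropy weighted inversely to class frequency (the screening task
is imbalanced and recall-oriented). Feature standardization is fitted
on the training split only. Epoch-level training loss/accuracy are
aggregated over the minibatch passes; validation metrics come from a
deterministic full pass. A fixed seed fixes initialization, batch order
and the dropout stream, making runs bit-reproducible on one platform.
"60 iterations" is read as 60 epochs, the scale on which the training
curves stabilize.

## Evaluation and experiments

Splits are stratified 60/20/20 train/validation/test (126/42/42 at
n = 210). The metric panel is accuracy, precision, recall, F1 and
Mann-Whitney (rank) AUC, all with respect to the MD class. The bench
tunes RF, Gaussian NB, GB, MLP and DT over small fixed grids on
validation F1 and selects the winner by validation F1 with a recall
tiebreak; RF and DT use balanced class weights. Note that balanced
class weighting deliberately trades accuracy for recall, so under pure
noise the weighted models sit *below* the majority-class accuracy; the
null test checks the one-sided bound (no model beats majority beyond
noise).

All experiment designs are paired: identical stratified splits per seed
across arms (verified by split hashes), medians over 10 seeds.

* **Comparison**: selected tabular classifier vs DeepPsy on identical
  splits; paired recall differences with a sign test.
* **Ablation**: four nested feature sets — 1: network + performance +
  consumption; 2: performance + consumption; 3: network + performance;
  4: performance only. The model is retrained per dataset (not
  input-masked); the trajectory branch is active only when the network
  channel is present, otherwise the model reduces to the basic branch.
  The insomnia and session summaries are assigned to the network
  channel since they derive from the internet logs.
* **Sweeps**: first-layer kernel count and batch size over {2, 4, 8,
  16, 32}, paired seeds; fluctuation = max − min of per-value medians.
* **Curves**: the stabilization epoch is the first epoch after which
  the training loss varies by less than 1% of its full range.

## Problem sizes

Default experiments use the standard 210-student design with 60-day
logs, 10 seeds per condition, chosen as the smallest replication that
gives stable medians for a stochastic trainer. Generator property tests
use n = 1000–2000 where distributional claims need power.

## What passing tests do and do not show

The simulator plants clean, monotone, independent channel effects with
Gaussian-ish noise and no confounding (no term-time structure, no
level/gender differences, no label noise, no missing channels beyond
the injected corruption). Recovering planted signal therefore shows the
pipeline is implemented correctly and can detect signal of the assumed
form — it says nothing about effect sizes, label quality or
generalization in real student populations, and none of these features
are claimed to measure clinical constructs. The headline metrics
reported on synthetic cohorts are properties of the simulation, not of
any real screening deployment.

## Numerical choices and degenerate inputs

* Entropy: 0·log 0 = 0; empty meal profile → sentinel, entropy 0 +
  imputation flag.
* k-means: sklearn Lloyd with `n_init=10`; the test suite checks the
  best-of-restarts SSE against exhaustive enumeration on 8-point
  instances (global optimum in ≥ 45/50, never below it).
* AUC: rank-based with average ranks, i.e. half credit for ties;
  undefined (NaN) for single-class labels.
* Selection ties: validation F1, then recall, then lexicographic name.
* Pooling of odd dims: right/bottom padding; mean over genuine cells.
* Non-finite training loss raises immediately with epoch/batch
  context.
* Single-class training or split data raise typed errors.

## Known limitations

* The generative forms are the package's own reconstruction of an
  undeposited data-collection design; alternative forms with the same
  monotone structure would be equally valid.
* The LSTM input projection (16 → 64) is a reconstruction where the
  stated widths do not compose.
* The anomaly-score weighting `1 − n_c/N` treats the cluster-size
  fraction as the down-weighting factor; other readings of the ratio
  are conceivable.
* CPU-only; the numpy trainer is intended for cohort-scale (hundreds
  of students) problems, not large-scale deployment.
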