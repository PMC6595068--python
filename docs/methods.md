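# Methods

This note documents the models, the simulator, and the design choices
behind `hfreadmit`, in the spirit of a statistical package's model
documentation.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cohort construction and labeling

Claims are integer-dated hospitalization records (day offsets within a
single observation window, 365 days by default); stays are disjoint
and ordered, with ties on admission day broken by discharge day and
then by input order.  A patient enters the cohort when they have at
least one hospitalization with heart failure (CCS diagnosis code 108)
as primary diagnosis, admitted early enough to allow a full 30-day
lookahead (admit day ≤ window end − 30, the analogue of restricting
index events to January–November in a calendar year), and were ≥ 18
years old.

Labels: y_t = 1 iff the next admission starts within 30 days of event
t's discharge, **inclusive** at exactly 30.  All events are labeled
with the same rule (the `Convex_HF_NonHF` loss needs non-HF labels);
a final event is labeled 0 only when ≥ 30 days of observation remain
after discharge, otherwise it is censored.  Timelines are truncated at
the last labelable HF event and patients without one are dropped, so
every retained timeline ends in the HF index event whose label the
models predict.  The test suite pins this labeler against an
independent all-later-events scan.

Deliberately out of scope: the transfer/same-day-stay/death
refinements of full administrative readmission measures — only the
30-day rule above is implemented.

## The synthetic claims generator

The generator is the study-conditions authority, emulating an
all-payer HF inpatient cohort: mean events per patient 1.9 (count
K ~ 1 + Poisson(0.9)), 67% HF-primary admissions, age ~ N(73, 14²)
clipped to [18, 100], 49% female, the six-category pay-source mix
dominated by Medicare (76.4%), length of stay 1 + Poisson(4) capped at
21 days, and a 23.6% 30-day readmission rate among HF events.

After each event a latent indicator r_t ~ Bernoulli(p_t) decides
whether the *next* admission follows within 30 days (gap uniform on
1..30) or later (uniform on 31..75):

    logit(p_t) = logit(base_readmit_rate)
               + beta_history · (z_prior_events + z_prior_readmits)
               + beta_event · (z_age, z_los, z_comorbidities)

History features are standardized with *theoretical* moments derived
from the configuration (Poisson moments for the prior-event count; a
compound-binomial approximation for the prior-readmission count), so
the mechanism is identical at any cohort size.  `beta_history` is one
scalar ≥ 0 — the single knob that makes the "does history help?"
question testable; `beta_event` adds event-level signal visible to
every model.

Two structural choices make the labeled rate calibrate exactly to the
base rate instead of being diluted by terminal events: (1) the
generator stores the drawn gap, never the label — labels are always
recomputed by the timeline module, keeping one source of truth for the
rule; (2) a *final* HF event with r = 1 materializes one non-HF
continuation admission inside 30 days (itself removed again by
truncation), so every retained HF event's label equals its Bernoulli
draw.  Long gaps are compressed to their 31-day minimum near the
window edge; when even that overruns, the sequence ends early.  The
real inter-admission gap distribution of claims data is unknown to us;
the uniform two-component mixture is a modelling choice, and gaps just
past the window edge are allowed (the window only censors terminal
labels).

What passing tests on this simulator do **not** show: robustness to
coding noise, transfers, mortality censoring, seasonal admission
patterns, or the long-tailed code vocabularies of real claims — the
generator's vocabularies are small and its gap mixture is stylized.

## Features

Per event: one-hot primary diagnosis, multi-hot secondary diagnoses,
procedures and comorbidity flags, one-hot sex and pay source (each
block with an explicit UNK slot for unseen codes), plus z-scored age
and length of stay.  Vocabularies and moments come from the training
fold only, slots ordered lexicographically; a constant training
feature gets unit SD with a log note.  An optional summary group
(z-scored prior-event and prior-HF counts) is appended **only** for
event-view models (MLP, LR) via a switch — this is how the logistic
baseline is granted history access for a fair face-off, and it is off
whenever the contrast under study is history-free event view vs
sequence view.  The event index in the timeline *is* the prior-event
count, so it lives in the summary group rather than among the base
numerics.  Sequences longer than `t_max` (default: 95th percentile of
training lengths, capped at 20) keep their most recent events.

Class imbalance: per-class weights N/(2·N_c), whose weighted class
frequency averages to 1.

## Objectives

Per-step loss is the weighted cross-entropy −w·log p̂(y_t).  The four
sequence aggregations (`LastHF`, `Uniform_HF`, `Convex_HF_lastHF`,
`Convex_HF_NonHF`) are all expressible as fixed per-step weight
vectors, which is exactly how both the reference implementation and
the training path compute them — one arithmetic, no drift.  Our
orientation of the convex weight: α multiplies the HF-average term,
so α = 1 recovers `Uniform_HF` and α = 0 recovers `LastHF`; α is a
validation-set hyperparameter (grid 0.1…0.9 in search spaces).  On an
all-HF timeline `Convex_HF_NonHF` degenerates to the HF average (so a
single-event timeline yields the last-HF loss for any α) rather than
scaling the loss by α — the alternative would silently down-weight
short timelines.  The total objective adds (λ/2)‖θ‖² over weight
matrices, biases excluded.

## Models

All neural families run on a small bundled reverse-mode autodiff
engine over numpy (validated end-to-end by finite-difference tests);
training is mini-batch gradient descent (plain SGD by default, Adam
optional), with global gradient-norm clipping (default 5.0), optional
inverted dropout, and best-epoch selection by validation AUC.

- **RNN** — GRU by default (LSTM by config) unrolled over the
  timeline, a softmax output per step; honours all four loss kinds.
- **RNNSS** — the RNN with scheduled sampling: the previous step's
  label, one-hot, is concatenated to the next input; it is the true
  label with probability ε (else sampled from the model), with linear,
  exponential or inverse-sigmoid decay of ε per epoch and a neutral
  (0.5, 0.5) start token.  The feedback weight rows are
  zero-initialized and the remaining parameters share the RNN's
  initialization stream, so at initialization RNNSS coincides exactly
  with the RNN; decoding feeds greedy predictions.
- **CRF families** — exact linear-chain inference in log space.
  `unary` variant: per-step unary scores plus one static 2×2
  transition matrix A.  `pairwise` variant: input-dependent per-step
  2×2 transition scores that replace A and subsume the unaries for
  t ≥ 2 (the first step keeps a unary term; this is the parsimonious
  reading of an input-dependent pairwise parameterization).  No
  start/stop boundary states.  `CRF_only` computes potentials
  affinely from raw features, `NeuralCRF` through one tanh hidden
  layer, `RNNCRF` from GRU features.  Training minimizes the NLL with
  the analytic gradient (expected minus observed sufficient
  statistics); each sequence is weighted by the class weight of its
  last-event label.  Prediction is the forward–backward marginal
  p(y_T = 1); Viterbi breaks ties toward label 0.
- **CNN** — the padded T_max × d timeline matrix through two 3×3
  convolution (same padding) + 2×2 max-pool blocks and a fully
  connected layer; last-HF loss only.
- **CNN-Wide** — full-width kernels of heights {2, 3, 5}, max-over-time
  pooling to one scalar per kernel, concatenation, one FC layer;
  last-HF loss only.
- **MLP** — tanh feed-forward net on the last event's features alone
  (event view); last-HF loss only.
- **LR** — penalized logistic regression (L1 or L2, liblinear via
  scikit-learn, tolerance 1e-6) on the last event, optionally with the
  summary features; coefficients feed the importance module.

Divergence (non-finite loss, parameters or validation predictions)
raises an error naming the epoch and step size.  Fitted models are
`ReadmissionResults` objects (parameters, history, `predict_proba`,
`summary()`); the package follows the configured-model / fitted-results
split throughout.

## Evaluation

Stratified 5-fold cross-validation on the last-HF label, each training
set donating a stratified 10% validation split; the schema, class
weights and all hyperparameter selection see training data only.
AUC is the normalized Mann–Whitney U (ties ½).  The cross-validated
AUC interval averages per-fold AUCs and estimates the variance from
per-observation influence functions computed within each test fold
(φ = (F₀(s) − θ)/p₁ for positives and (S₁(s) − θ)/p₀ for negatives),
pooled across folds — the cross-validated-AUC estimator; a
2,000-resample percentile bootstrap is the independent check, and the
suite verifies 92–98% empirical coverage on a binormal score model.
The Youden cutoff maximizes sensitivity + specificity − 1 on the
probability scale, ties to the smallest cutoff (for separated scores:
the smallest score above all negatives), reported as the across-fold
mean ± SD.  The AUC-by-timeline-length curve pools patients with
length ≤ L ("cumulative"; an == L mode is available by flag),
skipping single-class bins with a log note.

## Feature importance

LASSO coefficients are normalized by each fold's maximum absolute
coefficient and averaged across folds.  Perturbation importance
toggles one binary feature of the **last HF event only** on/off and
averages p(on) − p(off) over test patients (all of them); numeric
features are rejected, and alternative perturbation schemes can be
plugged in through the strategy hook.  Ranking agreement uses top-k
Jaccard overlap, computed separately for the increase and decrease
directions.

## Orchestration and reproducibility

Hyperparameter search is uniform random over a discrete space, trained
on a 90/10 split of a 30% subsample of one randomly chosen fold's
training set (default budget 20 trials per family), with a persisted
trial log.  One master seed drives everything; stage seeds are derived
by stable hashing of (master, stage, fold), so `run_study` reproduces
its comparison table bit for bit.

### Problem sizes

The packaged experiments run at desk scale: cohorts of 4,000–50,000
simulated patients, 6–8 training epochs, hidden sizes ~32.  The
acceptance script uses 20,000 patients for calibration, 4,000 for the
5-fold model comparison and 10,000 per arm for the history-signal
contrast; the test suite's history-separation check uses 20,000
patients and 3 seeds per arm.  These sizes give binomial/AUC noise
well inside the asserted margins while keeping a full run in minutes
on one CPU.

## Known limitations

- The simulator's gap mixture and small vocabularies understate the
  messiness of real claims; absolute AUCs here say nothing about
  real-data performance, only the *contrasts* (history vs no history,
  sequence vs event view) transfer as qualitative findings.
- Exact CRF inference is specific to the binary chain (|V| = 2);
  higher-order or large-label CRFs are out of scope.
- The numpy training loop is single-threaded; it is sized for the
  desk-scale cohorts above, not for millions of patients.
- Scheduled sampling decays ε per epoch (not per batch); with few
  epochs the practical difference from batch-level schedules is
  minor but nonzero.
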