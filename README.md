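# hfreadmit

Timeline-aware modelling of **30-day all-cause readmission after a
heart-failure (HF) hospitalization**, built on administrative claims.

Hospital claims lack the clinical depth of EHR data, but they carry a
patient's full *timeline* of hospitalizations — and a history of
repeated admissions is itself a readmission risk factor.  This package
implements the complete comparison pipeline for the question *"does
timeline history improve 30-day readmission prediction over the index
event alone?"*: a synthetic claims generator with a controllable
history-dependence, cohort construction and outcome labeling, a model
zoo spanning sequence labeling (RNNs, linear-chain CRFs and their
hybrids), sequence classification (CNNs) and event-view baselines
(MLP, penalized logistic regression), and a cross-validated AUC
evaluation harness.  It is aimed at methods researchers in clinical
risk prediction who need a fully reproducible, access-unrestricted
test bed with known ground truth.

## The problem and the models

Each patient contributes a temporally ordered sequence of
hospitalization events x̄₁ … x̄_T (x̄_t ∈ ℝᵈ encodes diagnoses,
procedures, comorbidities, demographics, length of stay).  Event *t*
is labeled y_t = 1 when the next admission occurs within 30 days of
its discharge (Δt ≤ 30, inclusive); timelines are truncated at the
last labelable HF event (CCS diagnosis 108), whose label is the
prediction target.

Training minimizes a class-weighted cross-entropy aggregated per
timeline in one of four ways — the loss of the last HF event
(`LastHF`), the uniform average over HF events (`Uniform_HF`), or a
convex combination (weight α) of the HF average with either the
last-HF loss or the non-HF average — plus an L2 penalty (λ/2)‖θ‖².
CRF-based models instead minimize the negative conditional
log-likelihood −log p(y | x) of the whole label sequence, with exact
forward–backward inference and Viterbi decoding over unary potentials
with a static 2×2 transition matrix, or input-dependent per-step
pairwise potentials.  Readmission risk is scored as the posterior
marginal p(y_T = 1 | x).

The synthetic generator draws, after every event, a latent readmission
indicator from Bernoulli(p_t) with

    logit(p_t) = logit(base rate) + β_hist · z(history) + β_event · z(event),

so the strength of history dependence is a single knob (β_hist = 0
gives a memoryless cohort) and the labeled readmission rate calibrates
exactly to the configured base rate (23.6% by default).

## Worked example

```python
from hfreadmit import (SimConfig, generate_claims, build_timelines,
                       cohort_summary, make_folds, evaluate_model_cv,
                       ModelConfig)
from hfreadmit.objectives import LossSpec

claims = generate_claims(SimConfig(n_patients=4000, beta_history=1.0,
                                   seed=7))
timelines = build_timelines(claims)
print(cohort_summary(timelines)[["n_patients", "hf_readmission_rate",
                                 "timeline_length_mean"]])

plan = make_folds([tl.last_label for tl in timelines], seed=7)
cfg = ModelConfig(family="RNN", loss=LossSpec("LastHF"), epochs=8,
                  optimizer="adam", lr=0.01, seed=7)
report = evaluate_model_cv(timelines, cfg, plan)
print(f"RNN CV-AUC {report.cv_auc:.3f} "
      f"(95% CI {report.ci_low:.3f}-{report.ci_high:.3f})")
```

Output:

```
n_patients              3279.000000
hf_readmission_rate        0.241771
timeline_length_mean       1.836536
dtype: float64
RNN CV-AUC 0.786 (95% CI 0.768-0.805)
```

A cohort of 4,000 simulated patients yields 3,279 analyzable
timelines whose labeled HF readmission rate (24.2%) sits at the
configured base rate plus history effects; the recurrent sequence
labeler reaches 0.786 cross-validated AUC on this history-driven
cohort, far above an event-view model without history access (~0.5
when β_event = 0 — the core "does history help?" contrast).

The same pipeline is scriptable from the shell:

```bash
hfreadmit simulate --out claims.csv --seed 7
hfreadmit build-timelines --claims claims.csv --out timelines.jsonl
hfreadmit run-study --config study.yaml --out-dir run/ --seed 7
```

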