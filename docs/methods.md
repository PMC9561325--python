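# Methods

## Model

The package predicts in-hospital mortality from a patient's ordered
admission records.  Inputs per visit t are the multi-hot diagnosis vector
x_t over the ICD-9 category vocabulary D, the multi-hot DRG vector p_t over
the DRG vocabulary L, the admission-type weight m_t ∈ {1, 2} (1 =
emergency/urgent, 2 = elective/newborn), and two day-valued gaps: Δ_{t−1:t}
from the previous discharge to the current admission, and Δ_{t:T} from the
current admission to the last discharge in scope.

Both code families pass through a ReLU embedding layer (dimension d = 32 by
default, matching the hidden sizes commonly used for this model family;
hidden state 64 for both recurrent branches).  Two independent Care-LSTMs
(unshared parameters) produce g_t for the visit-level branch and e_t for
the variable-level branch.  The Care-LSTM modifies only the three gates of
a standard LSTM: the input gate is scaled by 1/m_t, the forget gate
additionally receives P_f·P_{t−1} and Q_f·q_t with
q_t = [Δ/60, Δ/180, Δ/365], and the output gate receives P_o·P_t.  The
candidate cell keeps the standard form tanh(W_c X_t + U_c h_{t−1} + b_c):
the modification is deliberately confined to the gates, so that with
P = 0, Δ = 0, m = 1 the cell reduces exactly to the standard LSTM (this
reduction is a tested invariant).  The divisor of the third time scale is
365 (the set 60/180/365); the scales are configurable.  The previous
treatment embedding at the first visit is the zero vector, and the initial
(h, C) state is zero.

Attention and pooling: α is a softmax across the visits of the prefix
(a per-visit softmax of a scalar would be identically 1 and carry no
information); β_t = tanh(W_β e_t + b_β) is a d-vector in [−1,1];
r_t = 1/(m_t + ln(1+Δ)) ∈ (0,1]; w_t = r_t ⊙ (α_t + β_t)/2 with α
broadcast across d (the ablated variant uses w_t = r_t ⊙ α_t); and
h̄ = Σ w_t ⊙ X_t / Σ w_t elementwise.  Because β can be negative the
pooled denominator may cancel; its magnitude is floored at ε = 1e-8
(sign preserved, derivative treated as zero inside the floor).  The head
is a 2-unit linear layer with softmax over {discharged, death}.

**Prefix semantics.** The training loss indexes a label per visit, so the
model emits one risk per visit, computed from the prefix 1..i alone:
attention, harmonic weights, pooling and the head are applied to the first
i visits.  Δ_{t:T} inside r is therefore measured to the prefix's own last
discharge — this is what makes the prediction after visit i provably
independent of later visits (a tested invariant), and is why the encoded
sequence retains raw admission/discharge day offsets alongside the
full-sequence Δ_{t:T} vector.

## Training protocol

Loss: mean over patients of the per-patient mean over visit prefixes of
binary cross-entropy, plus L1 and L2 penalties (coefficient 1e-4 each) on
weight matrices, biases excluded.  Optimizer: Adadelta with decay ρ = 0.1
(as printed in the reference protocol, although unusually small for
Adadelta; configurable) and ε = 1e-6, with each update scaled by the
slanted triangular schedule η_t = η_max (1 + p(ratio−1))/ratio, p rising
linearly to 1 over the first cut = T·cut_frac iterations and falling
linearly back to 0 at T; defaults cut_frac = 0.1, ratio = 32,
η_max = 0.1, T = epochs × batches-per-epoch.  Batch size 80 patients;
default 100 epochs ("iterations" in the protocol is read as epochs, since
the schedule's T counts optimizer steps).  Inverted dropout with keep
probability 0.8 is applied to h̄ at train time (the protocol does not
localize the dropout; h̄ is the natural bottleneck).  Embeddings are
initialised by intra-visit skip-gram with negative sampling (the context
of a code is the other codes of the same visit; 5 negatives from a
unigram^0.75 noise distribution) and then fine-tuned end to end; purely
random initialisation is available via `pretrain_embeddings=False`.

Gradients are hand-derived reverse-mode passes through the whole graph
(embeddings, both recurrences, attention, pooling, head, regularizers) in
numpy; the test suite checks every parameter tensor against central finite
differences at 1e-4 relative tolerance, and both cells against scalar-loop
oracles at 1e-10.

Evaluation is patient-level: the score of a patient is the risk after
their final visit; confusion counts use threshold 0.5 (no threshold is
stated in the protocol); AUROC uses the rank (Mann–Whitney) formulation
with half-credit for ties, cross-checked against scikit-learn in a test.
Cross-validation is stratified by the death label and split at patient
level to avoid leakage across a patient's prefixes; fold summaries report
mean ± standard deviation over folds (labelled as sd).  "Hard positives"
are decedents misclassified in strictly more than half of their test
appearances across repeated cross-validation.

## Synthetic cohorts

The generator emulates the statistical shape of a cleaned ICU cohort:
visit counts from a geometric distribution truncated to [2, 10] with mean
2.57; ~13 distinct diagnosis codes per visit (Poisson, capped at 39) and
1–3 DRG codes (mean 2.23); four comorbidity blocks of 12 codes whose
members co-occur within a visit (within-block probability 0.75); 60%
emergency admissions; log-normal inter-visit gaps (μ = 3.0, σ = 1.2 days —
median ≈ 20 days with a long tail, exercising the three gate time scales)
and log-normal lengths of stay (μ = 1.6, σ = 0.6).  Death is Bernoulli at
the final visit with logit = baseline_logit + lethal_effect × k, where k
counts the distinct "lethal" codes (five codes inside the first block)
appearing anywhere in the patient's history.  Lethal codes are drawn only
as within-block codes — severe diagnoses occurring in the context of their
syndrome — which makes k nearly bimodal (0 vs 3–5).

The defaults were fixed by a design-time power calculation on the
mechanism itself (no model training involved): with baseline_logit = −4
and lethal_effect = 3 the death prevalence is ≈ 0.47 (close to the
balanced positive/negative ratio of the real cohorts this emulates) and
the Bayes-optimal AUC of the mechanism is ≈ 0.98, leaving headroom for a
trained model to demonstrate signal recovery; with lethal_effect = 0 and
baseline_logit = 0 the label is a fair coin independent of the record, so
any model's held-out AUC must concentrate at 0.5.  The signal-recovery
experiment uses n = 2000 patients, a 75/25 patient-level split and 20
epochs, averaged over 3 seeds — problem sizes chosen so the whole
experiment runs in minutes on one CPU while leaving the pass/fail margins
wide.  What these synthetic cohorts do **not** emulate: real ICD-9/DRG
semantics and frequencies (codes are abstract tokens), within-patient
disease progression (visits are exchangeable given the block draws),
seasonal/calendar structure, and censoring or transfers.  Passing tests
demonstrate that the implementation recovers a known generative signal and
honours its contracts — not clinical performance on real data.

## Data cleaning

Patients with fewer than 2 or more than 10 admissions are excluded; ICD-9
codes are truncated to their first 3 characters (configurable, since
interpretability case reports in this model family sometimes print
full-length codes); EMERGENCY/URGENT map to m = 1 and ELECTIVE/NEWBORN to
m = 2 (the smallest integers realising "emergency weighs more" under the
1/m_t gate scaling); day gaps are floors of elapsed time, with the first
visit's gap 0 and negative gaps (overlapping admissions) clamped to 0.
Two repairs are implied by the data model's invariants and applied before
the count filter: visits with no diagnosis codes are dropped (the model
has no input for them), and visits recorded after an in-hospital death are
truncated so death can only mark a final visit.  Vocabularies are
lexicographically ordered for determinism.  Out-of-vocabulary codes at
encoding time are dropped with a warning; a visit losing all its diagnosis
codes that way is an error naming the visit.

## Numerical and design notes

* Checkpoints are JSON text (named arrays + metadata): models are small
  and text round-trips are byte-stable, which the determinism contract
  (same seed ⇒ byte-identical checkpoint) relies on.
* The per-code interpretability report projects β_t back onto a visit's
  active codes as score(c) = β_t · W_xemb[:, c], normalized over the
  visit's codes — a reporting convention for reading the d-dimensional β
  at code granularity, not part of the model.
* Cross-entropy in the standalone loss utility clips predictions into
  [1e-7, 1−1e-7]; the training path computes the loss from logits and
  needs no clipping.
* At short training lengths the model's scores discriminate well (AUC)
  but stay compressed near 0.5, so threshold-based metrics lag; this is a
  calibration effect of the bounded pooled representation and the small
  effective learning rates early in the triangular schedule.
* Known limitations: no GPU path and no fused kernels (pure numpy); no
  reverse-time training (deliberately, following the model's design); no
  GRU/Bi-LSTM variants; the skip-gram is intra-visit only (no
  visit-sequence context window).
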