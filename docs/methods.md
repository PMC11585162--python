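# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `edewarn`, and what its synthetic experiments
do and do not establish.

## Problem setting

A visit to the emergency department produces two data modalities: a
triage snapshot (14 demographic/triage features plus a first vital-sign
panel) and an irregular stream of vital-sign measurements (systolic and
diastolic blood pressure, heart rate, oxygen saturation, body
temperature, respiratory rate). The outcomes of interest are cardiac
arrest (CA) and its resuscitated subset (CPR); CA is defined as the
union of CPR and death, and death-only visits correspond to patients
with do-not-resuscitate orders. Two prediction tasks follow: CA on the
full in-hospital cohort, and CPR on the cohort with death-only visits
removed. Visits with fewer than two measurement instances are excluded
from both (an "instance" is a distinct timestamp, which may carry any
subset of channels).

## Preprocessing

**Cleaning.** Raw values are strings. Unicode NFKC maps full-width
digits/punctuation to half-width; anything non-numeric becomes missing;
numeric values outside the physiologic validity interval are removed.
Intervals: SBP/DBP/HR [0, 300), SpO2 [0, 100], BT/RR [0, 50).

**Time anchoring.** T = ceil((t − anchor)/3600), computed exactly on
integer seconds (so t = anchor − 3600 gives T = −1, and anything within
the hour before the anchor lands in the T = 0 bin). The anchor is the
CPR execution time when one exists, else the last measurement time —
which means death-only visits are scored further from their true arrest
time, a known bias inherited from the data model. Measurements after
the CPR time are discarded: prediction precedes the event.

**Gridding.** One column per hour from the earliest index to 0; within
a bin the latest timestamp wins (most-recent-value semantics, consistent
with carry-forward); the triage panel enters as the earliest instance.
An observed-mask preserves provenance through imputation.

**Imputation.** Carry the most recent earlier value of the same channel
forward; cells with no earlier observation take the per-channel median.
Medians — and the per-feature modes used for tabular imputation — are
fitted on the *training partition only*. The source protocol pools "all
patients"; restricting to the training split is a deliberate deviation
to keep the test partition out of the statistics. Mode ties break
alphabetically.

**Tabular encoding.** Categorical features one-hot over the categories
seen in training (sorted); missing or unseen values map to the training
mode. Numeric features (age, pain index, GCS) pass through unscaled by
default — the model projects the vector into a fixed 32-wide feature
space anyway — with an optional z-scoring flag.

## Windows and augmentation

Window size W = 25 hours, right edge at T = −k, stride 1 h. A grid of
length L yields `true_length = min(W, L − k)` real columns; shorter
windows are zero-padded *after* the last real column, and every encoder
reads its output at `true_length − 1`, making the pad value irrelevant
(verified by property tests that perturb padding arbitrarily).

Training/validation augmentation emits shifts k = 0…min(S, L − W) for
event visits (S defaults to 13 for CA; CPR experiments sweep 0–8) and
k = 0 only for controls. Two readings of the shift rule are defensible
for 25 < L < 25 + S; this package only emits *fully unpadded* shifted
windows, refusing to manufacture truncated copies of long stays. At
inference, horizon k requires at least one originally observed column at
T ≤ −k — the weaker of the two plausible eligibility rules, chosen so
horizon 8 retains short-but-real histories.

## The model

Eight tokens of dimension 8 (1 tabular + 1 multivariate + 6 univariate):

- **Base encoder** — sequential-attention tabular encoder in the spirit
  of TabNet: input projected to 32 features; two decision steps, each a
  softmax attention mask over the features followed by a ReLU transform,
  summed; linear map to the token. Full TabNet (sparsemax, ghost batch
  norm, shared steps) is not reproduced — no deep-learning framework is
  available in this environment, so the network stack is a purpose-built
  numpy autodiff engine and the encoder keeps only the attentive
  feature-selection idea.
- **Multivariate encoder** — TCN: four residual blocks of dilated causal
  convolutions, kernel 3, dilations 1/2/4/8, width 32 (receptive field
  61 ≥ 25). Output read at `true_length − 1`, linear map to the token.
- **Univariate encoders** — six independent single-input GRUs, hidden
  size 16, advanced in lock-step for speed but sharing no weights;
  hidden state read at `true_length − 1`, per-channel linear map to the
  token. These give sparsely measured channels (SpO2 misses ~81% of
  instances) a representation uncontaminated by the others.
- **Interaction layer** — bare 4-head scaled dot-product self-attention
  over the 8 tokens (no residual/feed-forward sublayers; the sequence is
  short and a feed-forward head follows immediately). Attention weights
  are retained for interpretability.
- **Output head** — concatenated post-attention tokens → 64-unit ReLU
  layer (dropout 0.1 in training) → sigmoid. The probability is clamped
  to [1e−12, 1 − 1e−12] so the open-interval contract survives float64
  sigmoid saturation.

Raw vitals are normalised before the temporal encoders by fixed
physiologic centre/spread constants per channel (e.g. HR (85, 20),
BT (36.8, 0.8)) — not data-dependent, so inference needs no extra state.
Ablation flags remove any component; removing attention concatenates the
raw tokens.

Temporal-encoder hyperparameters, the token dimension of the temporal
branches, and the head architecture are package choices — the source
protocol fixes only the tabular encoder's 32-in/8-out dimensions, the
four attention heads, the loss, and the optimiser settings.

## Training and evaluation protocol

Adam, lr 1e−4, batch 64, early stopping after 80 epochs without
validation-AUPRC improvement; parameters restored from the best epoch.
Splits are 8:1:1, stratified on (stay ≤ / > 25 h) × the four
(CPR, dead) combinations; within a stratum of n, the test set takes
ceil(n/10), validation floor(n/10), training the rest (so a stratum of 5
splits 4/0/1 and the test side of a tiny stratum is never empty).
Validation is augmented like training (per the source protocol; this
inflates validation AUPRC — a documented caveat, and on easy synthetic
cohorts it saturates at 1.0 within a few epochs, so the selected
snapshot can be an early one). Ties in validation AUPRC do not count as
improvement.

AUROC uses tie-aware pairwise concordance (ties 0.5); AUPRC is
non-interpolated step area (average precision); both are delegated to
scikit-learn and cross-checked in the test suite against exhaustive
brute-force enumeration on all small instances. Binary metrics use the
threshold maximising F1 on validation scores, frozen before the test
partition is touched. Attention importance is the attention each token
receives, averaged over heads, query rows and (positive test) windows,
normalised to sum to 1.

## Rule-based baselines

EDICAS, MEWS and NEWS ship as editable YAML point tables validated on
load (known variables only, non-overlapping bands, positive points);
vitals are read from the carried-forward grid column at T = −k, tabular
items from triage, and a missing variable never fires. The EDICAS item
set is the published one, but its per-item weights could not be
recovered unambiguously from available renderings; the bundled weights
are defensible defaults, flagged in the file, and should be checked
against the original publication before any clinical use. MEWS/NEWS
follow the standard published charts; the NEWS supplemental-oxygen item
is omitted (no oxygen-therapy field in the schema) and AVPU is mapped
onto GCS.

## Synthetic cohorts

The generator emulates the data-generating setting the pipeline assumes:
log-normal stays (median 8 h, clipped 1 h–5 d), exponential
inter-instance gaps (mean 2 h, clipped 0.25–6 h), per-instance
per-channel missingness calibrated by a fixed point so realized rates
match the observed hospital rates (0.718–0.815) even after
all-channels-missing instances vanish, CPR prevalence 0.2% and
death-only 0.7% by default, and a deterioration ramp in event visits:
HR +2.0, RR +0.8, SBP −2.0, SpO2 −0.5 units/hour beginning 12 h before
the event anchor, values clamped to validity. The ramp is anchored to
the event, so short-stay patients arrive already partway into it —
deterioration does not politely wait for triage. Triage features carry
one weak planted association (ambulance arrival, odds ratio 3) so the
tabular branch has signal; other feature distributions are fixed,
arbitrary, and carry no outcome information.

What a green synthetic experiment establishes: the pipeline's plumbing
and contracts, and that the model recovers a planted, monotone,
event-anchored drift under realistic missingness and imbalance. What it
does not establish: performance on real patients, whose deterioration is
heterogeneous, nonlinear, confounded with treatment, and far harder than
a clean ramp — on these cohorts the rule-based scores are competitive
with the deep model, precisely because the planted signal is simple
threshold-crossing drift.

## Known limitations

- Death-only visits are anchored at their last measurement, not the
  unrecorded arrest time; their labels are systematically "late".
- The numpy network trains on one CPU; desk-scale experiments use a
  shortened Adam schedule (lr 1e−3, ~25 epochs) rather than the default
  lr 1e−4 / patience 80, which would take hours at these sizes.
- Early prediction (horizon 8) on short-stay synthetic cohorts is weak:
  most event visits simply lack 8+ hours of history, and the few that
  remain are dominated by carried-forward values.
- No model-based imputation, no transformer temporal encoder, no
  calibration analysis — all outside the design's scope.
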