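# Methods

`cardiofm` implements masked multimodal pretraining for cardiac sensing
signals at configurable scale, together with the downstream adaptation modes
used to evaluate such models. This note records the model, the synthetic
data it is exercised on, and the numerical and design choices a maintainer
would want to know.

## Input unification

A record is a C×T waveform over any non-empty subset of the 13 canonical
channels (12 ECG leads I, II, III, aVR, aVL, aVF, V1–V6, plus PPG), with an
optional free-text report. Lead II is the conventional single-lead channel
for wearable-style records.

**Signal tokens.** After preprocessing, each channel is cut into
non-overlapping windows of w = 0.1 s; with T samples per channel there are
N_S = ⌊T/w·fs⁻¹⌋ windows (trailing remainder dropped, never padded). Each
window is linearly projected to the model width d and receives two additive
learnable embeddings: a channel embedding indexed by the *canonical* channel
id, and a temporal embedding indexed by the window position. Indexing the
channel table canonically — rather than by position within the record — is
what makes the model channel-agnostic: lead II always uses the same
embedding row whether it arrives alone or inside a 12-lead record, and no
parameter anywhere depends on the channel subset.

**Text tokens.** Reports are lower-cased, split on whitespace/punctuation,
and encoded by a greedy longest-match WordPiece-style subword vocabulary
trained on the report corpus (default size 2,048; all single characters are
always included, so encoding is total). Sequences are right-truncated or
PAD-extended to exactly N_L = 64 ids. Each id embedding receives a shared
text-type embedding and a 1-D positional embedding.

**Unified sequence.** The model input is `[CLS; signal tokens]`, or
`[CLS; signal tokens; text tokens]` when a report is present. The CLS token
is a learnable vector whose encoder output `z_cls` serves as the global
record representation; it carries no positional embedding.

## Masked pretraining

75% of signal tokens and 50% of non-PAD text tokens are masked uniformly at
random without replacement, per record; masked counts are round-half-up of
r·n so the stated fractions are exact whenever r·n is integral. The CLS
token is never masked. PAD positions are excluded from masking, from the
encoder input and from the decoder sequence — they carry no information.

Only visible tokens enter the encoder (a pre-norm ViT-style transformer;
full bidirectional attention, GELU MLPs). The decoder receives the projected
visible outputs re-inserted at their sequence positions, a single shared
learnable mask token at every masked position, and decoder-width positional
embeddings re-added (channel + temporal for signal positions, 1-D positions
for text); two shallow transformer blocks and linear heads then predict the
patch vector at each masked signal position and vocabulary logits at each
masked text position.

Losses are computed at masked positions only:

* `L_S` — mean squared error over all patch elements at masked signal
  positions, computed on the z-scored signal (the preprocessing target);
  mean (not sum) reduction keeps the value comparable across channel counts.
* `L_L` — mean cross-entropy of the true token ids at masked text positions.
* `total = L_S + L_L` with unit weights; records without text contribute
  `L_S` alone.

The locality property — ground truth at visible positions does not enter
either term — is enforced structurally (the loss reads truth only at masked
indices) and audited by finite perturbation in the tests.

## Architecture presets

| preset | depth | width d | heads |
|--------|-------|---------|-------|
| tiny   | 4     | 128     | 4     |
| base   | 12    | 384     | 6     |
| large  | 24    | 768     | 12    |

All presets share an asymmetric decoder: depth 2, width 128, MLP ratio 2
(the decoder is deliberately lightweight; the encoder is what is kept for
downstream use). Every dimension is overridable through `EncoderConfig`.

## Preprocessing

Per channel: 4th-order zero-phase Butterworth band-pass (0.5–40 Hz for ECG,
0.4–10 Hz for PPG), then a per-record, per-channel z-score. Constant
channels cannot be z-scored and map to zeros with a warning; non-finite
samples are rejected. The default sampling rate is 100 Hz so one 0.1-s
patch is 10 samples; inputs at other rates are polyphase-resampled.
Per-record (rather than corpus-level) normalization was chosen because it
requires no fitted state and makes every record self-contained.

## Downstream adaptation

* **CLS classification / univariate regression.** A two-layer MLP on
  `z_cls`. Classification trains with the asymmetric focal loss
  (defaults gamma_pos = 0, gamma_neg = 4, probability margin clip = 0.05,
  following the loss's original defaults); multiclass tasks are cast as
  one-hot multilabel under this loss. With all hyperparameters zero the
  loss is exactly binary cross-entropy. Regression uses MSE.
* **Dense sequence-to-sequence regression.** Features are tapped from four
  evenly spaced encoder blocks (a 1-D adaptation of the dense-prediction
  transformer head). Per tap, signal-token features are reassembled on the
  time axis — features of different input channels at the same patch index
  are averaged — projected to a common width, fused deepest-first through
  residual 1-D convolution units, then upsampled from token resolution to
  sample resolution (nearest-neighbour repeat + convolution, ×2 then
  ×(patch_len/2)). Output length equals the input sample count exactly.
  Blood-pressure summaries are read off a predicted ABP window as
  SBP = max, DBP = min.
* **Frozen feature extraction.** `z_cls` embeddings with no parameter
  updates, consumed by shallow predictors (logistic regression / ridge in
  the CLI's `evaluate`).

## Training recipes

AdamW with betas (0.9, 0.95) and weight decay 5e-2 throughout; decay is
applied only to weight matrices — biases, LayerNorm affines, all embedding
tables and the CLS/mask tokens are exempt (decaying the weakly supervised
CLS token measurably degrades the global representation). Linear warmup
over an initial fraction of steps then cosine decay to zero; validation
every `eval_every` steps with the best checkpoint retained (never a worse
one than seen); uniform sampling over corpus sources per minibatch.
Pretraining uses LR 5e-4 (tiny preset).

Fine-tuning uses layer-wise decay 0.75: block k of D gets
base_lr·0.75^(D−k), the embedders sit one decay step below block 1, the
task head trains at the base rate. The decayed scales are built by
successive multiplication so the adjacent-block identity
lr_k = 0.75·lr_{k+1} holds exactly in floating point. Three further recipe
options matter in the low-label regime: `label_fraction` subsampling is
stratified by class; `head_warmup_frac` runs an initial
linear-probe phase (encoder frozen, head trained on frozen features)
before joint fine-tuning — gradients from a randomly initialized head
otherwise distort pretrained features in the first steps, which can
collapse small-label runs to near-chance; and classification checkpoints
are selected on validation macro-F1 rather than the surrogate loss, which
decouple at small label budgets.

The full reference recipe (25M steps, eval every 2,500, batch 256) is
expressible through `TrainConfig`; the shipped defaults are desk scale.

## Synthetic data

The generator emulates the *structure* of multimodal cardiac corpora with
exact ground truth, not physiological realism:

* **ECG**: per beat, five Gaussian bumps (P, Q, R, S, T at fixed offsets
  relative to the R peak); a fixed full-rank 12×5 lead-mixing matrix scales
  the bumps per lead, so inter-lead correlations are known and any lead is
  linearly informative about the others (making lead-to-lead reconstruction
  well-posed). Additive white noise (sd 0.05 of R amplitude) and sinusoidal
  baseline wander (amplitude 0.1, 0.3 Hz) by default.
* **Rhythm classes**: the regular class has RR = 60/HR with 2% Gaussian
  jitter; the irregular class draws RR from a gamma distribution with CV
  0.3 and has its P component zeroed (fibrillation-like). A 0.25-s
  refractory floor keeps beat times strictly increasing.
* **PPG**: an asymmetric fast-rise/slow-decay pulse per beat, delayed 0.2 s
  after the R peak.
* **ABP**: a second pulse train (0.25-s delay, with a small reflected
  component), affinely rescaled per record so the window max/min equal the
  drawn SBP/DBP exactly — extraction therefore recovers them exactly on
  noiseless records, and the z-scored ABP is a deterministic function of
  the beat schedule, making PPG→ABP dense regression well-posed.
* **Covariate**: an age-like value in [20, 80] that monotonically shifts
  heart rate (+0.3 bpm per year relative to 50) and scales the T-wave.
* **Reports**: templated sentences consistent with the class ("sinus …" vs
  "… fibrillation …"); 10% receive an unrelated distractor clause.

Defaults: 10-s records at 100 Hz, all 13 channels, balanced classes, HR
55–95 bpm, SBP 100–160 / DBP 60–90 mmHg. What passing tests on this
generator shows: the pipeline's mechanics (tokenization, masking, losses,
transfer, dense recovery) are correct and learnable signal is exploited.
What it does not show: performance on real ECG morphology, pathology
diversity, sensor artefacts or clinical text — no clinical claim follows.

## Study scales

The packaged studies (`cardiofm.experiments`, also recomputed by
`scripts/acceptance.py`) run the tiny preset with a 64-wide decoder on
500-record lead II + PPG corpora with reports (3-s records for
pretraining, 4-s for the rhythm task). The two coupled channels are the
smallest configuration in which masked reconstruction has genuine
cross-channel structure to learn — with a single lead, some seeds stall at
the predict-the-conditional-mean plateau. The studies: masked pretraining
for 2,000 steps at batch 8 over three seeds; rhythm-classification
fine-tuning at LR 3e-4 with 100% labels (direct fine-tuning) and 10%
labels (linear-probe-then-fine-tune, three seeds, against a from-scratch
control trained identically); dense PPG→ABP regression (200 records,
frozen encoder, 300 head-training steps). Validation `L_S` is tracked on a
held-out split with masks resampled from a fixed seed at every evaluation,
so successive evaluations are comparable. The studies run in float32 via
an explicit context; the package default stays float64.

## Numerical notes

* Tensor math runs on a small reverse-mode autodiff core written for this
  package (numpy-backed); float64 by default, float32 selectable through a
  context manager. Every non-trivial adjoint is checked against central
  finite differences in the tests.
* Ragged batches (records with different visible counts) are zero-padded
  and excluded from attention via an additive −1e9 bias; padded rows are
  never read back. A fused batched forward is used for training and is
  tested to agree with the per-record operations to 1e-10.
* Softmax and log-softmax are computed in shifted (max-subtracted) form.
* The asymmetric loss clamps probabilities with eps = 1e-12 inside logs;
  the BCE-equivalence contract holds to 1e-10.
* Checkpoints store config, vocabulary, all weights and metadata in a
  single `.npz` with a JSON header (schema-versioned).

## Known limitations

* The transformer is CPU-bound float64; the base/large presets are
  configurable but not practical to pretrain here.
* WFDB support covers the common format-16 single-`.dat` layout only.
* The text decoder predicts token ids at masked positions; it is not a
  generative language model.
* Uniform-source sampling treats all corpora equally regardless of size;
  size-proportional sampling is not implemented.
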