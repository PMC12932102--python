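# cardiofm

Masked multimodal pretraining for multichannel cardiac biosignals, at
configurable scale.

Continuous cardiac recordings arrive in wildly heterogeneous shapes: a
bedside monitor yields lead II and a PPG trace, a diagnostic cart yields 12
ECG leads plus a machine-generated report, a wearable yields a single lead.
`cardiofm` implements a channel-agnostic foundation-model workflow for this
setting: any subset of the 13 canonical channels (leads I, II, III, aVR,
aVL, aVF, V1–V6, and PPG) is tokenized into 0.1-s patch embeddings with
canonical channel and temporal embeddings, optional report text is appended
as WordPiece-style tokens, and a ViT-style encoder is pretrained by masked
reconstruction — 75% of signal tokens and 50% of text tokens are hidden and
a lightweight decoder must restore them, with losses computed only at the
hidden positions:

    L_S = ‖S_M − Ŝ_M‖²  (MSE over masked signal patches)
    L_L = −log p(L_M)    (cross-entropy over masked text ids)

The pretrained encoder's CLS output `z_cls` then serves three adaptation
modes: MLP classification/regression on `z_cls` (asymmetric focal loss /
MSE), dense sequence-to-sequence waveform regression through a 1-D
dense-prediction head tapping four encoder blocks (e.g. PPG → ABP, with
SBP/DBP read off as the window max/min), and frozen feature extraction for
shallow classifiers. Fine-tuning uses layer-wise learning-rate decay
(0.75 per block toward the input).

Because the intended pretraining corpora are clinical-scale, the package
ships a seeded synthetic generator (beat-structured multi-lead ECG with a
fixed lead-mixing matrix, coupled PPG/ABP with known SBP/DBP, regular vs
irregular rhythm classes, templated reports) so the entire pipeline is
testable end-to-end on one CPU. See `docs/methods.md` for the model and
generator details.

It is aimed at researchers prototyping biosignal self-supervision methods
and at teaching settings; it makes no clinical claims.

## Worked example

```bash
cardiofm synth --n 400 --seed 7 --duration 4 --channels II --out scratch/corpus
cardiofm pretrain --corpus scratch/corpus --preset tiny --steps 300 \
    --batch-size 8 --seed 7 --out scratch/pre
cardiofm finetune --checkpoint scratch/pre/checkpoint.npz \
    --corpus scratch/corpus --task rhythm --steps 300 --seed 7 --out scratch/ft
```

which prints (seed 7, a few minutes on one CPU core):

```
wrote 400 records to scratch/corpus
best validation loss 1.2524; checkpoint at scratch/pre/checkpoint.npz
{"auc": 0.9232736572890026, "macro_f1": 0.7953964194373402}
```

The pretraining loss is the total masked-reconstruction objective
`L_S + L_L` on held-out records (its starting value is ≈ 7–8 for an
untrained tiny model: ≈ 2 from signal patches plus ≈ ln V from text; 1.25
means most of both is being reconstructed). The fine-tune line reports held-out AUC
and macro-F1 for the binary rhythm task — the generator's classes are
separable from the waveform by construction, so accuracy rises toward 1.0
with the larger budgets used in `scripts/acceptance.py`. The same
workflow is available as library calls (`generate_corpus`,
`run_pretraining`, `run_finetune`, `run_dense_training`,
`extract_embeddings`); `cardiofm reconstruct --task abp` trains the dense
head and writes predicted waveforms, `cardiofm embed` / `evaluate` cover
the frozen-feature mode.

## Repository layout

```
src/cardiofm/
  autograd.py    float64 reverse-mode autodiff core
  nn.py          layers (attention, conv1d, ...), AdamW, LR schedule
  channels.py    canonical 13-channel set + alias table
  signals.py     SignalRecord, filtering/z-score, patch segmentation
  text.py        WordPiece-style vocabulary, fixed-length encoding
  model.py       unified sequence, masking, encoder/decoder, losses,
                 checkpoints
  heads.py       CLS heads, asymmetric loss, dense 1-D DPT head, SBP/DBP
  train.py       pretraining/fine-tuning loops, layer-wise LR, metrics
  synth.py       synthetic corpus generator with exact ground truth
  experiments.py desk-scale study recipes
  io.py          array-container + minimal WFDB (format 16) I/O
  cli.py         synth / pretrain / finetune / embed / reconstruct / evaluate
```
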