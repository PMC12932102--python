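"""Reproducible desk-scale studies exercising the full pipeline.

These recipes fix the study conditions used by the test suite and the
acceptance script: a 500-record lead II + PPG corpus with reports for
masked pretraining (tiny preset, 2,000 steps) — the two coupled channels
give the masked objective real cross-channel structure to learn —
rhythm-classification transfer with full and 10% label budgets over three
seeds, and dense PPG-to-ABP waveform regression.  Pretraining records are
3 s at 100 Hz, task records 4 s: long enough for several beats, small
enough that every study runs on one CPU core in minutes.  The study model
pairs the tiny encoder with a 64-wide decoder (the usual asymmetric
masked-autoencoder proportion for a 128-wide encoder).

All randomness is derived from a single base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import default_dtype
from .model import CSFM, EncoderConfig
from .synth import Corpus, GeneratorConfig, generate_corpus
from .text import Vocabulary, fit_vocabulary
from .train import (TaskSpec, TrainConfig, run_dense_training, run_finetune,
                    PretrainResult, run_pretraining)

RHYTHM_TASK = TaskSpec("binary", 2, lambda tr: tr.label)

PRETRAIN_N_RECORDS = 500
STUDY_DURATION = 3.0          # s per pretraining record
TASK_DURATION = 4.0           # s per rhythm-task record (a few more beats)
STUDY_CHANNELS = ("II", "PPG")   # cross-channel redundancy drives masked learning
PRETRAIN_STEPS = 2000
PRETRAIN_BATCH = 8
PRETRAIN_LR = 5e-4            # tiny-preset pretraining rate
FINETUNE_LR = 3e-4
FINETUNE_WARMUP = 0.1
DEC_WIDTH = 64                # MAE-proportional narrow decoder for d=128


def study_corpus(seed: int, n_records: int = PRETRAIN_N_RECORDS,
                 duration: float = STUDY_DURATION) -> Corpus:
    """Lead II + PPG corpus with paired reports."""
    return generate_corpus(GeneratorConfig(
        n_records=n_records, duration=duration, channels=STUDY_CHANNELS,
        seed=seed))


def build_model(vocab: Vocabulary, seed: int) -> CSFM:
    cfg = EncoderConfig.from_preset("tiny", vocab_size=vocab.size,
                                    dec_d=DEC_WIDTH)
    return CSFM(cfg, seed=seed)


@dataclass
class PretrainStudy:
    corpus: Corpus
    vocab: Vocabulary
    results: list          # PretrainResult per seed
    seeds: list

    def val_ls_ratios(self) -> list[float]:
        """Best validation L_S relative to its pre-training value, per seed."""
        out = []
        for res in self.results:
            curve = res.history["val_L_S"]
            out.append(min(curve) / curve[0])
        return out


def run_pretrain_study(base_seed: int, n_seeds: int = 3,
                       steps: int = PRETRAIN_STEPS) -> PretrainStudy:
    """Masked multimodal pretraining of the tiny preset, repeated over seeds.

    Studies run in float32 (the package default is float64): training is
    GEMM-bound and single precision is ample for SGD-style optimization.
    """
    corpus = study_corpus(base_seed)
    vocab = fit_vocabulary([tr.report for tr in corpus.truths])
    seeds = [base_seed + k for k in range(n_seeds)]
    results = []
    with default_dtype(np.float32):
        for s in seeds:
            model = build_model(vocab, seed=s)
            cfg = TrainConfig(base_lr=PRETRAIN_LR, batch_size=PRETRAIN_BATCH,
                              max_steps=steps, eval_every=max(1, steps // 4),
                              patience=8, seed=s, val_cap=16)
            results.append(run_pretraining([corpus], model, vocab, cfg))
    return PretrainStudy(corpus, vocab, results, seeds)


@dataclass
class TransferStudy:
    full_metrics: dict
    pretrained_10pct: list      # macro-F1 per seed
    scratch_10pct: list


def run_transfer_study(study: PretrainStudy, base_seed: int) -> TransferStudy:
    """Rhythm-classification transfer from the seed-0 pretrained checkpoint.

    Full-label fine-tuning once; 10%-label fine-tuning over three seeds for
    the pretrained-init and random-init arms.  Both arms share the recipe
    (AdamW, layer-wise decay 0.75, warmup).
    """
    corpus = study_corpus(base_seed + 101, duration=TASK_DURATION)
    pretrained_state = study.results[0].model.state_dict()

    def pretrained_model() -> CSFM:
        model = build_model(study.vocab, seed=base_seed)
        model.load_state_dict(pretrained_state)
        return model

    with default_dtype(np.float32):
        # full-label arm: direct fine-tuning; the linear-probe phase is
        # reserved for the label-scarce arms where random-head gradients
        # distort pretrained features the most
        full_cfg = TrainConfig(base_lr=FINETUNE_LR, batch_size=PRETRAIN_BATCH,
                               max_steps=600, eval_every=25, patience=30,
                               warmup_frac=FINETUNE_WARMUP, seed=base_seed)
        full = run_finetune(pretrained_model(), corpus, RHYTHM_TASK, full_cfg)

        pretrained_f1, scratch_f1 = [], []
        for k in range(3):
            s = base_seed + k
            cfg10 = TrainConfig(base_lr=FINETUNE_LR, batch_size=PRETRAIN_BATCH,
                                max_steps=400, eval_every=25, patience=30,
                                warmup_frac=FINETUNE_WARMUP,
                                head_warmup_frac=0.2, seed=s,
                                label_fraction=0.10)
            res_p = run_finetune(pretrained_model(), corpus, RHYTHM_TASK, cfg10)
            res_s = run_finetune(build_model(study.vocab, seed=s + 100), corpus,
                                 RHYTHM_TASK, cfg10)
            pretrained_f1.append(res_p.metrics["macro_f1"])
            scratch_f1.append(res_s.metrics["macro_f1"])
    return TransferStudy(full.metrics, pretrained_f1, scratch_f1)


def zscore_abp_target(rec, tr) -> np.ndarray:
    z = (tr.abp - tr.abp.mean()) / tr.abp.std()
    return z[None, :]


def run_dense_study(study: PretrainStudy, base_seed: int) -> dict:
    """PPG -> ABP dense waveform regression with the pretrained encoder."""
    corpus = generate_corpus(GeneratorConfig(
        n_records=200, duration=STUDY_DURATION, channels=("PPG",),
        with_text=False, seed=base_seed + 7))
    with default_dtype(np.float32):
        model = build_model(study.vocab, seed=base_seed)
        model.load_state_dict(study.results[0].model.state_dict())
        cfg = TrainConfig(base_lr=1e-3, batch_size=PRETRAIN_BATCH, max_steps=300,
                          eval_every=100, patience=8, seed=base_seed)
        result = run_dense_training(model, corpus, ["PPG"], zscore_abp_target, 1,
                                    cfg)
    return result.metrics


def sbp_dbp_recovery(seed: int, n_records: int = 20) -> float:
    """Max absolute SBP/DBP extraction error (mmHg) on noiseless records."""
    from .heads import sbp_dbp_from_abp
    corpus = generate_corpus(GeneratorConfig(
        n_records=n_records, duration=STUDY_DURATION, channels=("PPG",),
        noise_sd=0.0, wander_amp=0.0, with_text=False, seed=seed))
    err = 0.0
    for tr in corpus.truths:
        bp = sbp_dbp_from_abp(tr.abp)
        err = max(err, abs(bp.sbp - tr.sbp), abs(bp.dbp - tr.dbp))
    return err


__all__ = [
    "PretrainStudy", "TransferStudy", "run_pretrain_study",
    "run_transfer_study", "run_dense_study", "sbp_dbp_recovery",
    "study_corpus", "build_model", "zscore_abp_target", "RHYTHM_TASK",
    "PRETRAIN_STEPS", "STUDY_DURATION", "PRETRAIN_N_RECORDS",
]
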