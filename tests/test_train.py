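"""Training engine: LR schedules, pretraining loop, fine-tuning, metrics."""

import numpy as np
import pytest

from cardiofm.model import CSFM, EncoderConfig
from cardiofm.nn import warmup_cosine_lr
from cardiofm.synth import GeneratorConfig, generate_corpus
from cardiofm.text import fit_vocabulary
from cardiofm.train import (TaskSpec, TrainConfig, compute_metrics,
                            extract_embeddings, layerwise_lr_groups,
                            run_finetune, run_pretraining)


def micro_train_model(depth=2, seed=0):
    return CSFM(EncoderConfig(depth=depth, d=32, heads=2, dec_depth=1,
                              dec_d=32, dec_heads=2, n_l=16, vocab_size=64,
                              n_s_max=120), seed=seed)


@pytest.fixture(scope="module")
def train_corpus():
    corpus = generate_corpus(GeneratorConfig(
        n_records=80, duration=2.0, channels=("II",), seed=50))
    _, _, te = corpus.split()
    assert len(np.unique(corpus.labels[te])) == 2   # AUC well defined
    return corpus


class TestLayerwiseLR:
    def test_reference_geometric_sequence(self):
        model = CSFM(EncoderConfig(depth=4, d=32, heads=2, dec_d=32,
                                   vocab_size=16, n_l=8), seed=0)
        groups = layerwise_lr_groups(model, None, 1e-4, 0.75)
        block_lrs = [g["lr"] for g in groups if g["name"].startswith("block")]
        np.testing.assert_allclose(block_lrs,
                                   [4.21875e-5, 5.625e-5, 7.5e-5, 1e-4])
        assert groups[-1]["lr"] == 1e-4          # head at base rate

    @pytest.mark.parametrize("depth", [2, 3, 4, 6])
    def test_adjacent_ratio_exactly_decay(self, depth):
        model = micro_train_model(depth=depth)
        groups = layerwise_lr_groups(model, None, 3e-4, 0.75)
        lrs = [g["lr"] for g in groups if g["name"].startswith("block")]
        for a, b in zip(lrs[:-1], lrs[1:]):
            assert a / b == pytest.approx(0.75, abs=1e-15)

    def test_decay_one_gives_equal_rates(self):
        model = micro_train_model()
        groups = layerwise_lr_groups(model, None, 1e-3, 1.0)
        assert len({g["lr"] for g in groups}) == 1

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError):
            layerwise_lr_groups(micro_train_model(), None, 1e-3, 0.0)


class TestSchedule:
    def test_warmup_and_final_endpoints(self):
        base, steps = 1e-3, 1000
        warm_end = int(0.05 * steps)
        assert warmup_cosine_lr(warm_end - 1, steps, base) == pytest.approx(base)
        assert warmup_cosine_lr(steps - 1, steps, base) < 1e-5 * base
        # warmup is linear
        assert warmup_cosine_lr(24, steps, base) == pytest.approx(base / 2)

    def test_cosine_is_monotone_after_warmup(self):
        lrs = [warmup_cosine_lr(s, 200, 1e-3) for s in range(10, 200)]
        assert all(a >= b for a, b in zip(lrs[:-1], lrs[1:]))


class TestPretrainingLoop:
    def test_seeded_runs_are_bit_identical(self, train_corpus):
        vocab = fit_vocabulary([tr.report for tr in train_corpus.truths], 64)
        cfg = TrainConfig(base_lr=5e-4, batch_size=4, max_steps=12,
                          eval_every=6, patience=10, seed=3, val_cap=4)
        r1 = run_pretraining([train_corpus], micro_train_model(seed=1), vocab, cfg)
        r2 = run_pretraining([train_corpus], micro_train_model(seed=1), vocab, cfg)
        assert r1.history["train_loss"] == r2.history["train_loss"]
        assert r1.history["val_total"] == r2.history["val_total"]

    def test_uniform_source_sampling(self, train_corpus):
        second = generate_corpus(GeneratorConfig(
            n_records=80, duration=2.0, channels=("II",), seed=51))
        third = generate_corpus(GeneratorConfig(
            n_records=80, duration=2.0, channels=("II",), seed=52))
        vocab = fit_vocabulary([tr.report for tr in train_corpus.truths], 64)
        cfg = TrainConfig(base_lr=5e-4, batch_size=2, max_steps=180,
                          eval_every=1000, patience=10, seed=4, val_cap=2)
        res = run_pretraining([train_corpus, second, third],
                              micro_train_model(seed=2), vocab, cfg)
        counts = np.bincount(res.history["source_choices"], minlength=3)
        expected, sd = 60, np.sqrt(180 * (1 / 3) * (2 / 3))
        assert (np.abs(counts - expected) <= 3 * sd).all()

    def test_best_checkpoint_not_worse_than_any_eval(self, train_corpus):
        vocab = fit_vocabulary([tr.report for tr in train_corpus.truths], 64)
        cfg = TrainConfig(base_lr=5e-4, batch_size=4, max_steps=20,
                          eval_every=5, patience=10, seed=5, val_cap=4)
        res = run_pretraining([train_corpus], micro_train_model(seed=3),
                              vocab, cfg)
        assert res.best_val <= min(res.history["val_total"]) + 1e-12

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_pretraining([], micro_train_model(), None, TrainConfig())


class TestFinetuneAndEmbeddings:
    def test_finetune_runs_and_reports_metrics(self, train_corpus):
        cfg = TrainConfig(base_lr=1e-4, batch_size=4, max_steps=10,
                          eval_every=5, patience=10, seed=6)
        res = run_finetune(micro_train_model(seed=4), train_corpus,
                           TaskSpec("binary", 2, lambda tr: tr.label), cfg)
        assert set(res.metrics) == {"auc", "macro_f1"}
        assert 0.0 <= res.metrics["auc"] <= 1.0

    def test_twelve_lead_checkpoint_finetunes_on_single_lead(self):
        # channel-agnostic transfer: same weights, different channel subset
        twelve = generate_corpus(GeneratorConfig(
            n_records=24, duration=2.0,
            channels=tuple(c for c in GeneratorConfig().channels
                           if c != "PPG"), seed=53))
        single = generate_corpus(GeneratorConfig(
            n_records=24, duration=2.0, channels=("II",), seed=54))
        model = micro_train_model(seed=5)
        cfg = TrainConfig(base_lr=1e-4, batch_size=4, max_steps=4,
                          eval_every=2, patience=10, seed=7)
        res12 = run_finetune(model, twelve,
                             TaskSpec("multiclass", 2, lambda tr: tr.label), cfg)
        res1 = run_finetune(res12.model, single,
                            TaskSpec("multiclass", 2, lambda tr: tr.label), cfg)
        assert 0.0 <= res1.metrics["macro_f1"] <= 1.0

    def test_regression_task_reports_mae_r2(self, train_corpus):
        cfg = TrainConfig(base_lr=1e-4, batch_size=4, max_steps=6,
                          eval_every=3, patience=10, seed=8)
        res = run_finetune(micro_train_model(seed=6), train_corpus,
                           TaskSpec("regression", 1, lambda tr: tr.age), cfg)
        assert res.metrics["mae"] >= 0.0

    def test_embeddings_deterministic_and_gradient_free(self, train_corpus):
        model = micro_train_model(seed=7)
        records = train_corpus.records[:4]
        e1 = extract_embeddings(model, records)
        e2 = extract_embeddings(model, records)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (4, model.cfg.d)
        assert all(p.grad is None for p in model.parameters())


class TestMetrics:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 1, 0])
        scores = np.array([[0.9, 0.1], [0.1, 0.9], [0.2, 0.8], [0.8, 0.2]])
        m = compute_metrics(scores, labels, "binary")
        assert m["auc"] == 1.0 and m["macro_f1"] == 1.0
        r = compute_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                            "regression")
        assert r["mae"] == 0.0 and r["r2"] == 1.0

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 5000)
        scores = rng.random(10_000)
        m = compute_metrics(scores, labels, "binary")
        assert abs(m["auc"] - 0.5) < 0.02

    def test_toy_contingency_macro_f1(self):
        # per class: TP=1, FP=1, FN=1, TN=1  ->  F1 = 0.5 each class
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.1, 0.9], [0.9, 0.1], [0.1, 0.9]])
        m = compute_metrics(scores, labels, "multiclass")
        assert m["macro_f1"] == 0.5

    def test_single_class_auc_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(np.array([0.2, 0.4]), np.array([1, 1]), "binary")

    def test_multilabel_macro_f1(self):
        labels = np.array([[1, 0], [0, 1], [1, 1]])
        scores = np.array([[0.9, 0.2], [0.1, 0.8], [0.7, 0.9]])
        m = compute_metrics(scores, labels, "multilabel")
        assert m["macro_f1"] == 1.0
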