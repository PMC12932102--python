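"""Encoder/decoder forward contracts and the masked reconstruction losses."""

import numpy as np
import pytest

from cardiofm.model import (CSFM, MaskPlan, pretrain_forward,
                            pretrain_forward_reference, pretraining_loss,
                            sample_mask_plan, full_visibility_plan,
                            save_checkpoint, load_checkpoint, EncoderConfig,
                            PRESETS)
from cardiofm.signals import SignalRecord, segment_signal
from cardiofm.text import TextTokenIds


def patches_for(model, names, n_samples=300, seed=0):
    vals = np.random.default_rng(seed).standard_normal((len(names), n_samples))
    return segment_signal(SignalRecord(vals, list(names), 100.0),
                          model.cfg.patch_seconds)


def text_ids(n_nonpad, n_l=16, seed=3):
    ids = np.zeros(n_l, dtype=np.int64)
    ids[:n_nonpad] = np.random.default_rng(seed).integers(3, 60, n_nonpad)
    return TextTokenIds(ids, np.arange(n_l) >= n_nonpad)


@pytest.fixture
def seq_and_plan(micro_model):
    seq = micro_model.assemble_input(
        patches_for(micro_model, ["II", "PPG"]), text_ids(8))
    plan = sample_mask_plan(seq, 0.75, 0.5, np.random.default_rng(0))
    return seq, plan


class TestEncoder:
    def test_permuting_visible_tokens_preserves_z_cls(self, micro_model,
                                                      seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        rng = np.random.default_rng(5)
        perm = np.concatenate([[0], 1 + rng.permutation(len(plan.visible_idx) - 1)])
        plan2 = MaskPlan(plan.masked_signal_idx, plan.masked_text_idx,
                         plan.visible_idx[perm], plan.r_signal, plan.r_text)
        enc2 = micro_model.encode(seq, plan2)
        np.testing.assert_allclose(enc.z_cls.numpy(), enc2.z_cls.numpy(),
                                   atol=1e-10)

    def test_same_weights_encode_any_channel_subset(self, micro_model):
        widths = set()
        for names in (["II"], ["PPG"], ["I", "aVR", "V6"],
                      ["I", "II", "III", "aVR", "aVL", "aVF",
                       "V1", "V2", "V3", "V4", "V5", "V6", "PPG"]):
            seq = micro_model.assemble_input(patches_for(micro_model, names))
            enc = micro_model.encode(seq, full_visibility_plan(seq))
            assert np.isfinite(enc.z_cls.numpy()).all()
            widths.add(enc.z_cls.shape[0])
        assert widths == {micro_model.cfg.d}

    def test_single_visible_token_is_finite(self, micro_model):
        seq = micro_model.assemble_input(
            patches_for(micro_model, ["II"], n_samples=200))  # 20 tokens
        plan = sample_mask_plan(seq, 0.95, 0.0, np.random.default_rng(0))
        assert plan.n_masked_signal == 19
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        losses = pretraining_loss(out, seq, plan)
        assert np.isfinite(losses["total"].item())

    def test_modality_views(self, micro_model, seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        n_sig_vis = len(seq.signal_positions) - plan.n_masked_signal
        assert enc.z_signal().shape[0] == n_sig_vis
        assert enc.z_text().shape[0] == 8 - plan.n_masked_text


class TestDecoder:
    def test_reconstruction_count_matches_mask(self, micro_model, seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        assert out.pred_patches.shape == (plan.n_masked_signal,
                                          micro_model.cfg.patch_len)
        assert out.text_logits.shape == (plan.n_masked_text,
                                         micro_model.cfg.vocab_size)

    def test_plan_mismatch_rejected(self, micro_model, seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        other = sample_mask_plan(seq, 0.75, 0.5, np.random.default_rng(123))
        with pytest.raises(ValueError, match="plan"):
            micro_model.reconstruct(enc, other)

    def test_same_channel_different_time_decoder_inputs_differ(self, micro_model):
        seq = micro_model.assemble_input(
            patches_for(micro_model, ["II"], n_samples=300))
        # mask two identical-content positions at different times
        vals = np.tile(np.arange(10.0), 30)[None, :]
        seq = micro_model.assemble_input(
            segment_signal(SignalRecord(vals, ["II"], 100.0), 0.1))
        plan = MaskPlan(np.array([3, 17]), np.array([], dtype=np.int64),
                        np.array([p for p in range(seq.length)
                                  if p not in (3, 17)]), 0.0, 0.0)
        enc = micro_model.encode(seq, plan)
        x, local = micro_model._decoder_inputs(seq, plan, enc.tokens)
        rows = x.numpy()[local[[3, 17]]]
        assert np.abs(rows[0] - rows[1]).max() > 1e-8

    def test_untrained_model_loss_is_finite(self, micro_model, seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        losses = pretraining_loss(out, seq, plan)
        for key in ("L_S", "L_L", "total"):
            assert np.isfinite(losses[key].item())


class TestLosses:
    def test_masked_only_locality_signal_and_text(self, micro_model,
                                                  seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        base = pretraining_loss(out, seq, plan)
        rng = np.random.default_rng(7)
        sig_pos = seq.signal_positions
        visible_sig = np.setdiff1d(sig_pos, plan.masked_signal_idx)
        for p in rng.choice(visible_sig, size=10, replace=False):
            row = np.nonzero(sig_pos == p)[0][0]
            seq.truth_patches[row] += rng.standard_normal(
                micro_model.cfg.patch_len)
        txt_pos = seq.text_positions[~seq.is_pad[seq.text_positions]]
        visible_txt = np.setdiff1d(txt_pos, plan.masked_text_idx)
        for p in visible_txt:
            seq.text_ids[seq.time_idx[p]] = (seq.text_ids[seq.time_idx[p]] + 1) % 60
        after = pretraining_loss(out, seq, plan)
        assert after["L_S"].item() == base["L_S"].item()
        assert after["L_L"].item() == base["L_L"].item()

    def test_vectorized_losses_match_explicit_loops(self, micro_model,
                                                    seq_and_plan):
        seq, plan = seq_and_plan
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        losses = pretraining_loss(out, seq, plan)
        # brute-force loop oracle
        sig_pos = list(seq.signal_positions)
        total, n = 0.0, 0
        for i, p in enumerate(plan.masked_signal_idx):
            truth = seq.truth_patches[sig_pos.index(p)]
            pred = out.pred_patches.numpy()[i]
            for e in range(len(truth)):
                total += (truth[e] - pred[e]) ** 2
                n += 1
        l_s_loop = total / n
        ll_total = 0.0
        for i, p in enumerate(plan.masked_text_idx):
            row = out.text_logits.numpy()[i]
            row = row - row.max()
            logp = row - np.log(np.exp(row).sum())
            ll_total -= logp[seq.text_ids[seq.time_idx[p]]]
        l_l_loop = ll_total / plan.n_masked_text
        assert abs(losses["L_S"].item() - l_s_loop) <= 1e-10 * abs(l_s_loop)
        assert abs(losses["L_L"].item() - l_l_loop) <= 1e-10 * abs(l_l_loop)

    def test_perfect_reconstruction_gives_zero_loss(self, micro_model,
                                                    seq_and_plan):
        from cardiofm.model import ReconstructionOutput, signal_token_rows
        from cardiofm.autograd import Tensor
        seq, plan = seq_and_plan
        rows = signal_token_rows(seq, plan.masked_signal_idx)
        ids = seq.text_ids[seq.time_idx[plan.masked_text_idx]]
        logits = np.full((plan.n_masked_text, micro_model.cfg.vocab_size), -1e4)
        logits[np.arange(len(ids)), ids] = 1e4
        out = ReconstructionOutput(Tensor(seq.truth_patches[rows].copy()),
                                   Tensor(logits))
        losses = pretraining_loss(out, seq, plan)
        assert losses["L_S"].item() == 0.0
        assert losses["L_L"].item() < 1e-12

    def test_empty_masked_sets_rejected(self, micro_model):
        seq = micro_model.assemble_input(
            patches_for(micro_model, ["II"], n_samples=200))
        plan = full_visibility_plan(seq)
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        with pytest.raises(ValueError, match="nothing to reconstruct"):
            pretraining_loss(out, seq, plan)

    def test_missing_text_total_is_signal_loss(self, micro_model):
        seq = micro_model.assemble_input(
            patches_for(micro_model, ["II"], n_samples=200))
        plan = sample_mask_plan(seq, 0.75, 0.5, np.random.default_rng(0))
        enc = micro_model.encode(seq, plan)
        out = micro_model.reconstruct(enc, plan)
        losses = pretraining_loss(out, seq, plan)
        assert "L_L" not in losses
        assert losses["total"].item() == losses["L_S"].item()


class TestFusedPath:
    def test_fused_batch_matches_modular_path(self, micro_model,
                                              tokenized_items):
        from cardiofm.model import sequence_layout
        items = tokenized_items[:6]
        layouts = [sequence_layout(p, t) for p, t in items]
        rng = np.random.default_rng(11)
        plans = [sample_mask_plan(l, 0.75, 0.5, rng) for l in layouts]
        fused = pretrain_forward(micro_model, items, None, plans=plans)
        ref = pretrain_forward_reference(micro_model, items, None, plans=plans)
        for key in ("L_S", "L_L", "total"):
            a, b = fused[key].item(), ref[key].item()
            assert abs(a - b) <= 1e-10 * max(1.0, abs(b))

    def test_encode_uniform_matches_per_record_path(self, micro_model):
        from cardiofm.model import encode_uniform
        ps = [patches_for(micro_model, ["II", "PPG"], seed=s) for s in range(3)]
        x, _ = encode_uniform(micro_model, ps)
        for i, p in enumerate(ps):
            seq = micro_model.assemble_input(p)
            enc = micro_model.encode(seq, full_visibility_plan(seq))
            np.testing.assert_allclose(x.numpy()[i], enc.tokens.numpy(),
                                       atol=1e-10)


class TestConfigAndCheckpoint:
    def test_preset_table(self):
        assert set(PRESETS) == {"tiny", "base", "large"}
        cfg = EncoderConfig.from_preset("tiny")
        assert (cfg.depth, cfg.d, cfg.heads) == (4, 128, 4)
        with pytest.raises(ValueError, match="preset"):
            EncoderConfig.from_preset("huge")

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(d=100, heads=3)
        with pytest.raises(ValueError, match="decoder"):
            EncoderConfig(d=64, heads=2, dec_d=128)

    def test_checkpoint_roundtrip_preserves_outputs(self, micro_model,
                                                    small_vocab, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, micro_model, small_vocab, extra={"step": 5})
        model2, vocab2, extra = load_checkpoint(path)
        assert extra["step"] == 5
        assert vocab2.token_to_id == small_vocab.token_to_id
        ps = patches_for(micro_model, ["II"], n_samples=200)
        seq1 = micro_model.assemble_input(ps)
        seq2 = model2.assemble_input(ps)
        e1 = micro_model.encode(seq1, full_visibility_plan(seq1))
        e2 = model2.encode(seq2, full_visibility_plan(seq2))
        np.testing.assert_array_equal(e1.z_cls.numpy(), e2.z_cls.numpy())
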