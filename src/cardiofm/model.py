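"""Masked multimodal encoder-decoder for cardiac biosignals and text.

The unified input sequence for record *i* is

    E_i = [e_CLS; E_i^S]              (no report)
    E_i = [e_CLS; E_i^S; E_i^L]       (signal + report)

where each signal token is `W s_{j,k} + channel_emb[j] + temporal_emb[k]`
(channel j indexed by *canonical* channel id, so the same lead always uses
the same embedding row no matter which subset of channels a record carries)
and each text token is `id_emb[l_k] + text_type_emb + text_pos_emb[k]`.

Pretraining masks 75% of signal tokens and 50% of non-pad text tokens,
encodes only the visible tokens with a ViT-style transformer, re-inserts
learnable mask tokens (with their positional embeddings re-added) for a
shallow decoder, and scores reconstruction only at masked positions:
mean-squared error on signal patches, cross-entropy on text token ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autograd import Tensor, concat, stack
from .channels import N_CHANNELS
from .signals import PatchSet
from .text import TextTokenIds, Vocabulary

MODALITY_CLS, MODALITY_SIGNAL, MODALITY_TEXT = 0, 1, 2

PRESETS = {
    "tiny": dict(depth=4, d=128, heads=4),
    "base": dict(depth=12, d=384, heads=6),
    "large": dict(depth=24, d=768, heads=12),
}

_NEG_INF = -1e9


@dataclass
class EncoderConfig:
    """Architecture + tokenization hyperparameters for one model scale."""

    preset: str = "tiny"
    depth: int = 4
    d: int = 128
    heads: int = 4
    mlp_ratio: float = 4.0
    dec_depth: int = 2
    dec_d: int = 128
    dec_heads: int = 4
    dec_mlp_ratio: float = 2.0
    patch_seconds: float = 0.1
    sampling_rate: float = 100.0
    n_s_max: int = 200          # supports records up to n_s_max * w seconds
    n_l: int = 64
    vocab_size: int = 2048
    mask_ratio_signal: float = 0.75
    mask_ratio_text: float = 0.5

    def __post_init__(self):
        if self.d % self.heads:
            raise ValueError("d must be divisible by heads")
        if self.dec_d > self.d:
            raise ValueError("decoder width must not exceed encoder width")

    @property
    def patch_len(self) -> int:
        return int(round(self.patch_seconds * self.sampling_rate))

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "EncoderConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(preset=name, **{**PRESETS[name], **overrides})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnifiedTokenSequence:
    """Ordered token stream [CLS; signal tokens; optional text tokens]."""

    embeddings: Tensor            # (L, d)
    modality: np.ndarray          # (L,) in {0 cls, 1 signal, 2 text}
    channel_ids: np.ndarray       # (L,) canonical id for signal tokens, else -1
    time_idx: np.ndarray          # (L,) patch index / text position, cls -> -1
    is_pad: np.ndarray            # (L,) bool
    truth_patches: np.ndarray     # (n_signal, patch_len) ground-truth patch values
    text_ids: np.ndarray | None   # (N_L,) or None

    @property
    def length(self) -> int:
        return self.embeddings.shape[0]

    @property
    def signal_positions(self) -> np.ndarray:
        return np.nonzero(self.modality == MODALITY_SIGNAL)[0]

    @property
    def text_positions(self) -> np.ndarray:
        return np.nonzero(self.modality == MODALITY_TEXT)[0]

    @property
    def has_text(self) -> bool:
        return self.text_ids is not None


@dataclass
class MaskPlan:
    """Masked/visible partition of one sequence's maskable tokens."""

    masked_signal_idx: np.ndarray   # global sequence positions
    masked_text_idx: np.ndarray
    visible_idx: np.ndarray         # global positions: CLS + unmasked non-pad
    r_signal: float
    r_text: float

    @property
    def n_masked_signal(self) -> int:
        return len(self.masked_signal_idx)

    @property
    def n_masked_text(self) -> int:
        return len(self.masked_text_idx)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def sample_mask_plan(seq: UnifiedTokenSequence, r_signal: float, r_text: float,
                     rng: np.random.Generator) -> MaskPlan:
    """Uniform without-replacement masking within each modality.

    Exactly round(r·n) positions are masked per modality; the CLS token and
    text PAD positions are never masked and PADs are excluded from the
    visible set as well (they carry no information).
    """
    if not (0 <= r_signal < 1 and 0 <= r_text < 1):
        raise ValueError("mask ratios must lie in [0, 1)")
    sig_pos = seq.signal_positions
    txt_pos = seq.text_positions
    txt_nonpad = txt_pos[~seq.is_pad[txt_pos]] if len(txt_pos) else txt_pos
    n_sig = _round_half_up(r_signal * len(sig_pos))
    n_txt = _round_half_up(r_text * len(txt_nonpad))
    masked_sig = np.sort(rng.choice(sig_pos, size=n_sig, replace=False)) \
        if n_sig else np.empty(0, dtype=np.int64)
    masked_txt = np.sort(rng.choice(txt_nonpad, size=n_txt, replace=False)) \
        if n_txt else np.empty(0, dtype=np.int64)
    masked = set(masked_sig.tolist()) | set(masked_txt.tolist())
    visible = np.array(
        [p for p in range(seq.length)
         if p not in masked and not seq.is_pad[p]],
        dtype=np.int64,
    )
    return MaskPlan(masked_sig.astype(np.int64), masked_txt.astype(np.int64),
                    visible, r_signal, r_text)


def full_visibility_plan(seq: UnifiedTokenSequence) -> MaskPlan:
    """No-mask plan used at fine-tuning / inference time."""
    visible = np.nonzero(~seq.is_pad)[0].astype(np.int64)
    return MaskPlan(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                    visible, 0.0, 0.0)


@dataclass
class EncodedRepresentation:
    """Encoder outputs for one record: z_cls plus per-visible-token features."""

    z_cls: Tensor                  # (d,)
    tokens: Tensor                 # (n_visible, d), row order = visible_idx
    visible_idx: np.ndarray
    seq: UnifiedTokenSequence
    block_features: list | None = None   # per-block (n_visible, d) Tensors

    def z_signal(self) -> Tensor:
        rows = np.nonzero(self.seq.modality[self.visible_idx] == MODALITY_SIGNAL)[0]
        return self.tokens[rows]

    def z_text(self) -> Tensor:
        rows = np.nonzero(self.seq.modality[self.visible_idx] == MODALITY_TEXT)[0]
        return self.tokens[rows]


@dataclass
class ReconstructionOutput:
    """Decoder outputs at masked positions plus the loss report."""

    pred_patches: Tensor           # (n_masked_signal, patch_len)
    text_logits: Tensor | None     # (n_masked_text, V)
    losses: dict | None = None


class SignalEmbedder(nn.Module):
    """Patch projection + canonical channel / temporal embedding tables."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.proj = nn.Linear(cfg.patch_len, cfg.d, rng)
        self.channel_table = nn.Parameter(0.02 * rng.standard_normal((N_CHANNELS, cfg.d)))
        self.temporal_table = nn.Parameter(0.02 * rng.standard_normal((cfg.n_s_max, cfg.d)))

    def forward(self, patches: PatchSet) -> tuple[Tensor, np.ndarray, np.ndarray]:
        C, n_time, _ = patches.patches.shape
        if n_time > self.temporal_table.shape[0]:
            raise ValueError(
                f"record has {n_time} patches per channel; temporal table holds "
                f"{self.temporal_table.shape[0]}")
        chan_ids = patches.channel_ids
        flat = Tensor(patches.patches.reshape(C * n_time, -1))
        tok = self.proj(flat)                                    # (C*n, d)
        chan_idx = np.repeat(chan_ids, n_time)
        time_idx = np.tile(np.arange(n_time), C)
        tok = tok + self.channel_table.take_rows(chan_idx)
        tok = tok + self.temporal_table.take_rows(time_idx)
        return tok, chan_idx, time_idx


class TextEmbedder(nn.Module):
    """Token-id embedding + text-type + 1-D positional embeddings."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.id_table = nn.Parameter(0.02 * rng.standard_normal((cfg.vocab_size, cfg.d)))
        self.type_emb = nn.Parameter(0.02 * rng.standard_normal(cfg.d))
        self.pos_table = nn.Parameter(0.02 * rng.standard_normal((cfg.n_l, cfg.d)))

    def forward(self, ids: TextTokenIds) -> Tensor:
        if ids.ids.max(initial=0) >= self.id_table.shape[0]:
            raise ValueError("text token id out of vocabulary range")
        tok = self.id_table.take_rows(ids.ids)
        tok = tok + self.type_emb
        tok = tok + self.pos_table.take_rows(np.arange(len(ids.ids)))
        return tok


class CSFM(nn.Module):
    """Channel-agnostic masked multimodal autoencoder.

    One set of weights serves every non-empty subset of the 13 canonical
    channels; there are no subset-specific parameters.
    """

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.signal_embedder = SignalEmbedder(cfg, rng)
        self.text_embedder = TextEmbedder(cfg, rng)
        self.cls_token = nn.Parameter(0.02 * rng.standard_normal(cfg.d))
        self.blocks = [nn.TransformerBlock(cfg.d, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.norm = nn.LayerNorm(cfg.d)
        # decoder
        self.dec_embed = nn.Linear(cfg.d, cfg.dec_d, rng)
        self.mask_token = nn.Parameter(0.02 * rng.standard_normal(cfg.dec_d))
        self.dec_channel_table = nn.Parameter(
            0.02 * rng.standard_normal((N_CHANNELS, cfg.dec_d)))
        self.dec_temporal_table = nn.Parameter(
            0.02 * rng.standard_normal((cfg.n_s_max, cfg.dec_d)))
        self.dec_text_pos_table = nn.Parameter(
            0.02 * rng.standard_normal((cfg.n_l, cfg.dec_d)))
        self.dec_blocks = [nn.TransformerBlock(cfg.dec_d, cfg.dec_heads,
                                               cfg.dec_mlp_ratio, rng)
                           for _ in range(cfg.dec_depth)]
        self.dec_norm = nn.LayerNorm(cfg.dec_d)
        self.signal_head = nn.Linear(cfg.dec_d, cfg.patch_len, rng)
        self.text_head = nn.Linear(cfg.dec_d, cfg.vocab_size, rng)

    # ------------------------------------------------------------------
    def assemble_input(self, patches: PatchSet,
                       text: TextTokenIds | None = None) -> UnifiedTokenSequence:
        """Build [CLS; signal tokens; optional text tokens] with metadata."""
        sig_tok, chan_idx, time_idx = self.signal_embedder(patches)
        parts = [self.cls_token.reshape(1, -1), sig_tok]
        n_sig = sig_tok.shape[0]
        modality = [MODALITY_CLS] + [MODALITY_SIGNAL] * n_sig
        channel_ids = [-1] + chan_idx.tolist()
        time_pos = [-1] + time_idx.tolist()
        is_pad = [False] * (1 + n_sig)
        text_ids = None
        if text is not None:
            txt_tok = self.text_embedder(text)
            if txt_tok.shape[1] != sig_tok.shape[1]:
                raise ValueError("text/signal embedding width mismatch")
            parts.append(txt_tok)
            modality += [MODALITY_TEXT] * text.n_tokens
            channel_ids += [-1] * text.n_tokens
            time_pos += list(range(text.n_tokens))
            is_pad += text.pad_mask.tolist()
            text_ids = text.ids
        emb = concat(parts, axis=0)
        C, n_time, plen = patches.patches.shape
        return UnifiedTokenSequence(
            embeddings=emb,
            modality=np.array(modality),
            channel_ids=np.array(channel_ids),
            time_idx=np.array(time_pos),
            is_pad=np.array(is_pad, dtype=bool),
            truth_patches=patches.patches.reshape(C * n_time, plen),
            text_ids=text_ids,
        )

    # ------------------------------------------------------------------
    def _batch_pad(self, tensors: list[Tensor], width: int):
        """Stack ragged (n_i, w) tensors to (B, Lmax, w) + attention bias."""
        lengths = [t.shape[0] for t in tensors]
        lmax = max(lengths)
        rows = []
        for t, n in zip(tensors, lengths):
            if n < lmax:
                t = concat([t, Tensor(np.zeros((lmax - n, width)))], axis=0)
            rows.append(t)
        batch = stack(rows, axis=0)
        bias = np.zeros((len(tensors), 1, 1, lmax))
        for i, n in enumerate(lengths):
            bias[i, 0, 0, n:] = _NEG_INF
        if all(n == lmax for n in lengths):
            bias = None
        return batch, bias, lengths

    def encode_batch(self, seqs: list[UnifiedTokenSequence],
                     plans: list[MaskPlan],
                     collect_features: bool = False):
        """Encode the visible tokens of a batch of sequences.

        Ragged visible lengths are zero-padded and excluded from attention
        via an additive bias.  Returns (tokens, lengths, block_features):
        `tokens` is (B, Lmax, d); row order per record follows
        plan.visible_idx (CLS first).
        """
        vis = [seq.embeddings[plan.visible_idx] for seq, plan in zip(seqs, plans)]
        x, bias, lengths = self._batch_pad(vis, self.cfg.d)
        feats = []
        for block in self.blocks:
            x = block(x, bias)
            if collect_features:
                feats.append(x)
        x = self.norm(x)
        return x, lengths, (feats if collect_features else None)

    def encode(self, seq: UnifiedTokenSequence, plan: MaskPlan,
               collect_features: bool = False) -> EncodedRepresentation:
        x, lengths, feats = self.encode_batch([seq], [plan], collect_features)
        n = lengths[0]
        tokens = x[0][:n]
        return EncodedRepresentation(
            z_cls=tokens[0], tokens=tokens, visible_idx=plan.visible_idx,
            seq=seq,
            block_features=[f[0][:n] for f in feats] if feats else None,
        )

    # ------------------------------------------------------------------
    def _decoder_inputs(self, seq: UnifiedTokenSequence, plan: MaskPlan,
                        enc_tokens: Tensor) -> tuple[Tensor, np.ndarray]:
        """Decoder sequence over the non-PAD positions: projected visible
        tokens at their positions, the shared mask token at masked
        positions, positional embeddings re-added.  PAD positions carry no
        information and are omitted entirely."""
        keep = np.nonzero(~seq.is_pad)[0]
        local = np.full(seq.length, -1, dtype=np.int64)
        local[keep] = np.arange(len(keep))
        Lc = len(keep)
        proj = self.dec_embed(enc_tokens)                  # (n_vis, dd)
        is_visible = np.zeros(Lc, dtype=bool)
        is_visible[local[plan.visible_idx]] = True
        x = _scatter_rows(proj, local[plan.visible_idx], Lc)
        x = x + self.mask_token.reshape(1, -1) * Tensor((~is_visible)[:, None].astype(float))
        # re-add decoder positional information
        modality = seq.modality[keep]
        sig = modality == MODALITY_SIGNAL
        txt = modality == MODALITY_TEXT
        if sig.any():
            chan = self.dec_channel_table.take_rows(seq.channel_ids[keep][sig])
            temp = self.dec_temporal_table.take_rows(seq.time_idx[keep][sig])
            x = x + _scatter_rows(chan + temp, np.nonzero(sig)[0], Lc)
        if txt.any():
            tpos = self.dec_text_pos_table.take_rows(seq.time_idx[keep][txt])
            x = x + _scatter_rows(tpos, np.nonzero(txt)[0], Lc)
        return x, local

    def reconstruct_batch(self, seqs, plans, enc_tokens_list):
        dec_inputs, locals_ = [], []
        for seq, plan, enc_tok in zip(seqs, plans, enc_tokens_list):
            x, local = self._decoder_inputs(seq, plan, enc_tok)
            dec_inputs.append(x)
            locals_.append(local)
        x, bias, lengths = self._batch_pad(dec_inputs, self.cfg.dec_d)
        for block in self.dec_blocks:
            x = block(x, bias)
        x = self.dec_norm(x)
        outs = []
        for i, (seq, plan) in enumerate(zip(seqs, plans)):
            local = locals_[i]
            pred_patches = self.signal_head(x[i][local[plan.masked_signal_idx]]) \
                if plan.n_masked_signal else Tensor(np.zeros((0, self.cfg.patch_len)))
            logits = self.text_head(x[i][local[plan.masked_text_idx]]) \
                if plan.n_masked_text else None
            outs.append(ReconstructionOutput(pred_patches, logits))
        return outs

    def reconstruct(self, enc: EncodedRepresentation,
                    plan: MaskPlan) -> ReconstructionOutput:
        if not np.array_equal(plan.visible_idx, enc.visible_idx):
            raise ValueError("mask plan does not match the one used at encode time")
        return self.reconstruct_batch([enc.seq], [plan], [enc.tokens])[0]


def _scatter_rows(values: Tensor, idx: np.ndarray, length: int) -> Tensor:
    """Place rows of `values` at positions `idx` of a zero (length, w) tensor."""
    lookup = np.full(length, len(idx), dtype=np.int64)
    lookup[idx] = np.arange(len(idx))
    padded = concat([values, Tensor(np.zeros((1, values.shape[1])))], axis=0)
    return padded.take_rows(lookup)


# ----------------------------------------------------------------------
def signal_token_rows(seq: UnifiedTokenSequence, positions: np.ndarray) -> np.ndarray:
    """Map global sequence positions to rows of seq.truth_patches."""
    sig_pos = seq.signal_positions
    row_of = {int(p): r for r, p in enumerate(sig_pos)}
    return np.array([row_of[int(p)] for p in positions], dtype=np.int64)


def pretraining_loss(out: ReconstructionOutput, seq: UnifiedTokenSequence,
                     plan: MaskPlan) -> dict:
    """Masked-only reconstruction losses.

    L_S: mean squared error over all patch elements at masked signal
    positions; L_L: mean cross-entropy of the true token ids at masked text
    positions; total = L_S + L_L (unit weights).  Ground truth at visible
    positions never enters either term.
    """
    _, losses = _batched_losses([out], [seq], [plan])
    return losses


def _batched_losses(outs: list[ReconstructionOutput],
                    seqs: list[UnifiedTokenSequence],
                    plans: list[MaskPlan]) -> tuple[list[ReconstructionOutput], dict]:
    sig_preds, sig_truth = [], []
    txt_logits, txt_truth = [], []
    for out, seq, plan in zip(outs, seqs, plans):
        if plan.n_masked_signal:
            rows = signal_token_rows(seq, plan.masked_signal_idx)
            sig_preds.append(out.pred_patches)
            sig_truth.append(seq.truth_patches[rows])
        if plan.n_masked_text and out.text_logits is not None:
            txt_logits.append(out.text_logits)
            txt_truth.append(seq.text_ids[seq.time_idx[plan.masked_text_idx]])
    if not sig_preds and not txt_logits:
        raise ValueError("nothing to reconstruct: both masked sets are empty")
    losses: dict = {}
    total = None
    if sig_preds:
        pred = concat(sig_preds, axis=0) if len(sig_preds) > 1 else sig_preds[0]
        truth = np.concatenate(sig_truth, axis=0)
        diff = pred - Tensor(truth)
        l_s = (diff * diff).mean()
        losses["L_S"] = l_s
        total = l_s
    if txt_logits:
        logits = concat(txt_logits, axis=0) if len(txt_logits) > 1 else txt_logits[0]
        ids = np.concatenate(txt_truth)
        logp = logits.log_softmax(axis=-1)
        picked = logp[np.arange(len(ids)), ids]
        l_l = -picked.mean()
        losses["L_L"] = l_l
        total = l_l if total is None else total + l_l
    losses["total"] = total
    return outs, losses


@dataclass
class SequenceLayout:
    """Token-stream metadata for one record, without embeddings.

    Mirrors the metadata of :class:`UnifiedTokenSequence`; used by the
    batched pretraining path so mask plans can be drawn before any tensor
    work happens.
    """

    modality: np.ndarray
    channel_ids: np.ndarray
    time_idx: np.ndarray
    is_pad: np.ndarray
    truth_patches: np.ndarray
    text_ids: np.ndarray | None

    @property
    def length(self) -> int:
        return len(self.modality)

    @property
    def signal_positions(self) -> np.ndarray:
        return np.nonzero(self.modality == MODALITY_SIGNAL)[0]

    @property
    def text_positions(self) -> np.ndarray:
        return np.nonzero(self.modality == MODALITY_TEXT)[0]


def sequence_layout(patches: PatchSet,
                    text: TextTokenIds | None = None) -> SequenceLayout:
    C, n_time, plen = patches.patches.shape
    n_sig = C * n_time
    n_txt = text.n_tokens if text is not None else 0
    modality = np.concatenate([[MODALITY_CLS],
                               np.full(n_sig, MODALITY_SIGNAL),
                               np.full(n_txt, MODALITY_TEXT)]).astype(np.int64)
    channel_ids = np.concatenate([[-1], np.repeat(patches.channel_ids, n_time),
                                  np.full(n_txt, -1)]).astype(np.int64)
    time_idx = np.concatenate([[-1], np.tile(np.arange(n_time), C),
                               np.arange(n_txt)]).astype(np.int64)
    is_pad = np.zeros(1 + n_sig + n_txt, dtype=bool)
    if text is not None:
        is_pad[1 + n_sig:] = text.pad_mask
    return SequenceLayout(modality, channel_ids, time_idx, is_pad,
                          patches.patches.reshape(n_sig, plen),
                          text.ids if text is not None else None)


def pretrain_forward(model: CSFM, items: list, rng: np.random.Generator,
                     plans: list | None = None) -> dict:
    """One batched pretraining forward pass (fused across records).

    `items` is a list of (PatchSet, TextTokenIds | None).  Embedding
    lookups, projections and heads each run as a single fused operation
    over the whole batch; the result is numerically identical to running
    :meth:`CSFM.assemble_input` / :meth:`CSFM.encode` /
    :meth:`CSFM.reconstruct` record by record (covered by a test).
    Returns the loss dict whose 'total' entry is the scalar to
    backpropagate.
    """
    cfg = model.cfg
    B = len(items)
    layouts = [sequence_layout(p, t) for p, t in items]
    if plans is None:
        plans = [sample_mask_plan(lay, cfg.mask_ratio_signal,
                                  cfg.mask_ratio_text, rng) for lay in layouts]

    # ---- fused embeddings -------------------------------------------
    n_sig = [len(lay.signal_positions) for lay in layouts]
    n_txt = [len(lay.text_positions) for lay in layouts]
    all_patches = np.concatenate([lay.truth_patches for lay in layouts])
    chan_idx = np.concatenate(
        [lay.channel_ids[lay.signal_positions] for lay in layouts])
    time_idx = np.concatenate(
        [lay.time_idx[lay.signal_positions] for lay in layouts])
    if time_idx.max(initial=0) >= cfg.n_s_max:
        raise ValueError("record longer than the temporal embedding table")
    emb = model.signal_embedder
    sig_flat = (emb.proj(Tensor(all_patches))
                + emb.channel_table.take_rows(chan_idx)
                + emb.temporal_table.take_rows(time_idx))
    with_text = [lay.text_ids is not None for lay in layouts]
    if any(with_text):
        ids_flat = np.concatenate([lay.text_ids for lay in layouts
                                   if lay.text_ids is not None])
        pos_flat = np.concatenate([np.arange(len(lay.text_ids))
                                   for lay in layouts if lay.text_ids is not None])
        te = model.text_embedder
        txt_flat = (te.id_table.take_rows(ids_flat) + te.type_emb
                    + te.pos_table.take_rows(pos_flat))
        flat = concat([model.cls_token.reshape(1, -1), sig_flat, txt_flat,
                       Tensor(np.zeros((1, cfg.d)))], axis=0)
    else:
        flat = concat([model.cls_token.reshape(1, -1), sig_flat,
                       Tensor(np.zeros((1, cfg.d)))], axis=0)
    zero_row = flat.shape[0] - 1
    # flat row of global sequence position p in record b
    sig_off = 1 + np.concatenate([[0], np.cumsum(n_sig)[:-1]])
    txt_off = 1 + sum(n_sig) + np.concatenate([[0], np.cumsum(n_txt)[:-1]])

    def flat_row(b: int, pos: np.ndarray) -> np.ndarray:
        lay = layouts[b]
        out = np.zeros(len(pos), dtype=np.int64)
        sig = lay.modality[pos] == MODALITY_SIGNAL
        txt = lay.modality[pos] == MODALITY_TEXT
        out[sig] = sig_off[b] + (pos[sig] - 1)
        out[txt] = txt_off[b] + (pos[txt] - 1 - n_sig[b])
        return out

    # ---- encoder over visible tokens --------------------------------
    n_vis = [len(p.visible_idx) for p in plans]
    lmax = max(n_vis)
    vis_idx = np.full((B, lmax), zero_row, dtype=np.int64)
    for b, plan in enumerate(plans):
        vis_idx[b, :n_vis[b]] = flat_row(b, plan.visible_idx)
    x = flat.take_rows(vis_idx)                       # (B, lmax, d)
    bias = None
    if len(set(n_vis)) > 1:
        bias = np.zeros((B, 1, 1, lmax))
        for b, n in enumerate(n_vis):
            bias[b, 0, 0, n:] = _NEG_INF
    for block in model.blocks:
        x = block(x, bias)
    x = model.norm(x)

    # ---- decoder over non-PAD positions -----------------------------
    dec_proj = model.dec_embed(x)                     # (B, lmax, dd)
    dd = cfg.dec_d
    pool = concat([dec_proj.reshape(B * lmax, dd),
                   model.mask_token.reshape(1, dd),
                   Tensor(np.zeros((1, dd)))], axis=0)
    mask_row, dec_zero = B * lmax, B * lmax + 1
    keeps = [np.nonzero(~lay.is_pad)[0] for lay in layouts]
    n_dec = [len(k) for k in keeps]
    dmax = max(n_dec)
    dec_idx = np.full((B, dmax), dec_zero, dtype=np.int64)
    cidx = np.full((B, dmax), N_CHANNELS, dtype=np.int64)     # zero row
    tidx = np.full((B, dmax), cfg.n_s_max, dtype=np.int64)
    pidx = np.full((B, dmax), cfg.n_l, dtype=np.int64)
    for b, (lay, plan, keep) in enumerate(zip(layouts, plans, keeps)):
        slot = np.full(lay.length, -1, dtype=np.int64)
        slot[plan.visible_idx] = np.arange(n_vis[b])
        s = slot[keep]
        rows = np.where(s >= 0, b * lmax + s, mask_row)
        dec_idx[b, :n_dec[b]] = rows
        sig = lay.modality[keep] == MODALITY_SIGNAL
        txt = lay.modality[keep] == MODALITY_TEXT
        cidx[b, :n_dec[b]][sig] = lay.channel_ids[keep][sig]
        tidx[b, :n_dec[b]][sig] = lay.time_idx[keep][sig]
        pidx[b, :n_dec[b]][txt] = lay.time_idx[keep][txt]
    zero_dd = Tensor(np.zeros((1, dd)))
    chan_pool = concat([model.dec_channel_table, zero_dd], axis=0)
    temp_pool = concat([model.dec_temporal_table, zero_dd], axis=0)
    tpos_pool = concat([model.dec_text_pos_table, zero_dd], axis=0)
    y = (pool.take_rows(dec_idx) + chan_pool.take_rows(cidx)
         + temp_pool.take_rows(tidx) + tpos_pool.take_rows(pidx))
    dbias = None
    if len(set(n_dec)) > 1:
        dbias = np.zeros((B, 1, 1, dmax))
        for b, n in enumerate(n_dec):
            dbias[b, 0, 0, n:] = _NEG_INF
    for block in model.dec_blocks:
        y = block(y, dbias)
    y = model.dec_norm(y)
    y_flat = y.reshape(B * dmax, dd)

    # ---- masked-only heads and losses -------------------------------
    losses: dict = {}
    total = None
    ms_rows, ms_truth = [], []
    for b, (lay, plan, keep) in enumerate(zip(layouts, plans, keeps)):
        if plan.n_masked_signal:
            local = np.searchsorted(keep, plan.masked_signal_idx)
            ms_rows.append(b * dmax + local)
            ms_truth.append(lay.truth_patches[
                signal_token_rows(lay, plan.masked_signal_idx)])
    if ms_rows:
        preds = model.signal_head(y_flat.take_rows(np.concatenate(ms_rows)))
        diff = preds - Tensor(np.concatenate(ms_truth))
        l_s = (diff * diff).mean()
        losses["L_S"] = l_s
        total = l_s
    mt_rows, mt_ids = [], []
    for b, (lay, plan, keep) in enumerate(zip(layouts, plans, keeps)):
        if plan.n_masked_text and lay.text_ids is not None:
            local = np.searchsorted(keep, plan.masked_text_idx)
            mt_rows.append(b * dmax + local)
            mt_ids.append(lay.text_ids[lay.time_idx[plan.masked_text_idx]])
    if mt_rows:
        logits = model.text_head(y_flat.take_rows(np.concatenate(mt_rows)))
        ids = np.concatenate(mt_ids)
        logp = logits.log_softmax(axis=-1)
        l_l = -(logp[np.arange(len(ids)), ids]).mean()
        losses["L_L"] = l_l
        total = l_l if total is None else total + l_l
    if total is None:
        raise ValueError("nothing to reconstruct: both masked sets are empty")
    losses["total"] = total
    return losses


def pretrain_forward_reference(model: CSFM, items: list,
                               rng: np.random.Generator,
                               plans: list | None = None) -> dict:
    """Record-by-record pretraining forward through the modular operations
    (assemble / encode / reconstruct); the oracle for the fused path."""
    seqs = [model.assemble_input(p, t) for p, t in items]
    if plans is None:
        plans = [sample_mask_plan(s, model.cfg.mask_ratio_signal,
                                  model.cfg.mask_ratio_text, rng) for s in seqs]
    x, lengths, _ = model.encode_batch(seqs, plans)
    enc_tokens = [x[i][:n] for i, n in enumerate(lengths)]
    outs = model.reconstruct_batch(seqs, plans, enc_tokens)
    _, losses = _batched_losses(outs, seqs, plans)
    return losses


def encode_uniform(model: CSFM, patch_sets: list,
                   collect_features: bool = False):
    """Fused no-mask encoding of signal-only records with identical layout.

    All records must share channel set and patch count.  Returns
    (tokens, block_features): tokens is (B, 1 + C*N_S, d) with CLS at
    position 0; block_features is a list of per-block tensors of the same
    shape (or None).  Numerically identical to the per-record path.
    """
    cfg = model.cfg
    B = len(patch_sets)
    ref = patch_sets[0]
    C, n_time, plen = ref.patches.shape
    for p in patch_sets[1:]:
        if p.patches.shape != ref.patches.shape or \
                not np.array_equal(p.channel_ids, ref.channel_ids):
            raise ValueError("encode_uniform requires identical record layouts")
    if n_time > cfg.n_s_max:
        raise ValueError("record longer than the temporal embedding table")
    stacked = np.stack([p.patches.reshape(C * n_time, plen)
                        for p in patch_sets])          # (B, n, plen)
    emb = model.signal_embedder
    chan_idx = np.repeat(ref.channel_ids, n_time)
    time_idx = np.tile(np.arange(n_time), C)
    sig = (emb.proj(Tensor(stacked))
           + emb.channel_table.take_rows(chan_idx)
           + emb.temporal_table.take_rows(time_idx))   # (B, n, d)
    cls_rows = model.cls_token.reshape(1, -1).take_rows(
        np.zeros((B, 1), dtype=np.int64))              # (B, 1, d)
    x = concat([cls_rows, sig], axis=1)
    feats = []
    for block in model.blocks:
        x = block(x, None)
        if collect_features:
            feats.append(x)
    x = model.norm(x)
    return x, (feats if collect_features else None)


# ----------------------------------------------------------------------
# checkpoint container
CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, model: CSFM, vocab: Vocabulary | None = None,
                    extra: dict | None = None) -> None:
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": model.cfg.to_dict(),
        "vocab": vocab.token_to_id if vocab else None,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[CSFM, Vocabulary | None, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg = EncoderConfig(**meta["config"])
        model = CSFM(cfg)
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    model.load_state_dict(state)
    vocab = Vocabulary({t: int(i) for t, i in meta["vocab"].items()}) \
        if meta["vocab"] else None
    return model, vocab, meta["extra"]


__all__ = [
    "EncoderConfig", "UnifiedTokenSequence", "MaskPlan",
    "EncodedRepresentation", "ReconstructionOutput", "CSFM",
    "sample_mask_plan", "full_visibility_plan", "pretraining_loss",
    "pretrain_forward", "pretrain_forward_reference", "sequence_layout",
    "SequenceLayout", "encode_uniform", "save_checkpoint", "load_checkpoint",
    "PRESETS",
]
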