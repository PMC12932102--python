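"""Downstream adaptation heads.

Three adaptation modes sit on top of the pretrained encoder:

* CLS-based classification (MLP on ``z_cls``) trained with the asymmetric
  loss — multiclass tasks are handled as one-hot multilabel;
* CLS-based univariate regression trained with mean squared error;
* a dense sequence-to-sequence head that aggregates intermediate features
  from several transformer blocks and fuses them with residual 1-D
  convolutions and progressive upsampling back to sample resolution
  (a 1-D adaptation of the dense-prediction transformer head), used for
  waveform targets such as ABP or missing-lead reconstruction.

Blood-pressure summaries are read off a predicted ABP window as
SBP = max, DBP = min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor


class ClassificationHead(nn.Module):
    """Two-layer MLP over z_cls producing K logits."""

    def __init__(self, d: int, n_classes: int, rng: np.random.Generator,
                 hidden: int = 64, multilabel: bool = False):
        self.fc1 = nn.Linear(d, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_classes, rng)
        self.n_classes = n_classes
        self.multilabel = multilabel

    def forward(self, z_cls: Tensor) -> Tensor:
        if z_cls.shape[-1] != self.fc1.weight.shape[0]:
            raise ValueError(
                f"z_cls width {z_cls.shape[-1]} != head input {self.fc1.weight.shape[0]}")
        return self.fc2(self.fc1(z_cls).gelu())


class RegressionHead(nn.Module):
    """MLP over z_cls producing one real value, trained with MSE."""

    def __init__(self, d: int, rng: np.random.Generator, hidden: int = 64):
        self.fc1 = nn.Linear(d, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, z_cls: Tensor) -> Tensor:
        if z_cls.shape[-1] != self.fc1.weight.shape[0]:
            raise ValueError("z_cls width mismatch")
        return self.fc2(self.fc1(z_cls).gelu())


def classify(z_cls: Tensor, head: ClassificationHead) -> Tensor:
    """Class scores from the global representation.

    Multilabel heads return independent per-class probabilities (sigmoid);
    multiclass heads return a one-of-K distribution (softmax).
    """
    logits = head(z_cls)
    return logits.sigmoid() if head.multilabel else logits.softmax(axis=-1)


def regress_scalar(z_cls: Tensor, head: RegressionHead) -> Tensor:
    return head(z_cls)


def asymmetric_loss(logits: Tensor, targets: np.ndarray,
                    gamma_pos: float = 0.0, gamma_neg: float = 4.0,
                    clip: float = 0.05, eps: float = 1e-12) -> Tensor:
    """Asymmetric focal loss for multilabel / one-hot multiclass targets.

    Positives are weighted by (1-p)^gamma_pos, negatives by p_m^gamma_neg
    with the negative probability shifted down by `clip` (probability
    margin) and floored at zero.  With gamma_pos = gamma_neg = clip = 0 the
    loss reduces exactly to binary cross-entropy.  Mean over all elements.
    """
    targets = np.asarray(targets, dtype=np.float64)
    if not np.all((targets == 0) | (targets == 1)):
        raise ValueError("targets must be binary {0,1}")
    if targets.shape != logits.shape:
        raise ValueError("targets shape must match logits")
    p = logits.sigmoid()
    pm = (p - clip).relu() if clip > 0 else p
    log_p = (p + eps).log()
    log_1m = (1.0 - pm + eps).log()
    w_pos = (1.0 - p) ** gamma_pos if gamma_pos > 0 else None
    w_neg = pm ** gamma_neg if gamma_neg > 0 else None
    t = Tensor(targets)
    pos_term = t * log_p
    if w_pos is not None:
        pos_term = pos_term * w_pos
    neg_term = (1.0 - t) * log_1m
    if w_neg is not None:
        neg_term = neg_term * w_neg
    return -(pos_term + neg_term).mean()


class DenseHead(nn.Module):
    """Dense sequence-to-sequence regression head.

    Token features from `taps` encoder blocks are reassembled on the time
    axis (features of all input channels at the same patch index are
    averaged), projected to a common feature width, fused deepest-first with
    residual 1-D convolution units, and upsampled from token resolution
    (one token per w seconds) to sample resolution.  Output length equals
    the input sample count exactly for any input channel subset.
    """

    def __init__(self, d: int, patch_len: int, out_channels: int,
                 rng: np.random.Generator, n_taps: int = 4,
                 feat: int = 64, kernel: int = 5):
        self.patch_len = patch_len
        self.out_channels = out_channels
        self.n_taps = n_taps
        self.tap_proj = [nn.Linear(d, feat, rng) for _ in range(n_taps)]
        self.fuse = [nn.ResidualConvUnit(feat, kernel, rng) for _ in range(n_taps)]
        if patch_len % 2 == 0:
            self.up_factors = (2, patch_len // 2)
        else:
            self.up_factors = (patch_len, 1)
        self.up_conv1 = nn.Conv1d(feat, feat, kernel, rng)
        self.up_conv2 = nn.Conv1d(feat, feat, kernel, rng)
        self.out_conv = nn.Conv1d(feat, out_channels, kernel, rng)

    @staticmethod
    def tap_indices(depth: int, n_taps: int = 4) -> list[int]:
        """Evenly spaced block indices ending at the last block."""
        if depth < n_taps:
            return list(range(depth))
        return [round((i + 1) * depth / n_taps) - 1 for i in range(n_taps)]

    def forward(self, block_features: list[Tensor], n_channels: int,
                n_time: int, signal_start: int = 1) -> Tensor:
        """`block_features`: per-tap (B, L, d) encoder features (no masking).

        Signal tokens are assumed contiguous, channel-major, starting at
        `signal_start` (position 0 is CLS).
        """
        if not block_features:
            raise ValueError("need at least one tapped feature map")
        fused = None
        for proj, rcu, feats in zip(self.tap_proj, self.fuse, block_features):
            B, L, d = feats.shape
            sig = feats[:, signal_start:signal_start + n_channels * n_time, :]
            sig = sig.reshape(B, n_channels, n_time, d).mean(axis=1)   # (B, n_time, d)
            x = proj(sig).transpose(0, 2, 1)                           # (B, F, n_time)
            fused = x if fused is None else rcu(fused) + x
        fused = self.fuse[-1](fused) if fused is not None else None
        f1, f2 = self.up_factors
        x = self.up_conv1(fused.repeat_last(f1)).relu()
        if f2 > 1:
            x = self.up_conv2(x.repeat_last(f2)).relu()
        return self.out_conv(x)                                        # (B, C_out, T)


def dense_regress(model, patch_sets: list, head: DenseHead) -> Tensor:
    """Run the encoder without masking, tap intermediate blocks and predict
    a per-sample waveform aligned with the input time axis.

    `patch_sets` must be signal-only records of identical layout.
    """
    from .model import encode_uniform

    _, feats = encode_uniform(model, patch_sets, collect_features=True)
    taps = DenseHead.tap_indices(model.cfg.depth, head.n_taps)
    tapped = [feats[t] for t in taps]
    C, n_time, _ = patch_sets[0].patches.shape
    return head(tapped, C, n_time)


@dataclass
class BloodPressureSummary:
    """Window-level systolic/diastolic pressure in mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self):
        if self.sbp < self.dbp:
            raise ValueError("SBP must be >= DBP")


def sbp_dbp_from_abp(abp_window: np.ndarray) -> BloodPressureSummary:
    """SBP = window maximum, DBP = window minimum."""
    abp = np.asarray(abp_window, dtype=np.float64)
    if abp.size == 0:
        raise ValueError("empty ABP window")
    return BloodPressureSummary(sbp=float(abp.max()), dbp=float(abp.min()))


__all__ = [
    "ClassificationHead", "RegressionHead", "DenseHead",
    "BloodPressureSummary", "classify", "regress_scalar", "asymmetric_loss",
    "dense_regress", "sbp_dbp_from_abp",
]
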