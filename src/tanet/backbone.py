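"""Assembly of the full triple-attention network.

Data flow (band-first layout, batch B):

    DE (B,5,C,T) + PSD (B,5,C,T)
      -> per-band cross-modal attention, band-stacked   (B,5,C,T)
      -> CBAM channel + spatial gating                  (B,5,C,T)
      -> 2x (Conv2d 3x3 -> BatchNorm -> GELU)           (B,64,C,T)
      -> adaptive average pool                          (B,64,31,10)
      -> per-time-step flatten + linear + LayerNorm     (B,10,256)
      -> 2x Conformer block                             (B,10,256)
      -> global average pool over time steps            (B,256)
      -> 3-layer classifier, softmax                    (B,n_classes)

Each Conformer block is the half-step-FFN sandwich: ``x + 0.5 FFN(x)``,
pre-norm multi-head self-attention with residual, a depthwise-separable
convolution module with residual, ``x + 0.5 FFN(x)``, then a closing
LayerNorm.  The reference configuration (5 bands, 62 channels, 10 windows,
3 classes) counts 3.34 million trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cbam import CBAM, CbamConfig
from .mca import AttentionConfig, MCAFusion
from .nn import Tensor
from .nn.functional import adaptive_avg_pool2d

__all__ = ["ModelConfig", "ConvBlock", "SequenceProjection", "ConformerFFN",
           "ConformerConvModule", "ConformerBlock", "ClassifierHead", "TANet",
           "count_trainable_parameters", "save_checkpoint", "load_checkpoint"]

count_trainable_parameters = nn.count_trainable_parameters


@dataclass
class ModelConfig:
    """Every architectural hyperparameter of the network."""

    layout: str = "seed_like"
    n_bands: int = 5
    eeg_channels: int = 62
    windows: int = 10
    n_classes: int = 3
    mca_att_dim: int = 32
    mca_dropout: float = 0.3
    mca_bidirectional: bool = False
    cbam_reduction: int = 4
    cbam_kernel: int = 7
    conv_channels: tuple = (32, 64)
    conv_kernel: int = 3
    pool_target: tuple = (31, 10)
    d_model: int = 256
    n_heads: int = 8
    conformer_conv_kernel: int = 5
    ffn_expansion: int = 4
    n_blocks: int = 2
    dropout_conformer: float = 0.1
    classifier_dims: tuple = (128, 64)
    dropout_cls: tuple = (0.3, 0.2)

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @classmethod
    def seed_config(cls, **overrides) -> "ModelConfig":
        """62-channel, 10-window, 3-class configuration."""
        return cls(**overrides)

    @classmethod
    def deap_config(cls, **overrides) -> "ModelConfig":
        """32-channel, binary configuration with bidirectional fusion."""
        defaults = dict(layout="deap_like", eeg_channels=32, windows=60,
                        n_classes=2, mca_bidirectional=True)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        tuple_keys = {"conv_channels", "pool_target", "classifier_dims",
                      "dropout_cls"}
        kwargs = {k: (tuple(v) if k in tuple_keys else v) for k, v in d.items()}
        return cls(**kwargs)


class ConvBlock(nn.Module):
    """Two (Conv2d 3x3 -> BatchNorm -> GELU) stages mapping the band
    channels 5 -> 32 -> 64; padding preserves the spatial grid.  The convs
    carry no bias (the following BatchNorm supplies the shift)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2 = cfg.conv_channels
        pad = (cfg.conv_kernel - 1) // 2
        self.in_channels = cfg.n_bands
        self.conv1 = nn.Conv2d(cfg.n_bands, c1, cfg.conv_kernel, rng,
                               padding=pad, bias=False)
        self.bn1 = nn.BatchNorm2d(c1)
        self.conv2 = nn.Conv2d(c1, c2, cfg.conv_kernel, rng, padding=pad,
                               bias=False)
        self.bn2 = nn.BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        x = self.bn1(self.conv1(x)).gelu()
        return self.bn2(self.conv2(x)).gelu()


class SequenceProjection(nn.Module):
    """Turn the pooled (B, 64, 31, T) map into a T-token sequence: the time
    axis becomes the token axis, each token is the flattened 64*31 = 1984
    channel-by-space column, linearly mapped to d_model and layer-normed."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c_out = cfg.conv_channels[-1]
        self.expected_hw = (c_out, cfg.pool_target[0])
        self.fan_in = c_out * cfg.pool_target[0]
        self.linear = nn.Linear(self.fan_in, cfg.d_model, rng)
        self.norm = nn.LayerNorm(cfg.d_model)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, T = x.shape
        if (C, H) != self.expected_hw:
            raise ValueError(
                f"expected (*, {self.expected_hw[0]}, {self.expected_hw[1]}, T)"
                f", got {x.shape}")
        tokens = x.transpose(0, 3, 1, 2).reshape(B, T, C * H)
        return self.norm(self.linear(tokens))


class ConformerFFN(nn.Module):
    """Pre-norm feed-forward: LayerNorm -> Linear(d, e*d) -> GELU ->
    Linear(e*d, d) -> Dropout."""

    def __init__(self, d_model: int, expansion: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        hidden = expansion * d_model
        self.norm = nn.LayerNorm(d_model)
        self.linear1 = nn.Linear(d_model, hidden, rng)
        self.linear2 = nn.Linear(hidden, d_model, rng)
        self.dropout = nn.Dropout(dropout_p, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.dropout(self.linear2(self.linear1(self.norm(x)).gelu()))


class ConformerConvModule(nn.Module):
    """Depthwise-separable temporal convolution: LayerNorm -> depthwise
    conv (kernel 5, 'same' padding, no bias: BatchNorm follows) ->
    BatchNorm -> GELU -> pointwise 1x1 conv -> Dropout."""

    def __init__(self, d_model: int, kernel: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(d_model)
        self.depthwise = nn.DepthwiseConv1d(d_model, kernel, rng,
                                            padding=(kernel - 1) // 2,
                                            bias=False)
        self.bn = nn.BatchNorm1d(d_model)
        self.pointwise = nn.Linear(d_model, d_model, rng)
        self.dropout = nn.Dropout(dropout_p, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x).swapaxes(1, 2)           # (B, D, T)
        h = self.bn(self.depthwise(h)).gelu()
        h = self.pointwise(h.swapaxes(1, 2))      # back to (B, T, D)
        return self.dropout(h)


class ConformerBlock(nn.Module):
    """Half-step FFN / self-attention / conv module / half-step FFN, all
    residual, closed by a LayerNorm."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, p = cfg.d_model, cfg.dropout_conformer
        self.ffn1 = ConformerFFN(d, cfg.ffn_expansion, p, rng)
        self.attn_norm = nn.LayerNorm(d)
        self.attn = nn.MultiheadSelfAttention(d, cfg.n_heads, rng, dropout_p=p)
        self.conv = ConformerConvModule(d, cfg.conformer_conv_kernel, p, rng)
        self.ffn2 = ConformerFFN(d, cfg.ffn_expansion, p, rng)
        self.final_norm = nn.LayerNorm(d)

    def forward(self, x: Tensor) -> Tensor:
        x = x + 0.5 * self.ffn1(x)
        x = x + self.attn(self.attn_norm(x))
        x = x + self.conv(x)
        x = x + 0.5 * self.ffn2(x)
        return self.final_norm(x)


class ClassifierHead(nn.Module):
    """Three-layer MLP 256 -> 128 -> 64 -> n_classes with GELU + dropout on
    the hidden layers.  ``forward`` returns logits; ``probabilities``
    applies the softmax."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h1, h2 = cfg.classifier_dims
        p1, p2 = cfg.dropout_cls
        self.fc1 = nn.Linear(cfg.d_model, h1, rng)
        self.drop1 = nn.Dropout(p1, rng)
        self.fc2 = nn.Linear(h1, h2, rng)
        self.drop2 = nn.Dropout(p2, rng)
        self.fc3 = nn.Linear(h2, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop1(self.fc1(x).gelu())
        x = self.drop2(self.fc2(x).gelu())
        return self.fc3(x)

    def probabilities(self, x: Tensor) -> Tensor:
        return self.forward(x).softmax(axis=-1)


class TANet(nn.Module):
    """The full triple-attention network.

    ``forward`` takes matched DE/PSD tensors in the configured layout and
    returns class probabilities; ``forward_logits`` returns pre-softmax
    scores for training; ``forward_fused`` starts from an already fused
    band-stacked tensor (the route the segment-level pipeline uses, where
    cross-modal fusion happens on whole trials before segmentation).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        att_cfg = AttentionConfig(in_dim=cfg.windows, att_dim=cfg.mca_att_dim,
                                  dropout_p=cfg.mca_dropout,
                                  bidirectional=cfg.mca_bidirectional)
        self.mca = MCAFusion(att_cfg, rng, n_bands=cfg.n_bands,
                             layout=cfg.layout)
        self.cbam = CBAM(CbamConfig(n_channels=cfg.n_bands,
                                    reduction=cfg.cbam_reduction,
                                    spatial_kernel=cfg.cbam_kernel), rng)
        self.conv = ConvBlock(cfg, rng)
        self.projection = SequenceProjection(cfg, rng)
        self.blocks = nn.Sequential(*[ConformerBlock(cfg, rng)
                                      for _ in range(cfg.n_blocks)])
        self.classifier = ClassifierHead(cfg, rng)

    # -- forward paths ----------------------------------------------------

    def _check_layout(self, x: Tensor):
        cfg = self.cfg
        if cfg.layout == "seed_like":
            expected = (cfg.n_bands, cfg.eeg_channels, cfg.windows)
        else:
            expected = (cfg.eeg_channels, cfg.n_bands, cfg.windows)
        if tuple(x.shape[1:]) != expected:
            raise ValueError(
                f"layout mismatch: configured {cfg.layout} expects trailing "
                f"dims {expected}, got {tuple(x.shape[1:])}")

    def forward_fused(self, fused: Tensor) -> Tensor:
        """Band-stacked fused tensor -> logits.  Accepts band-first
        (B, 5, C, T); a channel-first deap-layout tensor (B, C, 5, T) is
        permuted to band-first."""
        fused = fused if isinstance(fused, Tensor) else Tensor(np.asarray(fused))
        if fused.shape[1] != self.cfg.n_bands:
            if fused.shape[2] == self.cfg.n_bands:
                fused = fused.transpose(0, 2, 1, 3)
            else:
                raise ValueError(
                    f"no band axis of size {self.cfg.n_bands} in {fused.shape}")
        x = self.cbam(fused)
        x = self.conv(x)
        x = adaptive_avg_pool2d(x, self.cfg.pool_target)
        x = self.projection(x)
        x = self.blocks(x)
        pooled = x.mean(axis=1)
        return self.classifier(pooled)

    def forward_logits(self, de, psd) -> Tensor:
        de = de if isinstance(de, Tensor) else Tensor(np.asarray(de))
        psd = psd if isinstance(psd, Tensor) else Tensor(np.asarray(psd))
        self._check_layout(de)
        self._check_layout(psd)
        return self.forward_fused(self.mca(de, psd))

    def forward(self, de, psd) -> Tensor:
        return self.forward_logits(de, psd).softmax(axis=-1)

    def predict(self, de, psd) -> np.ndarray:
        with nn.no_grad():
            probs = self.forward(de, psd).numpy()
        return probs.argmax(axis=-1)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: TANet, path):
    """Write weights (npz) plus a JSON manifest (layer name -> shape and the
    model config) next to it."""
    path = str(path)
    state = model.state_dict()
    np.savez(path if path.endswith(".npz") else path + ".npz", **state)
    manifest = {
        "config": model.cfg.to_dict(),
        "arrays": {k: list(v.shape) for k, v in state.items()},
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as f:
        json.dump(manifest, f, indent=1)


def load_checkpoint(path, seed: int = 0) -> TANet:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        manifest = json.load(f)
    model = TANet(ModelConfig.from_dict(manifest["config"]), seed=seed)
    with np.load(base + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
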