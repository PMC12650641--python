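"""Mutual cross-modal attention (MCA) fusing DE and PSD features per band.

Tokens are EEG channels; each token's feature vector is its sequence of time
windows.  Queries, keys and values are linear projections of the inputs into
an ``att_dim``-dimensional space; a final linear layer maps the attended
values back to the input width so the fused map keeps the input shape.

Two variants exist:

* unidirectional (the 62-channel, 10-window configuration): queries come
  from DE, keys and values from PSD;
* bidirectional (the 32-channel, 60-step configuration): the sum of both
  attention directions, ``Atten(f1, f2, f2) + Atten(f2, f1, f1)``, with
  separate projection weights per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["AttentionConfig", "scaled_dot_attention", "CrossModalAttention",
           "MCAFusion", "fuse_all_bands"]


@dataclass
class AttentionConfig:
    in_dim: int = 10
    att_dim: int = 32
    dropout_p: float = 0.3
    bidirectional: bool = False

    def __post_init__(self):
        if self.att_dim < 1:
            raise ValueError("att_dim must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")


def scaled_dot_attention(Q, K, V, dk: int | None = None):
    """``softmax(Q K^T / sqrt(dk)) V`` over the last two axes.

    Accepts plain arrays or autograd tensors (batched or not) and returns
    the same kind.  ``dk`` defaults to the key dimension.
    """
    as_array = not isinstance(Q, Tensor)
    Qt = Q if isinstance(Q, Tensor) else Tensor(np.asarray(Q, dtype=float))
    Kt = K if isinstance(K, Tensor) else Tensor(np.asarray(K, dtype=float))
    Vt = V if isinstance(V, Tensor) else Tensor(np.asarray(V, dtype=float))
    if Qt.shape[-1] != Kt.shape[-1]:
        raise ValueError(
            f"query dim {Qt.shape[-1]} != key dim {Kt.shape[-1]}")
    if Kt.shape[-2] != Vt.shape[-2]:
        raise ValueError(
            f"key count {Kt.shape[-2]} != value count {Vt.shape[-2]}")
    if dk is None:
        dk = Qt.shape[-1]
    scores = (Qt @ Kt.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
    out = scores.softmax(axis=-1) @ Vt
    return out.numpy() if as_array else out


class _DirectedAttention(nn.Module):
    """One attention direction: Q from the first input, K/V from the second,
    attended values projected back to the token width."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.att_dim = cfg.att_dim
        self.q_proj = nn.Linear(cfg.in_dim, cfg.att_dim, rng)
        self.k_proj = nn.Linear(cfg.in_dim, cfg.att_dim, rng)
        self.v_proj = nn.Linear(cfg.in_dim, cfg.att_dim, rng)
        self.out_proj = nn.Linear(cfg.att_dim, cfg.in_dim, rng)

    def forward(self, query_feats: Tensor, context_feats: Tensor) -> Tensor:
        q = self.q_proj(query_feats)
        k = self.k_proj(context_feats)
        v = self.v_proj(context_feats)
        return self.out_proj(scaled_dot_attention(q, k, v, self.att_dim))


class CrossModalAttention(nn.Module):
    """MCA for a single frequency band over (B, channels, windows) maps."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.forward_dir = _DirectedAttention(cfg, rng)
        if cfg.bidirectional:
            self.backward_dir = _DirectedAttention(cfg, rng)
        self.dropout = nn.Dropout(cfg.dropout_p, rng)

    def forward(self, de: Tensor, psd: Tensor) -> Tensor:
        if de.shape != psd.shape:
            raise ValueError(
                f"modality shape mismatch: DE {de.shape} vs PSD {psd.shape}")
        fused = self.forward_dir(de, psd)
        if self.cfg.bidirectional:
            fused = fused + self.backward_dir(psd, de)
        return self.dropout(fused)


class MCAFusion(nn.Module):
    """Independent per-band MCA, outputs stacked back into the 4-D layout.

    ``seed_like`` tensors (B, 5, C, T) carry bands on axis 1; ``deap_like``
    tensors (B, C, 5, T) carry them on axis 2.  The stacked output keeps the
    input layout.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator,
                 n_bands: int = 5, layout: str = "seed_like"):
        super().__init__()
        if layout not in ("seed_like", "deap_like"):
            raise ValueError(f"unknown layout {layout!r}")
        self.layout = layout
        self.n_bands = n_bands
        self.bands = [CrossModalAttention(cfg, rng) for _ in range(n_bands)]
        for i, band in enumerate(self.bands):
            self._modules[f"band{i}"] = band

    @property
    def band_axis(self) -> int:
        return 1 if self.layout == "seed_like" else 2

    def forward(self, de: Tensor, psd: Tensor) -> Tensor:
        de = de if isinstance(de, Tensor) else Tensor(np.asarray(de))
        psd = psd if isinstance(psd, Tensor) else Tensor(np.asarray(psd))
        ax = self.band_axis
        if de.shape != psd.shape:
            raise ValueError(
                f"modality shape mismatch: DE {de.shape} vs PSD {psd.shape}")
        if de.shape[ax] != self.n_bands:
            raise ValueError(
                f"expected {self.n_bands} bands on axis {ax}, got "
                f"{de.shape[ax]}")
        fused = []
        for b in range(self.n_bands):
            idx = (slice(None),) * ax + (b,)
            fused.append(self.bands[b](de[idx], psd[idx]))
        # stack on the band axis: insert a singleton axis per band, concat
        expanded = []
        for f in fused:
            shape = list(f.shape)
            shape.insert(ax, 1)
            expanded.append(f.reshape(*shape))
        return nn.concat(expanded, axis=ax)


def fuse_all_bands(de4d, psd4d, fusion: MCAFusion) -> Tensor:
    """Apply a fitted/initialised :class:`MCAFusion` to matched 4-D DE/PSD
    tensors and return the band-stacked fused tensor."""
    return fusion(de4d, psd4d)
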