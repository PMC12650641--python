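"""Convolution and pooling primitives with hand-written backward passes.

Kernel sizes in this model are tiny (3x3, 7x7 spatial; 5-tap temporal), so the
2-D convolution loops over kernel taps with strided views instead of a full
im2col buffer; the backward pass mirrors the same tap loop.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "depthwise_conv1d", "adaptive_avg_pool2d"]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """Cross-correlation of ``x`` (B,Cin,H,W) with ``weight`` (Cout,Cin,kh,kw)."""
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d: input has {Cin} channels, kernel expects {Cin_w}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((B, Cout, Ho, Wo), dtype=x.dtype)
    # out[b,k] = sum_{c,m,n} w[k,c,m,n] * xp[b,c,i+m,j+n]  (+ bias)
    for m in range(kh):
        for n in range(kw):
            patch = xp[:, :, m:m + Ho, n:n + Wo].reshape(B, Cin, -1)
            out += np.einsum("kc,bcl->bkl", weight.data[:, :, m, n], patch,
                             optimize=True).reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out += bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gx_pad = np.zeros_like(xp) if x.requires_grad else None
        for m in range(kh):
            for n in range(kw):
                patch = xp[:, :, m:m + Ho, n:n + Wo]
                if weight.requires_grad:
                    gw = np.einsum("bkl,bcl->kc", g.reshape(B, Cout, -1),
                                   patch.reshape(B, Cin, -1), optimize=True)
                    if weight.grad is None:
                        weight.grad = np.zeros_like(weight.data)
                    weight.grad[:, :, m, n] += gw
                if gx_pad is not None:
                    gx_pad[:, :, m:m + Ho, n:n + Wo] += np.einsum(
                        "kc,bkl->bcl", weight.data[:, :, m, n],
                        g.reshape(B, Cout, -1), optimize=True
                    ).reshape(B, Cin, Ho, Wo)
        if gx_pad is not None:
            x._accumulate(gx_pad[:, :, p:p + H, p:p + W])

    return Tensor._make(out, parents, backward)


def depthwise_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     padding: int) -> Tensor:
    """Per-channel 1-D convolution: x (B,C,T), weight (C,k) -> (B,C,T')."""
    B, C, T = x.shape
    Cw, k = weight.shape
    if C != Cw:
        raise ValueError(f"depthwise_conv1d: {C} channels vs kernel {Cw}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    To = T + 2 * p - k + 1
    out = np.zeros((B, C, To), dtype=x.dtype)
    for tap in range(k):
        out += weight.data[None, :, tap:tap + 1] * xp[:, :, tap:tap + To]
    if bias is not None:
        out += bias.data.reshape(1, C, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        gx_pad = np.zeros_like(xp) if x.requires_grad else None
        for tap in range(k):
            if weight.requires_grad:
                if weight.grad is None:
                    weight.grad = np.zeros_like(weight.data)
                weight.grad[:, tap] += (g * xp[:, :, tap:tap + To]).sum(axis=(0, 2))
            if gx_pad is not None:
                gx_pad[:, :, tap:tap + To] += weight.data[None, :, tap:tap + 1] * g
        if gx_pad is not None:
            x._accumulate(gx_pad[:, :, p:p + T])

    return Tensor._make(out, parents, backward)


def _pool_bins(n_in: int, n_out: int):
    """Adaptive-pooling bin edges: bin i covers [floor(i*n/o), ceil((i+1)*n/o))."""
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)  # ceil division
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, output_size: tuple[int, int]) -> Tensor:
    """Average-pool (B,C,H,W) to (B,C,Ho,Wo) with adaptive, possibly
    overlapping bins; upsamples by bin replication when the target exceeds
    the input size."""
    B, C, H, W = x.shape
    Ho, Wo = output_size
    hs, he = _pool_bins(H, Ho)
    ws, we = _pool_bins(W, Wo)
    out = np.empty((B, C, Ho, Wo), dtype=x.dtype)
    for i in range(Ho):
        row = x.data[:, :, hs[i]:he[i], :]
        for j in range(Wo):
            out[:, :, i, j] = row[:, :, :, ws[j]:we[j]].mean(axis=(2, 3))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(Ho):
            for j in range(Wo):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += (
                    g[:, :, i:i + 1, j:j + 1] / area
                )
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)
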