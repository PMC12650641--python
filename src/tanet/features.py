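"""Per-band differential-entropy and power-spectral-density features.

EEG trials are decomposed into the five canonical rhythm bands with
zero-phase 4th-order Butterworth filters; within sliding windows each band
yields either

* **DE** — the Gaussian differential entropy ``0.5 * ln(2 * pi * e * var)``
  of the band-limited window (nats, natural log), or
* **PSD** — the mean Welch spectral density over the band's frequency range
  (Hann-windowed 2-s segments, 50 % overlap, averaged periodograms).

Features are stacked to the (trials, bands, channels, windows) tensor the
network consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datatypes import (BandDefinition, BandFeatureTensor, DEFAULT_BANDS,
                        RawEEGDataset)

__all__ = ["WelchConfig", "bandpass_decompose", "differential_entropy",
           "welch_psd", "extract_features", "read_edf"]

logger = logging.getLogger(__name__)

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))


@dataclass
class WelchConfig:
    """Welch estimator settings: Hann-windowed segments of ``segment_s``
    seconds with fractional overlap ``overlap_frac``."""

    fs: float
    segment_s: float = 2.0
    overlap_frac: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.nperseg < 8:
            raise ValueError("segment too short: need segment_s * fs >= 8")

    @property
    def nperseg(self) -> int:
        return int(round(self.segment_s * self.fs))

    @property
    def noverlap(self) -> int:
        return int(self.nperseg * self.overlap_frac)

    @property
    def window_weight(self) -> float:
        """Energy of the Hann window (sum of squared taps) — the periodogram
        normaliser."""
        return float((sps.get_window("hann", self.nperseg) ** 2).sum())


def bandpass_decompose(x: np.ndarray, bands=DEFAULT_BANDS, fs: float = 200.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase band-pass copies of ``x`` (filtered forward and backward),
    one per band, stacked on a new leading axis."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty((len(bands),) + x.shape)
    for i, band in enumerate(bands):
        if band.f_hi >= fs / 2.0:
            raise ValueError(
                f"band {band.name!r} upper edge {band.f_hi} Hz is at or above "
                f"the Nyquist frequency {fs / 2.0} Hz")
        sos = sps.butter(order, [band.f_lo, band.f_hi], btype="bandpass",
                         fs=fs, output="sos")
        out[i] = sps.sosfiltfilt(sos, x, axis=-1)
    return out


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy of a band-limited window, in nats:
    ``0.5 * ln(2 * pi * e * var)`` with the sample variance (ddof=1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if x.max() == x.min():
        raise ValueError("degenerate window: zero variance, entropy undefined")
    var = float(x.var(ddof=1))
    return 0.5 * (_LN_2PIE + np.log(var))


def _de_from_variance(var: np.ndarray) -> np.ndarray:
    return 0.5 * (_LN_2PIE + np.log(var))


def welch_psd(x: np.ndarray, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Welch spectral density of ``x`` along its last axis.

    Hann-windowed periodograms, each normalised by the window energy, are
    averaged over all (overlapping) segments.  Returns ``(frequencies,
    density)`` with density in power per Hz.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < cfg.nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is shorter than one Welch "
            f"segment ({cfg.nperseg} samples)")
    freqs, psd = sps.welch(x, fs=cfg.fs, window="hann", nperseg=cfg.nperseg,
                           noverlap=cfg.noverlap, detrend=False,
                           scaling="density", axis=-1)
    return freqs, psd


def extract_features(raw: RawEEGDataset, bands=DEFAULT_BANDS,
                     window_s: float = 6.0, modality: str = "DE",
                     welch_cfg: WelchConfig | None = None) -> BandFeatureTensor:
    """Window every trial and compute per-band features.

    Output is (trials, bands, channels, n_windows) with
    ``n_windows = floor(duration / window_s)``; trailing samples that do not
    fill a window are dropped.
    """
    if modality not in ("DE", "PSD"):
        raise ValueError(f"modality must be 'DE' or 'PSD', got {modality!r}")
    n_trials, n_channels, n_samples = raw.signals.shape
    win = int(round(window_s * raw.fs))
    if win > n_samples:
        raise ValueError(
            f"window of {window_s} s ({win} samples) exceeds trial length "
            f"({n_samples} samples)")
    n_windows = n_samples // win
    dropped = n_samples - n_windows * win
    if dropped:
        logger.info("dropping %d trailing samples that do not fill a window",
                    dropped)
    used = raw.signals[:, :, :n_windows * win]

    if modality == "DE":
        banded = np.stack([
            bandpass_decompose(used[t], bands, raw.fs) for t in range(n_trials)
        ])  # (trials, bands, channels, samples)
        windows = banded.reshape(n_trials, len(bands), n_channels, n_windows,
                                 win)
        var = windows.var(axis=-1, ddof=1)
        values = _de_from_variance(np.maximum(var, np.finfo(float).tiny))
    else:
        cfg = welch_cfg or WelchConfig(fs=raw.fs)
        windows = used.reshape(n_trials, n_channels, n_windows, win)
        freqs, dens = welch_psd(windows, cfg)
        values = np.empty((n_trials, len(bands), n_channels, n_windows))
        for i, band in enumerate(bands):
            sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
            if not sel.any():
                raise ValueError(f"no Welch bins fall inside band {band.name!r}")
            values[:, i] = dens[..., sel].mean(axis=-1)

    return BandFeatureTensor(values=values, modality=modality,
                             layout="seed_like", window_s=window_s,
                             band_names=tuple(b.name for b in bands))


def read_edf(path) -> RawEEGDataset:
    """Load a single-trial EDF recording (requires the optional ``mne``
    dependency); the whole record becomes one unlabelled trial."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the 'mne' package "
                          "(install tanet-eeg[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return RawEEGDataset(signals=data[None, :, :], fs=float(raw.info["sfreq"]),
                         labels=np.array([0]))
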