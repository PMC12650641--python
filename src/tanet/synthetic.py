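"""Synthetic EEG and band-feature generators with controllable class structure.

The raw generator emulates the one property emotion decoders exploit:
class-conditional differences in narrow-band oscillatory power.  Each trial
is a sum of band-limited sinusoids — one per canonical band, with amplitude
``base_amplitude * class gain`` — on top of spatially correlated Gaussian
noise.  The feature generator skips the signal level entirely and draws
DE/PSD-shaped tensors whose per-class means separate by a chosen number of
standard deviations on a fixed subset of band x channel cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .datatypes import (BandDefinition, BandFeatureTensor, DEFAULT_BANDS,
                        LAYOUTS, RawEEGDataset)

__all__ = ["SyntheticSpec", "generate_raw_eeg", "generate_feature_dataset",
           "generate_deap_raw_features", "save_raw_dataset", "load_raw_dataset",
           "save_feature_tensor", "load_feature_tensor"]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic raw-EEG dataset.

    ``class_band_gain`` maps class label -> per-band amplitude multipliers
    (one per entry of ``bands``); ``channel_corr`` is the pairwise noise
    correlation achieved by mixing a shared noise source into every channel.
    """

    n_trials_per_class: int = 50
    n_channels: int = 62
    fs: float = 200.0
    duration: float = 60.0
    bands: tuple = DEFAULT_BANDS
    class_band_gain: dict = field(default_factory=lambda: {
        0: (1.0, 1.0, 1.0, 1.0, 1.0),
        1: (1.0, 1.2, 1.5, 1.0, 1.0),
        2: (1.2, 1.0, 0.7, 1.3, 1.0),
    })
    noise_sd: float = 5.0
    channel_corr: float = 0.3
    base_amplitude: float = 10.0
    n_subjects: int = 1
    seed: int = 0

    def validate(self):
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.channel_corr <= 1.0:
            raise ValueError("channel_corr must lie in [0, 1]")
        for band in self.bands:
            if self.fs <= 2.0 * band.f_hi:
                raise ValueError(
                    f"sampling rate {self.fs} Hz is too low for band "
                    f"{band.name!r} (upper edge {band.f_hi} Hz requires "
                    f"fs > {2 * band.f_hi} Hz)")
        for cls, gains in self.class_band_gain.items():
            if len(gains) != len(self.bands):
                raise ValueError(f"class {cls}: need one gain per band")
            if any(g <= 0 for g in gains):
                raise ValueError(f"class {cls}: gains must be positive")


def generate_raw_eeg(spec: SyntheticSpec) -> RawEEGDataset:
    """Draw a seeded raw-EEG dataset according to ``spec``.

    Per trial and band, a sinusoid with frequency uniform in the band and a
    random phase is broadcast coherently to all channels; the noise floor is
    Gaussian with inter-channel correlation ``spec.channel_corr``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_band_gain)
    n_samples = int(round(spec.fs * spec.duration))
    t = np.arange(n_samples) / spec.fs
    n_trials = spec.n_trials_per_class * len(classes)

    signals = np.empty((n_trials, spec.n_channels, n_samples))
    labels = np.empty(n_trials, dtype=np.int64)
    idx = 0
    for cls in classes:
        gains = spec.class_band_gain[cls]
        for _ in range(spec.n_trials_per_class):
            osc = np.zeros(n_samples)
            for band, gain in zip(spec.bands, gains):
                freq = rng.uniform(band.f_lo, band.f_hi)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                osc += spec.base_amplitude * gain * np.sin(
                    2.0 * np.pi * freq * t + phase)
            rho = spec.channel_corr
            shared = rng.standard_normal(n_samples)
            own = rng.standard_normal((spec.n_channels, n_samples))
            noise = spec.noise_sd * (np.sqrt(rho) * shared
                                     + np.sqrt(1.0 - rho) * own)
            signals[idx] = osc + noise
            labels[idx] = cls
            idx += 1

    order = rng.permutation(n_trials)
    subjects = np.arange(n_trials) % spec.n_subjects
    return RawEEGDataset(signals=signals[order], fs=spec.fs,
                         labels=labels[order], subject_ids=subjects)


def _class_shift_mask(layout: str, n_classes: int, cls: int) -> np.ndarray:
    """Deterministic, disjoint band x channel subsets that carry each
    class's mean shift (roughly an eighth of the cells per class)."""
    if layout == "seed_like":
        n_bands, n_channels = 5, 62
    else:
        n_bands, n_channels = 5, 32
    mask = np.zeros((n_bands, n_channels), dtype=bool)
    band = cls % n_bands
    block = n_channels // (2 * n_classes)
    lo = cls * block
    mask[band, lo:lo + block] = True
    mask[(band + 2) % n_bands, lo:lo + block] = True
    return mask


def generate_feature_dataset(layout: str, n_per_class: int, effect_size: float,
                             seed: int, n_classes: int | None = None
                             ) -> tuple[BandFeatureTensor, BandFeatureTensor,
                                        np.ndarray]:
    """Draw matched DE/PSD feature tensors with balanced labels.

    Class means differ by ``effect_size`` standard deviations on a fixed
    subset of band x channel cells (constant across windows).  ``seed_like``
    yields (n, 5, 62, 10) and 3 classes; ``deap_like`` yields (n, 32, 5, 60)
    and 2 classes.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_classes is None:
        n_classes = 3 if layout == "seed_like" else 2
    rng = np.random.default_rng(seed)

    if layout == "seed_like":
        shape = (5, 62, 10)
    else:
        shape = (32, 5, 60)
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)

    de = rng.standard_normal((n,) + shape)
    psd_raw = rng.standard_normal((n,) + shape)
    for cls in range(n_classes):
        mask = _class_shift_mask(layout, n_classes, cls)
        if layout == "seed_like":
            cell = mask[None, :, :, None]          # (1, bands, channels, 1)
        else:
            cell = mask.T[None, :, :, None]        # (1, channels, bands, 1)
        rows = labels == cls
        de[rows] += effect_size * cell
        psd_raw[rows] += effect_size * cell

    order = rng.permutation(n)
    de, psd_raw, labels = de[order], psd_raw[order], labels[order]
    # softplus keeps PSD nonnegative while preserving the mean-shift ordering
    psd = np.logaddexp(0.0, psd_raw)

    de_t = BandFeatureTensor(values=de, modality="DE", layout=layout)
    psd_t = BandFeatureTensor(values=psd, modality="PSD", layout=layout)
    return de_t, psd_t, labels


def generate_deap_raw_features(n_trials: int, effect_size: float, seed: int
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray]:
    """Emulate the pre-extracted DEAP feature layout.

    Returns ``(de, psd, valence, arousal)`` with features shaped
    (n_trials, 32, 5, 58, 4) and per-trial affect scores on the 1-9 scale.
    Trials with scores >= 5 receive the high-class band shifts so the
    binarised task is learnable at the requested effect size.
    """
    rng = np.random.default_rng(seed)
    valence = rng.uniform(1.0, 9.0, size=n_trials)
    arousal = rng.uniform(1.0, 9.0, size=n_trials)
    high = (valence >= 5.0).astype(int)

    de = rng.standard_normal((n_trials, 32, 5, 58, 4))
    psd_raw = rng.standard_normal((n_trials, 32, 5, 58, 4))
    for cls in (0, 1):
        mask = _class_shift_mask("deap_like", 2, cls)     # (5, 32)
        cell = mask.T[None, :, :, None, None]
        rows = high == cls
        de[rows] += effect_size * cell
        psd_raw[rows] += effect_size * cell
    psd = np.logaddexp(0.0, psd_raw)
    return de, psd, valence, arousal


# -- HDF5 round-trips ------------------------------------------------------

def save_raw_dataset(path, dataset: RawEEGDataset):
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=dataset.signals, track_times=False)
        f.create_dataset("labels", data=dataset.labels, track_times=False)
        f.create_dataset("subject_ids", data=dataset.subject_ids, track_times=False)
        f.attrs["meta"] = json.dumps({"fs": dataset.fs})


def load_raw_dataset(path) -> RawEEGDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return RawEEGDataset(signals=f["signals"][...], fs=meta["fs"],
                             labels=f["labels"][...],
                             subject_ids=f["subject_ids"][...])


def save_feature_tensor(path, tensor: BandFeatureTensor,
                        labels: np.ndarray | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values, track_times=False)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels), track_times=False)
        f.attrs["meta"] = json.dumps({
            "modality": tensor.modality, "layout": tensor.layout,
            "window_s": tensor.window_s, "band_names": list(tensor.band_names),
        })


def load_feature_tensor(path) -> tuple[BandFeatureTensor, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        labels = f["labels"][...] if "labels" in f else None
        tensor = BandFeatureTensor(
            values=f["values"][...], modality=meta["modality"],
            layout=meta["layout"], window_s=meta["window_s"],
            band_names=tuple(meta["band_names"]))
    return tensor, labels
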