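"""Shared containers for raw EEG and band-feature tensors.

Two tensor layouts are supported throughout the package, named after the
benchmark conventions they mirror:

* ``seed_like`` — per-trial features shaped (bands, channels, windows),
  stacked to (n, 5, 62, 10) by default: 5 canonical frequency bands,
  62 electrodes, 10 time windows.
* ``deap_like`` — per-trial features shaped (channels, bands, time),
  stacked to (n, 32, 5, 60): 32 electrodes, 5 bands, 60 one-second steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandDefinition", "DEFAULT_BANDS", "RawEEGDataset",
           "BandFeatureTensor", "LAYOUTS"]

LAYOUTS = ("seed_like", "deap_like")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]")


#: Conventional EEG rhythm boundaries (Hz).
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 50.0),
)


@dataclass
class RawEEGDataset:
    """Multichannel EEG in microvolts: ``signals`` is (trials, channels,
    samples) at sampling rate ``fs``; one integer label and subject id per
    trial."""

    signals: np.ndarray
    fs: float
    labels: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (trials, channels, samples)")
        if len(self.labels) != self.signals.shape[0]:
            raise ValueError("one label per trial required")
        if self.subject_ids is None:
            self.subject_ids = np.zeros(self.signals.shape[0], dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.signals.shape[2] / self.fs


@dataclass
class BandFeatureTensor:
    """One modality (DE or PSD) of band features in one of the two layouts.

    ``values`` is (n, 5, channels, windows) for ``seed_like`` and
    (n, channels, 5, time) for ``deap_like``.  DE values are unbounded reals
    (nats); PSD values are nonnegative.
    """

    values: np.ndarray
    modality: str
    layout: str = "seed_like"
    window_s: float = 1.0
    band_names: tuple = tuple(b.name for b in DEFAULT_BANDS)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.modality not in ("DE", "PSD"):
            raise ValueError(f"modality must be 'DE' or 'PSD', got {self.modality}")
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected {LAYOUTS}")
        if self.values.ndim != 4:
            raise ValueError("feature tensor must be 4-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature tensor contains non-finite values")
        if self.modality == "PSD" and (self.values < 0).any():
            raise ValueError("PSD features must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]
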