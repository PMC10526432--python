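"""Shared containers for multichannel EEG data.

A :class:`Recording` holds one subject's continuous multichannel signal;
an :class:`EpochSet` holds the fixed-length overlapping segments cut from
it, optionally restricted to a named rhythm band.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 16-channel subset of the 10-20 montage used throughout.
MONTAGE_16 = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG rhythm band: ``name`` with edges ``f_low``..``f_high`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


#: Canonical rhythm bands: theta, alpha1, alpha2, beta.
CANONICAL_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

BAND_NAMES = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    ``data`` is channels x samples in microvolts; row i is channel
    ``channel_names[i]``.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = MONTAGE_16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("Recording.data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Fixed-length overlapping segments from one recording.

    ``epochs`` is epochs x channels x samples; ``band`` is a rhythm name
    or ``"broadband"`` before rhythm extraction.
    """

    subject_id: str
    group: str
    band: str
    epochs: np.ndarray
    fs: float
    window: float
    step: float
    channel_names: tuple[str, ...] = MONTAGE_16

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("EpochSet.epochs must be 3-D")
        n_samp = int(round(self.window * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != n_samp:
            raise ValueError(
                f"epochs have {self.epochs.shape[2]} samples, "
                f"expected window*fs = {n_samp}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]
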