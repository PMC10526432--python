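"""Continuous recordings -> band-specific overlapping epochs.

Fixed pipeline order: downsample (250 -> 125 Hz) -> baseline removal ->
broadband 4-30 Hz Butterworth band-pass -> segmentation into 4 s windows
with 2 s overlap -> per-epoch rhythm extraction (theta, alpha1, alpha2,
beta) with the same filter design.

All filters are fourth-order Butterworth applied forward-backward
(zero phase). Zero-phase application matters here: a causal filter would
distort instantaneous phase and hence the phase-lag connectivity
computed downstream. The effective magnitude response is the square of
the design response.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .core import CANONICAL_BANDS, BandDefinition, EpochSet, Recording

DEFAULT_TARGET_FS = 125.0
DEFAULT_WINDOW = 4.0
DEFAULT_STEP = 2.0
DEFAULT_ORDER = 4
DEFAULT_BROADBAND = (4.0, 30.0)


def downsample(rec: Recording, target_fs: float = DEFAULT_TARGET_FS) -> Recording:
    """Anti-alias low-pass then decimate to ``target_fs``.

    The anti-alias filter is an eighth-order zero-phase low-pass at
    0.8 x the target Nyquist, which leaves the 4-30 Hz analysis band
    untouched at 125 Hz. Requires an integer decimation factor.
    """
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.fs} is not an integer multiple of {target_fs}"
        )
    if q == 1:
        return rec.copy_with(data=rec.data.copy())
    cutoff = 0.8 * (target_fs / 2.0)
    sos = signal.butter(8, cutoff, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=filtered[:, ::q], fs=target_fs)


def remove_baseline(rec: Recording) -> Recording:
    """Subtract each channel's mean."""
    return rec.copy_with(data=rec.data - rec.data.mean(axis=-1, keepdims=True))


def _bandpass_sos(f_low: float, f_high: float, fs: float, order: int):
    nyq = fs / 2.0
    if not 0 < f_low < f_high < nyq:
        raise ValueError(
            f"band ({f_low}, {f_high}) Hz invalid for fs={fs} (Nyquist {nyq})"
        )
    return signal.butter(order, (f_low, f_high), btype="bandpass", fs=fs,
                         output="sos")


def bandpass(rec: Recording, f_low: float = DEFAULT_BROADBAND[0],
             f_high: float = DEFAULT_BROADBAND[1],
             order: int = DEFAULT_ORDER) -> Recording:
    """Zero-phase Butterworth band-pass of the stated design order."""
    sos = _bandpass_sos(f_low, f_high, rec.fs, order)
    return rec.copy_with(data=signal.sosfiltfilt(sos, rec.data, axis=-1))


def segment(rec: Recording, window: float = DEFAULT_WINDOW,
            step: float = DEFAULT_STEP) -> EpochSet:
    """Cut overlapping epochs; count = floor((T - window)/step) + 1.

    Only full windows are kept (no padding of a trailing partial window).
    """
    w = window * rec.fs
    s = step * rec.fs
    if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError("window*fs and step*fs must be integer sample counts")
    w, s = int(round(w)), int(round(s))
    n = rec.n_samples
    if n < w:
        raise ValueError(
            f"recording of {n} samples shorter than one {w}-sample window"
        )
    n_epochs = (n - w) // s + 1
    starts = np.arange(n_epochs) * s
    epochs = np.stack([rec.data[:, st:st + w] for st in starts])
    return EpochSet(subject_id=rec.subject_id, group=rec.group,
                    band="broadband", epochs=epochs, fs=rec.fs,
                    window=window, step=step, channel_names=rec.channel_names)


def extract_rhythms(es: EpochSet,
                    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                    order: int = DEFAULT_ORDER) -> dict[str, EpochSet]:
    """Band-limit every epoch with the same Butterworth design, per band.

    Filtering is applied per-epoch (each 4 s segment filtered on its
    own), accepting short edge transients on 500-sample epochs.
    """
    out: dict[str, EpochSet] = {}
    for band in bands:
        sos = _bandpass_sos(band.f_low, band.f_high, es.fs, order)
        if es.n_epochs:
            filtered = signal.sosfiltfilt(sos, es.epochs, axis=-1)
        else:
            filtered = es.epochs.copy()
        out[band.name] = EpochSet(subject_id=es.subject_id, group=es.group,
                                  band=band.name, epochs=filtered, fs=es.fs,
                                  window=es.window, step=es.step,
                                  channel_names=es.channel_names)
    return out


def preprocess_recording(rec: Recording,
                         target_fs: float = DEFAULT_TARGET_FS,
                         broadband: tuple[float, float] = DEFAULT_BROADBAND,
                         window: float = DEFAULT_WINDOW,
                         step: float = DEFAULT_STEP,
                         order: int = DEFAULT_ORDER,
                         bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                         ) -> dict[str, EpochSet]:
    """Full pipeline for one recording; returns band -> EpochSet."""
    rec = downsample(rec, target_fs)
    rec = remove_baseline(rec)
    rec = bandpass(rec, *broadband, order=order)
    es = segment(rec, window=window, step=step)
    return extract_rhythms(es, bands=bands, order=order)
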