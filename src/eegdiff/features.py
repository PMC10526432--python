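"""Per-epoch EEG features: band power, fuzzy entropy, phase lag index.

Three estimator families, each computed per band-limited epoch:

* **Band power** — rectangular-window FFT periodogram P_x(f) = |X(f)|^2 / N,
  integrated over the band and divided by its width (so a flat spectrum
  of height c yields band power c for any band).
* **Fuzzy entropy** — FE(m, r, N) = ln phi_m(r) - ln phi_{m+1}(r), where
  phi_m averages the fuzzy similarity exp(-ln2 * (d_ij / r)^2) of all
  pairs of mean-removed length-m delay vectors, with d_ij the Chebyshev
  distance. Higher FE = more irregular signal.
* **PLI** — the absolute time-average of the sign of the wrapped
  instantaneous-phase difference between two channels, phases taken from
  the Hilbert analytic signal. 0 = no consistent lag asymmetry, 1 = a
  perfectly consistent nonzero lag; blind to zero-lag coupling.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.spatial.distance import pdist

from .core import BandDefinition, EpochSet

DEFAULT_EDGE_TRIM = 0.1


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided periodogram: ``power`` on the frequency grid ``freqs``."""

    freqs: np.ndarray
    power: np.ndarray
    n: int


@dataclass(frozen=True)
class FEParams:
    """Fuzzy-entropy parameters.

    ``r`` is the similarity width; with ``r_mode='relative'`` (default)
    it is a fraction of the epoch's standard deviation, with
    ``'absolute'`` it is in signal units.
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "relative"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("similarity width r must be > 0")
        if self.r_mode not in ("relative", "absolute"):
            raise ValueError("r_mode must be 'relative' or 'absolute'")


def periodogram(x: np.ndarray, fs: float) -> SpectrumEstimate:
    """Squared-magnitude FFT periodogram, one-sided.

    Interior bins are doubled so the bin-sum equals the signal energy
    sum(x^2) (Parseval with the one-sided convention).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("periodogram needs at least 2 samples")
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    # one-sided doubling; DC and (for even n) Nyquist appear once
    scale = np.full(spec.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumEstimate(freqs=freqs, power=spec * scale, n=n)


def band_power(spec: SpectrumEstimate, band: BandDefinition) -> float:
    """Bandwidth-normalised trapezoidal integral of the periodogram."""
    f, p = spec.freqs, spec.power
    if band.f_low < f[0] - 1e-12 or band.f_high > f[-1] + 1e-12:
        raise ValueError(
            f"band {band.name!r} ({band.f_low}-{band.f_high} Hz) outside "
            f"spectral grid 0-{f[-1]:.3g} Hz"
        )
    lo, hi = band.f_low, band.f_high
    inside = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inside], [hi]))
    vals = np.concatenate(([np.interp(lo, f, p)], p[inside],
                           [np.interp(hi, f, p)]))
    return float(np.trapezoid(vals, grid) / (hi - lo))


def _phi(vectors: np.ndarray, r: float) -> float:
    """Mean pairwise fuzzy similarity over mean-removed delay vectors.

    Self-matches are excluded; the condensed (upper-triangle) distance
    matrix suffices since the similarity is symmetric.
    """
    d = pdist(vectors, metric="chebyshev")
    sim = np.exp(-np.log(2.0) * (d / r) ** 2)
    n = vectors.shape[0]
    return float(2.0 * sim.sum() / (n * (n - 1)))


def _delay_vectors(x: np.ndarray, m: int, count: int) -> np.ndarray:
    idx = np.arange(count)[:, None] + np.arange(m)[None, :]
    v = x[idx]
    return v - v.mean(axis=1, keepdims=True)


def fuzzy_entropy(x: np.ndarray, params: FEParams = FEParams()) -> float:
    """FE(m, r, N) = ln phi_m - ln phi_{m+1}.

    Uses N - m delay vectors for both embedding dimensions, self-matches
    excluded. A zero-variance series has FE = 0 by convention (all delay
    vectors coincide, all similarities are 1).
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = x.std()
    if params.r_mode == "relative":
        if sd == 0:
            return 0.0
        r = params.r * sd
    else:
        r = params.r
    count = n - m  # same vector count for m and m+1
    phi_m = _phi(_delay_vectors(x, m, count), r)
    phi_m1 = _phi(_delay_vectors(x, m + 1, count), r)
    return float(np.log(phi_m) - np.log(phi_m1))


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase (rad) and amplitude from the analytic signal."""

    phase: np.ndarray
    amplitude: np.ndarray


def analytic_phase(x: np.ndarray) -> PhaseSeries:
    """Hilbert-transform analytic signal -> instantaneous phase/amplitude."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("analytic signal needs at least 4 samples")
    z = hilbert(x)
    return PhaseSeries(phase=np.angle(z), amplitude=np.abs(z))


def pli(phase_k: PhaseSeries | np.ndarray, phase_l: PhaseSeries | np.ndarray,
        edge_trim: float = DEFAULT_EDGE_TRIM) -> float:
    """Phase lag index: |< sign(wrap(phi_k - phi_l)) >_t| in [0, 1].

    ``edge_trim`` discards that fraction of samples at each end before
    averaging (Hilbert edge effects); phase differences are wrapped to
    (-pi, pi] before taking the sign, and sign(0) = 0.
    """
    pk = phase_k.phase if isinstance(phase_k, PhaseSeries) else np.asarray(phase_k)
    pl = phase_l.phase if isinstance(phase_l, PhaseSeries) else np.asarray(phase_l)
    if pk.shape != pl.shape:
        raise ValueError("phase series lengths differ")
    if not 0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must be in [0, 0.5)")
    n = pk.size
    k = int(np.floor(edge_trim * n))
    sl = slice(k, n - k if k else n)
    diff = pk[sl] - pl[sl]
    wrapped = np.angle(np.exp(1j * diff))
    return float(abs(np.mean(np.sign(wrapped))))


# ---------------------------------------------------------------------------
# feature-table assembly

FEATURE_FAMILIES = ("PSD", "FE", "PLI")
META_COLUMNS = ("subject_id", "group", "epoch")


def feature_columns(channel_names, bands) -> list[str]:
    """Structured column names: PSD_<band>_<ch>, FE_<band>_<ch>,
    PLI_<band>_<ch1>-<ch2> over all unordered channel pairs."""
    cols = []
    for band in bands:
        cols += [f"PSD_{band}_{ch}" for ch in channel_names]
        cols += [f"FE_{band}_{ch}" for ch in channel_names]
        cols += [f"PLI_{band}_{a}-{b}" for a, b in combinations(channel_names, 2)]
    return cols


def _epoch_features(epoch: np.ndarray, fs: float, band: BandDefinition,
                    fe_params: FEParams, edge_trim: float,
                    families: tuple[str, ...]) -> list[float]:
    n_ch = epoch.shape[0]
    row: list[float] = []
    if "PSD" in families:
        row += [band_power(periodogram(epoch[c], fs), band) for c in range(n_ch)]
    if "FE" in families:
        row += [fuzzy_entropy(epoch[c], fe_params) for c in range(n_ch)]
    if "PLI" in families:
        phases = np.angle(hilbert(epoch, axis=-1))
        row += [pli(phases[a], phases[b], edge_trim)
                for a, b in combinations(range(n_ch), 2)]
    return row


def build_feature_table(band_epochs: dict[str, EpochSet],
                        fe_params: FEParams = FEParams(),
                        edge_trim: float = DEFAULT_EDGE_TRIM,
                        bands: tuple[BandDefinition, ...] | None = None,
                        families: tuple[str, ...] = FEATURE_FAMILIES,
                        ) -> pd.DataFrame:
    """One row per epoch of one subject; columns per band and family.

    ``band_epochs`` maps band name -> band-limited EpochSet for a single
    subject (all sets aligned: same epoch count and channel order).
    ``families`` restricts computation to a subset of (PSD, FE, PLI).
    """
    from .core import CANONICAL_BANDS

    band_defs = {b.name: b for b in (bands or CANONICAL_BANDS)}
    names = [n for n in band_defs if n in band_epochs]
    if not names:
        raise ValueError("no requested band present in band_epochs")
    first = band_epochs[names[0]]
    counts = {band_epochs[n].n_epochs for n in names}
    subjects = {band_epochs[n].subject_id for n in names}
    if len(counts) != 1 or len(subjects) != 1:
        raise ValueError("band epoch sets are misaligned")

    cols: list[str] = []
    ch = first.channel_names
    for name in names:
        if "PSD" in families:
            cols += [f"PSD_{name}_{c}" for c in ch]
        if "FE" in families:
            cols += [f"FE_{name}_{c}" for c in ch]
        if "PLI" in families:
            cols += [f"PLI_{name}_{a}-{b}" for a, b in combinations(ch, 2)]

    rows = []
    for e in range(first.n_epochs):
        row: list[float] = []
        for name in names:
            es = band_epochs[name]
            row += _epoch_features(es.epochs[e], es.fs, band_defs[name],
                                   fe_params, edge_trim, families)
        rows.append(row)

    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "epoch", np.arange(first.n_epochs))
    df.insert(0, "group", first.group)
    df.insert(0, "subject_id", first.subject_id)
    return df


def cohort_feature_table(per_subject_bands, **kw) -> pd.DataFrame:
    """Concatenate per-subject feature tables (list of band -> EpochSet)."""
    tables = [build_feature_table(be, **kw) for be in per_subject_bands]
    return pd.concat(tables, ignore_index=True)


def split_feature_id(col: str) -> tuple[str, str, str]:
    """'PLI_beta_C3-P4' -> ('PLI', 'beta', 'C3-P4')."""
    family, band, target = col.split("_", 2)
    return family, band, target
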