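"""Synthetic two-group resting-state EEG cohorts.

Generates 16-channel recordings whose statistical structure mirrors what
the downstream analysis measures: a 1/f (pink) background band-limited to
0.5-30 Hz, per-band narrowband oscillators with random-walk phase jitter
(the irregularity knob raises signal complexity without moving band
power much), and optional pairwise phase coupling through a shared
oscillator injected into two channels at a fixed lag.

Group differences are expressed entirely through the config: per-group
band amplitudes (band power), per-group irregularity (entropy), and
per-group coupling strengths (phase-lag connectivity). Nothing here is a
claim about patient physiology; it is a generative ground truth against
which estimator recovery can be verified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BAND_NAMES, CANONICAL_BANDS, MONTAGE_16, Recording

#: Band edges for the oscillators, keyed by rhythm name.
_BAND_EDGES = {b.name: (b.f_low, b.f_high) for b in CANONICAL_BANDS}


def _draw_band_freq(rng: np.random.Generator, band: str) -> float:
    """A per-oscillator frequency from the central half of the band.

    Each independent oscillator gets its own frequency, so phases of
    uncoupled channels drift apart within a 4 s epoch instead of staying
    spuriously locked (distinct individual peak frequencies are also the
    realistic condition).
    """
    lo, hi = _BAND_EDGES[band]
    margin = 0.25 * (hi - lo)
    return float(rng.uniform(lo + margin, hi - margin))

#: Band-limit of the simulated background, matching a 0.5-30 Hz recording filter.
_NOISE_BAND = (0.5, 30.0)


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling between two channels in one band.

    The two channels share a common band oscillator injected at a
    constant phase ``lag``; ``strength`` maps group label -> mixing
    coefficient in [0, 1] (1 = the channel's band component is entirely
    the shared oscillator, 0 = fully independent).
    """

    channel_pair: tuple[str, str]
    band: str
    lag: float
    strength: dict[str, float]

    def __post_init__(self) -> None:
        a, b = self.channel_pair
        if a == b:
            raise ValueError("coupling channel labels must be distinct")
        if self.band not in _BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")
        for g, s in self.strength.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"coupling strength for {g!r} outside [0, 1]")


def _uniform_band_map(groups: tuple[str, str], value: float) -> dict:
    return {g: {b: value for b in BAND_NAMES} for g in groups}


@dataclass
class CohortConfig:
    """Study conditions for a two-group synthetic cohort.

    Defaults mirror the recording protocol the analysis targets: two
    groups of 38 and 34 subjects, 10 minutes of 16-channel EEG at
    250 Hz with 0.5-30 Hz content.
    """

    n_group_a: int = 38
    n_group_b: int = 34
    group_names: tuple[str, str] = ("GAD", "DD")
    duration: float = 600.0
    fs: float = 250.0
    channel_names: tuple[str, ...] = MONTAGE_16
    #: group -> band -> oscillator amplitude (uV).
    band_amp: dict = None
    noise_exponent: float = 1.0
    noise_scale: float = 8.0
    coupling: list = field(default_factory=list)
    #: group -> band -> phase random-walk step s.d. (rad/sample).
    irregularity: dict = None
    #: s.d. of the per-subject lognormal amplitude factor (per band).
    amp_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_amp is None:
            self.band_amp = _uniform_band_map(self.group_names, 4.0)
        if self.irregularity is None:
            self.irregularity = _uniform_band_map(self.group_names, 0.1)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def validate(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 subjects")
        if abs(self.duration * self.fs - round(self.duration * self.fs)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for g in self.group_names:
            for b in BAND_NAMES:
                if self.band_amp[g][b] < 0:
                    raise ValueError("band amplitudes must be >= 0")
        seen: set[tuple[str, str]] = set()
        for cs in self.coupling:
            for ch in cs.channel_pair:
                if ch not in self.channel_names:
                    raise ValueError(
                        f"coupling references channel {ch!r} absent from montage"
                    )
                key = (cs.band, ch)
                if key in seen:
                    raise ValueError(
                        f"channel {ch!r} appears in more than one coupling "
                        f"spec for band {cs.band!r}"
                    )
                seen.add(key)

    def group_sizes(self) -> dict[str, int]:
        return {self.group_names[0]: self.n_group_a,
                self.group_names[1]: self.n_group_b}


def _subject_seed_seq(config: CohortConfig, group: str, subject_index: int,
                      ) -> np.random.SeedSequence:
    # Counter-based derivation: independent of generation order.
    gi = config.group_names.index(group)
    return np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, subject_index))


def _pink_background(rng: np.random.Generator, n: int, fs: float,
                     exponent: float, scale: float) -> np.ndarray:
    """Spectrally shaped noise: |H(f)| ~ f^(-exponent/2... ) on 0.5-30 Hz."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f)
    lo, hi = _NOISE_BAND
    in_band = (f >= lo) & (f <= hi)
    gain[in_band] = f[in_band] ** (-exponent / 2.0)  # power ~ 1/f^exponent
    shaped = np.fft.irfft(spec * gain, n=n)
    sd = shaped.std()
    if sd > 0:
        shaped *= scale / sd
    return shaped


def _jittered_phase(rng: np.random.Generator, n: int, fs: float, f0: float,
                    jitter: float) -> np.ndarray:
    """Instantaneous phase of an oscillator at f0 with random-walk jitter."""
    phase0 = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    walk = np.cumsum(rng.standard_normal(n)) * jitter if jitter > 0 else 0.0
    return 2 * np.pi * f0 * t + phase0 + walk


def generate_recording(config: CohortConfig, group: str, subject_index: int,
                       seed: int | np.random.SeedSequence | None = None,
                       ) -> Recording:
    """Generate one subject's recording.

    Deterministic given (config.seed, group, subject_index); passing
    ``seed`` overrides the derived per-subject stream.
    """
    if group not in config.group_names:
        raise ValueError(f"unknown group label {group!r}")
    if seed is None:
        seed = _subject_seed_seq(config, group, subject_index)
    rng = np.random.default_rng(seed)

    n = config.n_samples
    n_ch = len(config.channel_names)
    ch_index = {c: i for i, c in enumerate(config.channel_names)}
    data = np.empty((n_ch, n))

    # Per-subject lognormal amplitude factors, drawn per (band, channel):
    # between-subject variance exists for every feature, and no single
    # draw moves a whole band coherently across the scalp.
    subj_scale = {
        b: np.exp(rng.normal(0.0, config.amp_sigma, size=n_ch))
        for b in BAND_NAMES
    }

    for i in range(n_ch):
        data[i] = _pink_background(rng, n, config.fs, config.noise_exponent,
                                   config.noise_scale)

    # Which (band, channel) slots are claimed by a coupling spec.
    coupled: dict[tuple[str, str], tuple[CouplingSpec, int]] = {}
    for cs in config.coupling:
        for pos, ch in enumerate(cs.channel_pair):
            coupled[(cs.band, ch)] = (cs, pos)

    shared_phase: dict[int, np.ndarray] = {}
    for k, cs in enumerate(config.coupling):
        jitter = config.irregularity[group][cs.band]
        shared_phase[k] = _jittered_phase(rng, n, config.fs,
                                          _draw_band_freq(rng, cs.band), jitter)

    for band in BAND_NAMES:
        jitter = config.irregularity[group][band]
        for ch in config.channel_names:
            amp = config.band_amp[group][band] * subj_scale[band][ch_index[ch]]
            own = np.cos(_jittered_phase(rng, n, config.fs,
                                         _draw_band_freq(rng, band), jitter))
            if (band, ch) in coupled:
                cs, pos = coupled[(band, ch)]
                s = cs.strength[group]
                k = config.coupling.index(cs)
                lag = 0.0 if pos == 0 else cs.lag
                shared = np.cos(shared_phase[k] - lag)
                comp = (1.0 - s) * own + s * shared
            else:
                comp = own
            if amp > 0:
                data[ch_index[ch]] += amp * comp

    sid = f"{group}{subject_index + 1:02d}"
    return Recording(subject_id=sid, group=group, data=data, fs=config.fs,
                     channel_names=config.channel_names)


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate the full two-group cohort (group A first, then group B)."""
    out = []
    for group, size in config.group_sizes().items():
        for idx in range(size):
            out.append(generate_recording(config, group, idx))
    return out


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Study-condition defaults with the qualitative group structure the
    analysis looks for: group B (DD-like) has elevated alpha1/beta power,
    a more irregular beta band, and band-specific connectivity
    differences in both directions.
    """
    g_a, g_b = "GAD", "DD"
    amp = {
        g_a: {"theta": 4.0, "alpha1": 6.0, "alpha2": 5.0, "beta": 3.0},
        g_b: {"theta": 4.0, "alpha1": 7.8, "alpha2": 5.0, "beta": 4.2},
    }
    irr = {
        g_a: {"theta": 0.10, "alpha1": 0.10, "alpha2": 0.10, "beta": 0.08},
        g_b: {"theta": 0.10, "alpha1": 0.10, "alpha2": 0.10, "beta": 0.16},
    }
    coupling = [
        # band, pair, stronger group; directions mixed as in the target
        # differential networks (group B higher except in alpha2).
        CouplingSpec(("F3", "C3"), "theta", np.pi / 3, {g_a: 0.2, g_b: 0.7}),
        CouplingSpec(("F4", "P4"), "theta", np.pi / 4, {g_a: 0.6, g_b: 0.2}),
        CouplingSpec(("FP1", "F7"), "alpha1", np.pi / 3, {g_a: 0.2, g_b: 0.7}),
        CouplingSpec(("O1", "P3"), "alpha2", np.pi / 4, {g_a: 0.7, g_b: 0.3}),
        CouplingSpec(("C4", "T4"), "beta", np.pi / 3, {g_a: 0.15, g_b: 0.7}),
        CouplingSpec(("F7", "T3"), "beta", np.pi / 4, {g_a: 0.2, g_b: 0.65}),
        CouplingSpec(("P3", "T5"), "beta", np.pi / 3, {g_a: 0.6, g_b: 0.2}),
    ]
    return CohortConfig(band_amp=amp, irregularity=irr, coupling=coupling,
                        seed=seed)
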