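"""Feature estimators: periodogram, band power, fuzzy entropy, PLI, table."""
import math

import numpy as np
import pytest

from eegdiff.core import BandDefinition, EpochSet
from eegdiff.features import (FEParams, SpectrumEstimate, analytic_phase,
                              band_power, build_feature_table, fuzzy_entropy,
                              periodogram, pli)

FS = 125.0
BETA = BandDefinition("beta", 13.0, 30.0)
THETA = BandDefinition("theta", 4.0, 8.0)


def _sine(f, seconds=4.0, amp=1.0, phase=0.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * f * t + phase)


# --------------------------------------------------------------------- PSD

class TestPeriodogram:
    def test_zero_in_zero_out(self):
        assert np.all(periodogram(np.zeros(500), FS).power == 0.0)

    def test_sinusoid_concentrates_in_one_bin(self):
        # 20 Hz with integer cycles in a 4 s window -> exactly on-bin
        x = _sine(20.0)
        spec = periodogram(x, FS)
        peak_bin = np.argmax(spec.power)
        assert spec.freqs[peak_bin] == pytest.approx(20.0)
        off = np.delete(spec.power, peak_bin)
        assert off.max() < 1e-10 * spec.power[peak_bin]

    def test_parseval(self):
        x = np.random.default_rng(0).standard_normal(501)
        spec = periodogram(x, FS)
        energy = np.sum(x**2)
        assert abs(spec.power.sum() - energy) / energy < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.array([1.0]), FS)


class TestBandPower:
    def test_zero_spectrum(self):
        spec = periodogram(np.zeros(500), FS)
        assert band_power(spec, BETA) == 0.0

    def test_flat_spectrum_normalisation_cancels(self):
        f = np.linspace(0, FS / 2, 251)
        spec = SpectrumEstimate(freqs=f, power=np.full_like(f, 3.7), n=500)
        for band in (BETA, THETA, BandDefinition("x", 5.5, 21.25)):
            assert band_power(spec, band) == pytest.approx(3.7)

    def test_sinusoid_band_selectivity(self):
        spec = periodogram(_sine(20.0), FS)
        assert band_power(spec, BETA) / max(band_power(spec, THETA), 1e-300) > 1e3

    def test_band_outside_grid_rejected(self):
        spec = periodogram(np.zeros(500), FS)
        with pytest.raises(ValueError, match="outside"):
            band_power(spec, BandDefinition("hf", 50.0, 70.0))


# --------------------------------------------------------------------- FE

def fuzzy_entropy_naive(x, m=2, r_frac=0.2):
    """Independent double-loop reference implementation."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * x.std()

    def phi(mm):
        cnt = n - m
        vs = []
        for i in range(cnt):
            v = x[i:i + mm]
            vs.append(v - v.mean())
        acc = 0.0
        for i in range(cnt):
            s = 0.0
            for j in range(cnt):
                if j == i:
                    continue
                d = max(abs(vs[i] - vs[j]))
                s += math.exp(-math.log(2.0) * (d / r) ** 2)
            acc += s / (cnt - 1)
        return acc / cnt

    return math.log(phi(m)) - math.log(phi(m + 1))


class TestFuzzyEntropy:
    def test_constant_series_is_zero(self):
        assert fuzzy_entropy(np.full(100, 2.5)) == 0.0

    def test_agrees_with_naive_double_loop(self):
        rng = np.random.default_rng(7)
        for x in rng.standard_normal((20, 50)):
            assert fuzzy_entropy(x) == pytest.approx(fuzzy_entropy_naive(x),
                                                     abs=1e-10)

    def test_noise_more_irregular_than_sinusoid(self):
        rng = np.random.default_rng(3)
        sin_fe = fuzzy_entropy(_sine(10.0))
        wins = sum(fuzzy_entropy(rng.standard_normal(500)) > sin_fe
                   for _ in range(100))
        assert wins == 100

    def test_discrimination_stable_across_r(self):
        rng = np.random.default_rng(4)
        noise = rng.standard_normal(500)
        tone = _sine(10.0)
        for r in (0.1, 0.2, 0.3):
            p = FEParams(m=2, r=r)
            assert fuzzy_entropy(noise, p) > fuzzy_entropy(tone, p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fuzzy_entropy(np.zeros(3), FEParams(m=2))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FEParams(m=0)
        with pytest.raises(ValueError):
            FEParams(r=-0.1)


# --------------------------------------------------------------------- phase / PLI

class TestAnalyticPhase:
    def test_recovers_instantaneous_frequency(self):
        ph = analytic_phase(np.cos(2 * np.pi * 10 * np.arange(500) / FS))
        inst = np.diff(np.unwrap(ph.phase)) * FS / (2 * np.pi)
        core = inst[50:-50]  # interior 80%
        assert np.all(np.abs(core - 10.0) / 10.0 < 0.01)

    def test_recovers_amplitude(self):
        ph = analytic_phase(3.5 * np.cos(2 * np.pi * 10 * np.arange(500) / FS))
        assert np.allclose(ph.amplitude[50:-50], 3.5, rtol=0.01)

    def test_sin_cos_quadrature(self):
        t = np.arange(500) / FS
        pc = analytic_phase(np.cos(2 * np.pi * 10 * t)).phase
        ps = analytic_phase(np.sin(2 * np.pi * 10 * t)).phase
        d = np.angle(np.exp(1j * (pc - ps)))
        assert np.allclose(d[50:-50], np.pi / 2, atol=0.01)


class TestPLI:
    def test_identical_signals_give_zero(self):
        p = analytic_phase(_sine(20.0))
        assert pli(p, p) == 0.0

    def test_constant_lag_gives_one(self):
        pk = analytic_phase(_sine(20.0))
        pl_ = analytic_phase(_sine(20.0, phase=-np.pi / 4))
        assert pli(pk, pl_, edge_trim=0.1) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_range_and_amplitude_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(500)
            y = rng.standard_normal(500)
            a, b = analytic_phase(x), analytic_phase(y)
            v = pli(a, b)
            assert 0.0 <= v <= 1.0
            assert pli(b, a) == v
            # phase-only statistic: rescaling either signal changes nothing
            assert pli(analytic_phase(7.3 * x), b) == pytest.approx(v, abs=1e-12)
            assert pli(a, a) == 0.0

    def test_independent_narrowband_signals_stay_low(self):
        from eegdiff.synth import _jittered_phase
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            a = analytic_phase(np.cos(_jittered_phase(rng, 500, FS, 19.0, 0.1)))
            b = analytic_phase(np.cos(_jittered_phase(rng, 500, FS, 22.0, 0.1)))
            vals.append(pli(a, b))
        assert np.mean(vals) < 0.2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            pli(np.zeros(10), np.zeros(11))


# --------------------------------------------------------------------- table

def _epochset(data, band, names):
    return EpochSet(subject_id="s1", group="A", band=band, epochs=data,
                    fs=FS, window=4.0, step=2.0, channel_names=names)


def test_full_table_has_608_feature_columns(tiny_cohort_table):
    meta = {"subject_id", "group", "epoch"}
    feature_cols = [c for c in tiny_cohort_table.columns if c not in meta]
    assert len(feature_cols) == 608  # 4 bands x (16 PSD + 16 FE + 120 PLI)
    assert not tiny_cohort_table.isna().any().any()
    pli_cols = [c for c in feature_cols if c.startswith("PLI_")]
    assert ((tiny_cohort_table[pli_cols] >= 0).all().all()
            and (tiny_cohort_table[pli_cols] <= 1).all().all())


def test_one_epoch_one_row():
    rng = np.random.default_rng(0)
    names = ("C3", "C4")
    bands = {"beta": _epochset(rng.standard_normal((1, 2, 500)), "beta", names)}
    df = build_feature_table(bands, bands=(BETA,))
    assert len(df) == 1
    assert list(df.columns[:3]) == ["subject_id", "group", "epoch"]


def test_channel_permutation_preserves_named_values():
    rng = np.random.default_rng(2)
    data = rng.standard_normal((2, 3, 500))
    names = ("C3", "C4", "P3")
    df1 = build_feature_table({"beta": _epochset(data, "beta", names)},
                              bands=(BETA,))
    perm = [2, 0, 1]
    df2 = build_feature_table(
        {"beta": _epochset(data[:, perm, :], "beta",
                           tuple(names[i] for i in perm))}, bands=(BETA,))
    for col in ("PSD_beta_C3", "FE_beta_P3"):
        assert df1[col].tolist() == pytest.approx(df2[col].tolist())
    # pair features match regardless of within-pair order
    assert df1["PLI_beta_C3-P3"].tolist() == pytest.approx(
        df2["PLI_beta_P3-C3"].tolist())


def test_misaligned_band_sets_rejected():
    rng = np.random.default_rng(3)
    names = ("C3", "C4")
    bands = {
        "beta": _epochset(rng.standard_normal((2, 2, 500)), "beta", names),
        "theta": _epochset(rng.standard_normal((3, 2, 500)), "theta", names),
    }
    with pytest.raises(ValueError, match="misaligned"):
        build_feature_table(bands, bands=(BETA, THETA))


def test_table_determinism():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((2, 2, 500))
    bands = {"beta": _epochset(data, "beta", ("C3", "C4"))}
    df1 = build_feature_table(bands, bands=(BETA,))
    df2 = build_feature_table(bands, bands=(BETA,))
    assert df1.equals(df2)
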