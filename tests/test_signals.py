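"""Tests of the ten benchmark generators and the surrogate EEG classes."""

import numpy as np
import pytest
from scipy import stats
from scipy import signal as sps

from entrosig import (
    GeneratorSpec,
    SEnConfig,
    SurrogateClassSpec,
    compare_groups,
    generate_ar1_sweep,
    generate_chirp,
    generate_harmonic_stack,
    generate_logistic,
    generate_lorenz,
    generate_mix,
    generate_quasiperiodic_noise,
    generate_signal,
    generate_surrogate_eeg_classes,
    generate_wgn_bandwidth_steps,
    generate_wgn_power_steps,
    sample_entropy,
)
from entrosig.signals import iterate_logistic, quasiperiodic_base

import oracles

SPEC = GeneratorSpec(seed=11)


def lag1_autocorr(x):
    x = x - x.mean()
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


# ---------------------------------------------------------------------------
# global invariants

@pytest.mark.parametrize("sid", range(1, 11))
def test_default_suite_shape_and_determinism(sid):
    a = generate_signal(sid, GeneratorSpec(seed=5))
    b = generate_signal(sid, GeneratorSpec(seed=5))
    assert a.n_samples == 10240
    assert a.fs == 256.0
    assert a.duration == pytest.approx(40.0)
    np.testing.assert_array_equal(a.samples, b.samples)
    if a.segments is not None:
        bounds = sorted(s[0] for s in a.segments)[1:]
        assert all(b in (10.0, 20.0, 30.0) for b in bounds)


# ---------------------------------------------------------------------------
# chirps

class TestChirp:
    def test_zero_crossing_rates_match_sweep_endpoints(self):
        sig = generate_chirp(spec=SPEC)
        x = sig.samples
        fs = sig.fs

        def zc_rate(seg):  # crossings per second / 2 = frequency estimate
            return np.sum(np.diff(np.signbit(seg)) != 0) / (len(seg) / fs) / 2

        assert zc_rate(x[: int(2 * fs)]) == pytest.approx(0.5, abs=0.3)
        assert zc_rate(x[-int(2 * fs):]) == pytest.approx(5.0, abs=0.5)

    def test_unmodulated_envelope_constant(self):
        sig = generate_chirp(spec=SPEC)
        # peak magnitude in 2 s chunks stays at the unit amplitude
        peaks = [np.abs(c).max() for c in np.array_split(sig.samples, 20)]
        assert np.ptp(peaks) < 0.05

    def test_modulated_envelope_closed_form(self):
        sig = generate_chirp(modulated=True, spec=SPEC)
        env = 0.75 + 0.25 * np.cos(2 * np.pi * 0.05 * sig.times)
        assert env[0] == pytest.approx(1.0)
        assert env[int(10 * sig.fs)] == pytest.approx(0.5)
        # the signal never exceeds its envelope and comes close to it near t=0
        assert np.all(np.abs(sig.samples) <= env + 1e-12)
        first_two_s = slice(0, int(2 * sig.fs))
        assert np.abs(sig.samples[first_two_s]).max() > 0.9

    def test_invalid_frequency_ordering_rejected(self):
        with pytest.raises(ValueError, match="f0"):
            generate_chirp(f0=5.0, f1=0.5, spec=SPEC)
        with pytest.raises(ValueError, match="alias"):
            generate_chirp(f0=1.0, f1=200.0, spec=SPEC)


# ---------------------------------------------------------------------------
# harmonic stack

class TestHarmonicStack:
    def test_two_harmonic_frequencies_are_log_space_endpoints(self):
        assert np.allclose(np.geomspace(0.4, 100.0, 2), [0.4, 100.0])

    @pytest.mark.parametrize("seg,expected_peaks", [(0, 1), (3, 7)])
    def test_spectral_peak_count(self, seg, expected_peaks):
        sig = generate_harmonic_stack(spec=SPEC)
        x = sig.segment_samples(seg)
        freqs = np.fft.rfftfreq(len(x), 1 / sig.fs)
        spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
        # count expected component frequencies carrying non-trivial power
        comps = np.geomspace(0.4, 100.0, expected_peaks) if expected_peaks > 1 else [0.4]
        found = 0
        floor = spec.max() * 1e-4
        for f in comps:
            idx = np.argmin(np.abs(freqs - f))
            if spec[max(0, idx - 2): idx + 3].max() > floor:
                found += 1
        assert found == expected_peaks


# ---------------------------------------------------------------------------
# quasi-periodic + noise

class TestQuasiperiodicNoise:
    def test_first_segment_is_noiseless(self):
        sig = generate_quasiperiodic_noise(spec=SPEC)
        base = quasiperiodic_base(sig.times)
        residual = sig.samples - base
        assert np.all(residual[: sig.n_samples // 4] == 0.0)

    def test_third_segment_noise_sd(self):
        sig = generate_quasiperiodic_noise(spec=SPEC)
        base = quasiperiodic_base(sig.times)
        resid = (sig.samples - base)[sig.n_samples // 2: 3 * sig.n_samples // 4]
        se = 0.3 / np.sqrt(2 * (len(resid) - 1))  # SE of a Gaussian SD estimate
        assert resid.std(ddof=1) == pytest.approx(0.3, abs=3 * se)


# ---------------------------------------------------------------------------
# WGN power / bandwidth

class TestWgnPowerSteps:
    def test_segment_variances_and_means(self):
        sig = generate_wgn_power_steps(spec=SPEC)
        for i, var in enumerate((0.1, 0.3, 0.5, 0.7)):
            seg = sig.segment_samples(i)
            se = var * np.sqrt(2 / (len(seg) - 1))  # SE of a variance estimate
            assert seg.var(ddof=1) == pytest.approx(var, abs=3 * se)
            assert abs(seg.mean()) < 4 * np.sqrt(var / len(seg))

    def test_segments_are_white(self):
        sig = generate_wgn_power_steps(spec=SPEC)
        for i in range(4):
            assert abs(lag1_autocorr(sig.segment_samples(i))) < 4 / np.sqrt(2560)


class TestWgnBandwidthSteps:
    def test_lowpassed_segment_power_confined_below_cutoff(self):
        sig = generate_wgn_bandwidth_steps(spec=SPEC)
        x = sig.segment_samples(0)  # 30 Hz cut-off
        freqs, psd = sps.welch(x, fs=sig.fs, nperseg=512)
        frac_above = psd[freqs > 35].sum() / psd.sum()
        assert frac_above < 0.01

    def test_final_segment_unfiltered_and_flat(self):
        spec = GeneratorSpec(seed=11)
        sig = generate_wgn_bandwidth_steps(spec=spec)
        raw = np.random.default_rng(spec.seed).normal(0.0, 1.0, spec.n_samples)
        np.testing.assert_array_equal(sig.segment_samples(3), raw[-2560:])
        freqs, psd = sps.welch(sig.segment_samples(3), fs=sig.fs, nperseg=512)
        # flat spectrum: low and high halves carry comparable power
        lo = psd[freqs < 64].mean()
        hi = psd[freqs >= 64].mean()
        assert 0.7 < lo / hi < 1.4

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_wgn_bandwidth_steps(cutoffs=(30.0, 60.0, 128.0), spec=SPEC)


# ---------------------------------------------------------------------------
# MIX process

class TestMixProcess:
    def test_pure_deterministic_limit(self):
        sig = generate_mix(p_start=0.0, p_end=0.0, spec=SPEC)
        k = np.arange(sig.n_samples)
        np.testing.assert_allclose(sig.samples, 2 * np.sin(2 * np.pi * k / 12))
        np.testing.assert_allclose(sig.samples[:-12], sig.samples[12:], atol=1e-9)

    def test_pure_noise_limit_is_uniform(self):
        sig = generate_mix(p_start=1.0, p_end=1.0, spec=SPEC)
        p = stats.kstest(sig.samples, stats.uniform(loc=-3, scale=6).cdf).pvalue
        assert p > 0.01

    def test_deterministic_fraction_sweeps_up(self):
        sig = generate_mix(spec=SPEC)
        k = np.arange(sig.n_samples)
        det = 2 * np.sin(2 * np.pi * k / 12)
        match = sig.samples == det
        p = np.linspace(0.9, 0.1, sig.n_samples)
        # block-wise deterministic fraction tracks 1 - p, rising ~0.1 -> ~0.9
        for block in (slice(0, 1024), slice(-1024, None)):
            assert match[block].mean() == pytest.approx(1 - p[block].mean(), abs=0.05)
        assert match[:1024].mean() < 0.2
        assert match[-1024:].mean() > 0.8


# ---------------------------------------------------------------------------
# AR(1)

class TestAr1Sweep:
    def test_zero_coefficient_is_white(self):
        sig = generate_ar1_sweep(p_start=0.0, p_end=0.0, spec=SPEC)
        assert abs(lag1_autocorr(sig.samples)) < 4 / np.sqrt(10240)

    def test_constant_coefficient_matches_closed_form(self):
        sig = generate_ar1_sweep(p_start=0.9, p_end=0.9, spec=SPEC)
        assert lag1_autocorr(sig.samples) == pytest.approx(0.9, abs=0.05)

    def test_default_sweep_signs(self):
        sig = generate_ar1_sweep(spec=SPEC)
        half = sig.n_samples // 2
        assert lag1_autocorr(sig.samples[: sig.n_samples // 8]) > 0.3
        assert lag1_autocorr(sig.samples[-sig.n_samples // 8:]) < -0.3

    def test_nonstationary_coefficient_rejected(self):
        with pytest.raises(ValueError, match="stationarity"):
            generate_ar1_sweep(p_start=1.0, p_end=0.0, spec=SPEC)


# ---------------------------------------------------------------------------
# logistic map

class TestLogisticMap:
    @pytest.mark.parametrize("mu,period", [(2.0, 1), (3.2, 2), (3.5, 4), (3.55, 8)])
    def test_period_matches_bruteforce_orbit_enumeration(self, mu, period):
        x = iterate_logistic(mu, 0.3, 10000, burn_in=1000)
        vals = np.sort(x)
        distinct = 1 + int(np.sum(np.diff(vals) > 1e-6))
        assert distinct == period
        assert oracles.logistic_orbit_period(mu) == period

    def test_mu2_converges_to_fixed_point(self):
        x = iterate_logistic(2.0, 0.3, 100, burn_in=1000)
        np.testing.assert_allclose(x, 0.5, atol=1e-9)  # x* = 1 - 1/mu

    def test_samples_stay_in_unit_interval(self):
        sig = generate_logistic(spec=SPEC)
        assert np.all((sig.samples > 0) & (sig.samples < 1))

    def test_default_has_two_regimes(self):
        sig = generate_logistic(spec=SPEC)
        assert [s[2] for s in sig.segments] == ["mu = 3.55", "mu = 3.8"]
        assert sig.segments[0][1] == 20.0


# ---------------------------------------------------------------------------
# Lorenz system

class TestLorenz:
    def test_halves_standardised(self):
        sig = generate_lorenz(spec=SPEC)
        for i in range(2):
            assert sig.segment_samples(i).std() == pytest.approx(1.0, abs=1e-6)

    def test_chaotic_half_autocorrelation_decays(self):
        sig = generate_lorenz(spec=SPEC)
        x = sig.segment_samples(0) - sig.segment_samples(0).mean()
        full = np.correlate(x, x, "full")[len(x) - 1:] / np.dot(x, x)
        # non-periodic: long-lag autocorrelation has decayed well below 1
        assert np.abs(full[len(x) // 2:]).max() < 0.8

    def test_duplicate_parameter_sets_reproduce(self):
        p = (10.0, 8.0 / 3.0, 28.0)
        sig = generate_lorenz(param_sets=(p, p), spec=SPEC)
        np.testing.assert_allclose(sig.segment_samples(0), sig.segment_samples(1))


# ---------------------------------------------------------------------------
# surrogate EEG classes

class TestSurrogateClasses:
    def test_regular_class_has_lower_sample_entropy(self):
        specs = [SurrogateClassSpec("regular", ar_coef=0.9),
                 SurrogateClassSpec("irregular", ar_coef=0.0)]
        data = generate_surrogate_eeg_classes(50, specs, duration=4.0, seed=2)
        vals = {lbl: [] for lbl in ("regular", "irregular")}
        for sig, lbl in data:
            vals[lbl].append(sample_entropy(sig.samples, SEnConfig(m=2, r=0.2)))
        res = compare_groups({k: np.array(v) for k, v in vals.items()}, "independent-2")
        assert np.mean(vals["regular"]) < np.mean(vals["irregular"])
        assert res.p_value < 0.01

    def test_duplicate_class_spec_warns(self):
        specs = [SurrogateClassSpec("a", ar_coef=0.5), SurrogateClassSpec("b", ar_coef=0.5)]
        with pytest.warns(UserWarning, match="indistinguishable"):
            generate_surrogate_eeg_classes(2, specs, duration=1.0, seed=0)

    def test_deterministic_under_seed(self):
        specs = [SurrogateClassSpec("a", ar_coef=0.8), SurrogateClassSpec("b", ar_coef=0.1)]
        d1 = generate_surrogate_eeg_classes(3, specs, duration=1.0, seed=9)
        d2 = generate_surrogate_eeg_classes(3, specs, duration=1.0, seed=9)
        for (s1, l1), (s2, l2) in zip(d1, d2):
            assert l1 == l2
            np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            generate_surrogate_eeg_classes(2, [SurrogateClassSpec("a")], seed=0)
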