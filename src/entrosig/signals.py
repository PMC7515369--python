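"""Synthetic benchmark signals for characterising entropy estimators.

Ten generators produce 40 s signals sampled at 256 Hz (the standard EEG
rate), each built from four 10 s regimes in which one signal-processing
property changes or grows: sinusoid frequency, amplitude modulation,
harmonic count, additive noise power, pure-noise power, noise bandwidth,
stochastic/deterministic mixing, coloured-noise spectrum, logistic-map
regime and Lorenz-system regime.  A separate surrogate generator emits
labelled EEG-like classes with controllable regularity so the group
study and classifier can be exercised without external recordings.

All stochastic generators are bit-reproducible under a fixed seed;
:func:`benchmark_suite` expands one master seed into independent
per-generator streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import Signal

__all__ = [
    "GeneratorSpec",
    "SurrogateClassSpec",
    "generate_chirp",
    "generate_harmonic_stack",
    "generate_quasiperiodic_noise",
    "generate_wgn_power_steps",
    "generate_wgn_bandwidth_steps",
    "generate_mix",
    "generate_ar1_sweep",
    "generate_logistic",
    "generate_lorenz",
    "generate_surrogate_eeg_classes",
    "generate_signal",
    "benchmark_suite",
    "SIGNAL_LABELS",
]


@dataclass
class GeneratorSpec:
    """Shared generator settings: sampling rate, duration and seed.

    Defaults (fs = 256 Hz, 40 s -> 10 240 samples) reproduce the
    benchmark study conditions; per-generator parameters are keyword
    arguments of the individual generator functions.
    """

    seed: int = 0
    fs: float = 256.0
    duration: float = 40.0

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def quarter_segments(self, descriptions) -> list[tuple[float, float, str]]:
        q = self.duration / 4
        return [(i * q, (i + 1) * q, d) for i, d in enumerate(descriptions)]


def _quarter_slices(n: int):
    q = n // 4
    return [slice(i * q, (i + 1) * q if i < 3 else n) for i in range(4)]


# ---------------------------------------------------------------------------
# 1 & 2: chirp signals

def generate_chirp(
    f0: float = 0.5,
    f1: float = 5.0,
    modulated: bool = False,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Constant- or modulated-amplitude linear chirp, ``f0`` -> ``f1`` Hz.

    The modulated variant multiplies by the envelope
    ``0.75 + 0.25 cos(2 pi 0.05 t)``, so the amplitude breathes between
    0.5 and 1.0 with a 20 s period.
    """
    if not 0 < f0 < f1:
        raise ValueError(f"need 0 < f0 < f1, got f0={f0}, f1={f1}")
    if f1 >= spec.fs / 2:
        raise ValueError(f"f1={f1} Hz aliases at fs={spec.fs} Hz")
    t = spec.t
    x = sps.chirp(t, f0=f0, f1=f1, t1=spec.duration, method="linear")
    label = "modulated amplitude chirp" if modulated else "constant amplitude chirp"
    if modulated:
        x = (0.75 + 0.25 * np.cos(2 * np.pi * 0.05 * t)) * x
    return Signal(x, spec.fs, label=label)


# ---------------------------------------------------------------------------
# 3: increasing number of harmonics

def generate_harmonic_stack(
    counts: tuple[int, ...] = (1, 2, 5, 7),
    f_lo: float = 0.4,
    f_hi: float = 100.0,
    a_hi: float = 0.5,
    a_lo: float = 0.005,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Four segments holding 1, 2, 5 and 7 sinusoidal harmonics.

    Component frequencies are log-spaced between ``f_lo`` (0.4 Hz base)
    and ``f_hi`` (100 Hz, the upper gamma-band edge); amplitudes are
    log-spaced from ``a_hi`` down to ``a_lo`` so the highest frequency
    is weakest, mimicking the 1/f-like spectra of real EEG.
    """
    if f_hi >= spec.fs / 2:
        raise ValueError(f"highest harmonic {f_hi} Hz aliases at fs={spec.fs} Hz")
    x = np.zeros(spec.n_samples)
    t = spec.t
    for sl, k in zip(_quarter_slices(spec.n_samples), counts):
        freqs = np.geomspace(f_lo, f_hi, k) if k > 1 else np.array([f_lo])
        amps = np.geomspace(a_hi, a_lo, k) if k > 1 else np.array([a_hi])
        x[sl] = sum(a * np.sin(2 * np.pi * f * t[sl]) for f, a in zip(freqs, amps))
    segs = spec.quarter_segments([f"{k} harmonics" for k in counts])
    return Signal(x, spec.fs, label="increasing number of harmonics", segments=segs)


# ---------------------------------------------------------------------------
# 4: quasi-periodic signal with increasing noise power

def generate_quasiperiodic_noise(
    noise_sd: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5),
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Two summed sinusoids (0.61 and 1 Hz) under a slow 0.05 Hz
    modulator (amplitude 0.1, offset 1), with white Gaussian noise of
    per-segment standard deviation 0/0.1/0.3/0.5 added.

    'Noise magnitude' is interpreted as the standard deviation of the
    additive noise.
    """
    t = spec.t
    base = quasiperiodic_base(t)
    rng = spec.rng()
    x = base.copy()
    for sl, sd in zip(_quarter_slices(spec.n_samples), noise_sd):
        if sd > 0:
            x[sl] += rng.normal(0.0, sd, sl.stop - sl.start)
    segs = spec.quarter_segments([f"noise SD {sd}" for sd in noise_sd])
    return Signal(x, spec.fs, label="quasi-periodic with increasing noise", segments=segs)


def quasiperiodic_base(t: np.ndarray) -> np.ndarray:
    """Noiseless quasi-periodic carrier used by the fourth benchmark."""
    mod = 1.0 + 0.1 * np.cos(2 * np.pi * 0.05 * t)
    return mod * (np.sin(2 * np.pi * 0.61 * t) + np.sin(2 * np.pi * 1.0 * t))


# ---------------------------------------------------------------------------
# 5: WGN of increasing power

def generate_wgn_power_steps(
    powers: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7),
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Four independent zero-mean white Gaussian segments of variance
    0.1/0.3/0.5/0.7 ('power' interpreted as variance)."""
    rng = spec.rng()
    x = np.empty(spec.n_samples)
    for sl, p in zip(_quarter_slices(spec.n_samples), powers):
        x[sl] = rng.normal(0.0, np.sqrt(p), sl.stop - sl.start)
    segs = spec.quarter_segments([f"variance {p}" for p in powers])
    return Signal(x, spec.fs, label="WGN of increasing power", segments=segs)


# ---------------------------------------------------------------------------
# 6: WGN of increasing bandwidth

def generate_wgn_bandwidth_steps(
    cutoffs: tuple[float, ...] = (30.0, 60.0, 100.0),
    fir_order: int = 425,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """One unit-variance WGN realisation; the first three 10 s segments
    are low-pass filtered (Hamming-window FIR of the given order) at
    30/60/100 Hz, the fourth is left unfiltered (full bandwidth)."""
    for c in cutoffs:
        if c >= spec.fs / 2:
            raise ValueError(f"cut-off {c} Hz is at or above Nyquist ({spec.fs / 2} Hz)")
    rng = spec.rng()
    raw = rng.normal(0.0, 1.0, spec.n_samples)
    x = raw.copy()
    slices = _quarter_slices(spec.n_samples)
    for sl, c in zip(slices[:3], cutoffs):
        taps = sps.firwin(fir_order + 1, c, window="hamming", fs=spec.fs)
        x[sl] = sps.filtfilt(taps, [1.0], raw[sl])
    segs = spec.quarter_segments(
        [f"low-pass {c} Hz" for c in cutoffs] + ["unfiltered"]
    )
    return Signal(x, spec.fs, label="WGN of increasing bandwidth", segments=segs)


# ---------------------------------------------------------------------------
# 7: MIX process

def generate_mix(
    p_start: float = 0.9,
    p_end: float = 0.1,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """MIX process: per-sample Bernoulli choice between the period-12
    sinusoid ``x_k = 2 sin(2 pi k / 12)`` and Uniform(-3, 3) noise.

    ``MIX_k = (1 - z_k) x_k + z_k y_k`` with ``z_k ~ Bernoulli(p_k)``
    and the mixing probability swept linearly from ``p_start`` (default
    0.9, mostly random) to ``p_end`` (default 0.1, mostly periodic).
    """
    if not (0 <= p_start <= 1 and 0 <= p_end <= 1):
        raise ValueError("mixing probabilities must lie in [0, 1]")
    n = spec.n_samples
    k = np.arange(n)
    x = 2.0 * np.sin(2 * np.pi * k / 12.0)
    rng = spec.rng()
    y = rng.uniform(-3.0, 3.0, n)
    p = np.linspace(p_start, p_end, n)
    z = rng.random(n) < p
    out = np.where(z, y, x)
    return Signal(out, spec.fs, label="MIX process")


# ---------------------------------------------------------------------------
# 8: AR(1) sweep

def generate_ar1_sweep(
    p_start: float = 0.9,
    p_end: float = -0.9,
    burn_in: int = 100,
    innovation_sd: float = 1.0,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """First-order autoregression with the coefficient swept linearly
    from +0.9 to -0.9 across the retained record, moving the coloured
    noise energy from low to high frequencies through white (p = 0).

    ``burn_in`` initial samples are generated at ``p_start`` and
    discarded; innovations are zero-mean Gaussian of SD 1.
    """
    if max(abs(p_start), abs(p_end)) >= 1:
        raise ValueError("AR(1) coefficient magnitude must stay below 1 (stationarity)")
    n = spec.n_samples
    rng = spec.rng()
    eps = rng.normal(0.0, innovation_sd, burn_in + n)
    coef = np.concatenate([np.full(burn_in, p_start), np.linspace(p_start, p_end, n)])
    x = np.empty(burn_in + n)
    prev = 0.0
    for i in range(burn_in + n):
        prev = coef[i] * prev + eps[i]
        x[i] = prev
    return Signal(x[burn_in:], spec.fs, label="AR(1) coefficient sweep")


# ---------------------------------------------------------------------------
# 9: logistic map

def iterate_logistic(mu: float, x0: float, n: int, burn_in: int = 0) -> np.ndarray:
    """Iterate ``x_{k+1} = mu x_k (1 - x_k)``, returning ``n`` samples
    after discarding ``burn_in`` iterates."""
    if not 0 < mu <= 4:
        raise ValueError("logistic parameter mu must lie in (0, 4]")
    if not 0 < x0 < 1:
        raise ValueError("initial value x0 must lie in (0, 1)")
    out = np.empty(n)
    x = x0
    for _ in range(burn_in):
        x = mu * x * (1.0 - x)
    for i in range(n):
        x = mu * x * (1.0 - x)
        if not 0.0 < x < 1.0:
            raise ValueError(f"logistic iterate escaped (0, 1) at step {i} (mu={mu})")
        out[i] = x
    return out


def generate_logistic(
    mu_segments: tuple[float, ...] = (3.55, 3.8),
    x0: float = 0.3,
    burn_in: int = 100,
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Logistic-map signal: one segment per ``mu`` value (default an
    8-cycle at mu = 3.55 for 20 s, then chaos at mu = 3.8 for 20 s).

    Each segment restarts from ``x0`` and discards its own ``burn_in``
    iterates so every regime is sampled on-attractor.
    """
    n = spec.n_samples
    seg_len = n // len(mu_segments)
    parts = []
    for i, mu in enumerate(mu_segments):
        length = seg_len if i < len(mu_segments) - 1 else n - seg_len * (len(mu_segments) - 1)
        parts.append(iterate_logistic(mu, x0, length, burn_in))
    seg_dur = spec.duration / len(mu_segments)
    segs = [
        (i * seg_dur, (i + 1) * seg_dur, f"mu = {mu}") for i, mu in enumerate(mu_segments)
    ]
    return Signal(np.concatenate(parts), spec.fs, label="logistic map", segments=segs)


# ---------------------------------------------------------------------------
# 10: Lorenz system

def _lorenz_rk4(state, sigma, beta, rho, dt, n_steps):
    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    out = np.empty((n_steps, 3))
    s = np.asarray(state, dtype=float)
    for i in range(n_steps):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(s)) or np.abs(s).max() > 1e6:
            raise ValueError(
                f"Lorenz integration blew up at step {i} "
                f"(sigma={sigma}, beta={beta}, rho={rho}, dt={dt})"
            )
        out[i] = s
    return out


def generate_lorenz(
    param_sets: tuple[tuple[float, float, float], ...] = ((10.0, 8.0 / 3.0, 28.0), (10.0, 8.0 / 3.0, 99.96)),
    dt: float | None = None,
    transient: float = 10.0,
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0),
    spec: GeneratorSpec = GeneratorSpec(),
) -> Signal:
    """Lorenz-system x-coordinate, one segment per (sigma, beta, rho) set.

    Defaults produce the chaotic butterfly (rho = 28) for the first
    half and a torus knot (rho = 99.96) for the second.  Fixed-step RK4
    at ``dt = 1/fs`` in system time units; a 10 s transient from the
    initial state (1, 1, 1) is discarded per parameter set, and each
    segment is standardised to zero mean and unit SD.
    """
    if dt is None:
        dt = 1.0 / spec.fs
    n = spec.n_samples
    seg_len = n // len(param_sets)
    parts = []
    for i, (sigma, beta, rho) in enumerate(param_sets):
        length = seg_len if i < len(param_sets) - 1 else n - seg_len * (len(param_sets) - 1)
        n_trans = int(round(transient / dt))
        traj = _lorenz_rk4(initial_state, sigma, beta, rho, dt, n_trans + length)
        x = traj[n_trans:, 0]
        parts.append((x - x.mean()) / x.std())
    seg_dur = spec.duration / len(param_sets)
    segs = [
        (i * seg_dur, (i + 1) * seg_dur, f"sigma={s}, beta={b:.4g}, rho={r}")
        for i, (s, b, r) in enumerate(param_sets)
    ]
    return Signal(np.concatenate(parts), spec.fs, label="Lorenz system", segments=segs)


# ---------------------------------------------------------------------------
# surrogate EEG-like class data

@dataclass
class SurrogateClassSpec:
    """Parameters of one surrogate class: an AR(1) base (regularity
    knob) optionally summed with a sinusoid (periodicity knob)."""

    label: str
    ar_coef: float = 0.0
    sine_freq: float = 0.0
    sine_amp: float = 0.0
    noise_sd: float = 1.0


def generate_surrogate_eeg_classes(
    n_per_class: int,
    class_specs: list[SurrogateClassSpec],
    fs: float = 256.0,
    duration: float = 4.0,
    seed: int = 0,
) -> list[tuple[Signal, str]]:
    """Labelled surrogate segments whose classes differ in regularity.

    Each segment is an AR(1) realisation (coefficient per class) plus an
    optional sinusoid; classes with higher AR coefficients or stronger
    sinusoids are more regular and carry lower embedding entropy.
    Deterministic under ``seed``.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least two classes")
    keys = [(c.ar_coef, c.sine_freq, c.sine_amp, c.noise_sd) for c in class_specs]
    if len(set(keys)) < len(keys):
        warnings.warn("duplicate class parameters: classes will be indistinguishable")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    burn = 100
    out: list[tuple[Signal, str]] = []
    for cls in class_specs:
        for j in range(n_per_class):
            eps = rng.normal(0.0, cls.noise_sd, burn + n)
            x = np.empty(burn + n)
            prev = 0.0
            for i in range(burn + n):
                prev = cls.ar_coef * prev + eps[i]
                x[i] = prev
            samples = x[burn:]
            if cls.sine_amp:
                samples = samples + cls.sine_amp * np.sin(2 * np.pi * cls.sine_freq * t)
            out.append((Signal(samples, fs, label=f"{cls.label}[{j}]"), cls.label))
    return out


# ---------------------------------------------------------------------------
# registry

SIGNAL_LABELS = {
    1: "constant amplitude chirp",
    2: "modulated amplitude chirp",
    3: "increasing number of harmonics",
    4: "quasi-periodic with increasing noise",
    5: "WGN of increasing power",
    6: "WGN of increasing bandwidth",
    7: "MIX process",
    8: "AR(1) coefficient sweep",
    9: "logistic map",
    10: "Lorenz system",
}


def generate_signal(signal_id: int, spec: GeneratorSpec = GeneratorSpec(), **overrides) -> Signal:
    """Generate benchmark signal 1-10 by id with default study parameters."""
    gens = {
        1: lambda: generate_chirp(modulated=False, spec=spec, **overrides),
        2: lambda: generate_chirp(modulated=True, spec=spec, **overrides),
        3: lambda: generate_harmonic_stack(spec=spec, **overrides),
        4: lambda: generate_quasiperiodic_noise(spec=spec, **overrides),
        5: lambda: generate_wgn_power_steps(spec=spec, **overrides),
        6: lambda: generate_wgn_bandwidth_steps(spec=spec, **overrides),
        7: lambda: generate_mix(spec=spec, **overrides),
        8: lambda: generate_ar1_sweep(spec=spec, **overrides),
        9: lambda: generate_logistic(spec=spec, **overrides),
        10: lambda: generate_lorenz(spec=spec, **overrides),
    }
    if signal_id not in gens:
        raise ValueError(f"signal_id must be 1..10, got {signal_id}")
    return gens[signal_id]()


def benchmark_suite(seed: int = 0, fs: float = 256.0, duration: float = 40.0) -> dict[int, Signal]:
    """All ten benchmark signals, the master seed expanded into
    independent per-generator streams."""
    children = np.random.SeedSequence(seed).spawn(10)
    return {
        sid: generate_signal(
            sid,
            GeneratorSpec(seed=int(children[sid - 1].generate_state(1)[0] % (2**31)), fs=fs, duration=duration),
        )
        for sid in range(1, 11)
    }
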