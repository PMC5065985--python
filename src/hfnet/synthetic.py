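"""Seeded generators for multichannel oscillatory recordings.

Every downstream stage of the toolkit (wavelet phases, coupling indices,
hyper-frequency networks, topology dynamics, classification) is exercised on
signals produced here: sums of sinusoidal oscillators with optional n:m
phase locking between channels, additive white Gaussian noise, and
oddball-style stimulus schedules.  The default geometry mirrors a typical
58-channel EEG setup sampled at 250 Hz in 10-s segments, but every knob is
configurable and unit tests run on much smaller fixtures.

No physiological realism is attempted: there is no 1/f background and no
volume conduction.  White noise is the null against which the surrogate
logic of :mod:`hfnet.hfn` is calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import hadamard
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "StimulusSchedule",
    "CoupledTo",
    "OscillatorSpec",
    "SegmentedRecording",
    "gen_stimulus_schedule",
    "gen_coupled_oscillators",
    "gen_event_modulated_recording",
    "default_channel_labels",
]


def default_channel_labels(n_channels: int) -> list[str]:
    """Generic channel names ``ch01 .. chNN``."""
    width = max(2, len(str(n_channels)))
    return [f"ch{i + 1:0{width}d}" for i in range(n_channels)]


@dataclass(frozen=True)
class StimulusSchedule:
    """Oddball-style event schedule.

    Parameters
    ----------
    onsets : array of float
        Event onsets in seconds from segment start, strictly increasing;
        consecutive differences lie within ``isi_bounds``.
    classes : array of str
        Per-event category, ``"standard"`` or ``"deviant"``.
    isi_bounds : (float, float)
        Inclusive bounds of the uniform inter-stimulus-interval distribution.
    """

    onsets: np.ndarray
    classes: np.ndarray
    isi_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        classes = np.asarray(self.classes)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "classes", classes)
        if onsets.ndim != 1 or classes.shape != onsets.shape:
            raise ValueError("onsets and classes must be 1-D and equally long")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def isis(self) -> np.ndarray:
        """Inter-stimulus intervals (differences of consecutive onsets)."""
        return np.diff(self.onsets)


@dataclass(frozen=True)
class CoupledTo:
    """Phase-locking target of an oscillator.

    Enforces ``n * phase(self) - m * phase(driver) == phase_lag`` at
    generation time (up to the optional lag jitter).  ``lag_jitter`` is the
    circular standard deviation (radians) of smooth wrapped noise added to
    the lag; ``jitter_timescale`` is the correlation time of that noise in
    seconds.  ``lag_jitter = 0`` yields exact locking.
    """

    channel: str
    frequency: float
    n: int = 1
    m: int = 1
    phase_lag: float = 0.0
    lag_jitter: float = 0.0
    jitter_timescale: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1 or self.n != int(self.n) or self.m != int(self.m):
            raise ValueError("n and m must be positive integers")
        if self.frequency <= 0:
            raise ValueError("driver frequency must be positive")
        if self.lag_jitter < 0:
            raise ValueError("lag_jitter must be nonnegative")


@dataclass(frozen=True)
class OscillatorSpec:
    """One sinusoidal component of one channel.

    ``snr`` is the ratio of oscillator power (amplitude**2 / 2) to the power
    of the additive white Gaussian noise contributed by this component.
    ``snr = inf`` (default) adds no noise; ``snr = 0`` drops the oscillator
    and emits pure noise at the power the oscillator would have had.

    ``phase_diffusion`` adds smooth wrapped phase noise (circular SD in
    radians, correlation time ``diffusion_timescale`` seconds) to an
    *uncoupled* oscillator, so that distinct channels decohere instead of
    holding a constant phase difference forever; coupled oscillators inherit
    their driver's phase (diffusion and all), which leaves the pair's locking
    untouched.
    """

    channel: str
    frequency: float
    amplitude: float = 1.0
    initial_phase: float = 0.0
    coupled_to: Optional[CoupledTo] = None
    snr: float = math.inf
    phase_diffusion: float = 0.0
    diffusion_timescale: float = 0.25

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if self.phase_diffusion < 0:
            raise ValueError("phase_diffusion must be nonnegative")
        if isinstance(self.coupled_to, tuple):
            object.__setattr__(self, "coupled_to", CoupledTo(*self.coupled_to))


@dataclass
class SegmentedRecording:
    """Channels x samples block with sampling metadata.

    The raw input of the analysis pipeline.  ``data`` has one row per
    channel; ``fs`` is the sampling rate in Hz; ``labels`` are unique channel
    names; ``schedule`` optionally carries the stimulus events of the
    segment.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    schedule: Optional[StimulusSchedule] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
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
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def gen_stimulus_schedule(
    n_events: int,
    isi_bounds: tuple[float, float] = (1.2, 1.5),
    p_deviant: float = 0.2,
    seed: Optional[int] = None,
    first_onset: Optional[float] = None,
) -> StimulusSchedule:
    """Draw an oddball stimulus schedule.

    Inter-stimulus intervals are iid uniform on ``isi_bounds`` and event
    classes are iid Bernoulli with deviant probability ``p_deviant``
    (defaults: ISI uniform on 1.2-1.5 s, standard:deviant 0.8:0.2).  By
    default the first onset is itself an ISI draw from segment start;
    ``first_onset`` pins it (e.g. 0.0 for a stimulus at segment start).
    """
    if n_events < 1:
        raise ValueError("n_events must be positive")
    lo, hi = float(isi_bounds[0]), float(isi_bounds[1])
    if lo > hi:
        raise ValueError("isi_bounds must be ordered (low, high)")
    if not 0.0 <= p_deviant <= 1.0:
        raise ValueError("p_deviant must be in [0, 1]")
    rng = np.random.default_rng(seed)
    isis = rng.uniform(lo, hi, size=n_events)
    onsets = np.cumsum(isis)
    if first_onset is not None:
        onsets = onsets - onsets[0] + float(first_onset)
    classes = np.where(rng.random(n_events) < p_deviant, "deviant", "standard")
    return StimulusSchedule(onsets=onsets, classes=classes, isi_bounds=(lo, hi))


def _smooth_unit_noise(rng: np.random.Generator, n: int, sigma_samples: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian noise with ~sigma_samples correlation."""
    x = rng.standard_normal(n)
    if sigma_samples > 0:
        x = gaussian_filter1d(x, sigma_samples, mode="reflect")
        sd = x.std()
        if sd > 0:
            x = x / sd
    return x


def _resolve_phases(
    specs: Sequence[OscillatorSpec],
    fs: float,
    n_samples: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Instantaneous phase time course of every spec, honouring coupling.

    A coupled spec inherits its phase from the driver spec identified by
    (channel, frequency); drivers must themselves be resolvable (chains are
    allowed, cycles are not).
    """
    t = np.arange(n_samples) / fs
    by_key = {(s.channel, s.frequency): i for i, s in enumerate(specs)}
    phases: dict[int, np.ndarray] = {}
    resolving: set[int] = set()

    def resolve(i: int) -> np.ndarray:
        if i in phases:
            return phases[i]
        if i in resolving:
            raise ValueError("cyclic coupling among oscillator specs")
        resolving.add(i)
        s = specs[i]
        c = s.coupled_to
        if c is None:
            phi = 2.0 * np.pi * s.frequency * t + s.initial_phase
            if s.phase_diffusion > 0:
                phi = phi + s.phase_diffusion * _smooth_unit_noise(
                    rng, n_samples, s.diffusion_timescale * fs
                )
            phases[i] = phi
        else:
            key = (c.channel, c.frequency)
            if key not in by_key:
                raise ValueError(f"driver oscillator {key} not among the specs")
            nominal = c.m * c.frequency / c.n
            if not math.isclose(nominal, s.frequency, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    "coupled oscillator frequency inconsistent with n:m ratio: "
                    f"expected {nominal} Hz, spec says {s.frequency} Hz"
                )
            drv = resolve(by_key[key])
            lag = np.full(n_samples, c.phase_lag)
            if c.lag_jitter > 0:
                lag = lag + c.lag_jitter * _smooth_unit_noise(
                    rng, n_samples, c.jitter_timescale * fs
                )
            phases[i] = (c.m * drv + lag) / c.n
        resolving.discard(i)
        return phases[i]

    for i in range(len(specs)):
        resolve(i)
    return phases


def _noise_sd(spec: OscillatorSpec) -> float:
    power = spec.amplitude**2 / 2.0
    if math.isinf(spec.snr):
        return 0.0
    if spec.snr == 0.0:
        return math.sqrt(power)
    return math.sqrt(power / spec.snr)


def gen_coupled_oscillators(
    specs: Sequence[OscillatorSpec],
    fs: float = 250.0,
    duration: float = 10.0,
    seed: Optional[int] = None,
    labels: Optional[Sequence[str]] = None,
    schedule: Optional[StimulusSchedule] = None,
) -> SegmentedRecording:
    """Render oscillator specs into a multichannel recording.

    Each channel is the sum of its oscillators (``amplitude * cos(phase)``)
    plus white Gaussian noise at each spec's stated SNR.  Coupled specs obey
    ``n*phase_self - m*phase_driver = phase_lag`` exactly when
    ``lag_jitter == 0``.
    """
    if not specs:
        raise ValueError("at least one oscillator spec required")
    nyquist = fs / 2.0
    for s in specs:
        if s.frequency >= nyquist:
            raise ValueError(f"frequency {s.frequency} Hz >= Nyquist ({nyquist} Hz)")
    n_samples = int(round(fs * duration))
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = list(dict.fromkeys(s.channel for s in specs))
    else:
        labels = list(labels)
    idx = {lab: k for k, lab in enumerate(labels)}
    for s in specs:
        if s.channel not in idx:
            raise ValueError(f"spec channel {s.channel!r} missing from labels")

    phases = _resolve_phases(specs, fs, n_samples, rng)
    data = np.zeros((len(labels), n_samples))
    for i, s in enumerate(specs):
        row = idx[s.channel]
        if s.snr > 0:
            data[row] += s.amplitude * np.cos(phases[i])
        sd = _noise_sd(s)
        if sd > 0:
            data[row] += rng.normal(0.0, sd, n_samples)
    return SegmentedRecording(data=data, fs=fs, labels=labels, schedule=schedule)


def oddball_fixture_specs(
    n_pairs: int = 6,
    frequency: float = 10.0,
    snr: float = 20.0,
    amplitude: float = 1.0,
    phase_lag: float = np.pi / 8.0,
    phase_diffusion: float = 0.0,
) -> list[OscillatorSpec]:
    """Driver/follower oscillator pairs for stimulus-locked fixtures.

    ``n_pairs`` channel pairs (labels ``drvNN``/``folNN``), all at one
    frequency, each follower locked 1:1 to its driver at ``phase_lag``
    (pi/8 by default, the centre of the positive locking band).  Driver
    initial phases are spread by 2 pi / n_pairs so that every cross-pair
    constant lag falls outside the +/- pi/4 locking band (for n_pairs <= 8).
    Feed the result to :func:`gen_event_modulated_recording`.
    """
    specs = []
    for p in range(n_pairs):
        drv, fol = f"drv{p + 1:02d}", f"fol{p + 1:02d}"
        specs.append(
            OscillatorSpec(
                channel=drv,
                frequency=frequency,
                amplitude=amplitude,
                initial_phase=2.0 * np.pi * p / n_pairs,
                snr=snr,
                phase_diffusion=phase_diffusion,
            )
        )
        specs.append(
            OscillatorSpec(
                channel=fol,
                frequency=frequency,
                amplitude=amplitude,
                snr=snr,
                coupled_to=CoupledTo(drv, frequency, 1, 1, phase_lag),
            )
        )
    return specs


def _isi_codewords(n_classes: int, n_pairs: int) -> np.ndarray:
    """Boolean (n_classes x n_pairs) code matrix with well-separated rows.

    Rows/columns of a Hadamard matrix (first row/column dropped, as those are
    constant) give pairwise Hamming distances of about half the code length.
    """
    size = 1
    while size < max(n_classes, n_pairs) + 1:
        size *= 2
    h = hadamard(size)
    return h[1 : n_classes + 1, 1 : n_pairs + 1] > 0


def gen_event_modulated_recording(
    schedule: StimulusSchedule,
    base: Sequence[OscillatorSpec],
    effect_size: float,
    seed: Optional[int] = None,
    fs: float = 250.0,
    duration: float = 10.0,
    detune_hz: float = 0.8,
    decoherence_rate: float = 0.5,
) -> SegmentedRecording:
    """Recording whose directed coupling pattern encodes the ISI index.

    Every coupled spec in ``base`` defines a channel pair.  Within each
    inter-stimulus interval k the *sign* of the pair's phase lag is set by a
    fixed binary codeword unique to k (Hadamard rows), so the direction of
    the lag -- hence which node of the pair "sends" -- carries the class.
    ``effect_size`` in [0, 1] mixes the locked component with an independent
    unlocked alternative: 1 gives full locking to the class pattern, 0
    removes all schedule dependence (no class structure).

    The unlocked alternative drifts steadily: pair p is detuned by
    ``detune_hz * (1 + p // 2)`` Hz with alternating sign, so every pair of
    unlocked channels differs in frequency by at least ``detune_hz``.  A
    steady relative drift sweeps the phase difference uniformly through the
    locking band, never lingering there, which keeps the windowed coupling of
    unlocked channels below a chance-calibrated network threshold in *every*
    window.  A mild phase random walk (``decoherence_rate`` rad/sqrt(s))
    jitters the band crossings on top.
    """
    if effect_size < 0 or effect_size > 1:
        raise ValueError("effect_size must lie in [0, 1]")
    if schedule.onsets[-1] >= duration:
        raise ValueError("schedule extends beyond the recording duration")
    n_samples = int(round(fs * duration))
    t = np.arange(n_samples) / fs
    rng = np.random.default_rng(seed)

    coupled = [s for s in base if s.coupled_to is not None]
    labels = list(dict.fromkeys(s.channel for s in base))
    n_classes = schedule.n_events
    code = _isi_codewords(n_classes, max(len(coupled), 1))

    # ISI index per sample (samples before the first onset belong to class 0)
    isi_idx = np.clip(np.searchsorted(schedule.onsets, t, side="right") - 1, 0, None)

    # Driver (uncoupled) phases are rendered once, shared by their followers.
    plain = [replace(s, coupled_to=None) for s in base if s.coupled_to is None]
    drv_phases = _resolve_phases(plain, fs, n_samples, rng)
    drv_by_key = {(s.channel, s.frequency): drv_phases[i] for i, s in enumerate(plain)}

    data = np.zeros((len(labels), n_samples))
    idx = {lab: k for k, lab in enumerate(labels)}
    for i, s in enumerate(plain):
        if s.snr > 0:
            data[idx[s.channel]] += s.amplitude * np.cos(drv_phases[i])
        sd = _noise_sd(s)
        if sd > 0:
            data[idx[s.channel]] += rng.normal(0.0, sd, n_samples)

    for p, s in enumerate(coupled):
        c = s.coupled_to
        key = (c.channel, c.frequency)
        if key not in drv_by_key:
            raise ValueError(f"driver oscillator {key} not among the base specs")
        drv = drv_by_key[key]
        lag_mag = abs(c.phase_lag) if c.phase_lag else np.pi / 8.0
        sign = np.where(code[isi_idx, p], 1.0, -1.0)
        # soften the lag flips over ~20 ms so the signal stays band-limited
        sign = gaussian_filter1d(sign, 0.02 * fs, mode="nearest")
        locked = (c.m * drv + sign * lag_mag) / c.n
        detune = detune_hz * (1.0 + p // 2) * (1.0 if p % 2 == 0 else -1.0)
        walk = np.cumsum(rng.normal(0.0, decoherence_rate / np.sqrt(fs), n_samples))
        free = (
            2.0 * np.pi * (s.frequency + detune) * t
            + rng.uniform(0.0, 2.0 * np.pi)
            + walk
        )
        x = s.amplitude * (
            effect_size * np.cos(locked) + (1.0 - effect_size) * np.cos(free)
        )
        data[idx[s.channel]] += x
        sd = _noise_sd(s)
        if sd > 0:
            data[idx[s.channel]] += rng.normal(0.0, sd, n_samples)

    return SegmentedRecording(data=data, fs=fs, labels=labels, schedule=schedule)
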