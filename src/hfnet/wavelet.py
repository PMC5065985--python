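"""Complex Morlet (Gabor) transform and instantaneous-phase extraction.

The analytic Morlet wavelet used here is

    psi(t) = (sigma^2 * pi)^(-1/4) * exp(-t^2 / (2 sigma^2)) * exp(j 2 pi f t)

i.e. a unit-energy Gaussian envelope around the central frequency ``f``.
The envelope width follows a constant-cycles rule sigma = n_cycles / (2 pi f)
by default (a fixed sigma in seconds can be requested instead).  Wavelet
coefficients are evaluated on a decimated grid (every ``time_step`` raw
samples; 5 samples at 250 Hz gives the 20-ms phase grid used throughout the
toolkit), and the instantaneous phase is the complex argument of the
coefficient, wrapped to (-pi, pi].

Samples whose wavelet support (truncated at 4 sigma) extends past the signal
edges are flagged invalid per frequency; nothing is dropped here, the flags
travel with the phase tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import fftconvolve

from .synthetic import SegmentedRecording

__all__ = [
    "MorletParams",
    "MorletCoefficients",
    "PhaseTensor",
    "morlet_transform",
    "instantaneous_phase",
    "wrap_phase",
]

#: analysis grid of the full transform (0.125-Hz steps up to 20 Hz)
DEFAULT_FREQS = np.arange(0.125, 20.0 + 1e-9, 0.125)
#: the ten frequencies of interest used for network construction
DEFAULT_FOIS = np.arange(2.0, 20.0 + 1e-9, 2.0)

_SUPPORT_SIGMAS = 4.0  # kernel truncation, in units of sigma


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


@dataclass(frozen=True)
class MorletParams:
    """Morlet transform configuration.

    ``freqs`` is the ascending frequency grid in Hz; ``n_cycles`` sets the
    envelope SD via sigma = n_cycles / (2 pi f) unless a fixed ``sigma`` (in
    seconds) is given; ``time_step`` is the decimation factor of the output
    grid in raw samples.
    """

    freqs: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    n_cycles: float = 5.0
    sigma: Optional[float] = None
    time_step: int = 5

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "freqs", freqs)
        if np.any(freqs < 0) or np.any(np.diff(freqs) <= 0) and freqs.size > 1:
            raise ValueError("freqs must be ascending and nonnegative")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.time_step < 1 or self.time_step != int(self.time_step):
            raise ValueError("time_step must be a positive integer")

    def sigma_at(self, f: float) -> float:
        """Envelope SD in seconds at central frequency ``f``."""
        if self.sigma is not None:
            return self.sigma
        if f <= 0:
            raise ValueError("constant-cycles sigma undefined at f <= 0")
        return self.n_cycles / (2.0 * np.pi * f)


@dataclass
class MorletCoefficients:
    """Complex wavelet coefficients on the decimated time grid.

    ``coeffs`` has shape (channels, freqs, phase_samples); ``valid`` flags,
    per frequency and phase sample, whether the wavelet support lay fully
    inside the signal.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    fs_phase: float
    time_step: int
    valid: np.ndarray
    labels: list[str]


@dataclass
class PhaseTensor:
    """Instantaneous phase per channel x frequency x phase sample.

    Values lie in (-pi, pi].  ``undefined`` flags zero-magnitude coefficients
    whose argument is not defined (emitted as phase 0).
    """

    phase: np.ndarray
    freqs: np.ndarray
    fs_phase: float
    valid: np.ndarray
    labels: list[str]
    undefined: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_phase_samples(self) -> int:
        return self.phase.shape[2]

    def channel_index(self, channel: Union[int, str]) -> int:
        if isinstance(channel, str):
            return self.labels.index(channel)
        return int(channel)

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if not np.isclose(self.freqs[i], f):
            raise ValueError(f"frequency {f} Hz not on the analysis grid")
        return i


def _kernel(f: float, sigma: float, fs: float) -> np.ndarray:
    half = int(np.ceil(_SUPPORT_SIGMAS * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = (sigma**2 * np.pi) ** -0.25 * np.exp(-(t**2) / (2.0 * sigma**2))
    return envelope * np.exp(2j * np.pi * f * t)


def morlet_transform(
    rec: SegmentedRecording, params: Optional[MorletParams] = None
) -> MorletCoefficients:
    """Morlet coefficients of every channel at every grid frequency.

    The coefficient at (channel, f, t) is the correlation of the channel with
    the unit-energy analytic Morlet centred at ``f``, evaluated every
    ``time_step`` raw samples.  For a symmetric kernel this equals the
    convolution used here.  Raises if any frequency reaches Nyquist or the
    signal is shorter than one wavelet support.
    """
    params = params or MorletParams()
    if np.max(params.freqs) >= rec.fs / 2.0:
        raise ValueError("max analysis frequency must stay below Nyquist")
    n = rec.n_samples
    step = params.time_step
    out_idx = np.arange(0, n, step)
    n_out = out_idx.size  # == floor((n-1)/step) + 1
    coeffs = np.empty((rec.n_channels, params.freqs.size, n_out), dtype=complex)
    valid = np.empty((params.freqs.size, n_out), dtype=bool)
    for k, f in enumerate(params.freqs):
        sigma = params.sigma_at(f)
        kern = _kernel(f, sigma, rec.fs)
        if kern.size > n:
            raise ValueError(
                f"signal ({n} samples) shorter than wavelet support at {f} Hz "
                f"({kern.size} samples)"
            )
        full = fftconvolve(rec.data, kern[None, :], mode="same", axes=1)
        coeffs[:, k, :] = full[:, out_idx]
        half = (kern.size - 1) // 2
        valid[k] = (out_idx >= half) & (out_idx <= n - 1 - half)
    return MorletCoefficients(
        coeffs=coeffs,
        freqs=params.freqs.copy(),
        fs_phase=rec.fs / step,
        time_step=step,
        valid=valid,
        labels=list(rec.labels),
    )


def instantaneous_phase(
    coeffs: Union[MorletCoefficients, np.ndarray]
) -> Union[PhaseTensor, np.ndarray]:
    """Element-wise complex argument, wrapped to (-pi, pi].

    Zero-magnitude coefficients have no defined argument; they are emitted as
    phase 0 and flagged in ``undefined``.  A bare ndarray input returns the
    bare phase array.
    """
    arr = coeffs.coeffs if isinstance(coeffs, MorletCoefficients) else np.asarray(coeffs)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wavelet coefficients must be finite")
    undefined = arr == 0
    phase = np.angle(arr)
    phase = np.where(phase == -np.pi, np.pi, phase)  # keep the (-pi, pi] convention
    phase = np.where(undefined, 0.0, phase)
    if not isinstance(coeffs, MorletCoefficients):
        return phase
    return PhaseTensor(
        phase=phase,
        freqs=coeffs.freqs,
        fs_phase=coeffs.fs_phase,
        valid=coeffs.valid,
        labels=coeffs.labels,
        undefined=undefined,
    )


def recording_phases(
    rec: SegmentedRecording,
    freqs: Optional[Sequence[float]] = None,
    n_cycles: float = 5.0,
    time_step: int = 5,
) -> PhaseTensor:
    """Convenience: Morlet transform + phase extraction in one call."""
    f = np.asarray(freqs, dtype=float) if freqs is not None else DEFAULT_FOIS.copy()
    params = MorletParams(freqs=f, n_cycles=n_cycles, time_step=time_step)
    return instantaneous_phase(morlet_transform(rec, params))
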