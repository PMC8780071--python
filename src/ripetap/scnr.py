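"""Single-channel noise reduction (SCNR) by spectral subtraction.

The denoiser estimates a per-bin noise floor by minimum tracking over a
trailing window of STFT frames and attenuates each time-frequency cell with
the gain

    G[k, n] = max( ((P[k, n] - beta * PN[k, n]) / P[k, n])**alpha , G_min )

where ``P`` is the bin energy (squared STFT magnitude), ``PN`` the tracked
noise floor, ``beta`` an oversubtraction factor, ``alpha`` the gain exponent
and ``G_min = 10**(-DB_red / 20)`` a gain floor that limits the per-bin
attenuation to ``DB_red`` decibels, suppressing musical-noise artefacts.
Defaults alpha=9, beta=45, DB_red=25 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import get_window

from .signal import TimeSignal

__all__ = [
    "ScnrConfig",
    "StftGrid",
    "GainMatrix",
    "stft_power",
    "noise_floor",
    "compute_gain",
    "apply_scnr",
]


@dataclass(frozen=True)
class ScnrConfig:
    """Parameters of the spectral-subtraction gain filter.

    alpha
        Gain exponent; larger values sharpen the transition between kept
        and suppressed cells.
    beta
        Oversubtraction factor applied to the noise-floor estimate.
    db_red
        Maximum per-bin attenuation in dB; sets the gain floor
        ``g_min = 10**(-db_red/20)``.
    noise_window_frames
        Trailing-window length L (frames) for minimum tracking; the floor
        at frame n is the minimum energy over frames [n-L, n].
    """

    alpha: float = 9.0
    beta: float = 45.0
    db_red: float = 25.0
    noise_window_frames: int = 20
    frame_length: int = 1024
    hop_length: int = 256
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.db_red <= 0:
            raise ValueError("db_red must be positive")
        if self.noise_window_frames < 1:
            raise ValueError("noise_window_frames must be >= 1")
        if self.frame_length < 2 or not 0 < self.hop_length <= self.frame_length:
            raise ValueError("invalid frame_length / hop_length")

    @property
    def g_min(self) -> float:
        """Gain floor 10**(-db_red/20); ~0.0562 at the default 25 dB."""
        return float(10.0 ** (-self.db_red / 20.0))


@dataclass
class StftGrid:
    """Complex STFT coefficients and their bin energies on one grid."""

    complex_frames: np.ndarray  # [freq bin, frame]
    power: np.ndarray           # squared magnitudes, same shape
    frame_length: int
    hop_length: int
    window_name: str
    sample_rate: int
    n_samples: int
    _sft: ShortTimeFFT = field(repr=False, compare=False, default=None)
    _p_min: int = field(repr=False, default=0)

    def frame_start(self, col: int) -> int:
        """Sample index where the analysis window of column ``col`` begins
        (may be negative for boundary frames, which are zero-padded)."""
        return (col + self._p_min) * self.hop_length - self._sft.m_num_mid

    def inverse(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        """Overlap-add inverse; reconstructs the analysed span."""
        coef = self.complex_frames if coefficients is None else coefficients
        return self._sft.istft(coef, k1=self.n_samples)


@dataclass(frozen=True)
class GainMatrix:
    """Per-cell spectral gains, all within [g_min, 1]."""

    gains: np.ndarray
    g_min: float


def _make_sft(config: ScnrConfig, sample_rate: int) -> ShortTimeFFT:
    win = get_window(config.window, config.frame_length, fftbins=True)
    return ShortTimeFFT(win, hop=config.hop_length, fs=sample_rate,
                        fft_mode="onesided")


def stft_power(signal: TimeSignal, config: ScnrConfig) -> StftGrid:
    """Short-time Fourier transform plus per-cell energies P[k, n]."""
    if len(signal) < config.frame_length:
        raise ValueError(
            f"signal of {len(signal)} samples is shorter than one frame "
            f"({config.frame_length} samples)"
        )
    sft = _make_sft(config, signal.sample_rate)
    coef = sft.stft(signal.samples)
    return StftGrid(
        complex_frames=coef,
        power=np.abs(coef) ** 2,
        frame_length=config.frame_length,
        hop_length=config.hop_length,
        window_name=config.window,
        sample_rate=signal.sample_rate,
        n_samples=len(signal),
        _sft=sft,
        _p_min=sft.p_min,
    )


def noise_floor(power: np.ndarray, window_frames: int) -> np.ndarray:
    """Minimum-statistics noise estimate PN[k, n] = min P[k, n-L .. n].

    The trailing window is clipped at the first frame, so early frames use
    whatever history exists.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    power = np.asarray(power, dtype=np.float64)
    if power.ndim != 2:
        raise ValueError("power must be a 2-D [bin, frame] matrix")
    L = window_frames
    # replicate-padding the first column is equivalent to clipping the window
    padded = np.concatenate([np.repeat(power[:, :1], L, axis=1), power], axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(padded, L + 1, axis=1)
    return windows.min(axis=-1)


def compute_gain(power: np.ndarray, noise: np.ndarray,
                 config: ScnrConfig) -> GainMatrix:
    """Spectral-subtraction gain with the base clamped to [0, 1] before the
    exponent; zero-energy cells receive the floor directly."""
    power = np.asarray(power, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if power.shape != noise.shape:
        raise ValueError("power and noise shapes differ")
    g_min = config.g_min
    with np.errstate(divide="ignore", invalid="ignore"):
        base = (power - config.beta * noise) / power
    base = np.clip(base, 0.0, 1.0)
    base[power <= 0.0] = 0.0
    gains = np.maximum(base**config.alpha, g_min)
    return GainMatrix(gains=gains, g_min=g_min)


def apply_scnr(signal: TimeSignal, config: ScnrConfig | None = None) -> TimeSignal:
    """Denoise a recording: STFT, noise-floor tracking, gain, inverse."""
    config = config or ScnrConfig()
    grid = stft_power(signal, config)
    floor = noise_floor(grid.power, config.noise_window_frames)
    gain = compute_gain(grid.power, floor, config)
    cleaned = grid.inverse(grid.complex_frames * gain.gains)
    return TimeSignal(cleaned, sample_rate=signal.sample_rate)
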