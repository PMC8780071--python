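"""Time-domain acoustic signals and WAV file I/O.

A tap recording is a short mono waveform; amplitudes are kept as floats
normalised to [-1, 1] regardless of the on-disk sample format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["TimeSignal", "read_wav", "write_wav"]

DEFAULT_SAMPLE_RATE = 44_100


@dataclass(frozen=True)
class TimeSignal:
    """One mono recording: float samples plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate

    def energy(self) -> float:
        return float(np.sum(self.samples**2))


def read_wav(path: str | Path) -> TimeSignal:
    """Read a mono WAV file (PCM 16-bit or float32) into a TimeSignal.

    PCM samples are rescaled to [-1, 1); float data is taken as-is.
    Multi-channel files are rejected.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return TimeSignal(samples, sample_rate=int(rate))


def write_wav(path: str | Path, signal: TimeSignal, *, fmt: str = "float32") -> None:
    """Write a TimeSignal to disk as mono WAV (``fmt``: 'float32' or 'pcm16')."""
    if fmt == "float32":
        data = signal.samples.astype(np.float32)
    elif fmt == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise ValueError(f"unknown WAV format {fmt!r}")
    wavfile.write(str(path), signal.sample_rate, data)
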