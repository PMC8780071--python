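"""From denoised tap recordings to model-ready spectral features.

Pipeline: align each waveform on its absolute maximum, crop a fixed-length
region of interest, convert to one-sided amplitude/phase spectra,
standardise the spectra with training-split statistics, min-max normalise
the auxiliary covariates (weight, temperature, humidity) and one-hot encode
the knock zone. Splitting is grouped by fruit so no fruit contributes to
more than one of train/test/validation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal import TimeSignal, read_wav

__all__ = [
    "Measurement",
    "SpectralFeatures",
    "FeatureDataset",
    "DatasetSplit",
    "Standardiser",
    "align_to_max",
    "crop_roi",
    "to_spectrum",
    "augment_flips",
    "split_dataset",
    "label_from_shelf_life",
    "build_features",
    "load_metadata_csv",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = (
    "fruit_id", "wav_path", "shelf_life_days", "zone",
    "weight_g", "temp_c", "humidity_pct", "label",
)

N_ZONES = 6
N_CLASSES = 4

DEFAULT_CROP_PRE = 128
DEFAULT_CROP_POST = 2048 - 128


def label_from_shelf_life(days: int) -> int:
    """Ripeness class by shelf-life week: class = min(4, days // 7 + 1)."""
    if days < 0:
        raise ValueError("shelf life must be non-negative")
    return min(N_CLASSES, days // 7 + 1)


@dataclass(frozen=True)
class Measurement:
    """One tap recording with its metadata and ripeness label."""

    signal: TimeSignal
    fruit_id: str
    shelf_life_days: int
    zone: int
    weight: float
    temperature: float
    humidity: float
    label: int

    def __post_init__(self) -> None:
        if not 1 <= self.zone <= N_ZONES:
            raise ValueError(f"zone must be in 1..{N_ZONES}, got {self.zone}")
        if not 1 <= self.label <= N_CLASSES:
            raise ValueError(f"label must be in 1..{N_CLASSES}, got {self.label}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class SpectralFeatures:
    """Standardised amplitude/phase spectra plus normalised covariates."""

    amplitude: np.ndarray
    phase: np.ndarray
    aux: np.ndarray


def align_to_max(signal: TimeSignal, target_index: int = DEFAULT_CROP_PRE) -> TimeSignal:
    """Shift the waveform (zero-padded, non-circular) so its absolute
    maximum lands on ``target_index``; ties break to the earliest sample."""
    x = signal.samples
    peak = float(np.max(np.abs(x)))
    if peak == 0.0:
        raise ValueError("cannot align an all-zero signal")
    idx = int(np.argmax(np.abs(x) == peak))  # earliest maximum
    shift = target_index - idx
    out = np.zeros_like(x)
    if shift > 0:
        out[shift:] = x[: len(x) - shift]
    elif shift < 0:
        out[: len(x) + shift] = x[-shift:]
    else:
        out = x.copy()
    return TimeSignal(out, sample_rate=signal.sample_rate)


def crop_roi(signal: TimeSignal, pre_samples: int = DEFAULT_CROP_PRE,
             post_samples: int = DEFAULT_CROP_POST,
             center_index: int | None = None) -> TimeSignal:
    """Fixed-length window of ``pre + post`` samples around the aligned
    maximum (``center_index`` defaults to ``pre_samples``, the alignment
    target); out-of-range parts are zero-padded."""
    if pre_samples < 0 or post_samples <= 0:
        raise ValueError("pre_samples must be >= 0 and post_samples > 0")
    n = len(signal)
    center = pre_samples if center_index is None else center_index
    start = center - pre_samples
    length = pre_samples + post_samples
    out = np.zeros(length)
    src_lo = max(start, 0)
    src_hi = min(start + length, n)
    if src_lo > start or src_hi < start + length:
        warnings.warn("crop window exceeds the signal; zero-padded",
                      stacklevel=2)
    if src_lo < src_hi:
        out[src_lo - start: src_hi - start] = signal.samples[src_lo:src_hi]
    return TimeSignal(out, sample_rate=signal.sample_rate)


def to_spectrum(signal: TimeSignal) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitudes and principal phases (length n//2 + 1)."""
    spec = np.fft.rfft(signal.samples)
    return np.abs(spec), np.angle(spec)


def augment_flips(measurements: Sequence[Measurement], *, vertical: bool = True,
                  horizontal: bool = True) -> list[Measurement]:
    """Waveform-level augmentation: amplitude negation ('vertical') and
    time reversal ('horizontal'), the 1-D analogues of image flips. Labels
    and covariates are copied unchanged; with both flips enabled each
    measurement yields 4 variants."""
    out: list[Measurement] = []
    for m in measurements:
        variants = [m.signal.samples]
        if vertical:
            variants.append(-m.signal.samples)
        if horizontal:
            variants.append(m.signal.samples[::-1])
        if vertical and horizontal:
            variants.append(-m.signal.samples[::-1])
        for v in variants:
            out.append(replace(m, signal=TimeSignal(v, m.signal.sample_rate)))
    return out


@dataclass
class FeatureDataset:
    """Column-major feature arrays for a set of measurements."""

    amplitude: np.ndarray   # (n, n_bins)
    phase: np.ndarray       # (n, n_bins)
    aux: np.ndarray         # (n, n_aux)
    labels: np.ndarray      # (n,), classes 1..4
    fruit_ids: np.ndarray   # (n,) str

    def __len__(self) -> int:
        return self.labels.size

    def take(self, indices: np.ndarray) -> "FeatureDataset":
        idx = np.asarray(indices)
        return FeatureDataset(self.amplitude[idx], self.phase[idx],
                              self.aux[idx], self.labels[idx],
                              self.fruit_ids[idx])


@dataclass
class DatasetSplit:
    train: FeatureDataset
    test: FeatureDataset
    validation: FeatureDataset


class Standardiser:
    """Per-component standardisation of spectra, min-max scaling of the
    scalar covariates and one-hot zone encoding.

    Statistics are estimated once from the training split (``fit``) and
    applied unchanged everywhere else, so held-out data never leaks into
    the normalisation.
    """

    EPS = 1e-8

    def __init__(self) -> None:
        self.fitted = False
        self.amp_mean: np.ndarray | None = None
        self.amp_std: np.ndarray | None = None
        self.phase_mean: np.ndarray | None = None
        self.phase_std: np.ndarray | None = None
        self.aux_min: np.ndarray | None = None
        self.aux_max: np.ndarray | None = None

    def fit(self, amplitude: np.ndarray, phase: np.ndarray,
            aux: np.ndarray) -> "Standardiser":
        self.amp_mean = amplitude.mean(axis=0)
        self.amp_std = np.maximum(amplitude.std(axis=0), self.EPS)
        self.phase_mean = phase.mean(axis=0)
        self.phase_std = np.maximum(phase.std(axis=0), self.EPS)
        self.aux_min = aux.min(axis=0)
        self.aux_max = aux.max(axis=0)
        self.fitted = True
        return self

    def transform(self, amplitude: np.ndarray, phase: np.ndarray,
                  aux: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.fitted:
            raise RuntimeError("Standardiser.transform called before fit")
        amp = (amplitude - self.amp_mean) / self.amp_std
        ph = (phase - self.phase_mean) / self.phase_std
        span = np.maximum(self.aux_max - self.aux_min, self.EPS)
        aux_scaled = np.clip((aux - self.aux_min) / span, 0.0, 1.0)
        return amp, ph, aux_scaled

    def to_json(self) -> str:
        payload = {k: np.asarray(v).tolist()
                   for k, v in self.__dict__.items() if k != "fitted"}
        payload["fitted"] = self.fitted
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Standardiser":
        data = json.loads(text)
        obj = cls()
        for key, value in data.items():
            setattr(obj, key, value if key == "fitted" else np.asarray(value))
        return obj


def encode_zone(zone: np.ndarray) -> np.ndarray:
    """One-hot over the six knock zones."""
    onehot = np.zeros((len(zone), N_ZONES))
    onehot[np.arange(len(zone)), np.asarray(zone) - 1] = 1.0
    return onehot


def split_dataset(measurements: Sequence[Measurement],
                  fractions: tuple[float, float, float] = (0.60, 0.25, 0.15),
                  seed: int = 0) -> tuple[list[Measurement], list[Measurement], list[Measurement]]:
    """Grouped train/test/validation split: each fruit's measurements land
    in exactly one subset. Fruits are shuffled deterministically and cut at
    the cumulative-count boundaries closest to the target fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    fruit_ids = sorted({m.fruit_id for m in measurements})
    if len(fruit_ids) < 3:
        raise ValueError("need at least 3 fruits for a 3-way grouped split")
    rng = np.random.default_rng(seed)
    order = [fruit_ids[i] for i in rng.permutation(len(fruit_ids))]
    counts = {fid: 0 for fid in fruit_ids}
    for m in measurements:
        counts[m.fruit_id] += 1
    total = len(measurements)

    cumulative = np.cumsum([counts[f] for f in order]) / total
    # cut after the fruit whose cumulative count is nearest each boundary
    b1 = int(np.argmin(np.abs(cumulative - fractions[0]))) + 1
    b2 = int(np.argmin(np.abs(cumulative - (fractions[0] + fractions[1])))) + 1
    b1 = min(b1, len(order) - 2)
    b2 = min(max(b2, b1 + 1), len(order) - 1)
    groups = (set(order[:b1]), set(order[b1:b2]), set(order[b2:]))
    subsets: tuple[list, list, list] = ([], [], [])
    for m in measurements:
        for g, s in zip(groups, subsets):
            if m.fruit_id in g:
                s.append(m)
                break
    return subsets


def _features_of(measurements: Sequence[Measurement],
                 pre: int, post: int, n_bins: int | None) -> tuple[np.ndarray, ...]:
    amps, phases, aux, labels, fids = [], [], [], [], []
    for m in measurements:
        aligned = align_to_max(m.signal, target_index=pre)
        cropped = crop_roi(aligned, pre, post)
        a, p = to_spectrum(cropped)
        if n_bins is not None:
            a, p = a[:n_bins], p[:n_bins]
        amps.append(a)
        phases.append(p)
        aux.append([m.weight, m.temperature, m.humidity])
        labels.append(m.label)
        fids.append(m.fruit_id)
    zones = encode_zone(np.array([m.zone for m in measurements]))
    return (np.array(amps), np.array(phases), np.array(aux),
            zones, np.array(labels), np.array(fids))


def build_features(train: Sequence[Measurement], test: Sequence[Measurement],
                   validation: Sequence[Measurement],
                   pre_samples: int = DEFAULT_CROP_PRE,
                   post_samples: int = DEFAULT_CROP_POST,
                   max_freq: float | None = None,
                   ) -> tuple[DatasetSplit, Standardiser]:
    """Align/crop/transform all splits; fit the standardiser on train only.

    ``max_freq`` (Hz) truncates the spectra to the informative band — the
    frequency-axis part of cropping to the region of interest; tap
    resonances live far below Nyquist, so the discarded bins are noise.
    The one-hot zone block is appended to the scaled covariates, giving
    aux vectors of length 9 (weight, temperature, humidity + 6 zones).
    """
    n_bins = None
    if max_freq is not None:
        rate = train[0].signal.sample_rate if train else 44_100
        n_fft = pre_samples + post_samples
        n_bins = max(1, min(int(max_freq * n_fft / rate) + 1, n_fft // 2 + 1))
    std = Standardiser()
    datasets = []
    for i, subset in enumerate((train, test, validation)):
        amp, ph, aux, zones, labels, fids = _features_of(
            subset, pre_samples, post_samples, n_bins)
        if i == 0:
            std.fit(amp, ph, aux)
        amp, ph, aux = std.transform(amp, ph, aux)
        datasets.append(FeatureDataset(amp, ph, np.hstack([aux, zones]),
                                       labels, fids))
    return DatasetSplit(*datasets), std


def load_metadata_csv(path: str | Path, *, load_audio: bool = True
                      ) -> list[Measurement]:
    """Read the metadata table (columns ``fruit_id, wav_path,
    shelf_life_days, zone, weight_g, temp_c, humidity_pct, label``) and the
    WAV files it references, resolved relative to the CSV location."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata CSV not found: {path}")
    measurements = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            signal = (read_wav(path.parent / row["wav_path"]) if load_audio
                      else TimeSignal(np.zeros(1), 1))
            measurements.append(Measurement(
                signal=signal,
                fruit_id=row["fruit_id"],
                shelf_life_days=int(row["shelf_life_days"]),
                zone=int(row["zone"]),
                weight=float(row["weight_g"]),
                temperature=float(row["temp_c"]),
                humidity=float(row["humidity_pct"]),
                label=int(row["label"]),
            ))
    return measurements
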